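"""Relaxed mean-field forward model (rMFM).

Each cortical region carries a synaptic gating variable S_i in [0, 1] obeying

    dS_i = [-S_i/tau_s + (1 - S_i) * gamma * H(x_i)] dt + sigma dW_i
    x_i  = w_i * J * S_i + G * J * sum_j C_ij S_j + I_i
    H(x) = (a*x - b) / (1 - exp(-d*(a*x - b)))

with per-region recurrent strength w_i and subcortical input I_i free
("relaxed" relative to the homogeneous mean-field model), a global coupling G
scaling the structural connectome C, and additive noise of amplitude sigma.
Gating activity drives an independent Balloon-Windkessel hemodynamic model per
region, whose BOLD output is correlated pairwise to give a simulated FC.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal

from . import _kernels
from .connectome import (
    BOLDSeries,
    FunctionalConnectome,
    StructuralConnectome,
    compute_fc,
)
from .errors import AlignmentError, DivergenceError, InvalidArgumentError

logger = logging.getLogger(__name__)

#: default initial gating state (low-activity branch)
_S_INIT = 0.1


def _load_constants() -> dict:
    text = (importlib.resources.files("braindyn") / "constants.yaml").read_text()
    return yaml.safe_load(text)


_CONSTANTS = _load_constants()


@dataclass(frozen=True)
class NeuralKinetics:
    """Constants of the reduced Wong-Wang population transfer and gating kinetics."""

    a: float
    b: float
    d: float
    gamma_kinetic: float
    tau_s: float
    J: float

    def __post_init__(self):
        for name in ("a", "b", "d", "gamma_kinetic", "tau_s", "J"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"kinetic constant {name} must be > 0")

    @classmethod
    def default(cls) -> "NeuralKinetics":
        return cls(**_CONSTANTS["kinetics"])


@dataclass(frozen=True)
class HemodynamicConstants:
    """Balloon-Windkessel constants (Friston 2003 lineage, 1.5T BOLD coefficients)."""

    kappa: float
    gamma_h: float
    tau_h: float
    alpha_g: float
    rho: float
    V0: float
    k1: float
    k2: float
    k3: float

    def __post_init__(self):
        for name in ("kappa", "gamma_h", "tau_h", "alpha_g", "rho", "V0", "k1", "k2", "k3"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"hemodynamic constant {name} must be > 0")
        if not 0 < self.alpha_g < 1:
            raise InvalidArgumentError("alpha_g must lie in (0, 1)")
        if not 0 < self.rho < 1:
            raise InvalidArgumentError("rho must lie in (0, 1)")

    @classmethod
    def default(cls) -> "HemodynamicConstants":
        return cls(**_CONSTANTS["hemodynamics"])


@dataclass
class RMFMParameters:
    """Per-region recurrent strengths w and inputs I, global coupling G, noise sigma."""

    w: np.ndarray
    I: np.ndarray
    G: float
    sigma: float
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        self.I = np.atleast_1d(np.asarray(self.I, dtype=float))
        if self.w.shape != self.I.shape or self.w.ndim != 1:
            raise AlignmentError("w and I must be 1-d vectors of equal length")
        if np.any(self.w < 0):
            raise InvalidArgumentError("recurrent strengths w must be >= 0")
        if self.G < 0:
            raise InvalidArgumentError("global coupling G must be >= 0")
        if self.sigma < 0:
            raise InvalidArgumentError("noise amplitude sigma must be >= 0")
        if self.region_labels is not None and len(self.region_labels) != self.w.size:
            raise AlignmentError("region label count does not match parameter length")

    @property
    def n_regions(self) -> int:
        return self.w.size

    def to_dict(self) -> dict:
        out = {"w": self.w.tolist(), "I": self.I.tolist(),
               "G": float(self.G), "sigma": float(self.sigma)}
        if self.region_labels is not None:
            out["labels"] = list(self.region_labels)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RMFMParameters":
        return cls(np.asarray(d["w"], float), np.asarray(d["I"], float),
                   float(d["G"]), float(d["sigma"]), d.get("labels"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RMFMParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings: step dt, total duration, discarded burn-in, output TR."""

    dt: float = 0.01
    duration: float = 984.0
    burn_in: float = 120.0
    tr_out: float = 2.0
    seed: int = 0
    #: neural steps per hemodynamic step (the Balloon-Windkessel time constants
    #: are ~1 s, so a coarser hemodynamic grid up to ~0.06 s is safe)
    bw_stride: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be > 0")
        if not 0 <= self.burn_in < self.duration:
            raise InvalidArgumentError("burn_in must lie in [0, duration)")
        if self.tr_out < self.dt:
            raise InvalidArgumentError("tr_out must be >= dt")
        if self.bw_stride < 1 or self.decim % self.bw_stride != 0:
            raise InvalidArgumentError(
                "bw_stride must be a positive divisor of tr_out/dt")

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "SimulationConfig":
        """Reduced-length preset used for screening runs and the test suite."""
        defaults = dict(dt=0.01, duration=76.0, burn_in=16.0, tr_out=0.6,
                        seed=seed, bw_stride=3)
        defaults.update(kw)
        return cls(**defaults)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def decim(self) -> int:
        return int(round(self.tr_out / self.dt))


@dataclass
class NeuralTrajectory:
    """Synaptic gating trajectory S[region, time] with its time axis in seconds."""

    S: np.ndarray
    t: np.ndarray
    clamp_events: int = 0
    n_updates: int = 0

    @property
    def clamp_fraction(self) -> float:
        return self.clamp_events / max(self.n_updates, 1)


def transfer_function(x, kinetics: NeuralKinetics | None = None):
    """Population firing rate H(x) = (a*x - b)/(1 - exp(-d*(a*x - b))).

    Total on the reals: the removable singularity at a*x = b evaluates to 1/d.
    """
    k = kinetics or NeuralKinetics.default()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("transfer_function input must be finite")
    u = k.a * x - k.b
    small = np.abs(u) < 1e-9
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 / k.d, safe / (1.0 - np.exp(-k.d * safe)))
    return out if out.ndim else float(out)


def total_input_current(S, sc: StructuralConnectome, params: RMFMParameters,
                        kinetics: NeuralKinetics | None = None) -> np.ndarray:
    """x_i = w_i*J*S_i + G*J*(C S)_i + I_i on a normalized SC."""
    k = kinetics or NeuralKinetics.default()
    S = np.asarray(S, dtype=float)
    if S.shape != (sc.n_regions,) or params.n_regions != sc.n_regions:
        raise AlignmentError("state/SC/parameter dimensions do not match")
    return params.w * k.J * S + params.G * k.J * (sc.weights @ S) + params.I


def neural_drift(S, sc: StructuralConnectome, params: RMFMParameters,
                 kinetics: NeuralKinetics | None = None) -> np.ndarray:
    """Deterministic drift dS/dt of the gating equations."""
    k = kinetics or NeuralKinetics.default()
    S = np.asarray(S, dtype=float)
    x = total_input_current(S, sc, params, k)
    return -S / k.tau_s + (1.0 - S) * k.gamma_kinetic * transfer_function(x, k)


def _prepare(sc, params, kinetics):
    if sc.n_regions != params.n_regions:
        raise AlignmentError("SC and parameter region counts differ")
    if not sc.normalized:
        logger.info("simulating on an un-normalized SC; G absorbs its scale")
    k = kinetics or NeuralKinetics.default()
    GC = np.ascontiguousarray(params.G * k.J * sc.weights)
    wJ = np.ascontiguousarray(params.w * k.J)
    I = np.ascontiguousarray(params.I)
    return k, GC, wJ, I


def _draw_noise(config: SimulationConfig, sigma: float, n: int,
                rng: np.random.Generator | None) -> np.ndarray:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if sigma == 0.0:
        return np.zeros((config.n_steps, n))
    return rng.standard_normal((config.n_steps, n)) * (sigma * np.sqrt(config.dt))


def integrate_neural(sc: StructuralConnectome, params: RMFMParameters,
                     kinetics: NeuralKinetics | None = None,
                     config: SimulationConfig | None = None,
                     noise: np.ndarray | None = None,
                     rng: np.random.Generator | None = None) -> NeuralTrajectory:
    """Euler-Maruyama integration of the gating equations; burn-in discarded.

    ``noise`` (n_steps x n, already scaled by sigma*sqrt(dt)) overrides the
    seeded draw; states are clamped to [0, 1] and clamp events counted.
    """
    config = config or SimulationConfig()
    k, GC, wJ, I = _prepare(sc, params, kinetics)
    n = sc.n_regions
    if noise is None:
        noise = _draw_noise(config, params.sigma, n, rng)
    S0 = np.full(n, _S_INIT)
    traj, clamps, bad = _kernels.integrate_gating(
        GC, wJ, I, config.dt, config.n_steps, noise,
        k.a, k.b, k.d, k.gamma_kinetic, k.tau_s, S0)
    if bad >= 0:
        raise DivergenceError(f"non-finite gating state at step {bad}", step=bad)
    t = (np.arange(config.n_steps) + 1) * config.dt
    keep = t > config.burn_in
    return NeuralTrajectory(S=traj[keep].T.copy(), t=t[keep],
                            clamp_events=int(clamps),
                            n_updates=config.n_steps * n)


def balloon_windkessel(z: np.ndarray, constants: HemodynamicConstants | None = None,
                       dt: float = 0.01, tr_out: float | None = None,
                       region_labels: list[str] | None = None) -> BOLDSeries:
    """Convert neural activity z[region, time] to BOLD via the Balloon-Windkessel ODEs.

    Each region is integrated independently from the resting state
    (s, f, v, q) = (0, 1, 1, 1); flow/volume are floored at 1e-6 with a warning.
    Output is decimated to ``tr_out`` (defaults to dt).
    """
    h = constants or HemodynamicConstants.default()
    z = np.ascontiguousarray(np.asarray(z, dtype=float))
    if z.ndim != 2:
        raise InvalidArgumentError("neural activity must be region x time")
    if not np.all(np.isfinite(z)):
        raise InvalidArgumentError("neural activity must be finite")
    s, f, v, q, floors = _kernels.balloon_windkessel_states(
        z, dt, h.kappa, h.gamma_h, h.tau_h, h.alpha_g, h.rho)
    if floors:
        warnings.warn(f"hemodynamic flow/volume floored {floors} times")
    y = h.V0 * (h.k1 * (1.0 - q) + h.k2 * (1.0 - q / v) + h.k3 * (1.0 - v))
    decim = 1 if tr_out is None else int(round(tr_out / dt))
    if decim < 1:
        raise InvalidArgumentError("tr_out must be >= dt")
    y = y[:, decim - 1::decim]
    return BOLDSeries(y, tr=dt * decim, region_labels=region_labels)


def hemodynamic_steady_state(z: float, constants: HemodynamicConstants | None = None):
    """Algebraic steady state (s, f, v, q, y) under constant neural drive z."""
    h = constants or HemodynamicConstants.default()
    s = 0.0
    f = 1.0 + z / h.gamma_h
    if f <= 0:
        raise InvalidArgumentError("steady-state flow is non-positive for this drive")
    v = f ** h.alpha_g
    E = 1.0 - (1.0 - h.rho) ** (1.0 / f)
    q = (f / h.rho) * E * v ** (1.0 - 1.0 / h.alpha_g)
    y = h.V0 * (h.k1 * (1.0 - q) + h.k2 * (1.0 - q / v) + h.k3 * (1.0 - v))
    return s, f, v, q, y


def transfer_function_derivative(x, kinetics: NeuralKinetics | None = None):
    """dH/dx of the population transfer function (chain rule through u = a*x - b)."""
    k = kinetics or NeuralKinetics.default()
    u = k.a * np.asarray(x, dtype=float) - k.b
    small = np.abs(u) < 1e-6
    safe = np.where(small, 1.0, u)
    e = np.exp(-k.d * safe)
    dHdu = np.where(small, 0.5, (1.0 - e * (1.0 + k.d * safe)) / (1.0 - e) ** 2)
    return k.a * dHdu


def drift_jacobian(S, sc: StructuralConnectome, params: RMFMParameters,
                   kinetics: NeuralKinetics | None = None) -> np.ndarray:
    """Jacobian dF/dS of the deterministic gating drift at state S."""
    k = kinetics or NeuralKinetics.default()
    S = np.asarray(S, dtype=float)
    x = total_input_current(S, sc, params, k)
    H = transfer_function(x, k)
    dHdx = transfer_function_derivative(x, k)
    gain = (1.0 - S) * k.gamma_kinetic * dHdx
    A = gain[:, None] * (params.G * k.J * sc.weights)
    np.fill_diagonal(A, -1.0 / k.tau_s - k.gamma_kinetic * H
                     + gain * params.w * k.J)
    return A


def find_stable_fixed_point(sc: StructuralConnectome, params: RMFMParameters,
                            kinetics: NeuralKinetics | None = None,
                            S_init: np.ndarray | None = None,
                            relax_time: float = 20.0,
                            relax_dt: float = 0.01) -> np.ndarray | None:
    """Fixed point reachable from the standard initial state (or a warm start).

    Relaxes the noise-free dynamics by forward Euler, then polishes with
    Newton iterations using the analytic Jacobian.  Returns None when no
    converged stable point is found.
    """
    k = kinetics or NeuralKinetics.default()
    if S_init is None:
        S = np.full(sc.n_regions, _S_INIT)
    else:
        S = np.asarray(S_init, dtype=float).copy()
        relax_time = min(relax_time, 0.5)
    for _ in range(int(relax_time / relax_dt)):
        S = np.clip(S + relax_dt * neural_drift(S, sc, params, k), 0.0, 1.0)
    for _ in range(10):
        f = neural_drift(S, sc, params, k)
        if np.abs(f).max() < 1e-11:
            break
        A = drift_jacobian(S, sc, params, k)
        try:
            S = np.clip(S + np.linalg.solve(A, -f), 0.0, 1.0)
        except np.linalg.LinAlgError:
            return None
    if np.abs(neural_drift(S, sc, params, k)).max() > 1e-6:
        return None
    return S


def linearized_gating_correlation(sc: StructuralConnectome, params: RMFMParameters,
                                  kinetics: NeuralKinetics | None = None,
                                  S_init: np.ndarray | None = None):
    """Stationary correlation of the gating fluctuations, linearized at the fixed point.

    Solves the Lyapunov equation A Q + Q A^T = -I for the Ornstein-Uhlenbeck
    approximation dS = A (S - S*) dt + sigma dW (the correlation matrix is
    invariant to the noise amplitude).  Returns (corr, S*) or (None, S*) when
    the reachable fixed point is absent or linearly unstable.
    """
    from scipy.linalg import solve_continuous_lyapunov

    S = find_stable_fixed_point(sc, params, kinetics, S_init=S_init)
    if S is None:
        return None, None
    A = drift_jacobian(S, sc, params, kinetics)
    if np.linalg.eigvals(A).real.max() >= -1e-6:
        return None, S
    Q = solve_continuous_lyapunov(A, -np.eye(sc.n_regions))
    d = np.sqrt(np.diag(Q))
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        return None, S
    corr = Q / np.outer(d, d)
    return corr, S


def simulate_fc(sc: StructuralConnectome, params: RMFMParameters,
                kinetics: NeuralKinetics | None = None,
                hemo: HemodynamicConstants | None = None,
                config: SimulationConfig | None = None,
                noise: np.ndarray | None = None,
                rng: np.random.Generator | None = None,
                return_bold: bool = False):
    """Simulated FC: forward-integrate gating + hemodynamics, correlate BOLD.

    Uses a fused compiled loop; BOLD samples inside the burn-in window are
    discarded before the Pearson correlation.
    """
    config = config or SimulationConfig()
    k, GC, wJ, I = _prepare(sc, params, kinetics)
    h = hemo or HemodynamicConstants.default()
    n = sc.n_regions
    if noise is None:
        noise = _draw_noise(config, params.sigma, n, rng)
    S0 = np.full(n, _S_INIT)
    bold, clamps, floors, bad = _kernels.simulate_bold(
        GC, wJ, I, config.dt, config.n_steps, noise, config.decim, config.bw_stride,
        k.a, k.b, k.d, k.gamma_kinetic, k.tau_s,
        h.kappa, h.gamma_h, h.tau_h, h.alpha_g, h.rho,
        h.V0, h.k1, h.k2, h.k3, S0)
    if bad >= 0:
        raise DivergenceError(f"non-finite gating state at step {bad}", step=bad)
    if floors:
        warnings.warn(f"hemodynamic flow/volume floored {floors} times")
    t_out = (np.arange(bold.shape[1]) + 1) * config.dt * config.decim
    keep = t_out > config.burn_in
    series = BOLDSeries(bold[:, keep], tr=config.tr_out,
                        region_labels=list(sc.region_labels))
    fc = compute_fc(series)
    if return_bold:
        return fc, series
    return fc


def kuramoto_metastability(bold: BOLDSeries, band: tuple[float, float] = (0.01, 0.08),
                           filter_order: int = 2) -> float:
    """SD over time of the Kuramoto order parameter of band-limited BOLD phases.

    Each regional series is band-pass filtered, its instantaneous phase theta_i(t)
    extracted by the analytic signal, and R(t) = |mean_i exp(i*theta_i(t))|
    summarized by its standard deviation (the metastability).
    """
    if bold.n_regions < 2:
        raise InvalidArgumentError("metastability needs >= 2 regions")
    low, high = band
    nyq = 0.5 / bold.tr
    if not 0 < low < high < nyq:
        raise InvalidArgumentError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:.4g} Hz)")
    x = bold.samples - bold.samples.mean(axis=1, keepdims=True)
    sos = signal.butter(filter_order, [low / nyq, high / nyq], btype="band", output="sos")
    filtered = signal.sosfiltfilt(sos, x, axis=1)
    phases = np.angle(signal.hilbert(filtered, axis=1))
    R = np.abs(np.exp(1j * phases).mean(axis=0))
    return float(R.std())
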