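# Methods

## The model

`braindyn` implements a relaxed mean-field model (rMFM) of whole-brain
resting-state dynamics. Each cortical parcel *i* of a structural connectome
C (streamline counts, symmetric, zero diagonal) carries a synaptic gating
fraction S_i ∈ [0, 1]:

    dS_i = [ −S_i/τ_s + (1 − S_i) γ H(x_i) ] dt + σ dW_i
    x_i  = w_i J S_i + G J Σ_j C_ij S_j + I_i
    H(x) = (a x − b) / (1 − exp(−d (a x − b)))

H is the population transfer function (firing rate in Hz); the singularity at
a·x = b is removable with value 1/d. The "relaxed" aspect is that the
recurrent strength w_i and the subcortical input I_i are free per region
rather than shared, giving 2n + 2 free parameters (with global coupling G and
noise amplitude σ): 138 for a 68-parcel cortex, 298 for 148 parcels.

Constants (versioned in `constants.yaml`): a = 270 nA⁻¹, b = 108, d = 0.154 s,
γ = 0.641, τ_s = 0.1 s, J = 0.2609 nA. Time is in seconds and H in Hz, the
scaling under which the low-activity branch sits at S* ≈ 0.03–0.2 with firing
rates of a few Hz.

Gating activity drives an independent Balloon–Windkessel hemodynamic model
per region (vasodilatory signal s, inflow f, venous volume v,
deoxyhemoglobin q):

    ṡ = z − κ s − γ_h (f − 1)        f̈ = ... (ḟ = s)
    τ_h v̇ = f − v^{1/α}              τ_h q̇ = (f/ρ)(1 − (1−ρ)^{1/f}) − q v^{1/α − 1}
    y = V0 [ k1 (1 − q) + k2 (1 − q/v) + k3 (1 − v) ]

with κ = 0.65 s⁻¹, γ_h = 0.41 s⁻¹, τ_h = 0.98 s, α = 0.32, ρ = 0.34,
V0 = 0.02 and the 1.5 T-era coefficients k1 = 7ρ, k2 = 2, k3 = 2ρ − 0.2
(configurable). Simulated FC is the Pearson correlation matrix of the BOLD
series after burn-in; the similarity between two FC matrices is the Pearson
correlation of their strict upper triangles.

## Numerical integration

Euler–Maruyama with dt = 0.01 s by default (0.02 s in the reduced test
preset); states are clamped to [0, 1] with clamp events counted (a property
check requires < 0.1 % of updates clamped at defaults). The hemodynamic ODEs
are much slower than the neural kinetics, so they may be advanced on a
coarser grid (`bw_stride` neural steps per hemodynamic step, driven by the
window-averaged gating); at stride 4 the resulting FC agrees with stride 1
to r > 0.999. Default session length is 984 s with 120 s burn-in, sampled at
TR = 2 s. Noise is pre-generated from a seeded numpy Generator, making every
simulation byte-reproducible.

## Linearization

Around the stable low-activity fixed point (found by relaxation plus Newton
polish with the analytic drift Jacobian), the fluctuations form an
Ornstein–Uhlenbeck process whose stationary covariance solves the Lyapunov
equation A Q + Q Aᵀ = −σ²I. The implied gating correlation matrix is a fast,
noise-free predictor of simulated FC (r ≈ 0.7 against long stochastic
simulations in the generator's regime) and is independent of σ. Passing the
OU cross-spectrum through the (linearized) hemodynamic transfer function was
tested and changes the predicted correlations negligibly, so the gating-level
correlation is used directly.

## Parameter estimation

The estimator mirrors the variational/EM style of the dynamic-causal-modeling
lineage while remaining fully specified here:

- **Proposals**: damped Gauss–Newton steps on the residual between the
  empirical FC upper triangle and the linearized FC prediction, computed by
  finite differences over a random block of parameters (default block 16 of
  the w coordinates plus G), with Levenberg–Marquardt damping and a
  trust-region cap of 5 probe steps per coordinate.
- **Shrinkage priors**: Gaussian priors center w at 0.65 (SD 0.4), I at
  0.30 nA (SD 0.008) and G at the center of its initialization range
  (SD 0.15). The tight I prior reflects that subcortical inputs vary little
  across cortex in this model family; it also resolves the near-collinearity
  between w_i and I_i (both act on regional excitability), loading regional
  signal onto w. I is therefore not probed in block updates by default
  (`probe_I` enables it).
- **Acceptance**: every proposal is evaluated by a stochastic forward
  simulation and accepted only if the simulated similarity improves. Noise
  seeds are fixed per iteration index, so all evaluations within an iteration
  are common-random-number paired. σ has no gradient in the (σ-invariant)
  linearized correlation and moves by an occasional multiplicative random
  walk inside proposals.
- **Multi-start**: the study design runs many random initializations
  (defaults: 500 iterations, 25 inits, averaging the top 5 by best
  similarity; test preset: 100 iterations, 3 inits, top 2). The consensus is
  the element-wise mean of the selected runs' best parameters.

Validation feeds a held-out SC through the fitted model, averages the FC of
many noise realizations, and reports the similarity to the held-out empirical
FC next to the direct SC–FC Pearson baseline (restricted to nonzero SC pairs
by default, since zero streamline counts are censored rather than measured);
the relative improvement is 100·(r_sim − r_base)/r_base.

## Synthetic cohorts

Because the study's MRI data are not deposited, the generator produces
cohorts with the statistical structure the analysis assumes:

- **Template SC**: log-normal edge weights (σ_ln = 2.2; streamline counts
  span orders of magnitude), exact edge count at the requested density,
  denser within-hemisphere blocks, then symmetric Sinkhorn scaling toward
  uniform nodal strength — emulating strength-normalized connectomes so that
  regional excitability differences reflect local parameters rather than raw
  degree. Per-subject SC applies multiplicative log-normal edge jitter
  (CV 0.2), preserving nonnegativity and the heavy tail.
- **Ground truth**: baseline w_i ~ U(0.35, 0.85) (widely heterogeneous),
  I_i ~ U(0.295, 0.305) nA (nearly homogeneous), σ = 0.01. G is calibrated
  per cohort by bisection so the linearized dynamics sit at a fixed spectral
  abscissa (target −0.8 s⁻¹, landing near −2 after the final bisection
  bracket) — the near-critical regime where FC carries structure; the
  calibration is stable across template seeds (12/12 stable draws).
- **Group effects**: non-baseline cohorts differ from baseline only at
  designated regions, by fractional shifts (defaults: −25 % in w and −20 %
  in I for the untreated group at five regions; −10 %/−8 % for the treated
  group, i.e. mostly recovered toward baseline).
- **FC observation noise**: additive Gaussian on the Fisher-z scale
  (SD 0.05), back-transformed and projected to the nearest valid correlation
  matrix by eigenvalue clipping.
- **Covariates**: ages are normal per group with equal means (so the design
  is age-matched by construction), clipped to [18, 70]. A cognitive
  composite Z-score is linear-Gaussian in the subject's standardized global
  network efficiency with configurable correlation (default 0.22, the weak
  regime reported for such associations); seven domain scores load 0.6 on
  the composite.

What the generator does **not** emulate: raw BOLD noise sources (scanner
drift, motion), diffusion-MRI/tractography artifacts, residual preprocessing
structure, or subject-level longitudinal correlation between the treated and
untreated visits. Passing tests therefore demonstrate internal consistency of
the pipeline under the model's own assumptions, not fidelity to any real
acquisition.

## Test-scale choices

The default test preset simulates 150 s sessions (20 s burn-in) at
dt = 0.02 s with hemodynamics on a 0.06 s grid, fits 100 iterations with 3
initializations, and uses cohorts of 6 subjects per group; the recovery
experiment spans 5 cohort seeds. Full-scale settings (984 s sessions, 500
iterations, 25 initializations, 1000 validation simulations) are the
defaults of the corresponding configuration objects.

## Known limitations

- **Weak per-region identifiability.** The Pearson-similarity objective on
  FC carries only faint information about individual w_i: w_i and I_i are
  near-collinear, and the correlation structure admits a near-symmetry under
  which an approximately *mirrored* w profile (negatively correlated with
  the true one) fits almost as well — optimization runs reproducibly land on
  either side. Consequently, absolute recovery of the w map from a single
  fitted cohort is poor at reduced budgets, and region-level group
  comparisons of fitted parameters are underpowered even when the planted
  group differences are plainly visible in the FC matrices themselves. The
  similarity objective itself improves robustly (the optimizer roughly
  quadruples the initial similarity), which is the behaviour the original
  study design actually relies on. Run-to-run averaging (top-k consensus)
  mitigates but does not remove the degeneracy; treat fitted regional maps
  as descriptive, not as identified quantities.
- **Strong SC–FC baseline in the synthetic world.** The generator's
  near-critical OU regime makes cohort-average FC strongly SC-driven: the
  direct SC–FC Pearson baseline on synthetic cohorts is ≈ 0.8, far above the
  ≈ 0.4 typical of real data. A model fitted at the reduced test budget can
  therefore sit *below* that baseline on held-out data, making the relative
  improvement statistic negative on synthetic cohorts even though the same
  statistic is positive on the study's reported values. This is a property
  of the synthetic world, not of the validation code.
- The estimator's proposal stage relies on the OU linearization; in regimes
  with escaped (high-activity) regions the linearization degrades and
  proposals fall back to prior pulls.
- The Freeman–Halton 2×3 exact test enumerates all tables and is intended
  for the small demographic tables it serves, not for large counts.
- Disconnected graphs at sparse thresholds report path length over connected
  pairs only (with the disconnected fraction logged); global efficiency
  handles disconnection natively.
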