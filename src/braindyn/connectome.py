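"""Connectome data model: structural/functional matrices, BOLD series, cohorts.

Structural connectivity (SC) holds streamline counts between cortical parcels;
functional connectivity (FC) holds Pearson correlations between regional BOLD
time series, optionally Fisher r-to-z transformed for averaging.  All matrix
operations align by region label, not by position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    BalanceFailureError,
    DegenerateInputError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

RAW_R = "raw-r"
FISHER_Z = "fisher-z"

#: |r| beyond this is clipped before arctanh.
_R_CLIP = 1.0 - 1e-7
_SYM_TOL = 1e-10


def default_labels(n_regions: int) -> list[str]:
    """Canonical region ordering: left-hemisphere parcels then right."""
    half = n_regions // 2
    labels = [f"lh_region{i:03d}" for i in range(half)]
    labels += [f"rh_region{i:03d}" for i in range(n_regions - half)]
    return labels


def _check_square_symmetric(m: np.ndarray, what: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidArgumentError(f"{what} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=_SYM_TOL, rtol=0.0):
        raise InvalidArgumentError(f"{what} must be symmetric to within {_SYM_TOL}")


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative region-by-region coupling matrix (streamline counts)."""

    weights: np.ndarray
    region_labels: list[str]
    normalized: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        _check_square_symmetric(self.weights, "SC weights")
        n = self.weights.shape[0]
        if len(self.region_labels) != n:
            raise AlignmentError(
                f"{len(self.region_labels)} labels for {n}x{n} SC matrix"
            )
        if np.any(np.diag(self.weights) != 0.0):
            raise InvalidArgumentError("SC diagonal must be zero")
        if np.any(self.weights < 0):
            raise InvalidArgumentError("SC weights must be nonnegative")
        # enforce exact symmetry so downstream linear algebra is clean
        self.weights = (self.weights + self.weights.T) / 2.0

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def normalize(self, mode: str = "max") -> "StructuralConnectome":
        """Rescale weights for modeling; the global coupling G absorbs overall scale.

        mode: ``max`` divides by the largest entry (default), ``mean-degree`` by
        the mean row sum, ``none`` returns a flagged copy unchanged.
        """
        w = self.weights
        if mode == "max":
            scale = w.max()
        elif mode == "mean-degree":
            scale = w.sum(axis=1).mean()
        elif mode == "none":
            scale = 1.0
        else:
            raise InvalidArgumentError(f"unknown SC normalization mode {mode!r}")
        if scale <= 0:
            raise DegenerateInputError("cannot normalize an all-zero SC matrix")
        return StructuralConnectome(w / scale, list(self.region_labels), normalized=True)


@dataclass
class FunctionalConnectome:
    """Region-by-region correlation matrix, in raw-r or fisher-z space."""

    values: np.ndarray
    region_labels: list[str]
    space: str = RAW_R

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_square_symmetric(self.values, "FC values")
        n = self.values.shape[0]
        if len(self.region_labels) != n:
            raise AlignmentError(f"{len(self.region_labels)} labels for {n}x{n} FC")
        if self.space not in (RAW_R, FISHER_Z):
            raise InvalidArgumentError(f"unknown FC space {self.space!r}")
        self.values = (self.values + self.values.T) / 2.0
        if self.space == RAW_R:
            if np.any(np.abs(self.values) > 1.0 + 1e-12):
                raise InvalidArgumentError("raw-r FC entries must lie in [-1, 1]")
            np.clip(self.values, -1.0, 1.0, out=self.values)
            np.fill_diagonal(self.values, 1.0)
        else:
            off = self.values[~np.eye(n, dtype=bool)]
            if not np.all(np.isfinite(off)):
                raise InvalidArgumentError("fisher-z FC off-diagonal must be finite")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BOLDSeries:
    """Region-by-time BOLD samples with sampling interval ``tr`` in seconds."""

    samples: np.ndarray
    tr: float
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] < 2:
            raise InvalidArgumentError("BOLD series needs >= 2 time points")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("BOLD series must be finite")
        if self.tr <= 0:
            raise InvalidArgumentError("tr must be positive")
        if self.region_labels is None:
            self.region_labels = default_labels(self.samples.shape[0])
        elif len(self.region_labels) != self.samples.shape[0]:
            raise AlignmentError("label count does not match BOLD region count")

    @property
    def n_regions(self) -> int:
        return self.samples.shape[0]


@dataclass
class TrainTestSplit:
    """Disjoint, exhaustive per-group train/test id lists with age-balance p-values."""

    train_ids: list[str]
    test_ids: list[str]
    balance_pvalues: dict[str, float] = field(default_factory=dict)


def compute_fc(bold: BOLDSeries) -> FunctionalConnectome:
    """Pearson FC matrix of a regional BOLD series (raw-r space, unit diagonal)."""
    x = bold.samples
    sd = x.std(axis=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = [bold.region_labels[i] for i in dead[:5]]
        raise DegenerateInputError(
            f"zero-variance BOLD series in region(s) {names}"
        )
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FunctionalConnectome(r, list(bold.region_labels), space=RAW_R)


def fisher_z(fc: FunctionalConnectome) -> FunctionalConnectome:
    """Fisher r-to-z transform (arctanh); diagonal stored as 0 by convention."""
    if fc.space != RAW_R:
        raise InvalidArgumentError("fisher_z expects a raw-r FC matrix")
    r = fc.values.copy()
    off = ~np.eye(fc.n_regions, dtype=bool)
    n_clip = int(np.sum(np.abs(r[off]) >= 1.0))
    if n_clip:
        warnings.warn(
            f"{n_clip} off-diagonal |r|=1 entries clipped to {_R_CLIP} before arctanh"
        )
        logger.warning("fisher_z clipped %d saturated correlations", n_clip)
    np.clip(r, -_R_CLIP, _R_CLIP, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return FunctionalConnectome(z, list(fc.region_labels), space=FISHER_Z)


def inverse_fisher_z(fc: FunctionalConnectome) -> FunctionalConnectome:
    """Back-transform a fisher-z FC matrix to raw correlations (tanh)."""
    if fc.space != FISHER_Z:
        raise InvalidArgumentError("inverse_fisher_z expects a fisher-z FC matrix")
    r = np.tanh(fc.values)
    np.fill_diagonal(r, 1.0)
    return FunctionalConnectome(r, list(fc.region_labels), space=RAW_R)


def average_matrices(matrices: list[np.ndarray] | list[FunctionalConnectome]) -> np.ndarray | FunctionalConnectome:
    """Element-wise mean of same-shape matrices (or same-label FC objects).

    Averaging z-transformed FC stays in fisher-z space; back-transforming is an
    explicit separate call.
    """
    if len(matrices) == 0:
        raise InvalidArgumentError("cannot average an empty list")
    first = matrices[0]
    if isinstance(first, FunctionalConnectome):
        labels, space = first.region_labels, first.space
        for m in matrices[1:]:
            if m.region_labels != labels:
                raise AlignmentError("FC matrices have mismatched region labels")
            if m.space != space:
                raise AlignmentError("cannot average FC matrices in different spaces")
        mean = np.mean([m.values for m in matrices], axis=0)
        if space == RAW_R:
            np.fill_diagonal(mean, 1.0)
        return FunctionalConnectome(mean, list(labels), space=space)
    arrs = [np.asarray(m, dtype=float) for m in matrices]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise AlignmentError("matrices have mismatched shapes")
    return np.mean(arrs, axis=0)


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return 1.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def split_train_test(
    cohort: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
    balance_alpha: float = 0.1,
    max_retries: int = 2000,
) -> TrainTestSplit:
    """Group-stratified random split, resampled until ages balance.

    Accepts the first split whose Welch age p-value is >= ``balance_alpha``
    both within every group (train vs test) and between groups on the train
    side.  ``cohort`` needs columns ``subject_id``, ``group``, ``age``.
    """
    if not 0 < fraction < 1:
        raise InvalidArgumentError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    groups = list(dict.fromkeys(cohort["group"]))
    for g in groups:
        n_g = int((cohort["group"] == g).sum())
        n_train = int(round(fraction * n_g))
        if min(n_train, n_g - n_train) < 2:
            raise InvalidArgumentError(
                f"group {g!r} too small for a {fraction:.2f} split with >=2 per side"
            )
    best_p = -1.0
    for _ in range(max_retries):
        train_ids: list[str] = []
        test_ids: list[str] = []
        for g in groups:
            sub = cohort[cohort["group"] == g]
            n_train = int(round(fraction * len(sub)))
            perm = rng.permutation(len(sub))
            ids = sub["subject_id"].to_numpy()
            train_ids += list(ids[perm[:n_train]])
            test_ids += list(ids[perm[n_train:]])
        pvals: dict[str, float] = {}
        for g in groups:
            sub = cohort[cohort["group"] == g]
            age_tr = sub[sub["subject_id"].isin(train_ids)]["age"].to_numpy(float)
            age_te = sub[sub["subject_id"].isin(test_ids)]["age"].to_numpy(float)
            pvals[f"{g}:train-vs-test"] = _welch_p(age_tr, age_te)
        tr = cohort[cohort["subject_id"].isin(train_ids)]
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                a1 = tr[tr["group"] == g1]["age"].to_numpy(float)
                a2 = tr[tr["group"] == g2]["age"].to_numpy(float)
                pvals[f"{g1}-vs-{g2}:train"] = _welch_p(a1, a2)
        worst = min(pvals.values())
        best_p = max(best_p, worst)
        if worst >= balance_alpha:
            return TrainTestSplit(train_ids, test_ids, pvals)
    raise BalanceFailureError(
        f"no age-balanced split found in {max_retries} tries", best_p=best_p
    )


# ---------------------------------------------------------------------------
# TSV dialect: square matrix with one header row of region labels; round-trips
# exactly at 17 significant digits.

def write_matrix_tsv(path, matrix: np.ndarray, labels: list[str]) -> None:
    m = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in m:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        rows = [[float(v) for v in line.rstrip("\n").split("\t")] for line in fh]
    m = np.array(rows, dtype=float)
    if m.shape != (len(labels), len(labels)):
        raise InvalidArgumentError(f"matrix in {path} is not square against its header")
    return m, labels


def read_sc_tsv(path, normalized: bool = False) -> StructuralConnectome:
    m, labels = read_matrix_tsv(path)
    return StructuralConnectome(m, labels, normalized=normalized)


def read_fc_tsv(path, space: str = RAW_R) -> FunctionalConnectome:
    m, labels = read_matrix_tsv(path)
    return FunctionalConnectome(m, labels, space=space)


def write_bold_tsv(path, bold: BOLDSeries) -> None:
    """BOLD dialect: label header, one row per time point (columns = regions)."""
    with open(path, "w") as fh:
        fh.write("\t".join(bold.region_labels) + "\n")
        for row in bold.samples.T:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_bold_tsv(path, tr: float) -> BOLDSeries:
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        rows = [[float(v) for v in line.rstrip("\n").split("\t")] for line in fh]
    samples = np.array(rows, dtype=float).T
    if samples.shape[0] != len(labels):
        raise InvalidArgumentError(
            f"BOLD file {path} has {samples.shape[0]} columns for "
            f"{len(labels)} labels")
    return BOLDSeries(samples, tr=tr, region_labels=labels)


def write_labels(path, labels: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(labels) + "\n")


def read_labels(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
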