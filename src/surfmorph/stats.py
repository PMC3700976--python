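"""Group inference: age adjustment, t / Hotelling T-squared maps, dual
permutation testing, and CDF-based FDR.

The inference stack mirrors standard surface-based morphometry practice:

1. at every vertex (and channel) the measure is adjusted for age at scan by
   residualizing on age, with diagnosis kept in the fitting design so the
   group signal is not absorbed into the age slope;
2. a two-sample statistic is computed per vertex — pooled-variance t (squared)
   for the scalar measures, Hotelling's T-squared for the multivariate ones;
3. the (diagnosis, age) covariate pairs are permuted across subjects without
   replacement (group sizes preserved) to obtain vertex-wise non-parametric
   p-values, and, from the same permutation stream, a map-level corrected p
   based on the suprathreshold vertex count;
4. the empirical CDF of vertex p-values against the y = x/q line gives the
   FDR critical threshold (the step-up Benjamini-Hochberg cut), when one
   exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


@dataclass
class CohortTable:
    """Subject id, binary group label (0 = term control, 1 = preterm), and
    age at scan in weeks."""

    subject_ids: list
    groups: np.ndarray
    ages: np.ndarray

    def __post_init__(self):
        self.groups = np.asarray(self.groups, dtype=int)
        self.ages = np.asarray(self.ages, dtype=float)
        if set(np.unique(self.groups)) - {0, 1}:
            raise ValueError("groups must be coded 0/1")
        if (self.groups == 0).sum() < 2 or (self.groups == 1).sum() < 2:
            raise ValueError("need at least two subjects per group")
        if not np.all(np.isfinite(self.ages)):
            raise ValueError("ages must be finite")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        return cls(subject_ids=list(df["subject_id"]),
                   groups=df["group"].to_numpy(),
                   ages=df["age_weeks"].to_numpy())

    def __len__(self):
        return len(self.groups)


@dataclass
class StatMaps:
    """Vertex-wise statistic and p maps plus the map-level summaries for one
    of the four measures."""

    statistic: str                     # detJ | logS | R | combined
    stat_values: np.ndarray            # t^2 or T^2 per vertex
    p_values: np.ndarray               # uncorrected permutation p
    corrected_p: float                 # map-level permutation p
    fdr_critical: float | None         # CDF/FDR critical p (None if no crossing)
    n_suprathreshold: int
    threshold: float
    n_permutations: int
    cdf_curve: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


# ---------------------------------------------------------------------------
# age adjustment
# ---------------------------------------------------------------------------

def adjust_for_age(values: np.ndarray, cohort: CohortTable) -> np.ndarray:
    """Residualize each vertex (and channel) on age at scan.

    Fits value = b0 + b1*age + b2*diagnosis by least squares and returns
    value - b1*(age - mean age); the diagnosis column keeps the group effect
    out of the estimated age slope.  Rank-deficient designs (constant age)
    skip the adjustment with a warning.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 2
    if squeeze:
        values = values[..., None]
    n = values.shape[0]
    if len(cohort) != n:
        raise ValueError("cohort size does not match value array")
    ages = cohort.ages
    if np.ptp(ages) == 0:
        warnings.warn("constant ages: age adjustment skipped", stacklevel=2)
        return values[..., 0] if squeeze else values
    X = np.column_stack([np.ones(n), ages, cohort.groups])
    beta = np.linalg.pinv(X) @ values.reshape(n, -1)     # (3, V*C)
    b_age = beta[1].reshape(values.shape[1:])
    centered = (ages - ages.mean())[:, None, None]
    adjusted = values - b_age[None] * centered
    return adjusted[..., 0] if squeeze else adjusted


# ---------------------------------------------------------------------------
# vertex statistics (vectorized over permutations via group moments)
# ---------------------------------------------------------------------------

def _perm_matrix(groups: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """(n_perm + 1, n) subject-permutation index matrix; row 0 is the
    identity (observed assignment).  Row r reassigns subject i the covariates
    of subject perms[r, i].  Falls back to exhaustive enumeration (with a
    warning) when fewer distinct label splits exist than requested
    permutations."""
    n = len(groups)
    n1 = int(groups.sum())
    total = comb(n, n1)
    perms = None
    if n_perm >= total:
        warnings.warn(f"requested {n_perm} permutations but only {total} "
                      "distinct label splits exist; enumerating exhaustively",
                      stacklevel=3)
        ones = np.flatnonzero(groups == 1)
        zeros = np.flatnonzero(groups == 0)
        perms = np.empty((total + 1, n), dtype=np.intp)
        perms[0] = np.arange(n)
        for r, idx in enumerate(combinations(range(n), n1), start=1):
            row = np.empty(n, dtype=np.intp)
            rest = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            row[list(idx)] = ones          # order-preserving reassignment
            row[rest] = zeros
            perms[r] = row
        return perms
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=np.intp)
    perms[0] = np.arange(n)
    for r in range(1, n_perm + 1):
        perms[r] = rng.permutation(n)
    return perms


def _t2_from_moments(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Squared pooled-variance two-sample t for every labeling row of B.

    X is (n, V); returns (rows, V).
    """
    n = X.shape[0]
    n1 = int(B[0].sum())
    n0 = n - n1
    Bf = B.astype(float)
    s = X.sum(axis=0)
    q = (X ** 2).sum(axis=0)
    s1 = Bf @ X
    q1 = Bf @ (X ** 2)
    s0 = s - s1
    ss1 = q1 - s1 ** 2 / n1
    ss0 = (q - q1) - s0 ** 2 / n0
    sp2 = (ss1 + ss0) / (n - 2)
    denom = sp2 * (1.0 / n0 + 1.0 / n1)
    diff = s1 / n1 - s0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = diff ** 2 / denom
    zero_var = denom <= 0
    if zero_var.any():
        t2[zero_var] = 0.0
    return t2


def _hotelling_from_moments(X: np.ndarray, B: np.ndarray,
                            ridge: float = 1e-12,
                            chunk: int = 64) -> np.ndarray:
    """Hotelling T^2 for every labeling row of B.  X is (n, V, d)."""
    n, V, d = X.shape
    n1 = int(B[0].sum())
    n0 = n - n1
    Xf = X.reshape(n, V * d)
    s = Xf.sum(axis=0).reshape(V, d)
    cross_all = np.einsum("nvi,nvj->vij", X, X)
    out = np.empty((B.shape[0], V))
    for start in range(0, B.shape[0], chunk):
        Bc = B[start:start + chunk].astype(float)
        r = Bc.shape[0]
        s1 = (Bc @ Xf).reshape(r, V, d)
        cross1 = np.einsum("rn,nvi,nvj->rvij", Bc, X, X, optimize=True)
        s0 = s[None] - s1
        SS1 = cross1 - np.einsum("rvi,rvj->rvij", s1, s1) / n1
        SS0 = (cross_all[None] - cross1) - np.einsum("rvi,rvj->rvij", s0, s0) / n0
        Sp = (SS1 + SS0) / (n - 2)
        tr = np.trace(Sp, axis1=-2, axis2=-1) / d
        Sp = Sp + (ridge * np.maximum(tr, 1e-300))[..., None, None] * np.eye(d)
        diff = s1 / n1 - s0 / n0
        sol = np.linalg.solve(Sp, diff[..., None])[..., 0]
        out[start:start + r] = (n1 * n0 / n) * np.einsum("rvi,rvi->rv", diff, sol)
    return out


def _adjusted_stat_matrix(X: np.ndarray, perms: np.ndarray, groups: np.ndarray,
                          ages: np.ndarray, ridge: float = 1e-12,
                          chunk: int = 64) -> np.ndarray:
    """Hotelling T^2 (t^2 when d = 1) for every covariate reassignment in
    ``perms``, with the age adjustment re-estimated under that assignment.

    Each permutation moves the (diagnosis, age) covariate PAIR of a subject
    onto another subject's data, the GLM value = b0 + b1*age + b2*diagnosis
    is refitted, the data residualized as value - b1*(age - mean age), and
    the two-sample statistic computed.  Permuting the covariate rows jointly
    keeps the test exact under the null even though the groups differ in age:
    permuting diagnosis alone (with ages pinned to the data) makes the
    observed labeling the most age-aligned one and inflates the false
    positive rate.  Because the covariate pair moves as a unit, the design
    Gram matrix is permutation-invariant and everything reduces to a few
    weighted group moments per permutation.
    """
    n, V, d = X.shape
    g = (np.asarray(groups) == 1).astype(float)
    n1 = int(g.sum())
    n0 = n - n1
    a = np.asarray(ages, dtype=float)
    ac = a - a.mean()
    A2 = float(ac @ ac)
    # design scalars — identical for every covariate reassignment
    M = np.array([[n, a.sum(), n1],
                  [a.sum(), a @ a, a @ g],
                  [n1, a @ g, n1]])
    alpha, beta, gamma = np.linalg.inv(M)[1]
    k1 = float(ac @ g)            # sum of centered age over group 1
    f1 = float((ac ** 2) @ g)
    Xf = X.reshape(n, V * d)
    s = Xf.sum(axis=0).reshape(V, d)
    q = np.einsum("nvi,nvj->vij", X, X)
    out = np.empty((perms.shape[0], V))
    eye = np.eye(d)
    for start in range(0, perms.shape[0], chunk):
        pc = perms[start:start + chunk]
        r = pc.shape[0]
        Gr = g[pc]                                    # (r, n) permuted labels
        Ar = a[pc]
        ACr = ac[pc]
        G1 = (Gr @ Xf).reshape(r, V, d)               # group-1 sums of y
        AYS = (Ar @ Xf).reshape(r, V, d)              # sums of a*y
        AYAC = (ACr @ Xf).reshape(r, V, d)            # sums of (a - abar)*y
        E1 = ((Gr * ACr) @ Xf).reshape(r, V, d)       # group-1 sums of ac*y
        C1 = np.einsum("rn,nvi,nvj->rvij", Gr, X, X, optimize=True)
        b = alpha * s[None] + beta * AYS + gamma * G1  # age slope (r, V, d)
        s1 = G1 - b * k1
        s0 = s[None] - s1                             # total adjusted sum = s
        bE = np.einsum("rvi,rvj->rvij", b, E1)
        S1 = (C1 - bE - np.swapaxes(bE, -1, -2)
              + np.einsum("rvi,rvj->rvij", b, b) * f1)
        bA = np.einsum("rvi,rvj->rvij", b, AYAC)
        T = (q[None] - bA - np.swapaxes(bA, -1, -2)
             + np.einsum("rvi,rvj->rvij", b, b) * A2)
        S0 = T - S1
        SS1 = S1 - np.einsum("rvi,rvj->rvij", s1, s1) / n1
        SS0 = S0 - np.einsum("rvi,rvj->rvij", s0, s0) / n0
        Sp = (SS1 + SS0) / (n - 2)
        tr = np.trace(Sp, axis1=-2, axis2=-1) / d
        Sp = Sp + (ridge * np.maximum(tr, 1e-300))[..., None, None] * eye
        diff = s1 / n1 - s0 / n0
        sol = np.linalg.solve(Sp, diff[..., None])[..., 0]
        out[start:start + r] = (n1 * n0 / n) * np.einsum("rvi,rvi->rv", diff, sol)
    return out


def t_stat_map(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Squared two-sample pooled-variance t statistic per vertex."""
    groups = np.asarray(groups, dtype=int)
    B = np.zeros((1, len(groups)), dtype=bool)
    B[0, groups == 1] = True
    return _t2_from_moments(np.asarray(values, dtype=float), B)[0]


def hotelling_map(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Hotelling's T^2 per vertex for (n, V, d) channel data with pooled
    sample covariance; a tiny trace-scaled ridge guards singular cases."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=int)
    n = len(groups)
    d = values.shape[2]
    if n - 2 <= d:
        raise ValueError("need n1 + n2 - 2 > d for the pooled covariance")
    B = np.zeros((1, n), dtype=bool)
    B[0, groups == 1] = True
    return _hotelling_from_moments(values, B)[0]


# ---------------------------------------------------------------------------
# permutation testing (single seeded stream for both levels)
# ---------------------------------------------------------------------------

def _stat_matrix(values: np.ndarray, perms: np.ndarray, groups: np.ndarray,
                 ages: np.ndarray | None = None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if ages is not None and np.ptp(ages) > 0:
        X = values[..., None] if values.ndim == 2 else values
        return _adjusted_stat_matrix(X, perms, groups, ages)
    B = (np.asarray(groups)[perms] == 1)
    if values.ndim == 2:
        return _t2_from_moments(values, B)
    return _hotelling_from_moments(values, B)


def _p_from_null(stat_rows: np.ndarray) -> np.ndarray:
    """Per-vertex permutation p for every row of the stat matrix.

    Every row (the observed labeling is row 0) is compared against the full
    set of N = n_perm + 1 labelings including itself, so p >= 1/N (add-one
    smoothing) and the observed row has no asymmetric advantage over the
    permuted rows — the map-level correction built on these p-maps is exact
    under exchangeability.
    """
    N, V = stat_rows.shape
    all_sorted = np.sort(stat_rows, axis=0)
    p = np.empty_like(stat_rows)
    for v in range(V):
        # counting ">=" with a tiny relative slack keeps floating-point ties
        # (e.g. complementary label splits, which give identical statistics)
        # on the same side regardless of summation order
        thresh = stat_rows[:, v] - 1e-9 * np.abs(stat_rows[:, v]) - 1e-300
        ge = N - np.searchsorted(all_sorted[:, v], thresh, side="left")
        p[:, v] = ge / N
    return p


def vertex_permutation(values: np.ndarray, cohort: CohortTable,
                       n_perm: int = 10000, seed: int = 0) -> np.ndarray:
    """Vertex-wise permutation p-values (labels reassigned without
    replacement, group sizes preserved; add-one smoothing)."""
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    perms = _perm_matrix(cohort.groups, n_perm, seed)
    S = _stat_matrix(values, perms, cohort.groups)
    return _p_from_null(S)[0]


def mapwise_permutation(values: np.ndarray, cohort: CohortTable,
                        threshold: float = 0.05, n_perm: int = 10000,
                        seed: int = 0) -> tuple:
    """Map-level corrected p from the suprathreshold vertex count, using the
    same permutation stream as the vertex-wise test (single pass).

    Returns (corrected_p, observed_count, vertex_p).
    """
    perms = _perm_matrix(cohort.groups, n_perm, seed)
    S = _stat_matrix(values, perms, cohort.groups)
    P = _p_from_null(S)
    counts = (P <= threshold).sum(axis=1)
    observed = counts[0]
    corrected = (1.0 + np.sum(counts[1:] >= observed)) / (1.0 + (len(counts) - 1))
    return float(corrected), int(observed), P[0]


def fdr_cdf(p_values: np.ndarray, q: float = 0.05) -> tuple:
    """CDF-based FDR: the critical p is the largest p(i) <= q*i/m (the highest
    non-origin crossing of the empirical CDF with y = x/q); None when no such
    point exists.  Also returns the CDF curve as an (m, 2) array of
    (p, empirical CDF)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value list")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    i = np.arange(1, m + 1)
    ok = p <= q * i / m
    critical = float(p[ok][-1]) if ok.any() else None
    cdf = np.column_stack([p, i / m])
    return critical, cdf


# ---------------------------------------------------------------------------
# the four-statistic analysis
# ---------------------------------------------------------------------------

def analyze_statistic(name: str, values: np.ndarray, cohort: CohortTable,
                      n_perm: int = 10000, seed: int = 0,
                      threshold: float = 0.05, q: float = 0.05,
                      adjust_age: bool = True) -> StatMaps:
    """Full inference for one measure: age adjustment (re-estimated under
    every permuted labeling), observed map, vertex-wise and map-level
    permutation p, FDR critical value."""
    values = np.asarray(values, dtype=float)
    ages = cohort.ages if adjust_age else None
    if adjust_age and np.ptp(cohort.ages) == 0:
        warnings.warn("constant ages: age adjustment skipped", stacklevel=2)
        ages = None
    perms = _perm_matrix(cohort.groups, n_perm, seed)
    S = _stat_matrix(values, perms, cohort.groups, ages=ages)
    P = _p_from_null(S)
    p_obs = P[0]
    counts = (P <= threshold).sum(axis=1)
    corrected = (1.0 + np.sum(counts[1:] >= counts[0])) / (1.0 + (len(counts) - 1))
    critical, cdf = fdr_cdf(p_obs, q)
    return StatMaps(statistic=name, stat_values=S[0], p_values=p_obs,
                    corrected_p=float(corrected), fdr_critical=critical,
                    n_suprathreshold=int(counts[0]), threshold=threshold,
                    n_permutations=perms.shape[0] - 1, cdf_curve=cdf)


def group_analysis(detJ: np.ndarray, logS: np.ndarray, R: np.ndarray,
                   cohort: CohortTable, statistics=("detJ", "logS", "R", "combined"),
                   n_perm: int = 10000, seed: int = 0, threshold: float = 0.05,
                   q: float = 0.05, adjust_age: bool = True) -> dict:
    """Run the requested subset of the four statistics.

    detJ and R are (n_subjects, n_vertices); logS is (n_subjects, n_vertices,
    3); the combined measure concatenates logS and R per vertex.
    """
    data = {
        "detJ": detJ,
        "logS": logS,
        "R": R,
        "combined": (np.concatenate([logS, R[..., None]], axis=2)
                     if "combined" in statistics else None),
    }
    out = {}
    for i, name in enumerate(statistics):
        out[name] = analyze_statistic(name, data[name], cohort, n_perm=n_perm,
                                      seed=seed, threshold=threshold, q=q,
                                      adjust_age=adjust_age)
    return out
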