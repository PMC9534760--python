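"""Phenotypic divergence: variance components, P_ST and Mantel tests.

P_ST is the phenotypic analogue of Q_ST,

    P_ST = c * sigma_b2 / (c * sigma_b2 + 2 * h2 * sigma_w2),

where sigma_b2 and sigma_w2 are the between- and within-population trait
variances, h2 the (unknown) heritability and c the fraction of
between-population variance that is additive. The value depends on c and
h2 only through the ratio r = c / h2, so the package evaluates P_ST over
a grid of ratios. Variance components come from a one-way random-intercept
model fit by REML, profiled in the single ratio lambda = sigma_b2 /
sigma_w2; uncertainty from a stratified nonparametric bootstrap over
individuals within populations.

The selection inference compares P_ST with neutral F_ST: the critical
c/h2 ratio is the point where the lower P_ST confidence bound meets the
upper F_ST bound — the smaller it is, the more robust the inference of
divergent selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "PstGridResult",
    "MantelResult",
    "fit_one_way_reml",
    "compute_pst",
    "pst_bootstrap_ci",
    "critical_ch2_ratio",
    "pairwise_pst_matrix",
    "mantel_test",
    "default_ratio_grid",
]

NONE_BELOW_GRID = "none_below_grid"
BEYOND_GRID = "beyond_grid"


def default_ratio_grid() -> np.ndarray:
    """c/h2 grid 0.05 ... 2.0 in steps of 0.05 (spans reported critical values)."""
    return np.round(np.arange(1, 41) * 0.05, 10)


@dataclass(frozen=True)
class VarianceComponents:
    """REML (or moment) estimates for the one-way random-effects model."""

    sigma_b2: float
    sigma_w2: float
    n_populations: int
    n_total: int
    method: str = "reml"

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0 or self.sigma_w2 < 0:
            raise ValueError("variance components must be >= 0")
        if not (self.n_total >= self.n_populations >= 2):
            raise ValueError("need n_total >= n_populations >= 2")


@dataclass
class PstGridResult:
    """P_ST over a c/h2 grid with stratified-bootstrap percentile CIs."""

    ratios: np.ndarray
    pst_point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int
    components: VarianceComponents
    boot_sigma_b2: np.ndarray  # per-replicate components, kept for refinement
    boot_sigma_w2: np.ndarray
    n_degenerate: int = 0
    critical_ratio: float | str | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio": self.ratios,
                "pst": self.pst_point,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str = "greater"


# ---------------------------------------------------------------------------
# REML for y_ij = mu + u_i + e_ij
# ---------------------------------------------------------------------------

def _group_arrays(values: np.ndarray, codes: np.ndarray, n_groups: int):
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    sum_i = np.bincount(codes, weights=values, minlength=n_groups)
    mean_i = np.divide(sum_i, n_i, out=np.zeros_like(sum_i), where=n_i > 0)
    ssw = np.bincount(codes, weights=values**2, minlength=n_groups) - n_i * mean_i**2
    return n_i, mean_i, np.maximum(ssw, 0.0)


def _reml_from_group_stats(
    n_i: np.ndarray, mean_i: np.ndarray, ssw_i: np.ndarray
) -> tuple[float, float]:
    """Profiled REML estimates (sigma_b2, sigma_w2) from per-group stats.

    The criterion is profiled in lambda = sigma_b2 / sigma_w2: for fixed
    lambda the GLS mean, the residual quadratic form and the determinant
    terms are closed-form, leaving a 1-D minimization on log(lambda) in
    [-12, 12] (the profile is unimodal for this model); the boundary
    lambda = 0 is always compared.
    """
    keep = n_i > 0
    n_i, mean_i, ssw_i = n_i[keep], mean_i[keep], ssw_i[keep]
    N = float(n_i.sum())
    grand = (n_i * mean_i).sum() / N
    ssb = (n_i * (mean_i - grand) ** 2).sum()
    if ssw_i.sum() + ssb <= 0.0:
        return 0.0, 0.0
    if ssw_i.sum() == 0.0:
        # no within-group variance: the profile likelihood degenerates, so
        # report the ANOVA moment estimates (sigma_w2 = MSW = 0,
        # sigma_b2 = MSB / n0 with the unequal-n correction n0)
        r = len(n_i)
        n0 = (N - (n_i**2).sum() / N) / (r - 1)
        return float(ssb / (r - 1) / n0), 0.0

    def neg2_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = n_i / (1.0 + n_i * lam)
        mu = (w * mean_i).sum() / w.sum()
        # n_i (ybar_i - mu)^2 / (1 + n_i lam) == w_i (ybar_i - mu)^2
        q = ssw_i.sum() + (w * (mean_i - mu) ** 2).sum()
        sw2 = q / (N - 1.0)
        return (
            (N - 1.0) * np.log(sw2)
            + np.log1p(n_i * lam).sum()
            + np.log(w.sum())
        )

    res = minimize_scalar(
        neg2_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [(-12.0, neg2_restricted_ll(-12.0)), (float(res.x), float(res.fun))]
    log_lam, crit = min(candidates, key=lambda t: t[1])
    lam = np.exp(log_lam)
    if log_lam <= -12.0 + 1e-8:
        lam = 0.0
    w = n_i / (1.0 + n_i * lam)
    mu = (w * mean_i).sum() / w.sum()
    q = ssw_i.sum() + (w * (mean_i - mu) ** 2).sum()
    sw2 = float(q / (N - 1.0))
    return float(lam * sw2), sw2


def fit_one_way_reml(
    traits: pd.DataFrame, trait: str | None = None, value_col: str = "value_c"
) -> VarianceComponents:
    """REML variance components for ``value ~ 1 + (1 | population)``.

    ``traits`` is a TraitTable (columns population, trait, value_c);
    ``trait`` filters rows by trait name when the table mixes traits.
    """
    df = traits
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    pops, codes = np.unique(df["population"].to_numpy(), return_inverse=True)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations for variance components")
    values = df[value_col].to_numpy(dtype=float)
    n_i, mean_i, ssw_i = _group_arrays(values, codes, len(pops))
    sb2, sw2 = _reml_from_group_stats(n_i, mean_i, ssw_i)
    return VarianceComponents(
        sigma_b2=sb2, sigma_w2=sw2,
        n_populations=len(pops), n_total=len(values), method="reml",
    )


# ---------------------------------------------------------------------------
# P_ST
# ---------------------------------------------------------------------------

def compute_pst(vc: VarianceComponents, ratio: float) -> float:
    """P_ST at a given c/h2 ratio: r*sb2 / (r*sb2 + 2*sw2)."""
    if ratio <= 0:
        raise ValueError("c/h2 ratio must be > 0")
    return _pst(vc.sigma_b2, vc.sigma_w2, ratio)


def _pst(sb2, sw2, ratio):
    sb2 = np.asarray(sb2, dtype=float)
    sw2 = np.asarray(sw2, dtype=float)
    num = ratio * sb2
    den = num + 2.0 * sw2
    if np.any(den == 0.0):
        raise ValueError("P_ST undefined: both variance components are zero")
    return num / den if num.ndim else float(num / den)


def pst_bootstrap_ci(
    traits: pd.DataFrame,
    trait: str | None = None,
    ratios: Sequence[float] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    value_col: str = "value_c",
    max_degenerate_frac: float = 0.2,
    unit: str = "individuals",
) -> PstGridResult:
    """P_ST over a c/h2 grid with a nonparametric bootstrap.

    With ``unit="individuals"`` (default) individuals are resampled with
    replacement within their population, preserving the sampling design;
    the resulting CI is conditional on the realized population effects
    and reflects within-population sampling error only. With
    ``unit="populations"`` a two-stage bootstrap resamples populations
    with replacement and then individuals within each drawn population,
    which also propagates the between-population sampling of sigma_b2
    (required for frequentist coverage of a generating P_ST). Components
    are refit by REML per replicate and P_ST evaluated at every grid
    ratio; CIs are percentile. Replicates where both components collapse
    to zero are dropped; more than ``max_degenerate_frac`` of them is an
    error.
    """
    if unit not in ("individuals", "populations"):
        raise ValueError("unit must be 'individuals' or 'populations'")
    if n_boot < 500:
        raise ValueError("n_boot must be >= 500")
    df = traits
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    pops, codes = np.unique(df["population"].to_numpy(), return_inverse=True)
    values = df[value_col].to_numpy(dtype=float)
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every population needs >= 2 individuals to bootstrap")
    grid = default_ratio_grid() if ratios is None else np.asarray(ratios, dtype=float)
    if (np.diff(grid) <= 0).any() or (grid <= 0).any():
        raise ValueError("ratio grid must be positive and strictly ascending")

    point = fit_one_way_reml(df, trait=None, value_col=value_col)
    rng = np.random.default_rng(seed)
    by_pop = [np.flatnonzero(codes == g) for g in range(len(pops))]
    sb = np.empty(n_boot)
    sw = np.empty(n_boot)
    n_groups = len(pops)
    for b in range(n_boot):
        if unit == "individuals":
            # stratified resample: same n per population as observed
            chosen = range(n_groups)
        else:
            chosen = rng.integers(0, n_groups, size=n_groups)
        vals = np.concatenate(
            [
                values[by_pop[g][rng.integers(0, len(by_pop[g]), size=len(by_pop[g]))]]
                for g in chosen
            ]
        )
        cds = np.repeat(np.arange(n_groups), sizes[list(chosen)])
        n_i, mean_i, ssw_i = _group_arrays(vals, cds, n_groups)
        sb[b], sw[b] = _reml_from_group_stats(n_i, mean_i, ssw_i)
    good = ~((sb == 0.0) & (sw == 0.0))
    n_degenerate = int((~good).sum())
    if n_degenerate > max_degenerate_frac * n_boot:
        raise ValueError(
            f"{n_degenerate}/{n_boot} bootstrap replicates degenerate (both components zero)"
        )
    if n_degenerate:
        logger.warning("dropped %d degenerate bootstrap replicates", n_degenerate)
    sb, sw = sb[good], sw[good]

    pst_point = np.array([compute_pst(point, r) for r in grid])
    lo = np.empty_like(grid)
    hi = np.empty_like(grid)
    for i, r in enumerate(grid):
        reps = _pst(sb, sw, r)
        lo[i], hi[i] = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return PstGridResult(
        ratios=grid, pst_point=pst_point, ci_low=lo, ci_high=hi,
        n_boot=n_boot, seed=seed, components=point,
        boot_sigma_b2=sb, boot_sigma_w2=sw, n_degenerate=n_degenerate,
    )


def critical_ch2_ratio(
    grid: PstGridResult, fst_upper: float, alpha: float = 0.05, tol: float = 1e-6
) -> float | str:
    """Largest c/h2 ratio at which P_ST is indistinguishable from F_ST.

    Returns the largest ratio r with ci_low(r) <= fst_upper, refined by
    bisection between the bracketing grid points using the stored
    bootstrap replicates. Sentinels: ``"none_below_grid"`` when even the
    smallest grid ratio separates, ``"beyond_grid"`` when the largest
    still overlaps.
    """
    if fst_upper < 0:
        raise ValueError("fst_upper must be >= 0")

    def ci_low_at(r: float) -> float:
        return float(np.percentile(_pst(grid.boot_sigma_b2, grid.boot_sigma_w2, r), 100 * alpha / 2))

    below = grid.ci_low <= fst_upper
    if not below.any():
        grid.critical_ratio = NONE_BELOW_GRID
        return NONE_BELOW_GRID
    if below.all():
        grid.critical_ratio = BEYOND_GRID
        return BEYOND_GRID
    crossings = np.flatnonzero(below[:-1] & ~below[1:])
    if below[-1]:
        # non-monotone tail; fall back to the last ratio still overlapping
        grid.critical_ratio = BEYOND_GRID
        return BEYOND_GRID
    if len(crossings) > 1:
        logger.warning("ci_low crosses fst_upper more than once; taking the last crossing")
    k = int(crossings[-1])
    lo_r, hi_r = float(grid.ratios[k]), float(grid.ratios[k + 1])
    # ci_low is increasing in r for each replicate set, so bisection is safe
    while hi_r - lo_r > tol:
        mid = 0.5 * (lo_r + hi_r)
        if ci_low_at(mid) <= fst_upper:
            lo_r = mid
        else:
            hi_r = mid
    result = 0.5 * (lo_r + hi_r)
    grid.critical_ratio = result
    return result


def pairwise_pst_matrix(
    traits: pd.DataFrame, trait: str | None = None, ratio: float = 1.0,
    value_col: str = "value_c",
) -> pd.DataFrame:
    """Matrix of P_ST values from per-pair variance-component refits.

    Entry (i, j) refits the one-way REML model on populations {i, j} only
    and evaluates P_ST at the given c/h2 ratio; pairs where both
    components vanish are NaN.
    """
    df = traits
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    pops = sorted(df["population"].unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = df[df["population"].isin([pops[i], pops[j]])]
            vc = fit_one_way_reml(sub, trait=None, value_col=value_col)
            try:
                val = compute_pst(vc, ratio)
            except ValueError:
                val = np.nan
            mat.iloc[i, j] = mat.iloc[j, i] = val
    return mat


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _tri(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices_from(mat, k=-1)]


def mantel_test(
    A: pd.DataFrame | np.ndarray,
    B: pd.DataFrame | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test between two symmetric distance matrices.

    r is the Pearson correlation of the strict lower triangles; the null
    distribution permutes the row/column labels of B jointly; p = (1 + #
    permuted r at least as extreme) / (n_permutations + 1). With
    ``exact=True`` all n! label permutations are enumerated instead
    (identity included) and p = #{r_perm >= r_obs} / n!.
    """
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("Mantel test refuses matrices with missing entries")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    x = _tri(a)
    y = _tri(b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant off-diagonal entries: Mantel r undefined")
    r_obs = float(pearsonr(x, y)[0])

    n = a.shape[0]
    if exact:
        from itertools import permutations as _perms
        from math import factorial

        perms = [np.array(p) for p in _perms(range(n))]
        n_permutations = factorial(n)
    else:
        rng = np.random.default_rng(seed)
        perms = (rng.permutation(n) for _ in range(n_permutations))
    count = 0
    for perm in perms:
        y_perm = _tri(b[np.ix_(perm, perm)])
        r_perm = float(pearsonr(x, y_perm)[0])
        if alternative == "greater":
            count += r_perm >= r_obs - 1e-12
        elif alternative == "less":
            count += r_perm <= r_obs + 1e-12
        elif alternative == "two-sided":
            count += abs(r_perm) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    if exact:
        p = count / n_permutations  # identity permutation is in the count
    else:
        p = (1 + count) / (n_permutations + 1)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_permutations,
                        seed=seed, alternative=alternative)
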