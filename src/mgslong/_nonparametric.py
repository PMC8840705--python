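"""Nonparametric test helpers shared by the longitudinal and responder modules.

Implements the Friedman test with mid-rank tie correction (valid for
k >= 2 repeated measures), the Nemenyi post-hoc on Friedman rank sums,
the Dunn post-hoc on Kruskal–Wallis joint ranks, Cliff's delta effect
size, Benjamini–Hochberg adjustment, and the one-group rank-based
ANOVA-type statistic for longitudinal designs (LD-F1).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "benjamini_hochberg",
    "friedman_test",
    "nemenyi_posthoc",
    "dunn_posthoc",
    "cliffs_delta",
    "ld_f1_anova_type",
]


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through unadjusted."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-squared test on a complete subjects × treatments matrix.

    Mid-ranks within subjects; the statistic carries the standard tie
    correction (matches ``scipy.stats.friedmanchisquare`` for k >= 3 and
    extends to k = 2).  Returns (chi2, p); a matrix whose rows are all
    constant yields chi2 = 0, p = 1.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects × treatments matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >=2 subjects and >=2 treatments, got {x.shape}")
    if np.isnan(x).any():
        raise ValueError("matrix must be complete (apply pairwise deletion first)")
    ranks = stats.rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction over within-subject tie groups
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    if denom <= 0:  # every row fully tied: no information
        return 0.0, 1.0
    chi2 /= denom
    p = float(stats.chi2.sf(chi2, k - 1))
    return float(chi2), p


def nemenyi_posthoc(matrix: np.ndarray) -> np.ndarray:
    """Nemenyi pairwise p-values after a Friedman test.

    For treatments i, j with mean within-subject ranks Rbar_i, Rbar_j over
    n subjects, the statistic |Rbar_i - Rbar_j| / sqrt(k(k+1)/(12 n)) is
    referred to the studentized range distribution (k groups, infinite
    df), divided by sqrt(2).  Returns a symmetric k × k matrix with unit
    diagonal.
    """
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    q = diff / se
    p = stats.studentized_range.sf(q, k, np.inf)
    np.fill_diagonal(p, 1.0)
    return p


def dunn_posthoc(groups: list[np.ndarray], p_adjust: str | None = None) -> np.ndarray:
    """Dunn's pairwise z-test p-values after a Kruskal–Wallis test.

    Joint mid-ranks over the pooled data with the usual tie correction;
    two-sided normal p-values, optionally BH-adjusted across pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([len(g) for g in groups])
    if (sizes == 0).any():
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(groups))]
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    k = len(groups)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p[i, j] = p[j, i] = 2.0 * stats.norm.sf(abs(z))
    if p_adjust == "fdr_bh":
        iu = np.triu_indices(k, 1)
        p[iu] = benjamini_hochberg(p[iu])
        p.T[iu] = p[iu]
    return p


_CLIFF_THRESHOLDS = ((0.147, "negligible"), (0.33, "small"), (0.474, "medium"))


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Cliff's delta effect size and its conventional magnitude label.

    d = (#{x_i > y_j} - #{x_i < y_j}) / (n_x n_y), in [-1, 1]; 0 means no
    effect, +/-1 means complete separation.  Magnitude: negligible if
    |d| < 0.147, small if |d| < 0.33, medium if |d| < 0.474, large
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    # O((nx+ny) log) via joint ranking rather than the nx*ny comparison table
    greater = 0
    less = 0
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    less = (len(ys) - np.searchsorted(ys, x, side="right")).sum()
    d = float(greater - less) / (len(x) * len(y))
    mag = "large"
    for thr, label in _CLIFF_THRESHOLDS:
        if abs(d) < thr:
            mag = label
            break
    return d, mag


def ld_f1_anova_type(matrix: np.ndarray) -> tuple[float, float, float]:
    """Rank-based ANOVA-type statistic for one group × repeated measures
    (the LD-F1 design).  Experimental.

    All n × t observations are jointly mid-ranked; the relative treatment
    effects p_hat_j = (Rbar_.j - 1/2) / N are tested for equality across
    time with the ANOVA-type statistic, referred to an F(fhat, inf)
    distribution with box-type estimated numerator df.  Returns
    (statistic, df, p).
    """
    x = np.asarray(matrix, dtype=float)
    n, t = x.shape
    if n < 2 or t < 2:
        raise ValueError("need >=2 subjects and >=2 time points")
    N = n * t
    ranks = stats.rankdata(x.ravel()).reshape(n, t)
    rbar = ranks.mean(axis=0)
    # centering contrast P = I - J/t
    P = np.eye(t) - np.ones((t, t)) / t
    # covariance of per-subject rank vectors, scaled to relative effects
    V = np.cov(ranks, rowvar=False, ddof=1) / (N**2)
    V = np.atleast_2d(V)
    phat = (rbar - 0.5) / N
    trPV = float(np.trace(P @ V))
    if trPV <= 0:  # all observations tied
        return 0.0, float(t - 1), 1.0
    stat = float(n * phat @ P @ phat / trPV)
    PV = P @ V
    df = trPV**2 / float(np.trace(PV @ PV))
    # F(df, inf) is chi2_df / df
    p = float(stats.chi2.sf(stat * df, df))
    return stat, float(df), p
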