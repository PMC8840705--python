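"""Longitudinal evolution analysis: the AUC of log10 fold change.

For each subject and feature (MGS or higher-rank taxon) a period — an
ordered set of visits starting at an initial time point (D-30 for the
pre-treatment period, D-1 for the on-treatment period) — defines a
trajectory of log10 fold changes relative to the initial visit.  The
signed trapezoidal area under that trajectory summarises the feature's
net evolution over the period: positive if it increased from its initial
value, negative if it decreased, exactly 0 if it was constant.  The
pre-treatment and on-treatment AUCs are then compared across subjects
with a paired Wilcoxon signed-rank test (BH-adjusted over features);
features flagged by the AUC contrast are followed up with Friedman tests
within each period (with Nemenyi post-hoc available) to localise where
the change happened.

Spearman correlation of features (or richness) with the Bristol stool
scale at each visit, with a cross-visit sign-consistency report, covers
the symptom-association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._nonparametric import (
    benjamini_hochberg,
    friedman_test,
    ld_f1_anova_type,
    nemenyi_posthoc,
)
from .io_model import MgsAbundanceTable, SampleMetadata, ValidationError, VisitSchedule

__all__ = [
    "Period",
    "prevalence_filter",
    "log_fold_trajectory",
    "auc_statistic",
    "period_aucs",
    "compare_evolution",
    "friedman_with_nemenyi",
    "correlate_bss",
    "bss_consistency_summary",
    "ld_f1_anova_type",
    "RAW_ALPHA",
    "ADJUSTED_ALPHA",
]

#: Significance conventions: a raw p-value is significant below 0.05,
#: an adjusted (BH) p-value below 0.1.  Both are always reported.
RAW_ALPHA = 0.05
ADJUSTED_ALPHA = 0.10


@dataclass(frozen=True)
class Period:
    """An ordered set of visits; the first is the fold-change reference."""

    visits: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.visits) < 2:
            raise ValidationError("a period needs at least 2 visits")

    @property
    def t_initial(self) -> str:
        return self.visits[0]

    def day_offsets(self, schedule: VisitSchedule, time: str = "days") -> np.ndarray:
        """Time coordinate per visit: real day offsets or visit indices."""
        if time == "days":
            days = schedule.days(self.visits)
        elif time == "index":
            days = np.arange(len(self.visits), dtype=float)
        else:
            raise ValidationError(f"time must be 'days' or 'index', got {time!r}")
        if not np.all(np.diff(days) > 0):
            raise ValidationError(f"period visits not in increasing day order: {self.visits}")
        return days


def prevalence_filter(
    mgs: MgsAbundanceTable, min_fraction: float = 0.10
) -> MgsAbundanceTable:
    """Keep features present (abundance > 0) in strictly more than
    ``min_fraction`` of all samples."""
    frac = (mgs.abundance > 0).mean(axis=0)
    keep = frac.index[frac > min_fraction]
    return MgsAbundanceTable(mgs.abundance[list(keep)])


def _default_pseudo(abundance: pd.DataFrame) -> float:
    arr = abundance.to_numpy()
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValidationError("all-zero abundance table: cannot infer pseudocount")
    return float(positive.min())


def log_fold_trajectory(
    values: np.ndarray, pseudo: float
) -> np.ndarray:
    """log10 fold change of each value relative to the first.

    v(T) = log10((a(T) + pseudo) / (a(T_initial) + pseudo)); the initial
    point maps to 0 by construction, and zeros anywhere stay finite.
    """
    a = np.asarray(values, dtype=float)
    if pseudo <= 0:
        raise ValidationError("pseudo must be positive")
    return np.log10((a + pseudo) / (a[0] + pseudo))


def auc_statistic(
    trajectory: np.ndarray, day_offsets: np.ndarray, normalize: bool = True
) -> float:
    """Signed trapezoidal area under a fold-change trajectory.

    Positive when the feature rises from its initial value, negative when
    it falls, exactly 0 for a constant trajectory.  When ``normalize``
    the area is divided by the period span so periods of different length
    (29 pre-treatment vs 36 on-treatment days) are comparable; the result
    is then a time-averaged log10 fold change.  Fewer than 2 points is
    undefined (NaN).
    """
    v = np.asarray(trajectory, dtype=float)
    t = np.asarray(day_offsets, dtype=float)
    if v.size < 2 or v.size != t.size:
        return float("nan")
    area = float(np.trapezoid(v, t))
    if normalize:
        area /= float(t[-1] - t[0])
    return area


def period_aucs(
    mgs: MgsAbundanceTable,
    metadata: SampleMetadata,
    period: Period,
    pseudo: float | None = None,
    normalize: bool = True,
    time: str = "days",
) -> pd.DataFrame:
    """AUC per (subject, feature) over one period.

    Subjects lacking the initial visit or having fewer than 2 samples in
    the period get NaN.  Missing intermediate visits are simply dropped
    from the trapezoid (the trajectory is integrated over the visits the
    subject actually has).
    """
    if pseudo is None:
        pseudo = _default_pseudo(mgs.abundance)
    days = period.day_offsets(metadata.schedule, time=time)
    subjects = metadata.subjects
    features = mgs.abundance.columns
    out = np.full((len(subjects), len(features)), np.nan)
    for si, subject in enumerate(subjects):
        samples = [metadata.sample_for(subject, v) for v in period.visits]
        mask = np.array(
            [s is not None and s in mgs.abundance.index for s in samples]
        )
        if not mask[0] or mask.sum() < 2:
            continue
        rows = [s for s, m in zip(samples, mask) if m]
        a = mgs.abundance.loc[rows].to_numpy(dtype=float)
        v = np.log10((a + pseudo) / (a[0][None, :] + pseudo))
        t = days[mask]
        area = np.trapezoid(v, x=t, axis=0)
        if normalize:
            area /= t[-1] - t[0]
        out[si] = area
    return pd.DataFrame(out, index=subjects, columns=features)


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray, zero_method: str = "wilcox") -> float:
    """Paired Wilcoxon signed-rank p; NaN when no informative pairs.

    Exact distribution for fewer than 26 informative pairs without ties,
    normal approximation with tie correction otherwise.  The method is
    chosen explicitly (never scipy's 'auto') so small tied samples use
    the tie-corrected approximation rather than a resampling fallback.
    """
    diff = a - b
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return float("nan")
    tied = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size < 26 and not tied) else "approx"
    res = stats.wilcoxon(a, b, zero_method=zero_method, method=method)
    return float(res.pvalue)


def compare_evolution(
    mgs: MgsAbundanceTable,
    metadata: SampleMetadata,
    before: Period,
    during: Period,
    pseudo: float | None = None,
    min_paired: int = 5,
    normalize: bool = True,
    time: str = "days",
    raw_alpha: float = RAW_ALPHA,
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Per-feature contrast of pre-treatment vs on-treatment evolution.

    For every feature, the per-subject AUCs over the two periods are
    compared with a paired Wilcoxon signed-rank test; p-values are
    BH-adjusted across features.  Features with raw p <= ``raw_alpha``
    are followed up with Friedman tests of the raw abundances within
    each period (complete cases), and flagged ``changed_before`` /
    ``changed_during`` when the within-period Friedman is also
    significant at ``raw_alpha``.  Features with fewer than
    ``min_paired`` paired subjects, or identical trajectories for every
    subject, are reported untested (NaN p).

    Returns a DataFrame indexed by feature with columns: n_paired,
    auc_before_mean, auc_during_mean, p_auc, q_auc, p_friedman_before,
    p_friedman_during, changed_before, changed_during.
    """
    if pseudo is None:
        pseudo = _default_pseudo(mgs.abundance)
    auc_b = period_aucs(mgs, metadata, before, pseudo, normalize, time)
    auc_d = period_aucs(mgs, metadata, during, pseudo, normalize, time)
    features = mgs.abundance.columns
    n_feat = len(features)
    p_auc = np.full(n_feat, np.nan)
    n_paired = np.zeros(n_feat, dtype=int)
    mean_b = np.full(n_feat, np.nan)
    mean_d = np.full(n_feat, np.nan)
    ab = auc_b.to_numpy()
    ad = auc_d.to_numpy()
    paired_mask = ~np.isnan(ab) & ~np.isnan(ad)
    for fi in range(n_feat):
        mask = paired_mask[:, fi]
        n_paired[fi] = int(mask.sum())
        if n_paired[fi] < min_paired:
            continue
        x, y = ab[mask, fi], ad[mask, fi]
        mean_b[fi], mean_d[fi] = x.mean(), y.mean()
        p_auc[fi] = _paired_wilcoxon(x, y, zero_method)
    q_auc = benjamini_hochberg(p_auc)

    p_fb = np.full(n_feat, np.nan)
    p_fd = np.full(n_feat, np.nan)
    flagged = np.where(~np.isnan(p_auc) & (p_auc <= raw_alpha))[0]
    for fi in flagged:
        feature = features[fi]
        for period, dest in ((before, p_fb), (during, p_fd)):
            matrix = _complete_case_matrix(mgs, metadata, period, feature)
            if matrix is not None:
                dest[fi] = friedman_test(matrix)[1]
    changed_before = np.isin(np.arange(n_feat), flagged) & (p_fb <= raw_alpha)
    changed_during = np.isin(np.arange(n_feat), flagged) & (p_fd <= raw_alpha)
    return pd.DataFrame(
        {
            "n_paired": n_paired,
            "auc_before_mean": mean_b,
            "auc_during_mean": mean_d,
            "p_auc": p_auc,
            "q_auc": q_auc,
            "p_friedman_before": p_fb,
            "p_friedman_during": p_fd,
            "changed_before": changed_before,
            "changed_during": changed_during,
        },
        index=features,
    )


def _complete_case_matrix(
    mgs: MgsAbundanceTable, metadata: SampleMetadata, period: Period, feature
) -> np.ndarray | None:
    rows = []
    for subject in metadata.subjects:
        samples = [metadata.sample_for(subject, v) for v in period.visits]
        if any(s is None or s not in mgs.abundance.index for s in samples):
            continue
        rows.append(mgs.abundance.loc[samples, feature].to_numpy(dtype=float))
    if len(rows) < 2:
        return None
    return np.asarray(rows)


def friedman_with_nemenyi(
    values: np.ndarray | pd.DataFrame,
) -> tuple[float, float, np.ndarray]:
    """Friedman test over a complete subjects × visits matrix, plus the
    Nemenyi pairwise p-value matrix on the within-subject rank sums."""
    matrix = np.asarray(values, dtype=float)
    chi2, p = friedman_test(matrix)
    pairwise = nemenyi_posthoc(matrix)
    return chi2, p, pairwise


def correlate_bss(
    values: pd.DataFrame | pd.Series,
    metadata: SampleMetadata,
    visits: list[str] | None = None,
    raw_alpha: float = RAW_ALPHA,
) -> pd.DataFrame:
    """Spearman correlation of per-sample feature values with BSS, at
    each visit separately, BH-adjusted within visit.

    ``values`` is a samples × features DataFrame (or a Series, e.g. MGS
    richness).  Returns a long DataFrame (feature, visit, n, rho, p, q);
    rho is NaN where BSS (or the feature) is constant at a visit.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(values.name or "value")
    visits = visits or metadata.schedule.visits
    meta = metadata.table.set_index("sample_id")
    records = []
    for visit in visits:
        rows = meta[meta["visit"] == visit]
        samples = [s for s in rows.index if s in values.index]
        bss = rows.loc[samples, "bss"].astype(float)
        ok = bss.notna()
        samples = [s for s, keep in zip(samples, ok) if keep]
        bss = bss[ok]
        ps, rhos = [], []
        for feature in values.columns:
            x = values.loc[samples, feature].astype(float)
            if len(x) < 3 or bss.nunique() < 2 or x.nunique() < 2:
                rhos.append(np.nan)
                ps.append(np.nan)
                continue
            rho, p = stats.spearmanr(x, bss)
            rhos.append(float(rho))
            ps.append(float(p))
        qs = benjamini_hochberg(np.asarray(ps))
        for feature, rho, p, q in zip(values.columns, rhos, ps, qs):
            records.append(
                {
                    "feature": feature,
                    "visit": visit,
                    "n": len(samples),
                    "rho": rho,
                    "p": p,
                    "q": q,
                }
            )
    return pd.DataFrame(records)


def bss_consistency_summary(
    correlations: pd.DataFrame, raw_alpha: float = RAW_ALPHA
) -> pd.DataFrame:
    """Cross-visit consistency of BSS correlations.

    For each feature: at how many visits it is significant (raw
    p <= alpha) and whether the significant correlations agree in sign.
    """
    out = []
    for feature, grp in correlations.groupby("feature", sort=False):
        sig = grp[(grp["p"] <= raw_alpha) & grp["p"].notna()]
        signs = np.sign(sig["rho"].to_numpy())
        out.append(
            {
                "feature": feature,
                "n_visits_significant": len(sig),
                "sign_consistent": bool(len(signs) > 0 and np.all(signs == signs[0])),
            }
        )
    return pd.DataFrame(out).set_index("feature")
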