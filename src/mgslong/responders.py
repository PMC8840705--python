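"""Responder stratification and group contrasts.

Subjects are clustered by k-means (k = 3) on the post-baseline deltas of
their Bristol stool scale (BSS at D8, D35, ... minus BSS at baseline
D-1).  Clusters are relabelled semantically: *early* responders show the
largest mean BSS drop at the first post-baseline visit, *non*-responders
the smallest overall drop, *late* responders are the remainder.  The
group-contrast battery then compares groups on clinical variables
(Mann–Whitney for quantitative, chi-squared for categorical), screens
the prevalence-filtered MGS with Kruskal–Wallis at each pre-treatment
visit (Dunn post-hoc), and reruns the AUC evolution contrast within
each group.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._nonparametric import cliffs_delta, dunn_posthoc
from .abundance import mgs_richness
from .io_model import MgsAbundanceTable, SampleMetadata, ValidationError
from .longitudinal import RAW_ALPHA, Period, compare_evolution

__all__ = [
    "ResponderAssignment",
    "kmeans_responders",
    "group_contrasts",
    "per_group_evolution",
    "cliffs_delta",
]

RESPONDER_LABELS = ("early", "late", "non")


@dataclass
class ResponderAssignment:
    """Per-subject responder labels with the delta-BSS features used.

    ``labels`` maps subject id -> 'early' | 'late' | 'non';
    ``deltas`` is the subjects × post-baseline-visit matrix of BSS
    changes from baseline; ``excluded`` lists subjects removed for
    missing data.  ``degenerate`` is set when the clusters were not
    separable (e.g. all-identical deltas) and labels are arbitrary.
    """

    labels: pd.Series
    deltas: pd.DataFrame
    excluded: list
    degenerate: bool = False

    def subjects(self, label: str) -> list:
        return sorted(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in RESPONDER_LABELS}


def _delta_bss(
    metadata: SampleMetadata, post_visits: list[str]
) -> tuple[pd.DataFrame, list]:
    baseline = metadata.schedule.baseline
    wide = metadata.bss_matrix()
    needed = [baseline] + list(post_visits)
    missing_cols = [v for v in needed if v not in wide.columns]
    if missing_cols:
        raise ValidationError(f"no BSS recorded for visits: {missing_cols}")
    complete = wide[needed].dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    deltas = complete[list(post_visits)].sub(complete[baseline], axis=0)
    return deltas, excluded


def kmeans_responders(
    metadata: SampleMetadata,
    post_visits: list[str] | None = None,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> ResponderAssignment:
    """Cluster subjects on delta BSS (post-baseline visits vs baseline).

    Lloyd's k-means with ``n_init`` seeded restarts (best inertia kept),
    deterministic given ``seed``.  Subjects with any required BSS value
    missing are excluded, not imputed.  With k = 3 the clusters get the
    semantic labels early/late/non as described in the module docstring;
    for other k the labels are cluster indices as strings.
    """
    post_visits = post_visits or [
        v
        for v in metadata.schedule.visits
        if metadata.schedule.day(v) > metadata.schedule.day(metadata.schedule.baseline)
    ]
    deltas, excluded = _delta_bss(metadata, post_visits)
    if k > len(deltas):
        raise ValidationError(
            f"k={k} but only {len(deltas)} subjects with complete BSS"
        )
    X = deltas.to_numpy(dtype=float)
    degenerate = bool(len(np.unique(X, axis=0)) < k)
    if degenerate:
        warnings.warn(
            "fewer distinct delta-BSS profiles than clusters; "
            "labels are arbitrary",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    if k == 3 and not degenerate:
        name_of = _semantic_labels(deltas, raw, km.cluster_centers_)
        labels = pd.Series([name_of[c] for c in raw], index=deltas.index)
    else:
        labels = pd.Series([str(c) for c in raw], index=deltas.index)
    return ResponderAssignment(labels, deltas, excluded, degenerate)


def _semantic_labels(
    deltas: pd.DataFrame, raw: np.ndarray, centers: np.ndarray
) -> dict[int, str]:
    """early = largest drop at the first post-baseline visit,
    non = smallest overall drop among the rest, late = remaining."""
    first = centers[:, 0]
    overall = centers.mean(axis=1)
    early = int(np.argmin(first))
    rest = [c for c in range(len(centers)) if c != early]
    non = max(rest, key=lambda c: overall[c])
    (late,) = [c for c in rest if c != non]
    return {early: "early", late: "late", non: "non"}


def _subject_table(metadata: SampleMetadata) -> pd.DataFrame:
    """One row per subject: age, sex, country, baseline BSS."""
    baseline = metadata.schedule.baseline
    per_subject = metadata.table.groupby("subject_id").first()[["age", "sex", "country"]]
    base_bss = metadata.bss_matrix().get(baseline)
    per_subject["baseline_bss"] = base_bss
    return per_subject


def group_contrasts(
    assignment: ResponderAssignment,
    metadata: SampleMetadata,
    mgs: MgsAbundanceTable | None = None,
    pre_visits: list[str] | None = None,
    raw_alpha: float = RAW_ALPHA,
) -> dict:
    """Baseline comparability and pre-treatment MGS screen across groups.

    Quantitative variables (age, baseline BSS, baseline MGS richness) get
    pairwise Mann–Whitney tests with Cliff's delta effect sizes;
    categorical variables (sex, country) chi-squared.  If an abundance
    table is given, every feature is screened with Kruskal–Wallis across
    the groups at each pre-treatment visit; features significant (raw
    p <= alpha) at *all* pre-treatment visits form the consistency screen
    and get Dunn post-hoc p-values.
    """
    groups = [g for g in RESPONDER_LABELS if g in set(assignment.labels)]
    if len(groups) < 2:
        groups = sorted(set(assignment.labels))
    members = {g: assignment.subjects(g) for g in groups}
    for g, subj in members.items():
        if len(subj) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    subj_table = _subject_table(metadata)

    quantitative: dict[str, pd.Series] = {
        "age": subj_table["age"].astype(float),
        "baseline_bss": subj_table["baseline_bss"].astype(float),
    }
    baseline = metadata.schedule.baseline
    if mgs is not None:
        rich = mgs_richness(mgs)
        base_samples = {
            s: metadata.sample_for(s, baseline) for s in assignment.labels.index
        }
        quantitative["baseline_mgs_richness"] = pd.Series(
            {
                s: float(rich[smp])
                for s, smp in base_samples.items()
                if smp is not None and smp in rich.index
            }
        )

    pairwise_rows = []
    for var, series in quantitative.items():
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                x = series.reindex(members[ga]).dropna().to_numpy()
                y = series.reindex(members[gb]).dropna().to_numpy()
                if len(x) == 0 or len(y) == 0:
                    continue
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
                d, mag = cliffs_delta(x, y)
                pairwise_rows.append(
                    {
                        "variable": var,
                        "group_a": ga,
                        "group_b": gb,
                        "mean_a": float(np.mean(x)),
                        "mean_b": float(np.mean(y)),
                        "p_mannwhitney": p,
                        "cliffs_delta": d,
                        "magnitude": mag,
                    }
                )
    quantitative_table = pd.DataFrame(pairwise_rows)

    categorical_rows = []
    for var in ("sex", "country"):
        table = pd.crosstab(
            assignment.labels, subj_table[var].reindex(assignment.labels.index)
        )
        if table.shape[1] < 2:
            categorical_rows.append({"variable": var, "chi2": 0.0, "p_chi2": 1.0})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        categorical_rows.append({"variable": var, "chi2": float(chi2), "p_chi2": float(p)})
    categorical_table = pd.DataFrame(categorical_rows)

    result: dict = {
        "groups": {g: len(members[g]) for g in groups},
        "quantitative": quantitative_table,
        "categorical": categorical_table,
    }

    if mgs is not None:
        pre_visits = pre_visits or [
            v
            for v in metadata.schedule.visits
            if metadata.schedule.day(v) <= metadata.schedule.day(baseline)
        ]
        kw = _kruskal_screen(assignment, metadata, mgs, groups, members, pre_visits)
        consistent = kw.index[(kw <= raw_alpha).all(axis=1)].tolist()
        dunn = {}
        for feature in consistent:
            per_visit = {}
            for visit in pre_visits:
                group_values = _group_values(
                    metadata, mgs, members, groups, visit, feature
                )
                if group_values is not None:
                    per_visit[visit] = pd.DataFrame(
                        dunn_posthoc(group_values), index=groups, columns=groups
                    )
            dunn[feature] = per_visit
        result["kruskal_wallis"] = kw
        result["consistent_features"] = consistent
        result["dunn"] = dunn
    return result


def _group_values(metadata, mgs, members, groups, visit, feature):
    out = []
    for g in groups:
        samples = [metadata.sample_for(s, visit) for s in members[g]]
        samples = [s for s in samples if s is not None and s in mgs.abundance.index]
        if len(samples) < 2:
            return None
        out.append(mgs.abundance.loc[samples, feature].to_numpy(dtype=float))
    return out


def _kruskal_screen(assignment, metadata, mgs, groups, members, visits) -> pd.DataFrame:
    pvals = pd.DataFrame(
        np.nan, index=mgs.abundance.columns, columns=visits, dtype=float
    )
    for visit in visits:
        sample_lists = []
        for g in groups:
            samples = [metadata.sample_for(s, visit) for s in members[g]]
            sample_lists.append(
                [s for s in samples if s is not None and s in mgs.abundance.index]
            )
        if any(len(s) < 2 for s in sample_lists):
            continue
        for feature in mgs.abundance.columns:
            vals = [
                mgs.abundance.loc[s, feature].to_numpy(dtype=float)
                for s in sample_lists
            ]
            if np.ptp(np.concatenate(vals)) == 0:
                pvals.loc[feature, visit] = 1.0
                continue
            pvals.loc[feature, visit] = float(stats.kruskal(*vals).pvalue)
    return pvals


def per_group_evolution(
    assignment: ResponderAssignment,
    mgs: MgsAbundanceTable,
    metadata: SampleMetadata,
    before: Period,
    during: Period,
    min_paired: int = 5,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run the AUC evolution contrast within each responder group.

    Groups with fewer than ``min_paired`` subjects are skipped (recorded
    as absent from the result).
    """
    results: dict[str, pd.DataFrame] = {}
    for label in sorted(set(assignment.labels)):
        subjects = assignment.subjects(label)
        if len(subjects) < min_paired:
            continue
        mask = metadata.table["subject_id"].isin(subjects)
        sub_meta = SampleMetadata(
            metadata.table[mask].copy(), metadata.schedule
        )
        results[label] = compare_evolution(
            mgs, sub_meta, before, during, min_paired=min_paired, **kwargs
        )
    return results
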