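"""Community-level stability: Bray–Curtis dissimilarity, PCoA, ANOSIM.

Dissimilarity is computed on log10-transformed MGS abundances.  Zeros
are kept at zero by the transform x -> log10(1 + x/pseudo) (equivalently
log10(x + pseudo) - log10(pseudo)), with the pseudocount defaulting to
the smallest nonzero abundance in the table.  Ordination is classical
PCoA (double-centered eigendecomposition, via scikit-bio); group
structure is tested with a seeded ANOSIM permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, wilcoxon

from .io_model import MgsAbundanceTable, SampleMetadata, ValidationError

__all__ = [
    "DissimilarityMatrix",
    "log10_transform",
    "bray_curtis",
    "paired_dissimilarity_to_baseline",
    "compare_baseline_dissimilarity",
    "pcoa",
    "anosim",
    "phylum_stability_chisq",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    d: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.d.to_numpy()
        if not np.allclose(arr, arr.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0):
            raise ValidationError("dissimilarity diagonal must be zero")
        if arr.min() < 0:
            raise ValidationError("dissimilarities must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.d.index)

    def value(self, i, j) -> float:
        return float(self.d.loc[i, j])

    def condensed(self) -> np.ndarray:
        return squareform(self.d.to_numpy(), checks=False)


def log10_transform(abundance: pd.DataFrame, pseudo: float | None = None) -> pd.DataFrame:
    """x -> log10(1 + x/pseudo); zero maps to zero, monotone increasing.

    ``pseudo`` defaults to the smallest strictly positive value in the
    table.
    """
    arr = abundance.to_numpy(dtype=float)
    if pseudo is None:
        positive = arr[arr > 0]
        if positive.size == 0:
            raise ValidationError("all-zero table: cannot infer a pseudocount")
        pseudo = float(positive.min())
    if pseudo <= 0:
        raise ValidationError("pseudo must be positive")
    return pd.DataFrame(
        np.log10(1.0 + arr / pseudo), index=abundance.index, columns=abundance.columns
    )


def bray_curtis(
    mgs: MgsAbundanceTable,
    log_transform: bool = True,
    pseudo: float | None = None,
) -> DissimilarityMatrix:
    """Bray–Curtis dissimilarity BC(i,j) = sum|a-b| / sum(a+b) on the
    (optionally log10-transformed) MGS abundance table.

    A pair of all-zero samples has an undefined BC; it is defined as 0
    with a warning.
    """
    table = mgs.abundance
    if log_transform:
        table = log10_transform(table, pseudo)
    arr = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        condensed = pdist(arr, metric="braycurtis")
    if np.isnan(condensed).any():
        warnings.warn(
            "all-zero sample pair(s): Bray-Curtis undefined, set to 0",
            stacklevel=2,
        )
        condensed = np.nan_to_num(condensed, nan=0.0)
    dm = pd.DataFrame(
        squareform(condensed), index=table.index, columns=table.index
    )
    return DissimilarityMatrix(dm)


def paired_dissimilarity_to_baseline(
    d: DissimilarityMatrix,
    metadata: SampleMetadata,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Per-subject dissimilarity between the baseline sample and every
    other visit.

    Returns a long DataFrame (subject_id, visit, day, dissimilarity) with
    one row per (subject, non-baseline visit) where both samples exist;
    subjects without a baseline sample are skipped.
    """
    schedule = metadata.schedule
    baseline = baseline or schedule.baseline
    rows = []
    for subject in metadata.subjects:
        base_sample = metadata.sample_for(subject, baseline)
        if base_sample is None or base_sample not in d.d.index:
            continue
        for visit in schedule.visits:
            if visit == baseline:
                continue
            other = metadata.sample_for(subject, visit)
            if other is None or other not in d.d.index:
                continue
            rows.append(
                {
                    "subject_id": subject,
                    "visit": visit,
                    "day": schedule.day(visit),
                    "dissimilarity": d.value(base_sample, other),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "visit", "day", "dissimilarity"])


def compare_baseline_dissimilarity(
    paired: pd.DataFrame, visit_a: str, visit_b: str
) -> tuple[float, int]:
    """Wilcoxon signed-rank comparison of baseline<->visit_a vs
    baseline<->visit_b dissimilarities over the subjects with both.

    Returns (p, n_pairs).
    """
    a = paired[paired["visit"] == visit_a].set_index("subject_id")["dissimilarity"]
    b = paired[paired["visit"] == visit_b].set_index("subject_id")["dissimilarity"]
    common = a.index.intersection(b.index)
    if len(common) < 2:
        return float("nan"), len(common)
    if np.allclose(a[common], b[common]):
        return 1.0, len(common)
    stat = wilcoxon(a[common], b[common])
    return float(stat.pvalue), len(common)


def pcoa(
    d: DissimilarityMatrix, n_axes: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical PCoA (metric MDS) of a dissimilarity matrix.

    Double-centering followed by eigendecomposition; axes are sorted by
    decreasing eigenvalue and negative eigenvalues are reported (their
    axes carry zero coordinates).  Returns (coordinates DataFrame with
    columns PCo1.., eigenvalues including negatives).
    """
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    ids = [str(s) for s in d.sample_ids]
    dm = DistanceMatrix(d.d.to_numpy(), ids=ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    coords = pd.DataFrame(
        res.samples.to_numpy(),
        index=d.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(res.samples.shape[1])],
    )
    if n_axes is not None:
        max_axes = coords.shape[1]
        if n_axes > max_axes:
            warnings.warn(
                f"requested {n_axes} axes, only {max_axes} available; truncated",
                stacklevel=2,
            )
            n_axes = max_axes
        coords = coords.iloc[:, :n_axes]
    return coords, eigvals


def _anosim_r(rank_condensed: np.ndarray, within: np.ndarray) -> float:
    m = rank_condensed.size
    r_within = rank_condensed[within].mean()
    r_between = rank_condensed[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    d: DissimilarityMatrix,
    grouping: pd.Series | dict,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """ANOSIM test of group separation on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 ranked dissimilarities; the permutation p-value includes
    the observed labelling, p = (b + 1)/(B + 1).  Deterministic given
    ``seed``.
    """
    if isinstance(grouping, dict):
        grouping = pd.Series(grouping)
    labels = grouping.reindex(d.sample_ids)
    if labels.isna().any():
        raise ValidationError("grouping missing for some samples")
    groups, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(groups) < 2 or (counts < 2).any():
        raise ValidationError("need >=2 groups with >=2 samples each")
    codes = pd.Categorical(labels).codes
    n = len(codes)
    ranks = rankdata(d.condensed())
    ii, jj = np.triu_indices(n, 1)
    observed_within = codes[ii] == codes[jj]
    r_obs = _anosim_r(ranks, observed_within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        within = perm[ii] == perm[jj]
        if _anosim_r(ranks, within) >= r_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return r_obs, float(p)


def phylum_stability_chisq(
    phylum_abundance: pd.DataFrame, metadata: SampleMetadata
) -> tuple[float, float, pd.DataFrame]:
    """Chi-squared test of the visits × phyla profile of mean relative
    abundances (each visit's means scaled to percentages).

    This operationalises "the phylum distribution remained constant over
    the timeline" as independence of the visit × phylum percentage table;
    the construction is an interpretation, documented as such.  Returns
    (chi2, p, table).
    """
    from scipy.stats import chi2_contingency

    visit = metadata.visit_of().reindex(phylum_abundance.index)
    means = phylum_abundance.groupby(visit).mean()
    means = means.reindex([v for v in metadata.schedule.visits if v in means.index])
    pct = means.div(means.sum(axis=1), axis=0) * 100.0
    pct = pct.loc[:, (pct > 0).any(axis=0)]
    chi2, p, _, _ = chi2_contingency(pct.to_numpy())
    return float(chi2), float(p), pct
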