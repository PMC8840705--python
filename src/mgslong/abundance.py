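"""From raw gene counts to MGS and higher-rank relative abundances.

The quantification chain is:

1. :func:`downsize` — rarefy every sample to a common mapped-read depth
   (study value 14.5 million) by simple random sampling of reads without
   replacement, i.e. a multivariate-hypergeometric draw per sample.
2. :func:`fpkm_normalize` — divide by gene length (kb) and sample depth
   (millions of mapped reads): reads per kilobase per million mapped
   reads.
3. :func:`mgs_abundance` — the relative abundance of an MGS in a sample
   is the arithmetic mean FPKM of its 50 marker genes; if strictly fewer
   than 10% of the markers are seen (frequency > 0) the abundance is set
   to exactly 0.
4. :func:`aggregate_taxa` — abundances at higher taxonomic ranks are the
   sum of the member MGS; MGS unannotated at a rank pool into an
   "unclassified <parent>" bucket so totals are conserved.

Richness (:func:`gene_richness`, :func:`mgs_richness`) counts features
with strictly positive abundance after downsizing / the zero rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_model import (
    TAXONOMIC_RANKS,
    FrequencyTable,
    GeneCountTable,
    MgsAbundanceTable,
    MgsCatalog,
    ValidationError,
)

__all__ = [
    "DownsizeSpec",
    "downsize",
    "fpkm_normalize",
    "mgs_abundance",
    "aggregate_taxa",
    "gene_richness",
    "mgs_richness",
    "select_markers",
]


@dataclass(frozen=True)
class DownsizeSpec:
    """Rarefaction parameters.

    target_depth
        Common mapped-read depth, in reads (study value 14,500,000).
    seed
        Seed for the without-replacement draw; same seed, same output.
    drop_below_target
        If True, samples shallower than the target are dropped (with the
        drop recorded by the caller); if False they raise.
    """

    target_depth: int = 14_500_000
    seed: int = 0
    drop_below_target: bool = False

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValidationError("target_depth must be positive")


def downsize(table: GeneCountTable, spec: DownsizeSpec) -> GeneCountTable:
    """Rarefy each sample to ``spec.target_depth`` mapped reads.

    Each retained output row sums exactly to the target depth, output
    counts never exceed input counts, and a sample already exactly at
    the target is returned unchanged.  The draw is multivariate
    hypergeometric (reads subsampled without replacement), reproducible
    given ``spec.seed``.
    """
    depths = table.mapped_depth
    shallow = depths.index[depths < spec.target_depth].tolist()
    if shallow and not spec.drop_below_target:
        raise ValidationError(
            f"samples below target depth {spec.target_depth}: {shallow}"
        )
    rng = np.random.default_rng(spec.seed)
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    out = np.empty((len(keep), table.counts.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy(dtype=np.int64)
        if depths[s] == spec.target_depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, spec.target_depth)
    return GeneCountTable(
        pd.DataFrame(out, index=keep, columns=table.counts.columns)
    )


def fpkm_normalize(table: GeneCountTable, lengths: pd.Series) -> FrequencyTable:
    """Gene-length and depth normalization: reads/(kb × million mapped reads).

    freq(s, g) = count(s, g) / (length(g)/1e3 × depth(s)/1e6).  The input
    is expected to be downsized already so depth is common across samples.
    """
    missing = [g for g in table.gene_ids if g not in lengths.index]
    if missing:
        raise ValidationError(f"genes without length: {missing[:5]}")
    len_kb = lengths.reindex(table.counts.columns).to_numpy(dtype=float) / 1e3
    depth_m = table.mapped_depth.to_numpy(dtype=float) / 1e6
    freq = table.counts.to_numpy(dtype=float) / (len_kb[None, :] * depth_m[:, None])
    return FrequencyTable(
        pd.DataFrame(freq, index=table.counts.index, columns=table.counts.columns)
    )


def mgs_abundance(
    freq: FrequencyTable,
    catalog: MgsCatalog,
    detection_fraction: float = 0.10,
) -> MgsAbundanceTable:
    """Marker-gene mean abundance per MGS with the detection zero rule.

    abundance(s, m) = mean FPKM over m's marker genes.  If the fraction
    of markers with strictly positive frequency is below
    ``detection_fraction`` (strict: exactly 10% detected out of 50, i.e.
    5 markers, is *not* below 10%), the abundance is set to exactly 0.
    Markers absent from the frequency table count as undetected zeros.
    """
    cols = {}
    for mgs in catalog.mgs_ids:
        markers = catalog.mgs_markers[mgs]
        if not markers:
            raise ValidationError(f"MGS {mgs!r} has no marker genes")
        sub = freq.freq.reindex(columns=markers, fill_value=0.0)
        vals = sub.to_numpy()
        mean = vals.mean(axis=1)
        detected = (vals > 0).mean(axis=1)
        mean[detected < detection_fraction] = 0.0
        cols[mgs] = mean
    table = pd.DataFrame(cols, index=freq.freq.index)
    return MgsAbundanceTable(table)


def _rank_labels(catalog: MgsCatalog, rank: str) -> pd.Series:
    """Taxon label at ``rank`` per MGS, pooling unannotated MGS into
    'unclassified <nearest annotated parent>'."""
    if rank not in TAXONOMIC_RANKS:
        raise ValidationError(
            f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}"
        )
    rank_pos = TAXONOMIC_RANKS.index(rank)
    labels = {}
    for mgs in catalog.mgs_ids:
        lineage = catalog.lineage(mgs)
        name = lineage.get(rank, "unclassified")
        if name and name.lower() not in ("unclassified", "nan", ""):
            labels[mgs] = name
            continue
        parent = "unclassified"
        for r in reversed(TAXONOMIC_RANKS[:rank_pos]):
            cand = lineage.get(r, "")
            if cand and cand.lower() not in ("unclassified", "nan", ""):
                parent = cand
                break
        labels[mgs] = f"unclassified {parent}" if parent != "unclassified" else "unclassified"
    return pd.Series(labels)


def aggregate_taxa(
    mgs: MgsAbundanceTable, catalog: MgsCatalog, rank: str
) -> pd.DataFrame:
    """Sum MGS abundances by taxon at ``rank`` (samples × taxa).

    The total abundance at every rank equals the total MGS abundance:
    unannotated MGS are pooled, never dropped.
    """
    labels = _rank_labels(catalog, rank)
    labels = labels.reindex(mgs.abundance.columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValidationError(f"MGS not in catalog: {missing[:5]}")
    return mgs.abundance.T.groupby(labels).sum().T


def gene_richness(table: GeneCountTable) -> pd.Series:
    """Number of genes with strictly positive count, per sample."""
    return (table.counts > 0).sum(axis=1)


def mgs_richness(mgs: MgsAbundanceTable) -> pd.Series:
    """Number of MGS with strictly positive abundance, per sample."""
    return (mgs.abundance > 0).sum(axis=1)


def select_markers(
    freq: FrequencyTable, catalog: MgsCatalog, n_markers: int = 50
) -> dict[str, list[str]]:
    """Optional helper: pick the ``n_markers`` most mutually co-abundant
    genes of each MGS (highest mean intra-MGS Spearman correlation across
    samples).

    Marker sets are normally an input; pipeline correctness never depends
    on this helper.
    """
    out: dict[str, list[str]] = {}
    for mgs, genes in catalog.mgs_members.items():
        present = [g for g in genes if g in freq.freq.columns]
        if len(present) <= n_markers:
            out[mgs] = list(present)
            continue
        sub = freq.freq[present].to_numpy()
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant genes give undefined rho
            rho, _ = spearmanr(sub)
            rho = np.atleast_2d(np.asarray(rho, dtype=float))
            np.fill_diagonal(rho, np.nan)
            mean_rho = np.nanmean(rho, axis=1)
        mean_rho = np.nan_to_num(mean_rho, nan=-np.inf)
        order = np.argsort(-mean_rho)[:n_markers]
        out[mgs] = [present[i] for i in sorted(order)]
    return out
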