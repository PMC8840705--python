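"""Data model and file formats for the longitudinal MGS pipeline.

The pipeline works on four tabular objects:

* :class:`GeneCountTable` — integer mapped-read counts per (sample, gene),
  the raw input produced upstream by read mapping against a gene catalog.
* :class:`MgsCatalog` — the metagenomic-species (MGS) definitions: which
  catalog genes belong to which MGS, which 50 of them are the "marker"
  genes whose mean frequency quantifies the MGS, gene lengths in bp, and
  a taxonomy from superkingdom down to species.
* :class:`FrequencyTable` / :class:`MgsAbundanceTable` — the normalized
  gene frequencies (FPKM) and the derived MGS relative abundances.
* :class:`SampleMetadata` — per-sample clinical annotations (subject,
  visit, Bristol stool scale, stool frequency, age, sex, country).

Files are plain TSV (UTF-8, tab-delimited, '.' decimal); count matrices
may alternatively be Matrix-Market coordinate triplets with two sidecar
label files, since catalog-scale matrices are sparse.  Readers validate
and reject rather than coerce; every accepted file round-trips through
the paired writer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ValidationError",
    "FormatError",
    "VisitSchedule",
    "GeneCountTable",
    "FrequencyTable",
    "MgsAbundanceTable",
    "MgsCatalog",
    "SampleMetadata",
    "TAXONOMIC_RANKS",
    "read_count_table",
    "write_count_table",
    "read_mgs_catalog",
    "write_mgs_catalog",
    "read_metadata",
    "write_metadata",
]

#: Ranks from coarsest to finest, as used in the catalog taxonomy table.
TAXONOMIC_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class ValidationError(ValueError):
    """An input value violates a data-model invariant."""


class FormatError(ValueError):
    """A file cannot be parsed under the declared format."""


# ---------------------------------------------------------------------------
# Visit schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VisitSchedule:
    """Mapping of free-form visit labels to integer day offsets.

    Visit ordering is derived solely from the day offsets, never from
    label lexicography.  The default reproduces the five stool-sampling
    visits of a 5-week treatment study: two screening visits (D-30,
    D-14), the pre-treatment baseline (D-1) and two on-treatment visits
    (D8, D35).
    """

    day_offsets: Mapping[str, int] = field(
        default_factory=lambda: {"D-30": -30, "D-14": -14, "D-1": -1, "D8": 8, "D35": 35}
    )
    baseline: str = "D-1"

    def __post_init__(self) -> None:
        if self.baseline not in self.day_offsets:
            raise ValidationError(f"baseline visit {self.baseline!r} has no day offset")
        offsets = list(self.day_offsets.values())
        if len(set(offsets)) != len(offsets):
            raise ValidationError("visit day offsets must be distinct")

    @property
    def visits(self) -> list[str]:
        """Visit labels sorted by day offset."""
        return sorted(self.day_offsets, key=self.day_offsets.__getitem__)

    def day(self, visit: str) -> int:
        try:
            return int(self.day_offsets[visit])
        except KeyError:
            raise ValidationError(f"unknown visit label {visit!r}") from None

    def days(self, visits: Iterable[str]) -> np.ndarray:
        return np.asarray([self.day(v) for v in visits], dtype=float)


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------


def _check_unique(labels: Sequence, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GeneCountTable:
    """Integer reads per (sample, gene).

    ``counts`` is a dense samples × genes DataFrame of non-negative
    integers.  ``mapped_depth`` is by definition the per-sample row sum.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "sample ids")
        _check_unique(self.counts.columns, "gene ids")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr)
            if np.any(frac != 0):
                r, c = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at (sample={self.counts.index[r]!r}, "
                    f"gene={self.counts.columns[c]!r})"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at (sample={self.counts.index[r]!r}, "
                f"gene={self.counts.columns[c]!r})"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def mapped_depth(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneCountTable) and self.counts.equals(other.counts)


@dataclass
class FrequencyTable:
    """Non-negative gene frequencies (FPKM) per (sample, gene)."""

    freq: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.freq.index, "sample ids")
        _check_unique(self.freq.columns, "gene ids")
        if self.freq.size and self.freq.to_numpy().min() < 0:
            raise ValidationError("frequencies must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.freq.index)

    @property
    def gene_ids(self) -> list:
        return list(self.freq.columns)


@dataclass
class MgsAbundanceTable:
    """Relative abundance per (sample, MGS) — marker-gene means after the
    detection zero rule."""

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.abundance.index, "sample ids")
        _check_unique(self.abundance.columns, "MGS ids")
        if self.abundance.size and self.abundance.to_numpy().min() < 0:
            raise ValidationError("abundances must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def mgs_ids(self) -> list:
        return list(self.abundance.columns)


# ---------------------------------------------------------------------------
# MGS catalog
# ---------------------------------------------------------------------------


@dataclass
class MgsCatalog:
    """MGS definitions: member genes, marker genes, gene lengths, taxonomy.

    ``taxonomy`` is indexed by MGS id with the columns of
    :data:`TAXONOMIC_RANKS`; any level may be ``"unclassified"``.
    An MGS whose marker set does not have ``expected_markers`` genes is
    accepted with a warning — the detection zero rule then uses the
    actual marker count as its denominator.
    """

    gene_lengths: pd.Series
    mgs_members: dict[str, list[str]]
    mgs_markers: dict[str, list[str]]
    taxonomy: pd.DataFrame
    expected_markers: int = 50

    def __post_init__(self) -> None:
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
            raise ValidationError(f"gene {bad!r} has non-positive length")
        seen: dict[str, str] = {}
        for mgs, genes in self.mgs_members.items():
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} belongs to both MGS {seen[g]!r} and {mgs!r}"
                    )
                seen[g] = mgs
        for mgs, markers in self.mgs_markers.items():
            members = set(self.mgs_members.get(mgs, ()))
            extra = set(markers) - members
            if extra:
                raise ValidationError(
                    f"MGS {mgs!r}: markers not among members: {sorted(extra)[:5]}"
                )
            if len(markers) == 0:
                raise ValidationError(f"MGS {mgs!r} has no marker genes")
            if len(markers) != self.expected_markers:
                warnings.warn(
                    f"MGS {mgs!r} has {len(markers)} marker genes "
                    f"(expected {self.expected_markers}); the detection rule "
                    "will use the actual count",
                    stacklevel=2,
                )
        missing_len = [
            g for genes in self.mgs_members.values() for g in genes
            if g not in self.gene_lengths.index
        ]
        if missing_len:
            raise ValidationError(f"genes without length: {missing_len[:5]}")

    @property
    def mgs_ids(self) -> list[str]:
        return list(self.mgs_members)

    def marker_count(self, mgs: str) -> int:
        return len(self.mgs_markers[mgs])

    def lineage(self, mgs: str) -> dict[str, str]:
        """Taxonomy of one MGS as a rank → name dict."""
        if mgs not in self.taxonomy.index:
            return {r: "unclassified" for r in TAXONOMIC_RANKS}
        row = self.taxonomy.loc[mgs]
        return {r: str(row.get(r, "unclassified")) for r in TAXONOMIC_RANKS}


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "visit",
    "bss",
    "stool_frequency",
    "age",
    "sex",
    "country",
]


@dataclass
class SampleMetadata:
    """Per-sample clinical annotations.

    ``table`` holds one row per stool sample with subject id, visit
    label, Bristol stool scale (integer 1–7 or missing), stool frequency
    per day (or missing), age, sex (M/F) and country.  Subjects with
    missing visits are flagged in :attr:`incomplete_subjects`, not
    dropped: downstream tests apply pairwise deletion.
    """

    table: pd.DataFrame
    schedule: VisitSchedule = field(default_factory=VisitSchedule)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        _check_unique(df["sample_id"], "sample ids")
        pair = df[["subject_id", "visit"]].apply(tuple, axis=1)
        if pair.duplicated().any():
            raise ValidationError(
                f"duplicate (subject, visit): {pair[pair.duplicated()].iloc[0]}"
            )
        for v in df["visit"].unique():
            self.schedule.day(v)  # raises on unknown label
        bss = df["bss"].dropna()
        bad = bss[(bss < 1) | (bss > 7) | (bss != bss.round())]
        if len(bad):
            raise ValidationError(
                f"BSS outside 1..7 for sample {df.loc[bad.index[0], 'sample_id']!r}: "
                f"{bad.iloc[0]}"
            )
        sex = df["sex"].dropna()
        if not set(sex.unique()) <= {"M", "F"}:
            raise ValidationError(f"sex must be M or F, got {sorted(set(sex))}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    @property
    def subjects(self) -> list:
        return sorted(self.table["subject_id"].unique())

    @property
    def incomplete_subjects(self) -> list:
        """Subjects missing at least one scheduled visit."""
        n_visits = len(self.schedule.day_offsets)
        counts = self.table.groupby("subject_id")["visit"].nunique()
        return sorted(counts.index[counts < n_visits])

    def sample_for(self, subject, visit) -> str | None:
        rows = self.table[
            (self.table["subject_id"] == subject) & (self.table["visit"] == visit)
        ]
        return None if rows.empty else rows["sample_id"].iloc[0]

    def visit_of(self) -> pd.Series:
        """Visit label indexed by sample id."""
        return self.table.set_index("sample_id")["visit"]

    def subject_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["subject_id"]

    def bss_matrix(self) -> pd.DataFrame:
        """Subjects × visits matrix of BSS values (NaN where missing)."""
        wide = self.table.pivot(index="subject_id", columns="visit", values="bss")
        return wide.reindex(columns=[v for v in self.schedule.visits if v in wide])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_labels(path: Path) -> list[str]:
    text = path.read_text(encoding="utf-8")
    return [line for line in text.splitlines() if line]


def read_count_table(path: str | Path, format: str = "tsv") -> GeneCountTable:
    """Read a gene count matrix.

    ``tsv``: header row of gene ids, first column sample ids.
    ``mtx-triplet``: Matrix-Market coordinate file ``X.mtx`` with sidecars
    ``X.mtx.rows`` (sample ids) and ``X.mtx.cols`` (gene ids).
    """
    path = Path(path)
    if format == "tsv":
        if path.stat().st_size == 0:
            raise ValidationError(f"{path} is empty")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no gene columns")
        df.index.name = None
        df.columns.name = None
        return GeneCountTable(df)
    if format == "mtx-triplet":
        mat = scipy.io.mmread(path)
        rows = _read_labels(path.with_suffix(path.suffix + ".rows"))
        cols = _read_labels(path.with_suffix(path.suffix + ".cols"))
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        if dense.shape != (len(rows), len(cols)):
            raise FormatError(
                f"{path}: matrix is {dense.shape}, sidecars give "
                f"({len(rows)}, {len(cols)})"
            )
        df = pd.DataFrame(dense, index=rows, columns=cols)
        return GeneCountTable(df)
    raise FormatError(f"unknown count-table format {format!r}")


def write_count_table(table: GeneCountTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        table.counts.to_csv(path, sep="\t", index_label="sample_id")
    elif format == "mtx-triplet":
        sparse = scipy.sparse.coo_matrix(table.counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        path.with_suffix(path.suffix + ".rows").write_text(
            "\n".join(map(str, table.sample_ids)) + "\n", encoding="utf-8"
        )
        path.with_suffix(path.suffix + ".cols").write_text(
            "\n".join(map(str, table.gene_ids)) + "\n", encoding="utf-8"
        )
    else:
        raise FormatError(f"unknown count-table format {format!r}")


def read_mgs_catalog(
    genes_path: str | Path,
    taxonomy_path: str | Path | None = None,
    expected_markers: int = 50,
) -> MgsCatalog:
    """Read MGS definitions.

    ``genes_path``: TSV with columns gene_id, length, mgs_id ('-' for
    genes outside any MGS), is_marker (0/1).  ``taxonomy_path``: TSV
    keyed by mgs_id with one column per taxonomic rank.
    """
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str, "mgs_id": str})
    required = {"gene_id", "length", "mgs_id", "is_marker"}
    if not required <= set(genes.columns):
        raise FormatError(f"gene table missing columns: {sorted(required - set(genes.columns))}")
    _check_unique(genes["gene_id"], "gene ids")
    lengths = genes.set_index("gene_id")["length"].astype(np.int64)
    members: dict[str, list[str]] = {}
    markers: dict[str, list[str]] = {}
    for _, row in genes.iterrows():
        mgs = row["mgs_id"]
        if mgs == "-" or pd.isna(mgs):
            continue
        members.setdefault(mgs, []).append(row["gene_id"])
        if int(row["is_marker"]):
            markers.setdefault(mgs, []).append(row["gene_id"])
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="mgs_id", dtype=str)
    else:
        taxonomy = pd.DataFrame(
            "unclassified", index=list(members), columns=list(TAXONOMIC_RANKS)
        )
    return MgsCatalog(lengths, members, markers, taxonomy, expected_markers)


def write_mgs_catalog(
    catalog: MgsCatalog, genes_path: str | Path, taxonomy_path: str | Path
) -> None:
    gene_to_mgs = {
        g: mgs for mgs, genes in catalog.mgs_members.items() for g in genes
    }
    marker_set = {
        g for markers in catalog.mgs_markers.values() for g in markers
    }
    rows = [
        {
            "gene_id": g,
            "length": int(catalog.gene_lengths[g]),
            "mgs_id": gene_to_mgs.get(g, "-"),
            "is_marker": int(g in marker_set),
        }
        for g in catalog.gene_lengths.index
    ]
    pd.DataFrame(rows).to_csv(genes_path, sep="\t", index=False)
    catalog.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="mgs_id")


def read_metadata(
    path: str | Path, schedule: VisitSchedule | None = None
) -> SampleMetadata:
    """Read per-sample metadata TSV (columns of ``_METADATA_COLUMNS``)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "subject_id": str, "visit": str, "sex": str, "country": str},
    )
    return SampleMetadata(df, schedule or VisitSchedule())


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    out = metadata.table[_METADATA_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)
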