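"""Synthetic study generator with known ground truth.

Emulates the shape of a 35-subject, 5-visit (D-30, D-14, D-1, D8, D35)
longitudinal stool-metagenomics study so every pipeline stage can be
exercised and scored without real data:

* a gene catalog clustered into MGS (60 genes each, 50 markers,
  log-normal gene lengths around 1 kb, nested taxonomy with a
  configurable unclassified fraction);
* latent per-(subject, visit) MGS relative abundances: log-normal with a
  per-MGS grand mean, a subject random effect (individuality) and
  temporal noise whose correlation decays exponentially with the day
  gap (so dissimilarity to baseline grows with interval length);
  per-subject carriage thinning is calibrated so per-sample MGS richness
  hits a configured mean and SD;
* optional injected treatment effects (feature × fold-change × onset
  visit) applied to every subject from the onset visit on — the study
  design is single-arm;
* read counts: MGS abundance spread over member genes proportionally to
  gene length, then one multinomial draw per sample at a sampled depth;
* Bristol stool scale trajectories from early-/late-/non-responder
  archetypes (early drops at D8, late at D35, non stays flat, with the
  early archetype starting highest), Gaussian noise, rounding to the
  1-7 scale, and optional missing samples.

Everything is deterministic given (config, seed), and the returned
ground-truth record is sufficient to score downstream detection tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .io_model import (
    GeneCountTable,
    MgsAbundanceTable,
    MgsCatalog,
    SampleMetadata,
    ValidationError,
    VisitSchedule,
)

__all__ = [
    "TreatmentEffect",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_catalog",
    "simulate_abundances",
    "simulate_counts",
    "simulate_bss",
    "simulate_study",
]

_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Actinobacteria",
    "Proteobacteria",
    "Verrucomicrobia",
)
_PHYLUM_WEIGHTS = (0.55, 0.25, 0.10, 0.07, 0.03)


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative shift of one feature from an onset visit onward."""

    feature: str
    fold_change: float
    onset_visit: str = "D8"

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults are desk scale — 200 MGS and ~100k reads/sample keep the
    full pipeline in seconds; :meth:`study_shape` reproduces the real
    study's dimensions (1438 MGS, richness 215 +/- 49, depth 22.3M +/-
    0.8M reads) for slow runs.
    """

    n_subjects: int = 35
    schedule: VisitSchedule = field(default_factory=VisitSchedule)
    n_mgs: int = 200
    genes_per_mgs: int = 60
    n_markers: int = 50
    richness_mean: float | None = None  # default: 60% of n_mgs
    richness_sd: float | None = None  # default: richness_mean / 5
    depth_mean: float = 500_000.0
    depth_sd: float = 10_000.0
    mgs_mean_sd: float = 1.0  # spread of per-MGS grand means (log10)
    subject_sd: float = 0.5  # subject random effect (log10)
    temporal_sd: float = 0.25  # within-subject temporal noise (log10)
    drift_rate: float = 0.05  # per-day decay of temporal autocorrelation
    unclassified_fraction: float = 0.2
    treatment_effects: tuple[TreatmentEffect, ...] = ()
    bss_mix: tuple[float, float, float] = (9 / 33, 10 / 33, 14 / 33)  # early/late/non
    bss_levels: tuple[tuple[float, float, float], ...] = (
        (6.2, 4.2, 4.2),  # early: pre-treatment level, D8 level, later level
        (5.6, 5.6, 3.6),  # late
        (4.9, 4.9, 4.9),  # non
    )
    bss_subject_sd: float = 0.7  # persistent between-subject baseline spread
    bss_noise_sd: float = 0.5  # per-visit measurement noise
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.bss_mix) - 1.0) > 1e-9:
            raise ValidationError("bss_mix proportions must sum to 1")
        if self.richness_mean is None:
            object.__setattr__(self, "richness_mean", 0.6 * self.n_mgs)
        if self.richness_sd is None:
            object.__setattr__(self, "richness_sd", self.richness_mean / 5.0)
        if min(self.richness_sd, self.subject_sd, self.temporal_sd, self.bss_noise_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not 0 < self.richness_mean <= self.n_mgs:
            raise ValidationError("richness_mean must be in (0, n_mgs]")

    @classmethod
    def study_shape(cls, **overrides) -> "SimulationConfig":
        """The real study's dimensions: 1438 MGS, richness 215 +/- 49,
        sequencing depth 22.3M +/- 0.8M reads."""
        base = dict(
            n_mgs=1438,
            richness_mean=215.0,
            richness_sd=49.0,
            depth_mean=22_300_000.0,
            depth_sd=800_000.0,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    @property
    def mgs_ids(self) -> list[str]:
        return [f"MGS{i + 1:04d}" for i in range(self.n_mgs)]

    def sample_id(self, subject: str, visit: str) -> str:
        return f"{subject}_{visit}"


@dataclass
class SimulatedStudy:
    """Bundle of generated inputs plus the ground-truth record."""

    counts: GeneCountTable
    catalog: MgsCatalog
    metadata: SampleMetadata
    latent: MgsAbundanceTable
    truth: dict


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


def simulate_catalog(config: SimulationConfig, seed: int = 0) -> MgsCatalog:
    """Gene catalog: log-normal lengths around 1 kb, the first
    ``n_markers`` genes of each MGS as markers, nested taxonomy."""
    rng = np.random.default_rng(seed)
    members: dict[str, list[str]] = {}
    markers: dict[str, list[str]] = {}
    lengths = {}
    for mgs in config.mgs_ids:
        genes = [f"{mgs}_g{j + 1:02d}" for j in range(config.genes_per_mgs)]
        members[mgs] = genes
        markers[mgs] = genes[: config.n_markers]
        for g in genes:
            lengths[g] = max(100, int(rng.lognormal(np.log(1000), 0.35)))
    phyla = rng.choice(_PHYLA, size=config.n_mgs, p=_PHYLUM_WEIGHTS)
    unclassified = rng.random(config.n_mgs) < config.unclassified_fraction
    rows = []
    for i, mgs in enumerate(config.mgs_ids):
        phylum = phyla[i]
        genus = f"g_{phylum[:4]}{i % 7 + 1}"
        rows.append(
            {
                "mgs_id": mgs,
                "superkingdom": "Bacteria",
                "phylum": phylum,
                "class": f"c_{phylum[:4]}",
                "order": f"o_{phylum[:4]}",
                "family": f"f_{phylum[:4]}{i % 3 + 1}",
                "genus": genus,
                "species": "unclassified" if unclassified[i] else f"s_{mgs}",
            }
        )
    taxonomy = pd.DataFrame(rows).set_index("mgs_id")
    return MgsCatalog(
        pd.Series(lengths), members, markers, taxonomy, config.n_markers
    )


# ---------------------------------------------------------------------------
# Latent abundances
# ---------------------------------------------------------------------------


def _calibrate_subject_richness_sd(prev: np.ndarray, target_sd: float) -> float:
    """Spread (on the logit scale) of the per-subject richness propensity
    needed so across-sample richness SD hits the target.

    Richness given propensity u is f(u) = sum sigmoid(logit(p_m) + u);
    total variance = Var_u f(u) + E_u sum q(1-q).  Solved by bisection
    with Gauss-Hermite quadrature over u.
    """
    logit_p = special.logit(np.clip(prev, 1e-6, 1 - 1e-6))
    nodes, weights = np.polynomial.hermite_e.hermegauss(31)
    weights = weights / weights.sum()

    def total_var(sigma: float) -> float:
        u = sigma * nodes
        q = special.expit(logit_p[None, :] + u[:, None])
        f = q.sum(axis=1)
        mean_f = float(weights @ f)
        var_between = float(weights @ (f - mean_f) ** 2)
        var_within = float(weights @ (q * (1 - q)).sum(axis=1))
        return var_between + var_within

    if total_var(0.0) >= target_sd**2:
        return 0.0
    try:
        return float(
            optimize.brentq(lambda s: total_var(s) - target_sd**2, 0.0, 10.0)
        )
    except ValueError:
        return 10.0


def simulate_abundances(
    config: SimulationConfig, seed: int = 0
) -> tuple[MgsAbundanceTable, dict]:
    """Latent MGS relative abundances per (subject, visit) plus ground truth.

    log10 abundance of a carried MGS = grand mean + subject effect +
    temporal noise with corr(dt) = exp(-drift_rate * |dt|); rows are
    normalized to sum to 1 *before* treatment effects are applied, so the
    realized fold change of an injected effect equals the configured one.
    Features carrying a treatment effect are forced to be present in
    every subject so the planted signal is scoreable.
    """
    rng = np.random.default_rng(seed)
    visits = config.schedule.visits
    days = config.schedule.days(visits)
    n_s, n_m, n_v = config.n_subjects, config.n_mgs, len(visits)

    # per-MGS prevalence: Beta around richness_mean/n_mgs, concentration 2
    # (a heavy-ish tail of rare species alongside a prevalent core)
    mu_p = config.richness_mean / config.n_mgs
    prev = rng.beta(2.0 * mu_p, 2.0 * (1 - mu_p), size=n_m)
    prev = np.clip(prev, 0.005, 0.999)
    prev *= mu_p / prev.mean()  # recenter the realized draw on the target
    prev = np.clip(prev, 0.005, 0.999)
    sigma_u = _calibrate_subject_richness_sd(prev, config.richness_sd)
    u = rng.normal(0.0, sigma_u or 0.0, size=n_s)
    carriage_p = special.expit(
        special.logit(np.clip(prev, 1e-6, 1 - 1e-6))[None, :] + u[:, None]
    )
    carriage = rng.random((n_s, n_m)) < carriage_p

    effect_idx = {}
    for eff in config.treatment_effects:
        if eff.feature not in config.mgs_ids:
            raise ValidationError(f"unknown effect feature {eff.feature!r}")
        effect_idx[config.mgs_ids.index(eff.feature)] = eff
    if effect_idx:
        carriage[:, list(effect_idx)] = True

    mgs_mean = rng.normal(0.0, config.mgs_mean_sd, size=n_m)
    subj_eff = rng.normal(0.0, config.subject_sd, size=(n_s, n_m))
    corr = np.exp(-config.drift_rate * np.abs(days[:, None] - days[None, :]))
    cov = (config.temporal_sd**2) * corr
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_v))
    eps = rng.standard_normal((n_s, n_m, n_v)) @ chol.T

    log10_a = mgs_mean[None, :, None] + subj_eff[:, :, None] + eps
    abundance = np.where(carriage[:, :, None], 10.0**log10_a, 0.0)
    # normalize each (subject, visit) profile to relative abundance
    totals = abundance.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    abundance = abundance / totals
    # inject treatment effects after normalization (exact fold change)
    for idx, eff in effect_idx.items():
        onset_day = config.schedule.day(eff.onset_visit)
        on = days >= onset_day
        abundance[:, idx, on] *= eff.fold_change

    sample_ids = [
        config.sample_id(s, v) for s in config.subjects for v in visits
    ]
    flat = abundance.transpose(0, 2, 1).reshape(n_s * n_v, n_m)
    table = MgsAbundanceTable(
        pd.DataFrame(flat, index=sample_ids, columns=config.mgs_ids)
    )
    truth = {
        "prevalence": pd.Series(prev, index=config.mgs_ids),
        "carriage": pd.DataFrame(
            carriage, index=config.subjects, columns=config.mgs_ids
        ),
        "treatment_effects": list(config.treatment_effects),
        "richness_logit_sd": sigma_u,
        "expected_richness": pd.Series(
            carriage.sum(axis=1).astype(float), index=config.subjects
        ),
    }
    return table, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def simulate_counts(
    latent: MgsAbundanceTable,
    catalog: MgsCatalog,
    config: SimulationConfig,
    seed: int = 0,
) -> GeneCountTable:
    """Multinomial read counts at a sampled depth per sample.

    Expected gene frequency = MGS abundance spread over its member genes
    proportionally to gene length (so the per-kb FPKM of each member gene
    recovers the MGS abundance up to a constant).
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(catalog.gene_lengths.index)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    weights = np.zeros((latent.abundance.shape[1], n_genes))
    for mi, mgs in enumerate(latent.abundance.columns):
        genes = catalog.mgs_members[mgs]
        idx = [gene_pos[g] for g in genes]
        glen = catalog.gene_lengths.iloc[idx].to_numpy(dtype=float)
        weights[mi, idx] = glen / glen.sum()
    out = np.zeros((len(latent.sample_ids), n_genes), dtype=np.int64)
    ab = latent.abundance.to_numpy()
    for si in range(ab.shape[0]):
        p = ab[si] @ weights
        total = p.sum()
        if total == 0:
            continue
        depth = max(1000, int(round(rng.normal(config.depth_mean, config.depth_sd))))
        out[si] = rng.multinomial(depth, p / total)
    return GeneCountTable(
        pd.DataFrame(out, index=latent.sample_ids, columns=gene_ids)
    )


# ---------------------------------------------------------------------------
# Bristol stool scale and metadata
# ---------------------------------------------------------------------------


def _bss_level(config: SimulationConfig, archetype: int, visit: str) -> float:
    pre_level, first_post, later_post = config.bss_levels[archetype]
    schedule = config.schedule
    day = schedule.day(visit)
    baseline_day = schedule.day(schedule.baseline)
    if day <= baseline_day:
        return pre_level
    post_days = sorted(
        schedule.day(v) for v in schedule.visits if schedule.day(v) > baseline_day
    )
    return first_post if day == post_days[0] else later_post


def simulate_bss(
    config: SimulationConfig, seed: int = 0
) -> tuple[SampleMetadata, pd.Series]:
    """Per-sample metadata with archetype-driven BSS trajectories.

    Returns (metadata, true archetype labels per subject).  Archetypes
    are assigned by the configured early/late/non mix; BSS = archetype
    level + a persistent per-subject offset + per-visit Gaussian noise,
    rounded and clamped to 1..7.  The subject offset reproduces the
    between-subject baseline spread of real cohorts; because archetype
    drops are whole points, it largely cancels out of the delta features
    used for responder clustering.  Missing samples (per
    ``missing_fraction``) are removed from the table entirely.
    """
    rng = np.random.default_rng(seed)
    subjects = config.subjects
    n = len(subjects)
    counts = np.floor(np.asarray(config.bss_mix) * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(np.asarray(config.bss_mix) * n - counts))] += 1
    archetypes = rng.permutation(np.repeat([0, 1, 2], counts))
    labels = pd.Series(
        np.array(["early", "late", "non"])[archetypes], index=subjects
    )
    sex = rng.choice(["M", "F"], size=n, p=[20 / 35, 15 / 35])
    country = rng.choice(["GBR", "NLD"], size=n, p=[23 / 35, 12 / 35])
    age = rng.integers(18, 61, size=n)
    subject_offset = rng.normal(0.0, config.bss_subject_sd, size=n)
    missing = rng.random((n, len(config.schedule.visits))) < config.missing_fraction
    rows = []
    for si, subject in enumerate(subjects):
        for vi, visit in enumerate(config.schedule.visits):
            if missing[si, vi]:
                continue
            level = _bss_level(config, archetypes[si], visit) + subject_offset[si]
            bss = int(np.clip(round(rng.normal(level, config.bss_noise_sd)), 1, 7))
            rows.append(
                {
                    "sample_id": config.sample_id(subject, visit),
                    "subject_id": subject,
                    "visit": visit,
                    "bss": bss,
                    "stool_frequency": int(np.clip(rng.poisson(2.2), 1, 10)),
                    "age": int(age[si]),
                    "sex": sex[si],
                    "country": country[si],
                }
            )
    metadata = SampleMetadata(pd.DataFrame(rows), config.schedule)
    return metadata, labels


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig, seed: int = 0) -> SimulatedStudy:
    """Generate a complete study: catalog, counts, metadata, ground truth.

    Sub-stages draw from seeds derived from ``seed``; missing samples
    (from the metadata stage) are removed from the count table too, so
    the two stay consistent.
    """
    catalog = simulate_catalog(config, seed + 1)
    latent, truth = simulate_abundances(config, seed + 2)
    metadata, labels = simulate_bss(config, seed + 4)
    keep = [s for s in latent.sample_ids if s in set(metadata.sample_ids)]
    latent = MgsAbundanceTable(latent.abundance.loc[keep])
    counts = simulate_counts(latent, catalog, config, seed + 3)
    truth = dict(truth)
    truth["responder_archetype"] = labels
    truth["config"] = config
    return SimulatedStudy(counts, catalog, metadata, latent, truth)
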