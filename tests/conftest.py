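import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mgslong import abundance as ab
from mgslong.io_model import (
    GeneCountTable,
    MgsCatalog,
    SampleMetadata,
    VisitSchedule,
)
from mgslong.synthetic_data import SimulationConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return VisitSchedule()


@pytest.fixture()
def toy_counts():
    return GeneCountTable(
        pd.DataFrame(
            [[1, 0, 2], [0, 5, 0]],
            index=["s1", "s2"],
            columns=["g1", "g2", "g3"],
        )
    )


@pytest.fixture()
def toy_catalog():
    """Two MGS x 3 genes each (all genes are markers)."""
    genes = {f"m{m}_g{j}": 1000 for m in (1, 2) for j in (1, 2, 3)}
    members = {"MGS1": ["m1_g1", "m1_g2", "m1_g3"], "MGS2": ["m2_g1", "m2_g2", "m2_g3"]}
    taxonomy = pd.DataFrame(
        {
            "superkingdom": ["Bacteria", "Bacteria"],
            "phylum": ["Firmicutes", "Firmicutes"],
            "class": ["c1", "c1"],
            "order": ["o1", "o1"],
            "family": ["f1", "f2"],
            "genus": ["g1", "g2"],
            "species": ["sp1", "unclassified"],
        },
        index=pd.Index(["MGS1", "MGS2"], name="mgs_id"),
    )
    return MgsCatalog(
        pd.Series(genes), members, dict(members), taxonomy, expected_markers=3
    )


def make_metadata(
    n_subjects=35,
    schedule=None,
    drop=(),
    bss_value=5,
):
    """Complete metadata grid with optional (subject_idx, visit) drops."""
    schedule = schedule or VisitSchedule()
    rows = []
    for i in range(n_subjects):
        for visit in schedule.visits:
            if (i, visit) in drop:
                continue
            rows.append(
                {
                    "sample_id": f"S{i + 1:02d}_{visit}",
                    "subject_id": f"S{i + 1:02d}",
                    "visit": visit,
                    "bss": bss_value,
                    "stool_frequency": 2,
                    "age": 30 + i % 20,
                    "sex": "M" if i % 2 else "F",
                    "country": "GBR" if i % 3 else "NLD",
                }
            )
    return SampleMetadata(pd.DataFrame(rows), schedule)


@pytest.fixture(scope="session")
def desk_study():
    """One desk-scale synthetic study shared across the suite."""
    return simulate_study(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def desk_pipeline(desk_study):
    """Quantification chain run on the desk-scale study."""
    counts = desk_study.counts
    spec = ab.DownsizeSpec(
        int(counts.mapped_depth.min()), seed=0, drop_below_target=True
    )
    down = ab.downsize(counts, spec)
    freq = ab.fpkm_normalize(down, desk_study.catalog.gene_lengths)
    mgs = ab.mgs_abundance(freq, desk_study.catalog)
    return {"down": down, "freq": freq, "mgs": mgs}
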