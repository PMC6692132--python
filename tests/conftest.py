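import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mutdfe import (CodingSequence, CodonUsageTable, SimConfig, TRNACopyTable,
                    write_dataset)
from mutdfe.config import AssayConfig, DFEMixture, TreeConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_cds() -> CodingSequence:
    # 12 codons: ATG GGT GGC CTG AAA TGG CGT TCT TAT CCG GAA TAA
    return CodingSequence(
        id="toy",
        seq="ATGGGTGGCCTGAAATGGCGTTCTTATCCGGAATAA",
        flank5="GCATTGCAAC", flank3="TTGCCAGGCA")


@pytest.fixture(scope="session")
def usage_table() -> CodonUsageTable:
    # informative counts for Gly and Leu; everything else smoothed to equal
    return CodonUsageTable.from_counts(
        {"GGT": 100, "GGC": 50, "GGA": 10, "GGG": 5,
         "CTG": 80, "CTA": 10, "TTA": 5, "TTG": 20, "CTT": 40, "CTC": 20})


@pytest.fixture(scope="session")
def trna_table() -> TRNACopyTable:
    # three species: Gly(ACC), Gly(GCC), Leu(CAG)
    return TRNACopyTable({"ACC": 4, "GCC": 2, "CAG": 1})


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced problem size for fast integration tests."""
    return SimConfig(
        seed=7, n_syn=12, n_nonsyn=20, n_nonsense=3,
        assay=AssayConfig(n_replicates=4, colonies_sampled=200),
        tree=TreeConfig(n_tips=12, polytomy_fraction=0.3),
        gene_length_codons=120)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthetic")
    return write_dataset(small_config, outdir)


@pytest.fixture()
def fitness_table_paperlike() -> pd.DataFrame:
    """A fitness table with the study's class composition: 39 synonymous,
    65 nonsynonymous, 6 nonsense; exactly 55 non-nonsense beneficial."""
    rng = np.random.default_rng(42)
    rows = []
    k = 0
    for cls, n in (("synonymous", 39), ("nonsynonymous", 65)):
        for i in range(n):
            k += 1
            beneficial = k <= 55  # first 55 of the 104 sense-class rows
            w = 1 + (rng.uniform(0.001, 0.12) if beneficial
                     else -rng.uniform(0.001, 0.12))
            rows.append({"mutation_id": f"m{k:03d}", "class": cls, "w_mean": w,
                         "sem": 0.01, "n_replicates": 5})
    for i in range(6):
        k += 1
        rows.append({"mutation_id": f"m{k:03d}", "class": "nonsense",
                     "w_mean": rng.uniform(0.80, 0.90), "sem": 0.01,
                     "n_replicates": 5})
    return pd.DataFrame(rows)
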