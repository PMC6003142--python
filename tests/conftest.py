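import numpy as np
import pandas as pd
import pytest

from haplorisk import (GenotypeTable, PhenotypeTable, SimulationConfig,
                       simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort: the two-SNP risk block plus 20
    equilibrium SNPs, 150 cases / 140 controls."""
    cfg = SimulationConfig(n_cases=150, n_controls=140,
                           n_equilibrium_snps=20, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size synthetic cohort at the default study conditions
    (164 SNPs, 829 cases / 765 controls)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture
def toy_genotypes():
    """Five samples at three SNPs with one missing call."""
    dosage = np.array([[0, 1, 2],
                       [1, 0, 1],
                       [2, 2, 0],
                       [0, 1, -1],
                       [1, 1, 0]], dtype=np.int8)
    return GenotypeTable(
        [f"S{i}" for i in range(5)], ["rs1", "rs2", "rs3"], dosage,
        [("A", "G"), ("C", "T"), ("G", "A")],
        chrom=np.array(["1", "1", "2"], object),
        pos=np.array([100, 200, 50]))


@pytest.fixture
def toy_phenotypes():
    frame = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(5)],
        "status": ["case", "case", "control", "control", "case"],
        "age": [60.0, 45.0, 50.0, 70.0, 38.0],
        "sex": pd.Categorical(["male", "female", "male", "male", "female"]),
        "smoking": pd.Categorical(["ever", "never", "never", "ever", "never"]),
        "drinking": pd.Categorical(["ever", "ever", "never", "never", "never"]),
    })
    return PhenotypeTable(frame)
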