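import numpy as np
import pandas as pd
import pytest

from raftlink.config import AnalysisParams, MissingnessModel, SimulationConfig
from raftlink import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_proteins=30,
        peptides_per_protein=(2, 4),
        n_replicates=4,
        frac_shifted=0.2,
        frac_copurifying=0.2,
        noise_cv=0.2,
        seed=1,
    )


@pytest.fixture
def fast_params():
    return AnalysisParams(n_boot=100, n_perm=20, edge_n_perm=50)


@pytest.fixture
def noiseless_config():
    return SimulationConfig(
        n_proteins=10,
        peptides_per_protein=(2, 3),
        n_replicates=3,
        frac_shifted=0.0,
        frac_copurifying=0.0,
        noise_cv=0.0,
        lipid_noise_cv=0.0,
        frac_lipids_differential=0.0,
        seed=7,
    )


def make_evidence(values: dict[tuple[str, str, str], float]) -> pd.DataFrame:
    """Hand-built evidence from {(peptide, protein, sample): intensity}."""
    rows = [
        {"peptide_id": pep, "protein_id": prot, "sample_id": s, "intensity": v}
        for (pep, prot, s), v in values.items()
    ]
    return pd.DataFrame(rows)


def make_design(genotypes=("wildtype", "mutant"), fractions=("DRM", "DSF", "SP", "IM"),
                n_replicates=4) -> pd.DataFrame:
    rows = [
        (f"{g}_{f}_r{r}", g, f, r)
        for g in genotypes for f in fractions for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "fraction", "replicate"])


@pytest.fixture
def lipid_library():
    return pd.DataFrame(
        {
            "name": [f"L{i}" for i in range(12)],
            "mz": np.linspace(400.0, 900.0, 12),
            "adduct": ["[M+H]+"] * 12,
            "rt": np.linspace(1.0, 16.0, 12),
        }
    )
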