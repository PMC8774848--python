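import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cogres import GenotypeDataset, SimulationConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_genotypes(dosage_columns, bp=None, chrom="1", ids=None):
    """Small hand-built genotype panel; columns are per-variant dosage vectors."""
    dos = np.column_stack([np.asarray(c, dtype=float) for c in dosage_columns])
    m = dos.shape[1]
    variants = pd.DataFrame(
        {
            "SNP": ids if ids is not None else [f"snp{j + 1}" for j in range(m)],
            "CHR": chrom,
            "BP": bp if bp is not None else 1 + 10_000 * np.arange(m),
            "A1": "G",
            "A2": "A",
            "INFO": 1.0,
        }
    )
    return GenotypeDataset(dosages=dos, variants=variants)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by read-only tests (independent sites)."""
    cfg = SimulationConfig(
        n_individuals=3000, n_snps=300, n_causal_edu=80, n_causal_res=80, seed=7
    )
    genotypes, cohort, factors, truth = simulate_cohort(cfg)
    return cfg, genotypes, cohort, factors, truth
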