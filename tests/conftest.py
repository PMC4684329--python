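import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated paired dataset shared by read-only tests."""
    from helpdm.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_subjects=12,
        chrom_lengths={"chr1": 600_000, "chr2": 400_000},
        n_genes=60,
        locus_density=5.0,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_genes():
    return pd.DataFrame(
        [
            {"gene_id": "GA", "chrom": "chr1", "strand": "+", "tss": 10_000, "tes": 20_000},
            {"gene_id": "GB1", "chrom": "chr1", "strand": "-", "tss": 40_000, "tes": 30_000},
        ]
    )
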