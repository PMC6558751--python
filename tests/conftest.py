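import numpy as np
import pandas as pd
import pytest

from metagrs import (
    EffectModel, GenotypePanel, LDBlockSpec, simulate_effects,
    simulate_genotypes, simulate_gwas_sumstats,
)


@pytest.fixture(scope="session")
def small_panel() -> GenotypePanel:
    """500 samples x 30 variants with moderate within-block LD."""
    return simulate_genotypes(500, LDBlockSpec(6, 5, within_r=0.3), seed=42)


@pytest.fixture(scope="session")
def small_truth(small_panel):
    return simulate_effects(small_panel, EffectModel(10, per_sd_hr=1.5),
                            seed=43)


@pytest.fixture(scope="session")
def small_sumstats(small_panel, small_truth):
    return simulate_gwas_sumstats(small_truth, small_panel, 20_000, 20_000,
                                  seed=44)


@pytest.fixture
def toy_panel() -> GenotypePanel:
    """Hand-built 2 samples x 3 variants panel for brute-force oracles."""
    dosages = np.array([[0.0, 1.0, 2.0], [2.0, 2.0, 0.0]], dtype=np.float32)
    variants = pd.DataFrame({
        "id": ["v1", "v2", "v3"],
        "chrom": [1, 1, 2],
        "pos": [100, 5000, 100],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "af": [0.5, 0.75, 0.5],
    })
    return GenotypePanel(dosages, variants, np.array(["s1", "s2"]))
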