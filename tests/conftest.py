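import numpy as np
import pandas as pd
import pytest

from koscan.io import GenotypeDataset
from koscan.simulate import PlantedKnockout, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small consanguineous cohort with two planted knockouts, shared by tests
    that only read from it."""
    cfg = SimulationConfig(
        n_samples=400,
        n_variants=2500,
        n_genes=400,
        target_regions=(("1", 0, 8_000_000),),
        roh_fraction_mean=0.1,
        roh_segment_mean_length=800_000.0,
        analyte_counts={"protein": 60, "metabolite": 60, "lab": 10},
        planted_knockouts=(
            PlantedKnockout("GENE00012", 2, ("PROT0003",), -5.0),
            PlantedKnockout("GENE00040", 3, ("MET0008",), 5.0, impact="MODERATE"),
        ),
        lod_censor_quantile=0.05,
        seed=101,
    )
    return simulate_cohort(cfg)


def make_dataset(genotypes, positions=None, chrom="1", samples=None, **variant_cols):
    """Hand-built GenotypeDataset from a (variants x samples) int array."""
    G = np.asarray(genotypes, dtype=np.int8)
    n_var, n_samp = G.shape
    if positions is None:
        positions = np.arange(1, n_var + 1) * 1000
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n_samp)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            **variant_cols,
        }
    )
    variants.index = pd.Index(
        [f"{chrom}:{p}:A:G" for p in positions], name="variant_id"
    )
    return GenotypeDataset(variants=variants, genotypes=G, samples=samples)
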