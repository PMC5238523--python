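import numpy as np
import pandas as pd
import pytest

from layergp import SimulationConfig, simulate_population, simulate_trait_and_drp
from layergp.io_formats import GenotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_panel(dosage, chrom="chr1", start=100, spacing=1000, rsq=None, category=None):
    """A minimal panel from a dosage matrix (individuals x SNPs)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypePanel(
        individual_ids=np.array([f"ind{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        dosage=dosage,
        snp_map=pd.DataFrame(
            {
                "chrom": [chrom] * m,
                "pos": start + spacing * np.arange(m),
                "ref": ["A"] * m,
                "alt": ["B"] * m,
            }
        ),
        rsq=rsq,
        category=category,
    )


@pytest.fixture
def random_panel(rng):
    """60 individuals x 120 SNPs of Hardy-Weinberg dosages, no missing."""
    p = rng.uniform(0.1, 0.9, 120)
    return make_panel(rng.binomial(2, p, size=(60, 120)))


@pytest.fixture(scope="session")
def small_population():
    """A small six-generation pedigreed population shared across tests."""
    cfg = SimulationConfig(
        n_founders=60,
        n_generations=4,
        n_matings=12,
        offspring_per_mating=6,
        n_snps=800,
        n_chromosomes=2,
        seed=3,
    )
    panel, pedigree, annotation = simulate_population(cfg)
    truth, drp = simulate_trait_and_drp(
        panel, n_qtl=cfg.n_qtl, h2=cfg.h2, reliability=cfg.drp_reliability,
        seed=5, qtl_genic_enrichment=1.0,
    )
    return {"cfg": cfg, "panel": panel, "pedigree": pedigree,
            "annotation": annotation, "truth": truth, "drp": drp}
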