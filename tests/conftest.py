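import numpy as np
import pandas as pd
import pytest

import straindiff as sd


@pytest.fixture(scope="session")
def two_strain_sim():
    """Small two-strain simulation with 10% planted effects."""
    cfg = sd.SimConfig(
        n_genes=1000, strains=("A", "B"), regions=("R",),
        replicates_per_cell=3, frac_unique_per_strain=0.05,
        frac_shared_signature=0.0, region_effect_sd=0.0, seed=101,
    )
    counts, samples, genes, truth = sd.simulate_counts(cfg)
    return cfg, counts, samples, genes, truth


@pytest.fixture(scope="session")
def eight_strain_study():
    """Small full-design run with planted unique and shared effects."""
    cfg = sd.SimConfig(
        n_genes=1200, seed=202, frac_unique_per_strain=0.005,
        frac_shared_signature=0.02, library_size_range=(1e6, 2e6),
    )
    counts, samples, genes, truth = sd.simulate_counts(cfg)
    result = sd.run_study(counts, samples, genes)
    return cfg, counts, samples, genes, truth, result


def random_deg_table(rng, strains, region="R", n_genes=200, p_deg=0.3):
    """Randomized pairwise DEG table for oracle comparisons."""
    genes = [f"g{i}" for i in range(n_genes)]
    rows = []
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            lfc = rng.normal(0, 1.5, n_genes)
            is_deg = rng.random(n_genes) < p_deg
            for g, f, d in zip(genes, lfc, is_deg):
                rows.append({
                    "gene": g, "contrast": f"{a}_vs_{b}", "region": region,
                    "log2FC": f, "is_deg": bool(d),
                    "fdr_global": 0.01 if d else 0.5,
                })
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
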