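import numpy as np
import pandas as pd
import pytest

import yewoffset as yo
from yewoffset import popgen


@pytest.fixture(scope="session")
def landscape_ds():
    """Small oligogenic landscape shared across tests."""
    cfg = yo.LandscapeConfig(
        n_pops=24, n_ind_per_pop=14, n_snps=400, frac_adaptive=0.05,
        cline_slope=2.0, missing_rate=0.05, seed=17,
    )
    return yo.simulate_landscape(cfg)


@pytest.fixture(scope="session")
def landscape_freqs(landscape_ds):
    """Filtered, imputed population allele frequencies of the shared landscape."""
    g = yo.filter_genotypes(landscape_ds.genotypes, 0.30, 0.30, 10)
    scores, _ = popgen.genotype_pca(g, n_components=2)
    pools = popgen.assign_gene_pools(scores, K=2, seed=3)
    g = yo.impute_modal_by_pool(g, pools.to_numpy())
    return g, yo.population_allele_freqs(g)


@pytest.fixture(scope="session")
def rda_results(landscape_ds, landscape_freqs):
    _, freqs = landscape_freqs
    return yo.RDA(freqs.freqs, landscape_ds.reference_climate.values).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_genotypes(calls, pops=None, contigs=None, positions=None):
    """Build a GenotypeMatrix from a plain array with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_snp = calls.shape
    pops = pops if pops is not None else ["p1"] * n_ind
    snp_meta = pd.DataFrame(
        {
            "id": [f"s{j}" for j in range(n_snp)],
            "contig": contigs if contigs is not None else ["c1"] * n_snp,
            "pos": positions if positions is not None else np.arange(1, n_snp + 1),
        }
    )
    ind_meta = pd.DataFrame(
        {"id": [f"i{k}" for k in range(n_ind)], "population": pops}
    )
    return yo.GenotypeMatrix(calls, snp_meta, ind_meta)
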