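import numpy as np
import pytest

import dartpop as dp


@pytest.fixture(scope="session")
def toy():
    """The fixed 6-accession x 12-locus hand-written panel."""
    return dp.toy_panel()


@pytest.fixture(scope="session")
def default_panel():
    """One default simulated panel (83 accessions), filtered, with truth."""
    gm, info, meta, truth = dp.generate_panel(dp.SimConfig(seed=1))
    gmf, infof, report = dp.filter_loci(gm, info)
    return gmf, infof, meta, truth


@pytest.fixture(scope="session")
def hwe_panel():
    """Panmictic panel whose calls follow Hardy-Weinberg proportions.

    Two seedlings per pool with full mixing draw each accession's two
    allele copies independently, so heterozygote frequency is exactly
    2pq — the regime the IBD moments estimator assumes.
    """
    cfg = dp.SimConfig(
        n_pools=1, group_sizes=(30,), group_labels=("x",),
        heterogeneity_by_group=(1.0,), seedlings_per_pool=2,
        pool_divergence=0.05, loci_per_chromosome={"1H": 1000, "2H": 1000},
        sweep_spec=[], n_duplicate_pairs=0, missing_rate=0.0, seed=42)
    gm, info, meta, truth = dp.generate_panel(cfg)
    return gm, info, meta, truth
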