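import numpy as np
import pandas as pd
import pytest

import asymlat as al


@pytest.fixture(scope="session")
def small_config():
    return al.GeneratorConfig(n_subjects=500, n_snps=200, seed=11, ld_block_size=10)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return al.gen_genotypes(small_config)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic asymmetry effects, for calibration tests."""
    # independent SNPs: calibration checks assume independent tests
    cfg = al.GeneratorConfig(n_subjects=800, n_snps=2000, seed=23, ld_block_size=1)
    G = al.gen_genotypes(cfg)
    truth = al.CohortTruth(causal_snp_ids=[], variance_explained=np.array([]))
    traits_tab, cov = al.gen_phenotypes(G, truth, cfg)
    return cfg, G, traits_tab, cov


def run_scan(G, traits_tab, cov, plan="I"):
    """Full trait -> normalize -> residualize -> scan pipeline."""
    tr = al.compute_asymmetry(traits_tab["left"], traits_tab["right"], plan=plan)
    y = al.normalize_trait(tr.values)
    resid = al.residualize(y, al.build_covariate_design(cov))
    return al.assoc_scan(resid, G)
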