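import numpy as np
import pandas as pd
import pytest

from apoeqtl.containers import EffectPlan, Pedigree
from apoeqtl.syndata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort (no planted effects), small enough for fast unit tests."""
    cfg = SimConfig(n_families=120, n_snps=12, n_lipid=3, n_polar=2, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Full-size cohort with a strong E2-specific effect planted on
    (snp001, polar_001): beta_E2 = 0.8, beta_E3 = -0.1."""
    plan = EffectPlan(pd.DataFrame([
        dict(snp_id="snp001", metabolite_id="polar_001", stratum="E2",
             beta_true=0.8),
        dict(snp_id="snp001", metabolite_id="polar_001", stratum="E3",
             beta_true=-0.1),
    ]))
    cfg = SimConfig(n_families=452, n_snps=16, n_lipid=2, n_polar=2, seed=42)
    return simulate_cohort(cfg, plan)


@pytest.fixture()
def toy_pedigree():
    """Three generations: grandparents, their son, his wife, two children."""
    return Pedigree(pd.DataFrame(
        [
            ("f1", "gf", "0", "0", "male"),
            ("f1", "gm", "0", "0", "female"),
            ("f1", "dad", "gf", "gm", "male"),
            ("f1", "mom", "0", "0", "female"),
            ("f1", "kid1", "dad", "mom", "male"),
            ("f1", "kid2", "dad", "mom", "female"),
        ],
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex"],
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
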