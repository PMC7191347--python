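import pytest

from arfpheno import PHENOTYPES, generate_cohort
from arfpheno.synthetic_cohort import GeneratorConfig


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Ten stays per phenotype, no noise, fixed seed."""
    cfg = GeneratorConfig(n_per_phenotype={c: 10 for c in PHENOTYPES}, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def table2_counts():
    """The published per-phenotype cohort sizes used for derived-rate checks."""
    from arfpheno import PhenotypeCode

    return {
        PhenotypeCode.P0_INVASIVE: 16809,
        PhenotypeCode.P1_NIPPV: 6653,
        PhenotypeCode.P2_HFNI: 1202,
        PhenotypeCode.P3_NIPPV_FAILURE: 1597,
        PhenotypeCode.P4_HFNI_FAILURE: 636,
        PhenotypeCode.P5_INVASIVE_TO_NIPPV: 649,
        PhenotypeCode.P6_INVASIVE_TO_HFNI: 188,
    }
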