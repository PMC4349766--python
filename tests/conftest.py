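import pytest

from somaticsim import (
    GermlineParams,
    apply_germline,
    make_synthetic_reference,
    set_base_ploidy,
    simulate_germline_variants,
)
from somaticsim.synthetic import RepeatPlan

REPEAT_PLAN = [
    RepeatPlan("AluSynth", 10, 300, 0.05),
    RepeatPlan("L1Synth", 6, 1500, 0.08),
]


@pytest.fixture(scope="session")
def small_ref_cat():
    """2 x 60 kb synthetic reference with two planted repeat families."""
    return make_synthetic_reference(2, 60_000, 0.45, REPEAT_PLAN, seed=11)


@pytest.fixture(scope="session")
def small_ref(small_ref_cat):
    return small_ref_cat[0]


@pytest.fixture(scope="session")
def small_catalog(small_ref_cat):
    return small_ref_cat[1]


@pytest.fixture(scope="session")
def pg_small(small_ref):
    variants = simulate_germline_variants(
        small_ref, GermlineParams(snv_count=300, seed=12)
    )
    return apply_germline(small_ref, variants), variants


@pytest.fixture()
def diploid_model(pg_small):
    pg, _variants = pg_small
    return set_base_ploidy(pg, 2, seed=0)


@pytest.fixture(scope="session")
def pg_snv_only(small_ref):
    """Personal genome without INDELs: identity liftover, clean segments."""
    variants = simulate_germline_variants(
        small_ref, GermlineParams(snv_count=200, indel_snv_ratio=0.0, seed=13)
    )
    return apply_germline(small_ref, variants), variants
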