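import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from castlib import end_model, experiments
from castlib import library_design as ld


@pytest.fixture(scope="session")
def fixture_mt():
    return end_model.wt_fixture()


@pytest.fixture(scope="session")
def small_manifest(fixture_mt):
    end = fixture_mt.left_end
    variants = ld.design_truncations(end, 10) + ld.design_substitutions(end, widths=(4,))[:25]
    return ld.assign_barcodes(variants, seed=7, wt_end=end.sequence)


@pytest.fixture(scope="session")
def target_screen_result():
    """The full two-library degenerate target screen at default depths.

    Shared across logo-arithmetic and logo-recovery tests (it is the
    expensive session fixture).
    """
    return experiments.target_screen(seed=101)
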