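import numpy as np
import pytest

from metamel import (
    OptimizerSettings,
    build_grid,
    build_luminaire,
    filter_metamers,
    optimize_target,
    score_metamer_set,
)


@pytest.fixture(scope="session")
def lum6():
    return build_luminaire("6ch")


@pytest.fixture(scope="session")
def lum8():
    return build_luminaire("8ch")


@pytest.fixture(scope="session")
def lum11():
    return build_luminaire("11ch")


@pytest.fixture(scope="session")
def quick_settings():
    # small search adequate for unit tests; the full-size defaults are
    # exercised implicitly through the same code path
    return OptimizerSettings(generations=80, max_archive=800)


@pytest.fixture(scope="session")
def mid_target():
    """A mid-gamut on-locus target near 4200 K from a reduced grid."""
    targets = build_grid(n_cct=5, duv_max=0.009, duv_step=0.003)
    return min(
        (t for t in targets if t.duv_level == 0),
        key=lambda t: abs(t.cct - 4200.0),
    )


@pytest.fixture(scope="session")
def harvested_set(lum11, mid_target, quick_settings):
    """A scored 11-channel metamer set reused across reduction tests."""
    run = optimize_target(
        lum11, mid_target, seed=42, repetitions=4, settings=quick_settings
    )
    ms = filter_metamers(run, max_members=200)
    assert ms.n >= 50
    return score_metamer_set(ms)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
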