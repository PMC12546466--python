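import numpy as np
import pytest

from eegsi import build_fixture
from eegsi.evaluation import ScenarioConfig, run_statistical_experiment
from eegsi.headmodel import LeadField, SourceSpace


@pytest.fixture(scope="session")
def fixture_bundle():
    """The default 64-electrode / 200-source spherical study bundle."""
    return build_fixture()


@pytest.fixture(scope="session")
def fifty_source_fixture(fixture_bundle):
    """Every fourth source of the bundle: a 50-location scan fixture."""
    montage, sources, model, L, _ = fixture_bundle
    idx = np.arange(0, 200, 4)
    cols = (3 * idx[:, None] + np.arange(3)).ravel()
    sub_sources = SourceSpace(sources.positions[idx], sources.head_center)
    return LeadField(L.gain[:, cols], montage=montage, source_space=sub_sources)


@pytest.fixture(scope="session")
def tangential_study(fixture_bundle):
    """100 tangential source cases at 5% noise, basic vs SVD HAL1R.

    Shared between the orientation-improvement test and the acceptance
    suite; the heavy solvers run once per session.
    """
    _, sources, _, L, _ = fixture_bundle
    cfg = ScenarioConfig("statistical_tangential", n_cases=100, noise_pct=5.0, seed=7)
    return run_statistical_experiment(cfg, ("hal1r", "svd_hal1r"), L, sources)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
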