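import datetime as dt

import pytest

from lurefx.data_io import CaptureRecord, Deployment, RefreshEvent
from lurefx.synthetic_data import ScenarioConfig, SpeciesTruth, generate_survey
from scipy.special import logit


def ts(day: int, hour: int = 0, minute: int = 0) -> dt.datetime:
    """Shorthand timestamp within a June-2013 deployment."""
    return dt.datetime(2013, 6, day, hour, minute)


@pytest.fixture
def small_deployments():
    return [
        Deployment("A", "s1", dt.date(2013, 6, 1), dt.date(2013, 6, 10)),
        Deployment(
            "B", "s1", dt.date(2013, 6, 1), dt.date(2013, 6, 10),
            inactive_dates=frozenset({dt.date(2013, 6, 5)}),
        ),
    ]


@pytest.fixture
def small_refresh():
    return [
        RefreshEvent("A", ts(1, 0)),
        RefreshEvent("A", ts(8, 12)),
        RefreshEvent("B", ts(1, 0)),
    ]


@pytest.fixture
def small_captures():
    return [
        CaptureRecord("genet", "A", ts(2, 6), "s1"),
        CaptureRecord("genet", "A", ts(2, 6, 30), "s1"),   # within 1 h
        CaptureRecord("genet", "A", ts(2, 8), "s1"),
        CaptureRecord("genet", "B", ts(3, 22), "s1"),
        CaptureRecord("civet", "A", ts(2, 6, 5), "s1"),    # other species
    ]


@pytest.fixture(scope="session")
def tiny_survey():
    """A small but complete synthetic survey for integration tests."""
    config = ScenarioConfig(
        n_stations=12,
        deployment_days=(40, 50),
        species=[
            SpeciesTruth("genet", psi=0.8, beta0=float(logit(0.15)),
                         beta_attract=-0.2),
            SpeciesTruth("duiker", psi=0.7, beta0=float(logit(0.1)),
                         beta_attract=0.15, diel_means_hours=(6.5, 18.0),
                         diel_kappas=(3.0, 3.0), diel_weights=(0.5, 0.5)),
        ],
        seed=42,
    )
    return generate_survey(config)
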