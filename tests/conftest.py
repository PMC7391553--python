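import pytest

from reefrules import (
    GeneratorConfig,
    StationRecord,
    default_archetypes,
    expert_ruleset,
    generate_stations,
)
from reefrules.stations import AttributeProfile


def make_profile(**overrides) -> AttributeProfile:
    """A valid all-sand baseline profile with keyword overrides.

    Substrate covers are taken as given; the caller is responsible for
    keeping their sum at 100 when overriding several of them.  ``sand``
    defaults to the remainder of the substrate partition.
    """
    values = {
        "depth": 8.0,
        "topography": 1.5,
        "complexity": 1.5,
        "sand": None,
        "debris": 0.0,
        "boulder": 0.0,
        "rock": 0.0,
        "slab": 0.0,
        "live_coral": 0.0,
        "dead_coral": 0.0,
        "erect_algae": 0.0,
        "algal_turf": 0.0,
        "seagrass": 0.0,
    }
    values.update(overrides)
    if values["sand"] is None:
        values["sand"] = 100.0 - sum(
            values[a] for a in ("debris", "boulder", "rock", "slab")
        )
    return AttributeProfile(**values)


def make_station(station_id="S1", habitat=None, **overrides) -> StationRecord:
    return StationRecord(
        station_id=station_id, profile=make_profile(**overrides), habitat=habitat
    )


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def synthetic_stations(archetypes):
    """Reference strict-mode low-overlap set: 200 stations per habitat."""
    config = GeneratorConfig(
        n_per_habitat={h: 200 for h in archetypes}, seed=11, overlap=1.0, strict=True
    )
    return generate_stations(archetypes, config)


@pytest.fixture(scope="session")
def expert_rules():
    return expert_ruleset()
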