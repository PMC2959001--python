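import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from operant_iiv import (SessionStructure, SimulationDesign, default_strain_params,
                         extract_traits, simulate_experiment)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def structure():
    return SessionStructure()


@pytest.fixture(scope="session")
def preset_params():
    return default_strain_params()


@pytest.fixture(scope="session")
def small_design(structure):
    """A reduced two-strain design for fast unit tests."""
    return SimulationDesign(n_rats_per_strain={"SHR": 6, "WKY": 5},
                            n_sessions=3, structure=structure, seed=7)


@pytest.fixture(scope="session")
def small_events(small_design, preset_params):
    return simulate_experiment(small_design, preset_params)


@pytest.fixture(scope="session")
def small_traits(small_events, structure):
    return extract_traits(small_events, structure)


def events_frame(rows):
    """Build an event table from (rat_id, strain, session, time_s, event_type) rows."""
    return pd.DataFrame(rows, columns=["rat_id", "strain", "session",
                                       "time_s", "event_type"])
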