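import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from achconnect import FlowRecipe, generate_fields, straight_coast_domain


@pytest.fixture(scope="session")
def small_domain():
    """A 100-km straight coast with 5-km point spacing (21 coastal points)."""
    return straight_coast_domain(
        length_km=100.0, point_spacing_km=5.0, grid_spacing_deg=0.05
    )


@pytest.fixture(scope="session")
def still_field(small_domain):
    recipe = FlowRecipe(jet_speed=0.0, eddy_amplitude=0.0, noise_sd=0.0)
    return generate_fields(small_domain, recipe, years=1, days_per_year=35, seed=0)


def uniform_field(domain, u=0.0, v=0.0, days=35, seed=0):
    recipe = FlowRecipe(
        jet_speed=float(np.hypot(u, v)),
        jet_direction_deg=float(np.degrees(np.arctan2(v, u))),
        eddy_amplitude=0.0,
        noise_sd=0.0,
    )
    return generate_fields(domain, recipe, years=1, days_per_year=days, seed=seed)
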