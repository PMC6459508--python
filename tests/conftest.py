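import numpy as np
import pytest

from stacksdm.grid import ClimateStack, GridSpec
from stacksdm.synthetic import (ResponseParam, VirtualSpeciesTruth,
                                generate_climate_stack,
                                generate_virtual_species)


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec(n_rows=50, n_cols=50, cell_size_km=10.0)


@pytest.fixture(scope="session")
def stack(grid) -> ClimateStack:
    return generate_climate_stack(grid, n_vars=3, seed=11)


@pytest.fixture(scope="session")
def truth(stack) -> VirtualSpeciesTruth:
    """A cool-adapted forest frugivore responding to the first layer."""
    v1 = stack["bio1"]
    return VirtualSpeciesTruth(
        species_id="sp001", guild="FR", habitat="FT",
        response_params={"bio1": ResponseParam(
            optimum=float(np.quantile(v1, 0.2)), breadth=1.0, weight=12.0)},
        prevalence_target=0.2)


@pytest.fixture(scope="session")
def true_prob(stack, truth) -> np.ndarray:
    return generate_virtual_species(stack, truth)
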