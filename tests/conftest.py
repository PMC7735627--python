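import numpy as np
import pytest

from lifedisparity import (
    FixtureSpec,
    lifetable_from_hazard,
    make_fixture,
    run_scenario,
    scenario_presets,
)

FAMILIES = ["constant", "gompertz", "gompertz_makeham", "near_rectangular"]


def build_lifetable(family, params=None, **grid_kw):
    from lifedisparity import make_grid

    grid = make_grid(**grid_kw) if grid_kw else make_grid()
    spec = FixtureSpec(family, params or {}, grid=grid)
    return lifetable_from_hazard(make_fixture(spec))


@pytest.fixture(scope="session")
def lt_constant():
    return build_lifetable("constant")


@pytest.fixture(scope="session")
def lt_gompertz():
    return build_lifetable("gompertz")


@pytest.fixture(scope="session")
def lt_makeham():
    return build_lifetable("gompertz_makeham")


@pytest.fixture(scope="session")
def lt_nearrect():
    return build_lifetable("near_rectangular")


@pytest.fixture(scope="session")
def all_lifetables(lt_constant, lt_gompertz, lt_makeham, lt_nearrect):
    return {
        "constant": lt_constant,
        "gompertz": lt_gompertz,
        "gompertz_makeham": lt_makeham,
        "near_rectangular": lt_nearrect,
    }


@pytest.fixture(scope="session")
def full_trajectories():
    """The three canonical 150-year scenario runs at dt=1 (shared: ~1 s)."""
    return {name: run_scenario(p) for name, p in scenario_presets().items()}
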