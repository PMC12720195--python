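"""Shared fixtures: the expensive steady-state solutions are solved once
per session at the resolutions used for the headline results and reused by
both the unit and the acceptance tests."""

from __future__ import annotations

import pytest

from tumorph import krogh, spheroid
from tumorph.params import KroghGeometry, MetabolicParams, SpheroidGeometry


@pytest.fixture(scope="session")
def ferm_spheroid():
    """Fermentative spheroid, J_ferm_max 10 mM/min, 500 µm, 100 shells."""
    return spheroid.solve_steady_state(
        geometry=SpheroidGeometry(n_shells=100),
        metabolism=MetabolicParams(J_ferm_max=10.0),
    )


@pytest.fixture(scope="session")
def resp_spheroid():
    """Respiratory spheroid, J_resp_max 0.67 mM/min, 500 µm, 100 shells."""
    return spheroid.solve_steady_state(
        geometry=SpheroidGeometry(n_shells=100),
        metabolism=MetabolicParams(J_resp_max=0.67),
    )


@pytest.fixture(scope="session")
def mixed_spheroid():
    """Mixed phenotype spheroid (half rates: 5 / 0.33 mM/min), 60 shells."""
    return spheroid.solve_steady_state(
        geometry=SpheroidGeometry(n_shells=60),
        metabolism=MetabolicParams(J_ferm_max=5.0, J_resp_max=0.33),
    )


@pytest.fixture(scope="session")
def ferm_krogh():
    """Fermentative Krogh cylinder, J_ferm_max 1 mM/min, default geometry."""
    return krogh.simulate(metabolism=MetabolicParams(J_ferm_max=1.0))


@pytest.fixture(scope="session")
def resp_krogh():
    """Respiratory Krogh cylinder, J_resp_max 0.067 mM/min."""
    return krogh.simulate(metabolism=MetabolicParams(J_resp_max=0.067))


@pytest.fixture(scope="session")
def mixed_krogh():
    """Mixed-phenotype Krogh cylinder (0.5 / 0.033 mM/min)."""
    return krogh.simulate(
        metabolism=MetabolicParams(J_ferm_max=0.5, J_resp_max=0.033)
    )
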