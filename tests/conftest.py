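"""Shared fixtures: reference parameter sets and generator shortcuts."""

import numpy as np
import pytest

from nanospring.models import ConstructModel, SpringParams, WLCParams

# Fitted parameter sets for the two nanospring states (handles: Lp, L0, K0;
# spring: k, x0) and the theory column used for initialisation.
GQNS = dict(Lp=50.0, L0=1244.0, K0=1298.0, k=0.04, x0=189.0)
ANTI_GQNS = dict(Lp=49.0, L0=1211.0, K0=1446.0, k=0.03, x0=138.0)
THEORY = dict(Lp=50.0, L0=1400.0, K0=1250.0)

# AFM summary statistics used as generator ground truths
RADIUS_ANTI = 25.8   # nm, mean curvature radius, anti-GQ state
RADIUS_GQ = 43.9     # nm, mean curvature radius, GQ state
TURNS_ANTI = 3.5
TURNS_GQ = 1.7


def make_model(params=GQNS, F0=0.0) -> ConstructModel:
    return ConstructModel(
        handles=WLCParams(Lp=params["Lp"], L0=params["L0"], K0=params["K0"]),
        spring=SpringParams(k=params["k"], x0=params["x0"]),
        F0=F0,
    )


@pytest.fixture
def gqns_model() -> ConstructModel:
    return make_model(GQNS)


@pytest.fixture
def gqns_handles() -> WLCParams:
    return WLCParams(Lp=GQNS["Lp"], L0=GQNS["L0"], K0=GQNS["K0"])


@pytest.fixture
def force_grid() -> np.ndarray:
    return np.linspace(0.1, 8.2, 500)
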