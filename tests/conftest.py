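import numpy as np
import pytest

from uadyn.core import PhysiologyState
from uadyn.drugs import (
    DRUG_LIBRARY,
    ProductionInhibitorParams,
    ReabsorptionInhibitorParams,
)


@pytest.fixture
def fig9_phys() -> PhysiologyState:
    """The worked nomogram scenario: sUA 12 mg/dL, GFR 60 mL/min, FE0 0.03."""
    return PhysiologyState.from_clinical(gfr_ml_min=60.0, fe0=0.03, sua_mg_dl=12.0)


@pytest.fixture
def healthy_phys() -> PhysiologyState:
    """Typical healthy volunteer: GFR 100 mL/min, FE0 0.07, sUA 6 mg/dL."""
    return PhysiologyState.from_clinical(gfr_ml_min=100.0, fe0=0.07, sua_mg_dl=6.0)


@pytest.fixture
def oxypurinol_params() -> ProductionInhibitorParams:
    return DRUG_LIBRARY["oxypurinol"].params()


@pytest.fixture
def lesinurad_params() -> ReabsorptionInhibitorParams:
    return DRUG_LIBRARY["lesinurad"].params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180227)
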