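import numpy as np
import pytest

from leafthz import InstrumentParams, LeafRecord, SPECIES_DEFAULTS


@pytest.fixture
def quiet_instrument():
    """Instrument with every noise source switched off."""
    return InstrumentParams(drift_sd=0.0, point_tau_sd=0.0, detector_sd=0.0)


@pytest.fixture
def vv_params():
    return SPECIES_DEFAULTS["V_V"]


def make_leaf(mw=100.0, la=10.0, ldm=50.0, code="V_V", leaf_id="L1", tau=None):
    return LeafRecord(
        species_code=code,
        leaf_id=leaf_id,
        fresh_mass=mw + ldm,
        dry_mass=ldm,
        leaf_area=la,
        tau=tau,
    )


@pytest.fixture
def exact_line_records():
    """Leaves lying exactly on tau*L_A = 0.4*M_w (C0 = 0)."""
    leaves = []
    for i, mw in enumerate([50.0, 120.0, 300.0, 520.0, 880.0]):
        la = 5.0 + 3.0 * i
        leaves.append(
            make_leaf(mw=mw, la=la, leaf_id=f"L{i}", tau=0.4 * mw / la)
        )
    return leaves


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
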