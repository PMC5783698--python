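"""Model equations, parameter table, and the TNF forcing waveform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfkb_modehop import ModelParameters, ModelState, TNFSignal, model_rhs, tnf_value
from nfkb_modehop.errors import InvalidInputError
from nfkb_modehop.model import PARAM_NAMES, default_parameters

# the published defaults for all 15 constants
TABLE = {
    "kNin": 5.4, "kIin": 0.018, "kt": 1.03, "ktl": 0.24, "KI": 0.035,
    "KN": 0.029, "gamma_m": 0.018, "alpha": 1.05, "Ntot": 1.0, "ka": 0.24,
    "ki": 0.18, "kp": 0.036, "kA20": 0.0018, "IKKtot": 2.0, "A20": 0.0026,
}


def test_default_parameters_match_published_table():
    assert default_parameters().to_dict() == TABLE


def test_parameters_reject_nonpositive_values():
    with pytest.raises(InvalidInputError):
        ModelParameters(kNin=0.0)
    with pytest.raises(InvalidInputError):
        ModelParameters(Ntot=-1.0)


def test_parameter_file_round_trip(tmp_path):
    p = default_parameters().replace(kNin=6.0)
    path = tmp_path / "params.yaml"
    p.dump(path)
    assert ModelParameters.load(path) == p


@pytest.mark.parametrize(
    "t, expected",
    [(10.0, 1.1), (100.0, 0.9), (190.0, 1.1), (280.0, 0.9)],
)
def test_square_pulse_levels(t, expected):
    sig = TNFSignal(period=180.0, amplitude=0.1, baseline=1.0, duty=0.5)
    assert tnf_value(t, sig) == pytest.approx(expected)


def test_zero_amplitude_equals_baseline():
    sig = TNFSignal(period=180.0, amplitude=0.0)
    assert all(tnf_value(t, sig) == 1.0 for t in (0.0, 17.3, 500.0))


def test_constant_flag_returns_baseline():
    sig = TNFSignal.constant(0.7)
    assert tnf_value(123.0, sig) == 0.7


def test_waveform_clamped_at_zero():
    sig = TNFSignal(period=100.0, amplitude=1.5, baseline=1.0)
    assert tnf_value(75.0, sig) == 0.0


def test_nonfinite_time_rejected():
    with pytest.raises(InvalidInputError):
        tnf_value(float("nan"), TNFSignal.constant())


def test_symmetric_wave_integrates_to_baseline():
    # with duty 0.5 and baseline >= amplitude the high and low half-cycles cancel
    sig = TNFSignal(period=90.0, amplitude=0.3)
    ts = np.linspace(0.0, 90.0, 9001)[:-1]
    mean = np.mean([tnf_value(t, sig) for t in ts])
    assert mean == pytest.approx(sig.baseline, abs=1e-6)


def test_rhs_nuclear_import_vanishes_at_full_occupancy(params):
    state = ModelState(Nn=params.Ntot, Im=0.1, I=0.0, IKKa=0.0, IKKi=0.0)
    d = model_rhs(state, 0.0, params, TNFSignal.constant())
    # with I = 0 the only Nn term is import, which must be zero at Nn = Ntot
    assert d[0] == pytest.approx(0.0, abs=1e-15)


def test_rhs_at_origin_equals_import_rate(params):
    # direct substitution: empty cell, TNF = 1 -> dNn/dt = kNin * Ntot
    d = model_rhs(ModelState(0, 0, 0, 0, 0), 0.0, params, TNFSignal.constant())
    assert d[0] == pytest.approx(params.kNin * params.Ntot)
    assert d[1] == d[2] == d[4] == 0.0
    # the full neutral IKK pool activates at rate ka * TNF * IKKtot
    assert d[3] == pytest.approx(params.ka * params.IKKtot)


def test_ikk_pool_is_conserved_by_construction(params):
    state = ModelState(Nn=0.3, Im=0.8, I=0.2, IKKa=0.5, IKKi=0.7)
    d = model_rhs(state, 0.0, params, TNFSignal.constant())
    # neutral IKK = IKKtot - IKKa - IKKi, so its implied derivative closes the sum
    d_neutral = -(d[3] + d[4])
    assert d[3] + d[4] + d_neutral == 0.0


@settings(max_examples=200, deadline=None)
@given(
    nn=st.floats(0.0, 1.0),
    im=st.floats(0.0, 10.0),
    iprot=st.floats(0.0, 3.0),
    u1=st.floats(0.0, 1.0),
    u2=st.floats(0.0, 1.0),
    face=st.integers(0, 4),
)
def test_vector_field_points_into_admissible_box(nn, im, iprot, u1, u2, face):
    """On each boundary face of the admissible box the outward component is <= 0."""
    params = default_parameters()
    ikka = params.IKKtot * u1
    ikki = (params.IKKtot - ikka) * u2
    y = [nn, im, iprot, ikka, ikki]
    lo_faces = {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}
    y[lo_faces[face]] = 0.0
    d = model_rhs(np.array(y), 0.0, params, TNFSignal.constant())
    assert d[face] >= -1e-12
    # upper faces: Nn = Ntot and IKKa + IKKi = IKKtot
    y2 = [params.Ntot, im, iprot, ikka, ikki]
    d2 = model_rhs(np.array(y2), 0.0, params, TNFSignal.constant())
    assert d2[0] <= 1e-12
    y3 = [nn, im, iprot, params.IKKtot - ikki, ikki]
    d3 = model_rhs(np.array(y3), 0.0, params, TNFSignal.constant())
    assert d3[3] + d3[4] <= 1e-12


def test_param_names_cover_dataclass():
    assert set(PARAM_NAMES) == set(TABLE)
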