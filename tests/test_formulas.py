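import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iolcalc.formulas import (
    CornealHeightClampWarning,
    HaigisConstants,
    InfeasibleRecordError,
    SRKTConstants,
    haigis_backsolve_elp,
    haigis_backsolve_elp_array,
    haigis_predict_refraction,
    haigis_refraction_at_elp_array,
    power_for_target_refraction,
    srkt_emmetropia_power,
    srkt_emmetropia_power_array,
    srkt_predict_refraction,
    srkt_refraction_array,
)

from .conftest import SAMPLING_RANGES, make_eye, random_biometry

A_REF = SRKTConstants(119.18)
HAIGIS_REF = HaigisConstants(-2.1245, 0.2032, 0.2866)

# Frozen fixtures: straight-line "spreadsheet" evaluation of the published
# equation chains at the mean training eye (L=23.92, K=44.35, ACD=3.15),
# independent of the vectorized implementation.
SRKT_REF_MEAN_EYE = -0.470779914915485      # A=119.18, P=20.0
SRKT_PEMME_MEAN_EYE = 19.2800510074424      # A=119.18
HAIGIS_REF_MEAN_EYE = -0.5386003358654073   # reference triple, P=20.0
HAIGIS_ELP_MEAN_EYE = 5.371052              # a0 + a1*3.15 + a2*23.92


def in_window_eye_strategy():
    kwargs = {
        name: st.floats(lo, hi, allow_nan=False)
        for name, (lo, hi) in SAMPLING_RANGES.items()
    }
    return st.fixed_dictionaries(kwargs)


class TestSRKT:
    def test_mean_eye_fixture(self, mean_eye):
        assert srkt_predict_refraction(mean_eye, A_REF, 20.0) == pytest.approx(
            SRKT_REF_MEAN_EYE, abs=1e-12
        )

    def test_emmetropia_power_fixture(self, mean_eye):
        assert srkt_emmetropia_power(mean_eye, A_REF) == pytest.approx(
            SRKT_PEMME_MEAN_EYE, abs=1e-10
        )

    def test_refraction_zero_at_emmetropia_power_bulk(self):
        bio = random_biometry(1000, seed=42)
        pemme = srkt_emmetropia_power_array(
            bio["axial_length"], bio["mean_keratometry"], 119.18
        )
        ref = srkt_refraction_array(
            bio["axial_length"], bio["mean_keratometry"], 119.18, pemme
        )
        assert np.max(np.abs(ref)) < 1e-6

    @given(eye=in_window_eye_strategy(), a=st.floats(114.0, 122.0))
    def test_refraction_strictly_decreasing_in_power(self, eye, a):
        grid = np.arange(-5.0, 40.5, 0.5)
        with np.errstate(all="ignore"):
            refs = srkt_refraction_array(
                eye["axial_length"], eye["mean_keratometry"], a, grid
            )
        assert np.all(np.diff(refs) < 0)

    @given(eye=in_window_eye_strategy())
    def test_emmetropia_power_increases_with_a_constant(self, eye):
        p_lo = srkt_emmetropia_power_array(eye["axial_length"], eye["mean_keratometry"], 118.0)
        p_hi = srkt_emmetropia_power_array(eye["axial_length"], eye["mean_keratometry"], 119.0)
        assert p_hi > p_lo

    @given(eye=in_window_eye_strategy(), delta=st.floats(0.1, 3.0))
    def test_longer_eye_needs_less_power(self, eye, delta):
        L = eye["axial_length"]
        if L + delta > SAMPLING_RANGES["axial_length"][1]:
            delta = SAMPLING_RANGES["axial_length"][1] - L
            if delta <= 0:
                return
        p1 = srkt_emmetropia_power_array(L, eye["mean_keratometry"], 119.18)
        p2 = srkt_emmetropia_power_array(L + delta, eye["mean_keratometry"], 119.18)
        assert p2 < p1

    def test_corneal_height_clamp_warns_and_sets_h_to_r(self):
        # A very long, very steep eye pushes the corneal-width chord past the
        # corneal radius, engaging the published square-root clamp.
        eye = make_eye(axial_length=36.0, mean_keratometry=55.0, iol_power=6.0)
        with pytest.warns(CornealHeightClampWarning):
            ref, workings = srkt_predict_refraction(eye, A_REF, 6.0, return_workings=True)
        assert workings.clamped
        assert workings.corneal_height == pytest.approx(workings.corneal_radius)
        assert np.isfinite(ref)

    def test_clamp_only_when_chord_exceeds_radius(self, mean_eye):
        _, workings = srkt_predict_refraction(mean_eye, A_REF, 20.0, return_workings=True)
        assert not workings.clamped
        assert (workings.corneal_width / 2) ** 2 <= workings.corneal_radius**2


class TestHaigis:
    def test_mean_eye_fixture(self, mean_eye):
        assert haigis_predict_refraction(mean_eye, HAIGIS_REF, 20.0) == pytest.approx(
            HAIGIS_REF_MEAN_EYE, abs=1e-12
        )

    def test_elp_outside_eye_is_domain_error(self, mean_eye):
        bad = HaigisConstants(-30.0, 0.2, 0.2)
        with pytest.raises(ValueError, match="a0=-30.0"):
            haigis_predict_refraction(mean_eye, bad, 20.0)

    @given(eye=in_window_eye_strategy())
    def test_refraction_strictly_decreasing_in_power(self, eye):
        grid = np.arange(-5.0, 40.5, 0.5)
        refs = haigis_refraction_at_elp_array(
            eye["axial_length"], eye["mean_keratometry"], 5.0, grid
        )
        assert np.all(np.diff(refs) < 0)

    def test_backsolve_round_trip_mean_eye(self, mean_eye):
        rx = haigis_predict_refraction(mean_eye, HAIGIS_REF, 20.0)
        d = haigis_backsolve_elp(mean_eye, 20.0, rx)
        assert d == pytest.approx(HAIGIS_ELP_MEAN_EYE, abs=1e-8)

    def test_backsolve_recovers_constructed_elp(self, mean_eye):
        rx = float(
            haigis_refraction_at_elp_array(
                mean_eye.axial_length, mean_eye.mean_keratometry, 4.0, 20.0
            )
        )
        assert haigis_backsolve_elp(mean_eye, 20.0, rx) == pytest.approx(4.0, abs=1e-8)

    def test_forward_inverse_round_trip_bulk(self):
        bio = random_biometry(1000, seed=7)
        rng = np.random.default_rng(8)
        d_true = rng.uniform(3.0, 7.0, size=1000)
        P = rng.choice(np.arange(10.0, 28.5, 0.5), size=1000)
        rx = haigis_refraction_at_elp_array(
            bio["axial_length"], bio["mean_keratometry"], d_true, P
        )
        d_back = haigis_backsolve_elp_array(
            bio["axial_length"], bio["mean_keratometry"], P, rx
        )
        assert np.max(np.abs(d_back - d_true)) < 1e-6

    def test_unattainable_refraction_is_infeasible(self, mean_eye):
        # At P = 6 D the attainable refraction over the whole ELP bracket is
        # about [+6.1, +10.7] D (brute-force scan), so a -0.2 D outcome has no
        # root.
        with pytest.raises(InfeasibleRecordError):
            haigis_backsolve_elp(mean_eye, 6.0, -0.2)


class TestPowerSelection:
    def test_exact_hit_returns_grid_power(self, mean_eye):
        target = srkt_predict_refraction(mean_eye, A_REF, 19.0)
        assert power_for_target_refraction("srkt", mean_eye, A_REF, target) == 19.0

    def test_mean_eye_brute_force_fixture(self, mean_eye):
        # Exhaustive 49-point scan fixes the answer at 19.5 D for a -0.20 D
        # target on the mean eye.
        assert power_for_target_refraction("srkt", mean_eye, A_REF, -0.20) == 19.5

    def test_tie_breaks_toward_higher_power(self, mean_eye):
        r1 = srkt_predict_refraction(mean_eye, A_REF, 19.0)
        r2 = srkt_predict_refraction(mean_eye, A_REF, 19.5)
        target = (r1 + r2) / 2.0
        assert power_for_target_refraction("srkt", mean_eye, A_REF, target) == 19.5

    def test_haigis_route(self, mean_eye):
        p = power_for_target_refraction("haigis", mean_eye, HAIGIS_REF, -0.20)
        ref = haigis_predict_refraction(mean_eye, HAIGIS_REF, p)
        # chosen power's prediction must be within half a grid step's effect
        assert abs(ref - (-0.20)) < 0.5

    def test_empty_grid_rejected(self, mean_eye):
        with pytest.raises(ValueError, match="step"):
            power_for_target_refraction("srkt", mean_eye, A_REF, 0.0, step=-1.0)
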