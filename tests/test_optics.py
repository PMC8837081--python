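"""Double-K SRK/T vergence chain: conversions, ELP, prediction, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from issiol import (
    EyeBiometry,
    InvalidGeometryError,
    LensConstants,
    OpticalConstants,
    adjusted_axial_length,
    elp_estimate,
    iss_iol_power,
    iss_predicted_refraction,
    keratometric_power,
    keratometric_radius,
    predicted_refraction_double_k,
    select_iol_power,
)
from conftest import random_valid_eyes
from oracles import physical_refraction, singlek_srkt_emmetropia_power, singlek_srkt_refraction

# Frozen before the main build from the independent step-by-step oracle.
ELP_FIXTURE = 5.3819974630  # mm, Kpre 43.86 D, L 24.0 mm, A 118.4
REF_FIXTURE = -0.0993056766  # D, L 26.75, Kpost 38.90, Kpre 43.86, A 118.4, LP 18.0


class TestKeratometricConversion:
    @pytest.mark.parametrize(
        "k_d, expected_mm",
        [
            (38.90, 8.68),  # calibration-cohort mean keratometry
            (38.95, 8.66),  # validation-cohort mean keratometry
            (337.5, 1.00),
        ],
    )
    def test_power_to_radius(self, k_d, expected_mm):
        assert round(keratometric_radius(k_d), 2) == expected_mm

    def test_radius_power_round_trip(self, rng):
        k = rng.uniform(30, 50, 200)
        back = np.array([keratometric_power(keratometric_radius(v)) for v in k])
        assert np.allclose(back, k, rtol=1e-12, atol=0)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            keratometric_radius(bad)
        with pytest.raises(ValueError):
            keratometric_power(bad)


class TestAdjustedAxialLength:
    def test_retinal_thickness_correction(self):
        assert adjusted_axial_length(24.0) == pytest.approx(24.17, abs=1e-12)
        assert adjusted_axial_length(26.75) == pytest.approx(26.8642025, abs=1e-12)
        # short-eye limit approaches the intercept
        assert adjusted_axial_length(1e-9) == pytest.approx(0.65696, abs=1e-6)


class TestElpEstimate:
    def test_frozen_fixture(self):
        elp = elp_estimate(43.86, 24.0, 118.4)
        assert elp.acd_est_mm == pytest.approx(ELP_FIXTURE, abs=1e-9)
        assert not elp.h_clamped

    def test_invariant_to_post_lasik_keratometry(self):
        """Double-K: ELP depends on Kpre only, never on measured Kpost."""
        e1 = EyeBiometry(25.0, 38.0)
        e2 = EyeBiometry(25.0, 44.0)
        lens = LensConstants(118.4, implanted_power_d=20.0)
        r1 = predicted_refraction_double_k(e1, lens)
        r2 = predicted_refraction_double_k(e2, lens)
        assert r1.elp.acd_est_mm == r2.elp.acd_est_mm

    def test_corneal_height_clamped_on_extreme_geometry(self):
        with pytest.warns(RuntimeWarning, match="clamp"):
            elp = elp_estimate(55.0, 39.0, 118.4)
        assert elp.h_clamped
        assert elp.h_mm == pytest.approx(elp.rpre_mm)

    def test_lens_at_retina_rejected(self):
        with pytest.raises(InvalidGeometryError):
            elp_estimate(43.86, 5.0, 124.9)


class TestPredictedRefraction:
    EYE = EyeBiometry(26.75, 38.90)

    def test_frozen_vergence_fixture(self):
        res = predicted_refraction_double_k(
            self.EYE, LensConstants(118.4, implanted_power_d=18.0)
        )
        assert res.predicted_refraction_d == pytest.approx(REF_FIXTURE, abs=1e-9)
        assert res.lopt_mm == pytest.approx(26.8642025, abs=1e-12)

    def test_matches_physical_vergence_oracle(self, rng):
        """Closed form equals root-finding on the physical vergence chain."""
        for eye in random_valid_eyes(25, rng):
            lp = float(rng.uniform(6, 30))
            closed = predicted_refraction_double_k(
                eye, LensConstants(118.4, implanted_power_d=lp)
            ).predicted_refraction_d
            oracle = physical_refraction(
                eye.axial_length_mm, eye.kpost_d, 43.86, 118.4, lp
            )
            assert closed == pytest.approx(oracle, abs=1e-9)

    def test_zero_power_reduces_to_aphakic_form(self):
        res = predicted_refraction_double_k(
            self.EYE, LensConstants(118.4, implanted_power_d=0.0)
        )
        na, nc, v = 1.336, 1.333, 12.0
        r, lopt = res.rpost_mm, res.lopt_mm
        aphakic = (1000 * na * (na * r - (nc - 1) * lopt)) / (
            na * (v * (na * r - (nc - 1) * lopt) + lopt * r)
        )
        assert res.predicted_refraction_d == pytest.approx(aphakic, abs=1e-12)

    def test_more_power_more_myopic(self, rng):
        for eye in random_valid_eyes(10, rng):
            refs = [
                predicted_refraction_double_k(
                    eye, LensConstants(118.4, implanted_power_d=lp)
                ).predicted_refraction_d
                for lp in (10.0, 15.0, 20.0, 25.0)
            ]
            assert all(a > b for a, b in zip(refs, refs[1:]))

    def test_implanted_power_required(self):
        with pytest.raises(ValueError, match="implanted_power_d"):
            predicted_refraction_double_k(self.EYE, LensConstants(118.4))


class TestIssCorrection:
    EYE = EyeBiometry(26.75, 38.90)
    LENS = LensConstants(118.4, implanted_power_d=18.0)

    @pytest.mark.parametrize("c", [0.0, 0.5, -1.2, 0.52])
    def test_additive_in_c(self, c):
        base = predicted_refraction_double_k(self.EYE, self.LENS)
        iss = iss_predicted_refraction(self.EYE, self.LENS, c)
        assert iss.predicted_refraction_d == pytest.approx(
            base.predicted_refraction_d + c, abs=1e-12
        )
        assert iss.c_applied_d == c


@st.composite
def valid_scenarios(draw):
    L = draw(st.floats(22.5, 31.0))
    kpost = draw(st.floats(34.0, 43.0))
    a = draw(st.floats(115.0, 121.0))
    dr = draw(st.floats(-3.0, 1.0))
    c = draw(st.floats(-1.0, 2.0))
    return L, kpost, a, dr, c


class TestPowerInversion:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(valid_scenarios())
    def test_power_then_refraction_recovers_target(self, scenario):
        """The power formula is the exact inverse of the prediction formula."""
        L, kpost, a, dr, c = scenario
        eye = EyeBiometry(L, kpost)
        lp = iss_iol_power(eye, dr, c, a)
        back = iss_predicted_refraction(
            eye, LensConstants(a, implanted_power_d=lp), c
        ).predicted_refraction_d
        assert back == pytest.approx(dr, abs=1e-9)

    def test_single_k_degeneracy(self, rng):
        """With Kpre = Kpost and C = 0 the chain is classical SRK/T."""
        for eye in random_valid_eyes(50, rng):
            lp = float(rng.uniform(8, 28))
            ours = predicted_refraction_double_k(
                eye, LensConstants(118.4, implanted_power_d=lp), kpre_d=eye.kpost_d
            ).predicted_refraction_d
            oracle = singlek_srkt_refraction(
                eye.axial_length_mm, eye.kpost_d, 118.4, lp
            )
            assert ours == pytest.approx(oracle, abs=1e-9)
            p_ours = iss_iol_power(eye, 0.0, 0.0, 118.4, kpre_d=eye.kpost_d)
            p_oracle = singlek_srkt_emmetropia_power(
                eye.axial_length_mm, eye.kpost_d, 118.4
            )
            assert p_ours == pytest.approx(p_oracle, abs=1e-9)

    def test_more_myopic_target_needs_more_power(self):
        eye = EyeBiometry(26.75, 38.90)
        p0 = iss_iol_power(eye, 0.0, 0.52, 118.4)
        p_myopic = iss_iol_power(eye, -1.0, 0.52, 118.4)
        assert p_myopic > p0


class TestPowerSelection:
    @pytest.mark.parametrize(
        "exact, step, expected",
        [
            (18.20, 0.5, 18.0),
            (18.30, 0.5, 18.5),
            (18.25, 0.5, 18.5),  # tie rounds up: myopic-residual preference
            (-0.25, 0.5, 0.0),
            (18.10, 0.25, 18.0),
        ],
    )
    def test_rounding(self, exact, step, expected):
        assert select_iol_power(exact, step) == pytest.approx(expected)

    def test_bad_step(self):
        with pytest.raises(ValueError):
            select_iol_power(18.0, 0.0)


class TestConstantsValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            OpticalConstants(na=1.0)
        with pytest.raises(ValueError):
            OpticalConstants(vertex_mm=-1)
        with pytest.raises(ValueError):
            EyeBiometry(10.0, 40.0)
        with pytest.raises(ValueError):
            LensConstants(90.0)
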