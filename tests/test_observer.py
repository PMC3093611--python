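"""The synthetic observer: prediction strength, effective contrast, calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError
from scipy.optimize import brentq

from motion_forecast.experiment import standard_display
from motion_forecast.observer import (
    ObserverParams,
    calibrate_defaults,
    default_observer,
    detection_probability,
    effective_contrast,
    expected_threshold,
    nonmonotone_bound,
    prediction_strength,
    simulate_trial,
)

LONG = 100.0  # seconds; saturates the temporal buildup


class TestPredictionStrength:
    def test_semisaturation_length(self, observer):
        cfg = standard_display("leading", inducer_length=15.0 / 60.0, duration=LONG)
        assert prediction_strength(observer, cfg) == pytest.approx(
            observer.prediction_amplitude / 2, rel=1e-9
        )

    def test_gap_efolding(self, observer):
        cfg0 = standard_display("leading", duration=LONG)
        cfg1 = standard_display("leading", duration=LONG, gap=25.0 / 60.0)
        assert prediction_strength(observer, cfg1) == pytest.approx(
            prediction_strength(observer, cfg0) / np.e, rel=1e-9
        )

    def test_temporal_semisaturation(self, observer):
        cfg = standard_display("leading", duration=0.122)
        cfg_long = standard_display("leading", duration=LONG)
        assert prediction_strength(observer, cfg) == pytest.approx(
            prediction_strength(observer, cfg_long) / 2, rel=1e-6
        )

    def test_trailing_and_baseline_are_zero(self, observer):
        assert prediction_strength(observer, standard_display("trailing", np.pi)) == 0.0
        assert prediction_strength(observer, standard_display("baseline")) == 0.0

    def test_dichoptic_scales_by_transfer(self, observer):
        mono = standard_display("leading")
        dich = standard_display("leading", dichoptic=True)
        assert prediction_strength(observer, dich) == pytest.approx(
            observer.interocular_transfer * prediction_strength(observer, mono)
        )

    def test_negative_geometry_rejected(self, observer):
        with pytest.raises(ValidationError):
            standard_display("leading", gap=-0.1)
        with pytest.raises(ValidationError):
            standard_display("leading", duration=-1.0)


class TestEffectiveContrast:
    def test_baseline_identity(self, observer):
        b = effective_contrast(observer, standard_display("baseline"), 0.8)
        assert b.effective_contrast == 0.8
        assert b.prediction_effective == 0.0
        assert b.suppression_divisor == 1.0

    def test_leading_inphase_boosts_then_divides(self, observer):
        cfg = standard_display("leading", 0.0, duration=LONG)
        b = effective_contrast(observer, cfg, 1.0)
        a_p = observer.prediction_amplitude
        assert b.phasor_sum == pytest.approx(1.0 + a_p, rel=1e-6)
        assert b.effective_contrast == pytest.approx(
            (1.0 + a_p) / (1.0 + observer.suppression_leading), rel=1e-6
        )

    def test_antiphase_closed_form_threshold(self, observer):
        """Antiphase threshold = theta0*(1+s_l) + a_p at asymptotic prediction."""
        cfg = standard_display("leading", np.pi, duration=LONG)
        expect = (
            observer.baseline_threshold * (1.0 + observer.suppression_leading)
            + observer.prediction_amplitude
        )
        assert expected_threshold(observer, cfg) == pytest.approx(expect, rel=1e-6)

    @pytest.mark.parametrize("phase", [0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
    @pytest.mark.parametrize("edge", ["leading", "trailing"])
    def test_expected_threshold_against_numeric_root(self, observer, edge, phase):
        """Closed-form threshold agrees with a brentq root of p(c) = 0.75."""
        cfg = standard_display(edge, phase)

        def f(c):
            eff = effective_contrast(observer, cfg, c).effective_contrast
            return detection_probability(observer, eff) - 0.75

        lo = nonmonotone_bound(observer, cfg) + 1e-9
        root = brentq(f, lo + 1e-6, 50.0, xtol=1e-12)
        assert expected_threshold(observer, cfg) == pytest.approx(root, rel=1e-8)


class TestDetectionProbability:
    def test_anchored_at_threshold(self, observer):
        assert detection_probability(observer, observer.baseline_threshold) == pytest.approx(0.75)

    def test_chance_and_ceiling(self, observer):
        assert detection_probability(observer, 0.0) == 0.5
        assert detection_probability(observer, 1e-9) == pytest.approx(0.5, abs=1e-6)
        assert detection_probability(observer, 1e9) == pytest.approx(1.0, abs=1e-9)

    def test_lapse_lowers_ceiling(self):
        obs = calibrate_defaults().model_copy(update={"lapse_rate": 0.02})
        assert detection_probability(obs, 1e9) == pytest.approx(0.98, abs=1e-9)
        assert detection_probability(obs, obs.baseline_threshold) == pytest.approx(0.74)


class TestSimulateTrial:
    def test_deterministic_given_seed(self, observer):
        cfg = standard_display("leading", 0.0)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            runs.append([simulate_trial(observer, cfg, 1.0, rng) for _ in range(50)])
        assert runs[0] == runs[1]

    def test_huge_contrast_always_correct(self, observer):
        cfg = standard_display("baseline")
        rng = np.random.default_rng(1)
        assert all(
            simulate_trial(observer, cfg, 1e6, rng)["correct"] for _ in range(200)
        )

    def test_proportion_correct_at_threshold(self, observer):
        """1e5 trials at the baseline threshold hit 75% within 3 binomial SEs."""
        cfg = standard_display("baseline")
        rng = np.random.default_rng(99)
        n = 100_000
        p = detection_probability(observer, observer.baseline_threshold)
        draws = rng.random(n) < p
        se3 = 3 * np.sqrt(0.75 * 0.25 / n)
        assert abs(draws.mean() - 0.75) < se3


class TestCalibration:
    def test_printed_ratio_inversion(self):
        obs = calibrate_defaults(1.49, 1.02, 2.06, baseline_threshold=1.0)
        assert obs.suppression_trailing == pytest.approx(0.49)
        assert obs.suppression_leading == pytest.approx(0.54)
        assert obs.prediction_amplitude == pytest.approx(0.52)
        assert obs.support_semisat_arcmin == 15.0
        assert obs.projection_constant_arcmin == 25.0
        assert obs.temporal_semisat_ms == 122.0

    def test_unity_ratios_give_null_observer(self):
        obs = calibrate_defaults(1.0, 1.0, 1.0)
        assert obs.suppression_trailing == 0.0
        assert obs.suppression_leading == 0.0
        assert obs.prediction_amplitude == 0.0
        cfg = standard_display("leading", np.pi)
        assert expected_threshold(obs, cfg) == pytest.approx(obs.baseline_threshold)

    def test_antiphase_below_inphase_rejected(self):
        with pytest.raises(ValueError, match="antiphase"):
            calibrate_defaults(1.49, 2.06, 1.02)

    def test_packaged_default_matches_calibration(self, observer):
        assert observer.model_dump() == calibrate_defaults().model_dump()

    @given(
        r_t=st.floats(1.0, 3.0),
        r_in=st.floats(0.9, 1.5),
        extra=st.floats(0.0, 2.0),
    )
    def test_calibration_roundtrip(self, r_t, r_in, extra):
        """Expected thresholds under the calibrated observer reproduce the ratios."""
        r_anti = r_in + extra
        if (r_in + r_anti) / 2 < 1.0:
            return  # negative leading suppression is outside the model
        obs = calibrate_defaults(r_t, r_in, r_anti)
        long = dict(duration=LONG)
        t0 = obs.baseline_threshold
        assert expected_threshold(obs, standard_display("trailing", 0.0, **long)) / t0 == pytest.approx(r_t, rel=1e-6)
        assert expected_threshold(obs, standard_display("leading", 0.0, **long)) / t0 == pytest.approx(r_in, rel=1e-6)
        assert expected_threshold(obs, standard_display("leading", np.pi, **long)) / t0 == pytest.approx(r_anti, rel=1e-6)


class TestModelInvariants:
    def test_quadrature_phases_equal_and_intermediate(self, observer):
        t90 = expected_threshold(observer, standard_display("leading", np.pi / 2))
        t270 = expected_threshold(observer, standard_display("leading", 3 * np.pi / 2))
        t0 = expected_threshold(observer, standard_display("leading", 0.0))
        t180 = expected_threshold(observer, standard_display("leading", np.pi))
        assert t90 == pytest.approx(t270, rel=1e-12)
        assert t0 < t90 < t180

    def test_trailing_edge_phase_flat(self, observer):
        ts = [
            expected_threshold(observer, standard_display("trailing", ph))
            for ph in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
        ]
        assert max(ts) - min(ts) == 0.0

    def _diff(self, observer, **kw):
        return expected_threshold(
            observer, standard_display("leading", np.pi, **kw)
        ) - expected_threshold(observer, standard_display("leading", 0.0, **kw))

    def test_interference_monotone_in_length_duration_gap(self, observer):
        lengths = [4, 10, 30, 100, 200]
        d_len = [self._diff(observer, inducer_length=v / 60) for v in lengths]
        assert np.all(np.diff(d_len) > 0)
        durations = [0.02, 0.05, 0.2, 0.5, 2.0]
        d_dur = [self._diff(observer, duration=v) for v in durations]
        assert np.all(np.diff(d_dur) > 0)
        gaps = [0, 10, 30, 100, 200]
        d_gap = [self._diff(observer, gap=v / 60) for v in gaps]
        assert np.all(np.diff(d_gap) < 0)

    def test_dichoptic_difference_scales_by_transfer(self, observer):
        mono = self._diff(observer)
        dich = self._diff(observer, dichoptic=True)
        assert dich == pytest.approx(observer.interocular_transfer * mono, rel=1e-12)

    def test_nonmonotone_bound_location(self, observer):
        """Effective contrast dips below the bound for antiphase targets."""
        cfg = standard_display("leading", np.pi, duration=LONG)
        bound = nonmonotone_bound(observer, cfg)
        assert bound == pytest.approx(observer.prediction_amplitude)
        eff = lambda c: effective_contrast(observer, cfg, c).effective_contrast
        assert eff(bound * 0.5) > eff(bound * 0.999)
        assert eff(bound * 2.0) > eff(bound * 1.5)
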