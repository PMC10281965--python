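import dataclasses

import numpy as np
import pytest

from pentrace.features import extract_features
from pentrace.recordings import DEVICE_PRESSURE_MAX
from pentrace.shapes import default_template
from pentrace.simulate import (DEFAULT_FEATURE_TARGETS, GroupParams,
                               MedianIQR, SubjectDraw, calibrate_generator,
                               default_group_params, grade_severity,
                               simulate_cohort, simulate_group_shape,
                               simulate_recording)


def _draw(**kw):
    defaults = dict(duration=5.0, base_pressure=1.5,
                    pressure_drift_amp=0.15, roughness_amp=0.3,
                    roughness_band=(2.5, 13.0), n_components=12,
                    tremor_amp=1.0, seed=99)
    defaults.update(kw)
    return SubjectDraw(**defaults)


class TestSimulateRecording:
    def test_deterministic_given_seed(self):
        tpl = default_template("spiral")
        a = simulate_recording(tpl, _draw())
        b = simulate_recording(tpl, _draw())
        assert a.equals(b)

    def test_sample_count_at_device_rate(self):
        rec = simulate_recording(default_template("square"),
                                 _draw(duration=10.0))
        assert rec.n_samples == 10 * 120 + 1
        assert rec.nominal_rate == 120.0

    def test_noise_free_draw_reproduces_base_pressure(self):
        draw = _draw(roughness_amp=0.0, pressure_drift_amp=0.0,
                     tremor_amp=0.0)
        rec = simulate_recording(default_template("triangular"), draw)
        assert extract_features(rec).AP == pytest.approx(1.5, abs=1e-12)
        np.testing.assert_allclose(rec.pressure, 1.5)

    def test_pressure_stays_in_device_range(self):
        draw = _draw(roughness_amp=1.2, base_pressure=2.4)
        rec = simulate_recording(default_template("spiral"), draw)
        assert rec.pressure.min() >= 0.0
        assert rec.pressure.max() <= DEVICE_PRESSURE_MAX
        assert "clipped_samples" in rec.meta

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_recording(default_template("spiral"),
                               _draw(duration=0.004))


class TestSeverity:
    @pytest.mark.parametrize("joa,grade", [
        (14, "mild"), (17, "mild"),
        (13, "moderate"), (9, "moderate"),
        (8, "severe"), (0, "severe"),
    ])
    def test_boundaries(self, joa, grade):
        assert grade_severity(joa).grade == grade

    @pytest.mark.parametrize("joa", [-1, 18])
    def test_out_of_range_rejected(self, joa):
        with pytest.raises(ValueError):
            grade_severity(joa)


class TestCohort:
    def test_default_structure(self, default_cohort):
        people = default_cohort.participants
        assert (people["group"] == "CM").sum() == 38
        assert (people["group"] == "nonCM").sum() == 66
        assert len(default_cohort.recordings) == 104 * 3
        per_participant = {}
        for rec in default_cohort.recordings:
            per_participant.setdefault(rec.participant_id, set()).add(
                rec.shape)
        assert all(len(s) == 3 for s in per_participant.values())

    def test_joa_allocation_reproduces_reference_counts(self,
                                                        default_cohort):
        cm = default_cohort.participants.query("group == 'CM'")
        grades = [grade_severity(int(j)).grade for j in cm["joa_score"]]
        assert grades.count("mild") == 9
        assert grades.count("moderate") == 18
        assert grades.count("severe") == 11

    def test_sex_counts_match_reference_fractions(self, default_cohort):
        people = default_cohort.participants
        noncm = people.query("group == 'nonCM'")
        cm = people.query("group == 'CM'")
        assert (noncm["sex"] == "F").sum() == 38
        assert (cm["sex"] == "F").sum() == 15

    def test_same_seed_same_cohort(self):
        kw = dict(n_noncm=5, n_cm=4, seed=11)
        a = simulate_cohort(default_group_params("nonCM"),
                            default_group_params("CM"), **kw)
        b = simulate_cohort(default_group_params("nonCM"),
                            default_group_params("CM"), **kw)
        assert a.participants.equals(b.participants)
        for ra, rb in zip(a.recordings, b.recordings):
            assert ra.equals(rb)

    def test_different_seed_different_pressures(self):
        a = simulate_cohort(default_group_params("nonCM"),
                            default_group_params("CM"),
                            n_noncm=3, n_cm=3, seed=1)
        b = simulate_cohort(default_group_params("nonCM"),
                            default_group_params("CM"),
                            n_noncm=3, n_cm=3, seed=2)
        assert not np.array_equal(a.recordings[0].pressure,
                                  b.recordings[0].pressure)

    @pytest.mark.parametrize("n_noncm,n_cm", [(0, 38), (66, 0)])
    def test_single_group_rejected(self, n_noncm, n_cm):
        with pytest.raises(ValueError):
            simulate_cohort(default_group_params("nonCM"),
                            default_group_params("CM"),
                            n_noncm=n_noncm, n_cm=n_cm, seed=0)


class TestCalibration:
    def test_shipped_defaults_are_a_fixed_point(self):
        """Re-calibrating from the packaged parameters changes nothing:
        the initial within-tolerance check short-circuits the search."""
        params = default_group_params("nonCM")
        targets = {shape: {k: DEFAULT_FEATURE_TARGETS[("nonCM", shape)][k][0]
                           for k in ("DT", "AP", "SP")}
                   for shape in ("spiral", "triangular")}
        out = calibrate_generator(params, targets, n_cal=66, seed=20240,
                                  tol=0.05)
        for shape in targets:
            assert out.shapes[shape].roughness.median == pytest.approx(
                params.shapes[shape].roughness.median)
            assert out.shapes[shape].duration.median == pytest.approx(
                DEFAULT_FEATURE_TARGETS[("nonCM", shape)]["DT"][0])

    def test_positive_sparc_target_rejected(self):
        params = default_group_params("CM")
        with pytest.raises(ValueError):
            calibrate_generator(
                params, {"spiral": {"DT": 9.8, "AP": 1.2, "SP": 50.0}},
                n_cal=8, seed=1)

    def test_clip_fraction_guard_trips(self):
        """A pressure level pushed against the device ceiling clips and
        is rejected rather than silently biasing the calibration."""
        from pentrace.simulate import CalibrationError, ShapeGroupParams
        params = default_group_params("CM")
        sp = params.shapes["spiral"]
        hot = ShapeGroupParams(
            duration=sp.duration,
            pressure=MedianIQR(4.0, 3.8, 4.1),
            roughness=MedianIQR(0.8, 0.7, 0.9))
        params = dataclasses.replace(
            params, shapes={**params.shapes, "spiral": hot})
        with pytest.raises(CalibrationError):
            calibrate_generator(
                params, {"spiral": {"DT": 9.8, "AP": 4.0, "SP": -116.3}},
                n_cal=12, seed=1)


def test_group_shape_batch_is_deterministic():
    recs1 = simulate_group_shape(default_group_params("CM"), "square",
                                 n=4, seed=3)
    recs2 = simulate_group_shape(default_group_params("CM"), "square",
                                 n=4, seed=3)
    for a, b in zip(recs1, recs2):
        assert a.equals(b)
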