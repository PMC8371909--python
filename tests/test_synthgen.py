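"""Generator contracts: gravity profiles, jump mechanics, frames, MVC."""

import math

import numpy as np
import pytest

import gravjump as gj
from gravjump.synthgen import simulate_parabola_gravity


class TestGravityProfiles:
    def test_zero_noise_steady_is_constant(self):
        tr = simulate_parabola_gravity("steady", 1.0, 0.0, 5.0, seed=0)
        assert np.all(tr.values == 1.0)
        assert tr.units == "g"

    def test_seeded_hyper_mean_recovers_level(self):
        tr = simulate_parabola_gravity("hyper", 1.81, 0.05, 10.0, seed=7)
        assert np.mean(tr.values) == pytest.approx(1.81, abs=0.02)

    def test_transition_ramp_is_zero_mean(self):
        tr = simulate_parabola_gravity("transition", 0.9, 0.0, 4.0, seed=0)
        assert np.mean(tr.values) == pytest.approx(0.9, abs=1e-9)
        assert tr.values[0] < tr.values[-1]

    def test_same_seed_bitwise_reproducible(self):
        a = simulate_parabola_gravity("hypo", 0.19, 0.06, 3.0, seed=42)
        b = simulate_parabola_gravity("hypo", 0.19, 0.06, 3.0, seed=42)
        assert np.array_equal(a.values, b.values)
        c = simulate_parabola_gravity("hypo", 0.19, 0.06, 3.0, seed=43)
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(profile="steady", level=1.0, noise_sd=0.01, duration=-1.0),
            dict(profile="steady", level=1.0, noise_sd=-0.1, duration=1.0),
            dict(profile="steady", level=2.5, noise_sd=0.0, duration=1.0),
            dict(profile="warp", level=1.0, noise_sd=0.0, duration=1.0),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_parabola_gravity(seed=0, **kwargs)

    def test_hypo_019_lands_in_lowest_cluster_downstream(self):
        """A 0.19 +/- 0.06 g jump is assigned to the 0-0.25 g cluster."""
        trial = gj.make_trial(0.19, seed=1, profile="hypo", noise_sd=0.06)
        marks = gj.mark_phases(trial)
        label = gj.assign_cluster(gj.summarize_gravity(trial.gravity_z, marks))
        assert label.name == "0-0.25" and not label.excluded


class TestDropJump:
    def test_isometric_braking_when_lengthening_zero(self, subject):
        trial = gj.make_trial(1.0, seed=5,
                              activation=gj.ActivationParams(lengthening=0.0))
        lf = trial.truth.lf_marks
        assert lf["MAJ"] == pytest.approx(lf["GC"], rel=0.01)

    def test_programmed_braking_stretch_is_recovered_in_truth(self):
        trial = gj.make_trial(1.2, seed=5,
                              activation=gj.ActivationParams(lengthening=0.20))
        lf = trial.truth.lf_marks
        assert lf["MAJ"] / lf["GC"] == pytest.approx(1.20, abs=0.01)

    def test_free_fall_time_from_25cm_at_1g(self, trial_1g):
        expected = math.sqrt(2 * 0.25 / 9.81)  # 0.226 s
        assert trial_1g.truth.gc - trial_1g.truth.fall_onset == pytest.approx(
            expected, abs=0.005)

    def test_grf_flight_and_contact_shape(self, trial_1g):
        grf = trial_1g.grf_total()
        truth = trial_1g.truth
        flight = grf.segment(truth.fall_onset + 0.02, truth.gc - 0.005)
        assert np.all(flight < 20.0)
        assert grf.value_at(truth.gc) > 20.0
        assert np.max(grf.values) > 1000.0

    def test_ankle_minimum_is_unique_and_at_maj(self, trial_1g):
        ank = trial_1g.ankle
        truth = trial_1g.truth
        i0, i1 = ank.span(truth.gc, truth.po)
        imin = i0 + np.argmin(ank.values[i0:i1 + 1])
        assert ank.time_at(imin) == pytest.approx(truth.maj, abs=1.5 / ank.rate)

    def test_gm_activity_drops_after_braking(self, report_1g):
        tab = report_1g.table.set_index("phase")
        assert tab.loc["MAJ", "gm_iemg"] > tab.loc["PO", "gm_iemg"]
        assert tab.loc["GC", "gm_iemg"] > tab.loc["DO", "gm_iemg"]  # pre-activation

    def test_negative_activation_gain_rejected(self):
        with pytest.raises(ValueError):
            gj.ActivationParams(gm_gain=-1.0)

    def test_gravity_must_span_the_jump(self, subject):
        short = simulate_parabola_gravity("steady", 1.0, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            gj.simulate_drop_jump(subject, short, seed=0)

    @pytest.mark.parametrize("level", [0.19, 0.62, 1.0, 1.41, 1.81])
    @pytest.mark.parametrize("seed", [1, 2])
    def test_truth_ordering_invariant(self, level, seed):
        t = gj.make_trial(level, seed=seed)
        tr = t.truth
        assert tr.fall_onset < tr.gc <= tr.maj <= tr.po


class TestUltrasoundRendering:
    def test_same_seed_identical_frames(self, noiseless_imaging):
        img_a, _ = gj.render_ultrasound_frame(40.0, seed=9)
        img_b, _ = gj.render_ultrasound_frame(40.0, seed=9)
        assert np.array_equal(img_a, img_b)
        img_c, _ = gj.render_ultrasound_frame(40.0, seed=10)
        assert not np.array_equal(img_a, img_c)

    def test_band_geometry_matches_truth(self, noiseless_imaging):
        img, truth = gj.render_ultrasound_frame(46.5, imaging=noiseless_imaging)
        mid = img.shape[1] // 2
        col = img[:, mid]
        sup_row = int(round(truth.sup_intercept + truth.sup_slope * mid))
        deep_row = int(round(truth.deep_intercept + truth.deep_slope * mid))
        # both band centers are local intensity maxima
        assert col[sup_row] > 0.8 and col[deep_row] > 0.8
        sep_mm = (deep_row - sup_row) * truth.mm_per_px
        assert sep_mm == pytest.approx(noiseless_imaging.thickness_mm, abs=0.5)

    def test_parallel_fiber_request_rejected(self):
        with pytest.raises(ValueError):
            gj.render_ultrasound_frame(46.5, fiber_angle_deg=0.0)

    def test_thickness_beyond_depth_rejected(self):
        with pytest.raises(ValueError):
            gj.render_ultrasound_frame(80.0, thickness_mm=55.0)

    def test_chord_shorter_than_separation_rejected(self):
        with pytest.raises(ValueError):
            gj.render_ultrasound_frame(10.0, thickness_mm=18.0)

    def test_truth_fiber_chord_length_is_programmed_lf(self, noiseless_imaging):
        _, truth = gj.render_ultrasound_frame(46.5, imaging=noiseless_imaging)
        for fib in truth.fibers:
            px = math.hypot(fib.x2 - fib.x1, fib.y2 - fib.y1)
            assert px * truth.mm_per_px == pytest.approx(46.5, abs=0.01)


class TestMVC:
    def test_noiseless_square_burst_returns_amplitude(self, subject):
        tr = gj.simulate_mvc(subject, noiseless=True)
        assert gj.mvc_reference(tr) == pytest.approx(subject.mvc_gm, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_seeded_mvc_recovers_programmed_amplitude(self, seed):
        subj = gj.SubjectParams(mvc_gm=2.0)
        tr = gj.simulate_mvc(subj, seed=seed)
        assert gj.mvc_reference(tr) == pytest.approx(2.0, rel=0.05)

    def test_zero_amplitude_fails_downstream_normalization(self):
        subj = gj.SubjectParams(mvc_gm=0.0)
        tr = gj.simulate_mvc(subj, seed=0)
        with pytest.raises(gj.DegenerateReferenceError):
            gj.mvc_reference(tr)
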