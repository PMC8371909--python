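"""Aponeurosis segmentation, fascicle geometry and agreement statistics."""

import math

import numpy as np
import pytest

import gravjump as gj
from gravjump.usseg import LineFit


def fit_rms_error(fit, slope, intercept, width):
    cols = np.arange(width)
    return float(np.sqrt(np.mean((fit.row_at(cols) - (slope * cols + intercept)) ** 2)))


def fiber_at(angle_deg, x0=50.0, y0=150.0, length=100.0):
    a = math.radians(angle_deg)
    return gj.FiberLine(x0, y0, x0 + length * math.cos(a), y0 - length * math.sin(a))


def icc2_oracle(a, b):
    """Brute-force two-way ANOVA decomposition for ICC(2,1)."""
    x = np.stack([a, b], axis=1)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestSegmentation:
    def test_noiseless_frame_fits_within_2px_rms(self, noiseless_imaging):
        img, truth = gj.render_ultrasound_frame(46.5, imaging=noiseless_imaging)
        apo = gj.segment_aponeuroses(img)
        W = img.shape[1]
        assert fit_rms_error(apo.superficial, truth.sup_slope,
                             truth.sup_intercept, W) < 2.0
        assert fit_rms_error(apo.deep, truth.deep_slope, truth.deep_intercept, W) < 2.0

    def test_default_speckle_fits_within_4px_rms(self):
        img, truth = gj.render_ultrasound_frame(46.5, seed=4)
        apo = gj.segment_aponeuroses(img)
        W = img.shape[1]
        assert fit_rms_error(apo.superficial, truth.sup_slope,
                             truth.sup_intercept, W) < 4.0
        assert fit_rms_error(apo.deep, truth.deep_slope, truth.deep_intercept, W) < 4.0

    def test_single_band_image_fails_with_diagnostic_mask(self):
        img = np.full((250, 300), 0.1)
        img[100:108, :] = 0.9  # one band only
        with pytest.raises(gj.SegmentationError) as exc:
            gj.segment_aponeuroses(img)
        assert exc.value.mask is not None

    def test_band_ordering_superficial_above_deep(self, noiseless_imaging):
        img, _ = gj.render_ultrasound_frame(40.0, imaging=noiseless_imaging)
        apo = gj.segment_aponeuroses(img)
        assert apo.superficial.row_at(150) < apo.deep.row_at(150)


class TestMeasureFascicles:
    def horizontal_pair(self, sep_px=50.0, top=50.0):
        return gj.AponeurosisPair(
            superficial=LineFit(0.0, top, 0.0, 299.0),
            deep=LineFit(0.0, top + sep_px, 0.0, 299.0),
        )

    def test_closed_form_20deg_geometry(self):
        # 10 mm separation at 0.2 mm/px = 50 px; fiber at 20 deg
        apo = self.horizontal_pair(sep_px=50.0)
        fibers = [fiber_at(20.0, x0=x) for x in (60.0, 100.0, 140.0)]
        m = gj.measure_fascicles(apo, fibers, scale=0.2, image_width=300)
        assert m.lf_mean == pytest.approx(10.0 / math.sin(math.radians(20.0)), rel=1e-6)
        assert m.pennation == pytest.approx(20.0, abs=1e-6)
        assert m.thickness_mean == pytest.approx(10.0, abs=1e-9)
        assert m.lf_sd == pytest.approx(0.0, abs=1e-9)  # three identical fibers

    def test_rendered_frame_recovers_programmed_46_5mm(self, noiseless_imaging):
        img, truth = gj.render_ultrasound_frame(46.5, imaging=noiseless_imaging)
        apo = gj.segment_aponeuroses(img)
        m = gj.measure_fascicles(apo, truth.fibers, truth.mm_per_px,
                                 image_width=img.shape[1])
        assert m.lf_mean == pytest.approx(46.5, abs=0.9)  # 2 %

    def test_parallel_fiber_rejected(self):
        apo = self.horizontal_pair()
        fibers = [fiber_at(0.5, x0=x) for x in (60.0, 100.0, 140.0)]
        with pytest.raises(gj.InvalidFiberError):
            gj.measure_fascicles(apo, fibers, scale=0.2, image_width=300)

    def test_wrong_fiber_count_rejected(self):
        apo = self.horizontal_pair()
        with pytest.raises(ValueError):
            gj.measure_fascicles(apo, [fiber_at(20.0)], scale=0.2)

    def test_rescaling_equivariance(self):
        """Halving mm/px doubles pixel geometry but leaves Lf in mm unchanged."""
        apo1 = self.horizontal_pair(sep_px=50.0, top=50.0)
        fib1 = [fiber_at(25.0, x0=x, y0=100.0) for x in (60.0, 100.0, 140.0)]
        m1 = gj.measure_fascicles(apo1, fib1, scale=0.2, image_width=300)
        apo2 = gj.AponeurosisPair(
            superficial=LineFit(0.0, 100.0, 0.0, 599.0),
            deep=LineFit(0.0, 200.0, 0.0, 599.0),
        )
        fib2 = [gj.FiberLine(2 * f.x1, 2 * f.y1, 2 * f.x2, 2 * f.y2) for f in fib1]
        m2 = gj.measure_fascicles(apo2, fib2, scale=0.1, image_width=600)
        assert m2.lf_mean == pytest.approx(m1.lf_mean, rel=1e-9)
        assert m2.thickness_mean == pytest.approx(m1.thickness_mean, rel=1e-9)

    def test_rotation_leaves_lf_and_pennation_unchanged(self, noiseless_imaging):
        """Inclining the whole geometry by 5 deg changes neither Lf nor pennation."""
        img0, tr0 = gj.render_ultrasound_frame(40.0, imaging=noiseless_imaging)
        m0 = gj.measure_fascicles(gj.segment_aponeuroses(img0), tr0.fibers,
                                  tr0.mm_per_px, image_width=img0.shape[1])
        tilted = gj.ImagingParams(speckle_sd=0.0, slope_deg=5.0)
        img5, tr5 = gj.render_ultrasound_frame(40.0, imaging=tilted)
        m5 = gj.measure_fascicles(gj.segment_aponeuroses(img5), tr5.fibers,
                                  tr5.mm_per_px, image_width=img5.shape[1])
        assert m5.lf_mean == pytest.approx(m0.lf_mean, rel=0.01)
        assert m5.pennation == pytest.approx(m0.pennation, rel=0.01)


class TestICC:
    def test_identical_series_icc_one(self):
        a = np.array([40.0, 42.0, 44.0, 46.0, 48.0, 50.0])
        assert gj.icc_agreement(a, a) == pytest.approx(1.0)

    def test_noise_matching_signal_variance_gives_half(self):
        rng = np.random.default_rng(7)
        a = rng.normal(45.0, 3.0, 120)
        b = a + rng.normal(0.0, 3.0, 120)
        icc = gj.icc_agreement(a, b)
        assert icc == pytest.approx(icc2_oracle(a, b), abs=1e-6)
        assert 0.35 < icc < 0.65  # analytic variance ratio sigma^2/(sigma^2+sigma^2)

    def test_anticorrelated_pairs_negative(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert gj.icc_agreement(a, a[::-1]) < 0.0

    def test_matches_anova_oracle_on_general_data(self):
        rng = np.random.default_rng(12)
        a = rng.normal(40, 5, 30)
        b = 0.9 * a + rng.normal(2, 2, 30)
        assert gj.icc_agreement(a, b) == pytest.approx(icc2_oracle(a, b), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(gj.UndefinedStatisticError):
            gj.icc_agreement(np.ones(6), np.ones(6))
        with pytest.raises(ValueError):
            gj.icc_agreement(np.arange(3.0), np.arange(3.0))


class TestTrackSequence:
    def test_programmed_braking_stretch_recovered_from_frames(self):
        trial = gj.make_trial(1.2, seed=8,
                              activation=gj.ActivationParams(lengthening=0.20))
        marks = gj.mark_phases(trial)
        fr = trial.frames
        idx = marks.frame_indices(fr.rate, fr.t0)
        labels = {v: k for k, v in idx.items()}
        df = gj.track_sequence(fr, idx.values(), "truth", phase_labels=labels,
                               normalize_do=True)
        by = df.set_index("phase")
        assert by.loc["MAJ", "lf_mm"] / by.loc["GC", "lf_mm"] == pytest.approx(
            1.20, abs=0.05)
        assert by.loc["DO", "lf_norm_do"] == pytest.approx(1.0)

    def test_braking_interval_frames_are_measurable(self, trial_1g):
        marks = gj.mark_phases(trial_1g)
        fr = trial_1g.frames
        i0, i1 = marks.frame_index("GC"), marks.frame_index("MAJ")
        df = gj.track_sequence(fr, range(i0, i1 + 1), "truth")
        assert len(df) == i1 - i0 + 1
        assert (df["lf_mm"] > 0).all()

    def test_all_failed_frames_raise_with_summary(self):
        blank = [np.zeros((250, 300)), np.zeros((250, 300))]
        with pytest.raises(gj.SegmentationError):
            gj.track_sequence(blank, [0, 1], lambda i: [], scale=0.2)
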