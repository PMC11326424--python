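"""Phantom generator: bolus curves, geometry, corruption, reproducibility."""

import numpy as np
import pytest

from daugs.core import BACKGROUND, BLOODPOOL, MYOCARDIUM
from daugs.phantom import (
    PhantomConfig,
    GammaVariate,
    gamma_variate_curve,
    inject_motion_error,
    internal_sampler,
    make_dataset,
    make_phantom,
    shifted_sampler,
)

from conftest import clean_phantom_config, DESK_SPEC


class TestGammaVariate:
    def test_zero_before_and_at_onset(self):
        t = np.array([0.0, 1.0, 2.0])
        assert np.all(gamma_variate_curve(t, t0=2.0, alpha=2, beta=3, A=1) == 0)

    def test_peak_value_is_amplitude(self):
        # peak at t = t0 + alpha*beta by construction
        assert gamma_variate_curve(
            np.array([1.0 + 2 * 3]), t0=1.0, alpha=2, beta=3, A=0.7
        )[0] == pytest.approx(0.7, abs=1e-12)

    def test_closed_form_scalar(self):
        # direct evaluation: A=1, t0=0, alpha=2, beta=3, t=3
        expected = (3 / 6.0) ** 2 * np.exp(2 - 1.0)
        got = gamma_variate_curve(np.array([3.0]), 0.0, 2.0, 3.0, 1.0)[0]
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(0, 1), (-1, 2), (2, 0)])
    def test_invalid_shape_rate(self, alpha, beta):
        with pytest.raises(ValueError):
            gamma_variate_curve(np.arange(3.0), 0.0, alpha, beta, 1.0)


class TestMakePhantom:
    def test_homogeneous_myocardium_single_curve(self):
        series, mask = make_phantom(clean_phantom_config(defect_spec=None))
        myo = series.intensities[mask.labels == MYOCARDIUM]
        assert np.allclose(myo, myo[0])  # every myocardial pixel same curve

    def test_deterministic_given_seed(self):
        cfg = clean_phantom_config(noise_sigma=0.02, shading_strength=0.2)
        s1, m1 = make_phantom(cfg)
        s2, m2 = make_phantom(cfg)
        assert np.array_equal(s1.intensities, s2.intensities)
        assert np.array_equal(m1.labels, m2.labels)

    def test_defect_halves_peak_enhancement(self):
        cfg = clean_phantom_config(defect_spec=(0.0, 1.0, 0.5))
        series, mask = make_phantom(cfg)
        vol = series.intensities
        enh = vol.max(axis=2) - vol[:, :, 0]  # peak minus pre-contrast
        n = cfg.image_size
        c = (n - 1) / 2.0
        rr, cc = np.mgrid[0:n, 0:n].astype(float)
        theta = np.mod(np.arctan2(rr - c, cc - c), 2 * np.pi)
        inside = (mask.labels == MYOCARDIUM) & (theta >= 0) & (theta < 1)
        outside = (mask.labels == MYOCARDIUM) & ~inside
        ratio = enh[inside].mean() / enh[outside].mean()
        assert ratio == pytest.approx(0.5, rel=1e-9)

    def test_mask_labels_exclusive_exhaustive(self):
        _, mask = make_phantom(clean_phantom_config())
        assert set(np.unique(mask.labels)) <= {BACKGROUND, MYOCARDIUM, BLOODPOOL}

    def test_bloodpool_peak_precedes_myocardial_peak(self):
        series, mask = make_phantom(clean_phantom_config())
        blood = series.intensities[mask.labels == BLOODPOOL].mean(axis=0)
        myo = series.intensities[mask.labels == MYOCARDIUM].mean(axis=0)
        assert np.argmax(blood) < np.argmax(myo)

    def test_geometry_invariant_enforced(self):
        with pytest.raises(ValueError):
            make_phantom(clean_phantom_config(cavity_radius=25, ring_thickness=10))

    def test_defect_multiplier_range_enforced(self):
        with pytest.raises(ValueError):
            PhantomConfig(defect_spec=(0.0, 1.0, 1.0)).validate()


class TestMotionError:
    def test_zero_shift_is_identity(self):
        series, mask = make_phantom(clean_phantom_config())
        out = inject_motion_error(series, mask, n_bad_frames=5, shift_px=0.0,
                                  seed=3)
        assert np.array_equal(out.intensities, series.intensities)

    def test_exactly_n_frames_differ(self):
        series, mask = make_phantom(clean_phantom_config())
        out = inject_motion_error(series, mask, n_bad_frames=3, shift_px=2.0,
                                  seed=3)
        differ = [
            not np.array_equal(out.intensities[:, :, f],
                               series.intensities[:, :, f])
            for f in range(series.n_frames)
        ]
        assert sum(differ) == 3

    def test_centroid_displacement_matches_shift(self):
        series, mask = make_phantom(clean_phantom_config())
        s = 3.0
        out = inject_motion_error(series, mask, n_bad_frames=series.n_frames,
                                  shift_px=s, seed=9)
        # centroid of thresholded bloodpool at the LV-peak frame region
        disp = []
        for f in range(series.n_frames):
            ref = series.intensities[:, :, f]
            thr = ref.mean() + 2 * ref.std()
            if (ref > thr).sum() < 20:
                continue
            c_ref = np.argwhere(ref > thr).mean(axis=0)
            c_out = np.argwhere(out.intensities[:, :, f] > thr).mean(axis=0)
            disp.append(np.linalg.norm(c_out - c_ref))
        assert np.mean(disp) == pytest.approx(s, rel=0.25)

    def test_excessive_shift_rejected(self):
        series, mask = make_phantom(clean_phantom_config())
        with pytest.raises(ValueError):
            inject_motion_error(series, mask, 1, shift_px=20.0, seed=0)


class TestMakeDataset:
    def test_singleton_and_determinism(self):
        d1 = make_dataset(1, internal_sampler("desk"), seed=5)
        d2 = make_dataset(1, internal_sampler("desk"), seed=5)
        assert len(d1) == 1
        assert np.array_equal(d1[0][0].intensities, d2[0][0].intensities)

    def test_series_ids_distinct_and_tagged(self):
        data = make_dataset(4, shifted_sampler("desk"), seed=2)
        ids = [s.series_id for s, _ in data]
        assert len(set(ids)) == 4 and all(i.startswith("shifted") for i in ids)

    def test_shifted_sampler_offsets_myocardial_amplitude(self):
        rng_i = np.random.default_rng(0)
        rng_s = np.random.default_rng(0)
        n = 400
        a_int = np.mean([internal_sampler("desk")(rng_i).curve_params["myo"].A
                         for _ in range(n)])
        a_shf = np.mean([shifted_sampler("desk")(rng_s).curve_params["myo"].A
                         for _ in range(n)])
        # configured offset is +0.15 on the myocardial peak amplitude
        assert a_shf - a_int == pytest.approx(0.15, abs=0.01)
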