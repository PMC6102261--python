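"""Detection, PSF fitting, precision, grouping and drift correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smlmpipe as sp
from smlmpipe.synthetic import FrameStack, _integrated_gaussian_patch

CAMERA = sp.CameraModel(pixel_size_nm=100.0, gain=1.0)


def render_single_frame(u0, v0, photons, sigma_px, size=32, background=0.0):
    cols = np.arange(size)
    rows = np.arange(size)
    return photons * _integrated_gaussian_patch(u0, v0, sigma_px, cols, rows) + background


class TestDetectEvents:
    def test_uniform_frame_yields_no_events(self):
        stack = FrameStack(np.full((3, 32, 32), 100, dtype=np.uint16), 100.0)
        assert len(sp.detect_events(stack, sp.DetectionConfig())) == 0

    def test_empty_stack_yields_empty_result(self):
        stack = FrameStack(np.zeros((0, 32, 32), dtype=np.uint16), 100.0)
        assert len(sp.detect_events(stack, sp.DetectionConfig())) == 0

    def test_bright_emitter_gives_one_candidate_at_its_pixel(self):
        frame = render_single_frame(16.5, 12.5, 5000, 1.5, background=5.0)
        stack = FrameStack(frame[None], 100.0)
        cand = sp.detect_events(stack, sp.DetectionConfig())
        assert len(cand) == 1
        assert (cand.iloc[0]["row"], cand.iloc[0]["col"]) == (12, 16)


class TestFitPsf:
    @pytest.mark.parametrize("offset", [(0.0, 0.0), (0.3, -0.2)])
    def test_noiseless_emitter_recovered_within_centipixel(self, offset):
        u0, v0 = 16.5 + offset[0], 15.5 + offset[1]
        frame = render_single_frame(u0, v0, 2000, 1.5, background=2.0)
        fits = sp.fit_psf(frame, (15, 16), CAMERA, sp.DetectionConfig())
        assert len(fits) == 1
        assert abs(fits[0].x_nm / 100 - u0) < 0.01
        assert abs(fits[0].y_nm / 100 - v0) < 0.01

    def test_noiseless_photon_count_within_one_percent(self):
        frame = render_single_frame(16.5, 15.5, 2000, 1.5, background=2.0)
        fit = sp.fit_psf(frame, (15, 16), CAMERA, sp.DetectionConfig())[0]
        assert fit.photons == pytest.approx(2000, rel=0.01)

    def test_overcrowded_window_discarded(self):
        frame = render_single_frame(16.5, 15.5, 2000, 1.5, background=2.0)
        cands = [(15, 16), (15, 17), (16, 16), (16, 17)]
        assert sp.fit_psf(frame, cands, CAMERA, sp.DetectionConfig()) == []


class TestLocalizationPrecision:
    def test_closed_form_at_zero_background(self):
        # sigma_a = 120 nm (sigma chosen so sigma^2 + a^2/12 = 120^2), N = 400:
        # sqrt(120^2/400 * 16/9) = (4/3) * 120/20 = 8 nm
        a = 100.0
        sigma = np.sqrt(120.0**2 - a**2 / 12)
        fit = sp.PsfFit(0, 0, photons=400, background_std=0.0, sigma_nm=sigma, residual=0)
        assert sp.localization_precision(fit, CAMERA) == pytest.approx(8.0, rel=1e-12)

    def test_scaling_law_in_photon_count_at_zero_background(self):
        fit1 = sp.PsfFit(0, 0, 400, 0.0, 150.0, 0)
        fit2 = sp.PsfFit(0, 0, 800, 0.0, 150.0, 0)
        r = sp.localization_precision(fit1, CAMERA) / sp.localization_precision(fit2, CAMERA)
        assert r == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_independent_arithmetic_oracle(self):
        # direct evaluation at sigma = 150 nm, a = 100 nm, N = 1000, b = 3
        sigma_a2 = 150.0**2 + 100.0**2 / 12
        expected = np.sqrt(
            sigma_a2 / 1000 * (16 / 9 + 8 * np.pi * sigma_a2 * 9 / (1000 * 100.0**2))
        )
        fit = sp.PsfFit(0, 0, 1000, 3.0, 150.0, 0)
        assert sp.localization_precision(fit, CAMERA) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_photons_and_background(self):
        base = sp.localization_precision(sp.PsfFit(0, 0, 500, 2.0, 150.0, 0), CAMERA)
        assert sp.localization_precision(sp.PsfFit(0, 0, 1000, 2.0, 150.0, 0), CAMERA) < base
        assert sp.localization_precision(sp.PsfFit(0, 0, 500, 4.0, 150.0, 0), CAMERA) > base

    def test_nonpositive_photons_rejected(self):
        with pytest.raises(ValueError):
            sp.localization_precision(sp.PsfFit(0, 0, 0.0, 1.0, 150.0, 0), CAMERA)


def _table(frames, xs, ys, photons=None):
    n = len(frames)
    return pd.DataFrame(
        {
            "frame": frames,
            "x_nm": xs,
            "y_nm": ys,
            "photons": photons if photons is not None else np.full(n, 100.0),
        }
    )


class TestGrouping:
    def test_single_localization_is_one_group(self):
        _, merged = sp.group_localizations(_table([5], [100.0], [200.0]))
        assert len(merged) == 1
        assert merged.iloc[0]["n_events"] == 1

    def test_nearby_consecutive_frames_merge(self):
        _, merged = sp.group_localizations(_table([10, 11], [1000.0, 1050.0], [0.0, 0.0]))
        assert len(merged) == 1

    def test_gap_beyond_max_gap_splits(self):
        # frames 10 and 70: dark gap of 59 frames > 50
        _, merged = sp.group_localizations(_table([10, 70], [1000.0, 1000.0], [0.0, 0.0]))
        assert len(merged) == 2

    def test_run_longer_than_max_on_splits(self):
        frames = list(range(10, 17))  # 7 consecutive frames > max_on = 5
        _, merged = sp.group_localizations(
            _table(frames, [1000.0] * 7, [0.0] * 7)
        )
        assert len(merged) == 2

    def test_photon_weighted_merge_and_conservation(self):
        t = _table([1, 2], [0.0, 300.0], [0.0, 0.0], photons=[100.0, 300.0])
        _, merged = sp.group_localizations(t, sp.GroupingConfig(radius_nm=400))
        assert len(merged) == 1
        assert merged.iloc[0]["photons"] == 400.0
        assert merged.iloc[0]["x_nm"] == pytest.approx(225.0)  # (0*100+300*300)/400

    def test_never_merges_beyond_radius(self, rng):
        xy = rng.uniform(0, 2000, (60, 2))
        frames = rng.integers(0, 30, 60)
        t = _table(frames, xy[:, 0], xy[:, 1])
        labelled, merged = sp.group_localizations(t)
        for _, grp in labelled.groupby("group_id"):
            pts = grp[["x_nm", "y_nm"]].to_numpy()
            com = pts.mean(axis=0)
            # members were admitted within radius of the running centre;
            # they cannot be arbitrarily far from the final centroid
            assert np.hypot(*(pts - com).T).max() <= 2 * 100.0

    def test_group_count_invariant_to_within_frame_order(self, rng):
        xy = rng.uniform(0, 2000, (40, 2))
        frames = np.repeat(np.arange(10), 4)
        t = _table(frames, xy[:, 0], xy[:, 1])
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        _, m1 = sp.group_localizations(t)
        _, m2 = sp.group_localizations(shuffled)
        assert len(m1) == len(m2)

    def test_empty_table_passes_through(self):
        t = _table([], [], [])
        labelled, merged = sp.group_localizations(t)
        assert len(labelled) == 0 and len(merged) == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_photons_conserved_and_partition_complete(self, seed):
        """Grouping conserves total photons exactly and labels every record."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 80))
        t = _table(
            rng.integers(0, 120, n),
            rng.uniform(0, 3000, n),
            rng.uniform(0, 3000, n),
            photons=rng.uniform(50, 5000, n),
        )
        labelled, merged = sp.group_localizations(t)
        assert merged["photons"].sum() == pytest.approx(t["photons"].sum(), rel=1e-12)
        assert (labelled["group_id"] >= 0).all()
        assert merged["n_events"].sum() == n


class TestDrift:
    def _fiducial_table(self, drift, n_frames=500, x0=800.0, y0=600.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        frames = np.arange(n_frames)
        dx, dy = drift.displacement(frames)
        return pd.DataFrame(
            {
                "frame": frames,
                "x_nm": x0 + dx + rng.normal(0, noise, n_frames),
                "y_nm": y0 + dy + rng.normal(0, noise, n_frames),
                "photons": 20000.0,
            }
        )

    def test_stationary_fiducial_gives_zero_trajectory(self):
        t = self._fiducial_table(sp.DriftTrajectory.zero(500))
        est = sp.estimate_drift(t, np.array([[800.0, 600.0]]))
        dx, dy = est.displacement(np.arange(500))
        assert np.abs(dx).max() < 1e-9 and np.abs(dy).max() < 1e-9

    def test_linear_drift_slope_recovered_within_five_percent(self):
        true = sp.DriftTrajectory.linear(2000, 0.5, 0.0)
        t = self._fiducial_table(true, n_frames=2000, noise=2.0)
        est = sp.estimate_drift(t, np.array([[800.0, 600.0]]))
        dx, _ = est.displacement([1999])
        slope = dx[0] / 1999
        assert abs(slope - 0.5) / 0.5 < 0.05

    def test_two_equal_fiducials_average_to_same_trajectory(self):
        true = sp.DriftTrajectory.linear(500, 0.4, -0.2)
        t1 = self._fiducial_table(true, x0=500.0, y0=500.0)
        t2 = self._fiducial_table(true, x0=1500.0, y0=1500.0)
        t = pd.concat([t1, t2], ignore_index=True)
        est_two = sp.estimate_drift(t, np.array([[500.0, 500.0], [1500.0, 1500.0]]))
        est_one = sp.estimate_drift(t1, np.array([[500.0, 500.0]]))
        frames = np.arange(500)
        np.testing.assert_allclose(
            est_two.displacement(frames)[0], est_one.displacement(frames)[0], atol=1e-9
        )

    def test_missing_fiducial_raises_with_candidates(self):
        t = self._fiducial_table(sp.DriftTrajectory.zero(500))
        with pytest.raises(ValueError, match="nearest candidates"):
            sp.estimate_drift(t, np.array([[5000.0, 5000.0]]), search_radius_nm=100.0)


class TestApplyDriftCorrection:
    def test_zero_trajectory_is_identity(self):
        t = _table([0, 100], [10.0, 20.0], [30.0, 40.0])
        out = sp.apply_drift_correction(t, sp.DriftTrajectory.zero(200))
        pd.testing.assert_frame_equal(out, t)

    def test_inject_then_correct_roundtrips(self, rng):
        drift = sp.DriftTrajectory(
            np.array([0, 50, 200]), np.array([0.0, 12.0, -5.0]), np.array([0.0, -3.0, 8.0])
        )
        frames = rng.integers(0, 201, 100)
        x = rng.uniform(0, 5000, 100)
        y = rng.uniform(0, 5000, 100)
        dx, dy = drift.displacement(frames)
        drifted = _table(frames, x + dx, y + dy)
        out = sp.apply_drift_correction(drifted, drift)
        np.testing.assert_allclose(out["x_nm"], x, atol=1e-9)
        np.testing.assert_allclose(out["y_nm"], y, atol=1e-9)

    def test_frame_outside_domain_rejected(self):
        t = _table([500], [0.0], [0.0])
        with pytest.raises(ValueError):
            sp.apply_drift_correction(t, sp.DriftTrajectory.zero(100))
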