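"""Mesh-grid photostimulation artifact: expected geometry, detection,
inpainting, and frame deletion."""

import numpy as np
import pytest

from holostim.artifact import (
    ArtifactMask,
    MovieBundle,
    delete_stim_frames,
    detect_artifact_pixels,
    expected_artifact_spacing,
    inpaint_artifact,
)


class TestExpectedSpacing:
    def test_linear_scan_ratio(self):
        assert expected_artifact_spacing(8.2e6, 1e6, "linear") == pytest.approx(8.2)
        assert expected_artifact_spacing(8.2e6, 2e5, "linear") == pytest.approx(41.0)

    def test_limit_approaches_one(self):
        assert expected_artifact_spacing(1e6, 1e6 - 1, "linear") == pytest.approx(1.0, rel=1e-5)

    def test_pixel_rate_below_rep_rate_rejected(self):
        with pytest.raises(ValueError, match="deleted"):
            expected_artifact_spacing(1e5, 1e6, "linear")

    def test_resonant_minimum_at_center_diverges_at_edges(self):
        n = 512
        cols = np.arange(n)
        sp = expected_artifact_spacing(8.2e6, 1e6, "resonant", cols, n)
        assert np.argmin(sp) in (n // 2 - 1, n // 2)
        assert sp[n // 2] == pytest.approx(8.2, rel=0.01)
        assert sp[0] > 5 * sp[n // 2]
        # monotone away from the center on each side
        assert np.all(np.diff(sp[: n // 2]) <= 1e-9)
        assert np.all(np.diff(sp[n // 2 :]) >= -1e-9)


def _simple_movie(frames, stim, **kw):
    n = len(frames)
    return MovieBundle(
        frames, np.arange(n) * 0.1, np.zeros(n, int), stim,
        kw.get("pixel_rate", 8.2e6), kw.get("f_rep", 1e6),
        kw.get("scan_model", "linear"),
    )


class TestDetection:
    def test_fixture_precision_and_recall(self, movie_fixture):
        """On the synthetic movie the two-stage detector recovers the
        injected mesh with precision and recall >= 0.9 (k_sigma = 3)."""
        got = movie_fixture["detected"].mask
        want = movie_fixture["truth"].artifact_mask
        tp = (got & want).sum()
        assert tp / got.sum() >= 0.9       # precision
        assert tp / want.sum() >= 0.9      # recall

    def test_no_stimulation_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        movie = _simple_movie(rng.normal(100, 3, (20, 32, 32)).clip(0), [])
        assert detect_artifact_pixels(movie).mask.sum() == 0

    def test_uniform_elevation_fails_geometry_gate(self):
        """A whole frame uniformly elevated has no narrow runs: the width
        test rejects everything, flagging the movie for frame deletion."""
        rng = np.random.default_rng(1)
        frames = rng.normal(100, 3, (21, 32, 32)).clip(0)
        frames[10] += 500.0
        movie = _simple_movie(frames, [(1.0, 1.05)])
        assert movie.stim_frame_mask()[10]
        assert detect_artifact_pixels(movie).mask.sum() == 0

    def test_missing_clean_frames_rejected(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(100, 3, (3, 16, 16)).clip(0)
        movie = MovieBundle(frames, [0.0, 0.1, 0.2], [0, 0, 0], [(0.0, 0.25)])
        with pytest.raises(ValueError, match="clean frames"):
            detect_artifact_pixels(movie)

    def test_mask_restricted_to_stim_frames(self, movie_fixture):
        det = movie_fixture["detected"]
        assert not det.mask[~det.stim_frames].any()
        with pytest.raises(ValueError, match="outside"):
            bad = det.mask.copy()
            bad[np.flatnonzero(~det.stim_frames)[0], 0, 0] = True
            ArtifactMask(bad, det.stim_frames)


class TestInpaint:
    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(100, 3, (12, 16, 16)).clip(0)
        movie = _simple_movie(frames, [(0.5, 0.55)])
        mask = ArtifactMask(np.zeros(frames.shape, bool), movie.stim_frame_mask())
        out = inpaint_artifact(movie, mask)
        assert np.array_equal(out.frames, movie.frames)

    def test_single_pixel_between_equal_neighbours(self):
        frames = np.full((11, 5, 5), 10.0)
        frames[5, 2, 2] = 200.0
        movie = _simple_movie(frames, [(0.5, 0.55)])
        mask = np.zeros(frames.shape, bool)
        mask[5, 2, 2] = True
        out = inpaint_artifact(movie, ArtifactMask(mask, movie.stim_frame_mask()))
        assert out.frames[5, 2, 2] == 10.0

    def test_fully_masked_row_falls_back_to_column(self):
        frames = np.full((11, 5, 5), 7.0)
        frames[5, 2, :] = 300.0
        movie = _simple_movie(frames, [(0.5, 0.55)])
        mask = np.zeros(frames.shape, bool)
        mask[5, 2, :] = True
        out = inpaint_artifact(movie, ArtifactMask(mask, movie.stim_frame_mask()))
        np.testing.assert_allclose(out.frames[5, 2], 7.0)

    def test_fixture_rmse_reduction(self, movie_fixture):
        """Cleaning shrinks the stimulation-frame RMSE against the
        artifact-free ground truth to < 0.2x the contaminated RMSE."""
        movie = movie_fixture["movie"]
        clean = movie_fixture["truth"].clean_frames
        got = movie_fixture["cleaned"].frames
        stim = movie_fixture["detected"].stim_frames
        rmse_before = np.sqrt(np.mean((movie.frames[stim] - clean[stim]) ** 2))
        rmse_after = np.sqrt(np.mean((got[stim] - clean[stim]) ** 2))
        assert rmse_after < 0.2 * rmse_before

    def test_unmasked_pixels_bit_identical(self, movie_fixture):
        movie = movie_fixture["movie"]
        mask = movie_fixture["detected"].mask
        got = movie_fixture["cleaned"].frames
        assert np.array_equal(got[~mask], movie.frames[~mask])

    def test_idempotent_for_fixed_mask(self, movie_fixture):
        once = movie_fixture["cleaned"]
        twice = inpaint_artifact(once, movie_fixture["detected"])
        assert np.array_equal(once.frames, twice.frames)


class TestDeleteFrames:
    def test_single_frame_interval_removed(self):
        frames = np.full((10, 4, 4), 5.0)
        movie = _simple_movie(frames, [(0.31, 0.39)])
        out, report = delete_stim_frames(movie)
        assert report.n_removed == 1
        assert report.removed_indices[0] == 3
        assert out.n_frames == 9
        # original timestamps preserved on survivors
        assert 0.3 not in out.timestamps
        assert out.timestamps[3] == pytest.approx(0.4)

    def test_no_intervals_is_identity(self):
        frames = np.full((6, 4, 4), 5.0)
        movie = _simple_movie(frames, [])
        out, report = delete_stim_frames(movie)
        assert report.n_removed == 0
        assert np.array_equal(out.frames, movie.frames)

    def test_multi_frame_interval_warns(self):
        frames = np.full((10, 4, 4), 5.0)
        movie = _simple_movie(frames, [(0.30, 0.55)])
        with pytest.warns(UserWarning, match="more than one frame"):
            out, report = delete_stim_frames(movie)
        assert report.n_removed == 3


def test_cleaned_traces_track_ground_truth(chain_fixture):
    """ROI dF/F from the cleaned movie correlates with ROI dF/F from the
    artifact-free movie at r >= 0.95 around stimulation epochs."""
    from holostim.analysis import dff_from_fluorescence, roi_fluorescence

    truth = chain_fixture["truth"]
    cleaned = chain_fixture["cleaned"]
    movie = chain_fixture["movie"]
    f_clean, ts = roi_fluorescence(
        truth.clean_frames, movie.plane_index, movie.timestamps,
        truth.cell_px, truth.cell_planes, radius_px=2.5,
    )
    dff_ref = dff_from_fluorescence(f_clean)
    dff_got = chain_fixture["traces"].dff
    sel = np.zeros(len(ts), bool)
    for tr in truth.trials:
        sel |= (ts >= tr.stim_start - 0.5) & (ts <= tr.stim_end + 2.0)
    checked = 0
    for i in range(dff_ref.shape[0]):
        # evaluate ROIs carrying actual transients; for noise-only traces
        # the correlation measures noise, not signal preservation
        if np.std(dff_ref[i, sel]) > 0.05:
            r = np.corrcoef(dff_ref[i, sel], dff_got[i, sel])[0, 1]
            assert r >= 0.95
            checked += 1
    assert checked >= 10
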