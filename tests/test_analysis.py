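"""Marker detection, distortion sampling, summary statistics, constancy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from gridwarp_qa.analysis import (
    MARKER_COLUMNS,
    MarkerSet,
    compare_to_baseline,
    compute_distortion,
    extract_markers,
    marker_mask,
    match_to_ground_truth,
    summarize,
)
from gridwarp_qa.synthetic import (
    DistortionModel,
    build_phantom_mr,
    marker_positions,
    true_marker_displacements,
)
from gridwarp_qa.volume import DeformationField

from conftest import SMALL_SHAPE, SMALL_SPACING


def _markerset_from_magnitudes(mags, radii):
    mags = np.asarray(mags, float)
    radii = np.asarray(radii, float)
    n = len(mags)
    ux = mags  # put the whole magnitude on x
    table = pd.DataFrame(
        {
            "marker_id": np.arange(n),
            "x_mm": radii,
            "y_mm": np.zeros(n),
            "z_mm": np.zeros(n),
            "ux_mm": ux,
            "uy_mm": np.zeros(n),
            "uz_mm": np.zeros(n),
            "magnitude_mm": mags,
            "r_mm": radii,
        }
    )
    return MarkerSet(table=table, isocenter=np.zeros(3))


class TestMarkerMask:
    def test_otsu_isolates_exactly_the_markers(self, small_mr_undistorted):
        mask = marker_mask(small_mr_undistorted)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        assert n == 27

    def test_threshold_above_markers_is_error(self, small_mr_undistorted):
        with pytest.raises(ValueError, match="empty"):
            marker_mask(small_mr_undistorted, threshold_strategy="fixed", threshold=2000.0)

    def test_threshold_below_body_is_error(self, small_mr_undistorted):
        with pytest.raises(ValueError, match="pathological"):
            marker_mask(small_mr_undistorted, threshold_strategy="fixed", threshold=10.0)

    def test_noisy_image_still_yields_marker_count(self, small_spec):
        """SNR 20 (sigma = marker intensity / 20): opening removes speckle."""
        noisy = build_phantom_mr(
            small_spec, DistortionModel(), shape=SMALL_SHAPE, spacing=SMALL_SPACING,
            noise_sigma=small_spec.mr_intensities["marker"] / 20.0, seed=42,
        )
        mask = marker_mask(noisy)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        assert n == 27

    def test_percentile_strategy(self, small_mr_undistorted):
        mask = marker_mask(small_mr_undistorted, threshold_strategy="percentile", percentile=99.5)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        assert n == 27


class TestExtractMarkers:
    def test_centroids_match_analytic_grid(self, small_mr_undistorted, small_spec):
        mask = marker_mask(small_mr_undistorted)
        cents = extract_markers(mask, small_mr_undistorted)
        pos = marker_positions(small_spec)
        assert len(cents) == len(pos)
        errs = [np.min(np.linalg.norm(cents - p, axis=1)) for p in pos]
        assert max(errs) < 0.25 * SMALL_SPACING

    def test_merged_markers_warned(self, small_mr_undistorted):
        mask = marker_mask(small_mr_undistorted).copy()
        # merge two neighbouring markers with a thick bridge along x
        idx = small_mr_undistorted.world_to_index(
            np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        ).round().astype(int)
        j, k = idx[0][1], idx[0][2]
        mask[idx[0][0]: idx[1][0] + 1, j - 1: j + 2, k - 1: k + 2] = True
        with pytest.warns(UserWarning, match="merged"):
            extract_markers(mask, small_mr_undistorted)

    def test_symmetric_sphere_centroid_is_exact(self, small_mr_undistorted, small_spec):
        """An isolated symmetric marker's intensity-weighted centroid sits
        at the sphere center to floating-point accuracy."""
        mask = marker_mask(small_mr_undistorted)
        cents = extract_markers(mask, small_mr_undistorted)
        center = cents[np.argmin(np.linalg.norm(cents, axis=1))]
        assert np.allclose(center, 0.0, atol=1e-9)

    def test_empty_mask_is_error(self, small_mr_undistorted):
        with pytest.raises(ValueError, match="empty"):
            extract_markers(np.zeros(SMALL_SHAPE, bool), small_mr_undistorted)

    def test_min_voxels_filters_speckle(self, small_mr_undistorted):
        mask = marker_mask(small_mr_undistorted)
        mask = mask.copy()
        mask[0, 0, 0] = True  # single-voxel speckle
        cents = extract_markers(mask, small_mr_undistorted, min_voxels=3)
        assert len(cents) == 27


class TestComputeDistortion:
    def _field_from_model(self, model, n=24, sp=8.0):
        origin = -(n - 1) / 2 * sp
        ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        pts = np.stack([ii, jj, kk], -1).reshape(-1, 3) * sp + origin
        return DeformationField(
            data=model.displacement(pts).reshape(n, n, n, 3),
            spacing=(sp,) * 3, origin=(origin,) * 3,
        )

    def test_zero_field_gives_zero_magnitudes(self):
        f = self._field_from_model(DistortionModel())
        ms = compute_distortion(f, [[0, 0, 0], [40, 0, 0], [0, -60, 20]], isocenter=(0, 0, 0))
        assert np.allclose(ms.table.magnitude_mm, 0.0)

    def test_linear_radial_magnitudes_analytic(self):
        """1% radial model: 1.0 mm at r=100, 2.0 mm at r=200 (on-node points)."""
        model = DistortionModel(radial_coeffs=(0.01, 0, 0))
        f = self._field_from_model(model, n=56, sp=8.0)
        ms = compute_distortion(f, [[100.0, 0, 0], [0, 200.0, 0]], isocenter=(0, 0, 0))
        assert np.allclose(ms.table.magnitude_mm, [1.0, 2.0], atol=1e-9)
        assert np.allclose(ms.table.r_mm, [100.0, 200.0])

    def test_full_pipeline_magnitudes_match_ground_truth(
        self, recovered_field, small_mr, small_spec, radial_model
    ):
        """Register -> detect -> sample: magnitudes within half a voxel of
        the simulator's ground truth."""
        mask = marker_mask(small_mr)
        cents = extract_markers(mask, small_mr)
        gt = true_marker_displacements(small_spec, radial_model)
        truth_pos = gt[["x_mm", "y_mm", "z_mm"]].to_numpy()
        # detected MR centroids are displaced; sample at the CT (truth) side
        ci, ti = match_to_ground_truth(cents, truth_pos, gate_mm=min(small_spec.grid_spacing) / 2)
        assert len(ci) == 27
        ms = compute_distortion(recovered_field, truth_pos[ti], isocenter=(0, 0, 0))
        err = np.abs(ms.table.magnitude_mm.to_numpy() - gt.magnitude_mm.to_numpy()[ti])
        assert np.sqrt(np.mean(err**2)) < 0.5 * SMALL_SPACING

    def test_empty_centroids_is_error(self):
        f = self._field_from_model(DistortionModel())
        with pytest.raises(ValueError, match="no marker"):
            compute_distortion(f, np.empty((0, 3)))

    def test_table_schema(self):
        f = self._field_from_model(DistortionModel())
        ms = compute_distortion(f, [[0, 0, 0]])
        assert list(ms.table.columns) == MARKER_COLUMNS


class TestSummarize:
    def test_single_bin_basic_stats(self):
        ms = _markerset_from_magnitudes([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        rep = summarize(ms)
        b0 = rep.bins[0]
        assert (b0["n"], b0["median_mm"], b0["max_mm"]) == (3, 2.0, 3.0)
        assert rep.bins[1]["n"] == rep.bins[2]["n"] == 0

    def test_q95_matches_order_statistic_oracle(self):
        """20 magnitudes 0.1k: q95 = 1.905 mm under linear interpolation
        between order statistics (x_(19) + 0.05 (x_(20) - x_(19)))."""
        mags = 0.1 * np.arange(1, 21)
        ms = _markerset_from_magnitudes(mags, np.full(20, 50.0))
        rep = summarize(ms)
        # independent oracle: h = 0.95 (n - 1), linear between neighbours
        h = 0.95 * 19
        lo, frac = int(np.floor(h)), h - int(np.floor(h))
        srt = np.sort(mags)
        oracle = srt[lo] + frac * (srt[lo + 1] - srt[lo])
        assert np.isclose(oracle, 1.905)
        assert np.isclose(rep.bins[0]["q95_mm"], oracle)

    def test_bin_boundary_is_half_open(self):
        ms = _markerset_from_magnitudes([1.0], [100.0])
        rep = summarize(ms)
        assert rep.bins[0]["n"] == 0 and rep.bins[1]["n"] == 1

    def test_binned_medians_increase_with_radial_model(self, small_spec):
        """A radially increasing model yields strictly increasing bin medians."""
        gt = true_marker_displacements(
            small_spec, DistortionModel(radial_coeffs=(0.03, 5e-7, 0.0))
        )
        ms = MarkerSet(table=gt, isocenter=np.zeros(3))
        rep = summarize(ms, bin_edges=(40.0, 80.0), cumulative_radii=(80.0,))
        meds = [b["median_mm"] for b in rep.bins]
        assert meds[0] < meds[1] < meds[2]

    def test_cumulative_within_radius(self):
        ms = _markerset_from_magnitudes([1.0, 2.0, 5.0], [50.0, 120.0, 250.0])
        rep = summarize(ms, cumulative_radii=(150.0,))
        c = rep.cumulative[150.0]
        assert c["n"] == 2 and c["max_mm"] == 2.0

    def test_empty_markerset_is_error(self):
        ms = _markerset_from_magnitudes([1.0], [10.0])
        ms.table = ms.table.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            summarize(ms)

    def test_json_round_trip(self, tmp_path):
        ms = _markerset_from_magnitudes([0.5, 1.5, 2.5], [50.0, 150.0, 250.0])
        rep = summarize(ms)
        path = tmp_path / "rep.json"
        rep.to_json(path)
        back = type(rep).from_json(path)
        assert back.to_dict() == rep.to_dict()

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.0, 20.0, allow_nan=False),
                st.floats(0.0, 300.0, allow_nan=False),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_statistics_invariants(self, data):
        """median <= q95 <= max per bin; bin populations sum to the total;
        every statistic equals the direct numpy computation per bin."""
        mags, radii = zip(*data)
        ms = _markerset_from_magnitudes(mags, radii)
        rep = summarize(ms)
        assert sum(b["n"] for b in rep.bins) == len(data)
        mags = np.asarray(mags)
        radii = np.asarray(radii)
        for b in rep.bins:
            sel = (radii >= b["lo_mm"]) & (radii < b["hi_mm"])
            if not sel.any():
                assert b["n"] == 0
                continue
            assert b["median_mm"] <= b["q95_mm"] + 1e-12
            assert b["q95_mm"] <= b["max_mm"] + 1e-12
            assert np.isclose(b["median_mm"], np.median(mags[sel]))
            assert np.isclose(b["q95_mm"], np.quantile(mags[sel], 0.95))
            assert np.isclose(b["max_mm"], mags[sel].max())


class TestConstancy:
    def _report(self, mags):
        return summarize(_markerset_from_magnitudes(mags, np.full(len(mags), 50.0)))

    def test_identical_reports_pass_with_zero_deltas(self):
        rep = self._report([0.5, 0.7, 0.9])
        verdict = compare_to_baseline(rep, rep, tolerances=0.0)
        assert verdict.passed
        assert all(d["delta"] == 0.0 for d in verdict.details)

    def test_shifted_median_fails_on_that_statistic(self):
        base = self._report([0.5, 0.6, 0.7])
        cur = self._report([0.8, 0.9, 1.0])
        verdict = compare_to_baseline(cur, base, tolerances={"median_mm": 0.2})
        assert not verdict.passed
        failing = [d for d in verdict.details if not d["passed"]]
        assert failing and all(d["statistic"] == "median_mm" for d in failing)

    def test_infinite_tolerance_always_passes(self):
        a = self._report([0.1, 0.2])
        b = self._report([5.0, 9.0])
        assert compare_to_baseline(a, b, tolerances=np.inf).passed

    def test_mismatched_bins_rejected(self):
        a = self._report([0.1])
        ms = _markerset_from_magnitudes([0.1], [10.0])
        b = summarize(ms, bin_edges=(50.0, 150.0))
        with pytest.raises(ValueError, match="bins"):
            compare_to_baseline(a, b)
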