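"""Synthetic islet generator: geometry, recordings, rendering, cohorts."""

import numpy as np
import pytest

import isletwave as iw
from isletwave.errors import FormatError, OutOfBoundsError, PackingInfeasibleError
from isletwave.synth import kernel_half_max_time


class TestGeometry:
    def test_single_cell_inside_radius(self):
        g = iw.make_islet_geometry(1, islet_radius=50.0, min_spacing=10.0, seed=1)
        assert g.n_cells == 1
        assert np.linalg.norm(g.positions[0]) <= 50.0

    def test_pairwise_spacing_brute_force(self):
        g = iw.make_islet_geometry(20, islet_radius=60.0, min_spacing=12.0, seed=7)
        # exhaustive O(n^2) check, independent of any library distance helper
        for i in range(20):
            for j in range(i + 1, 20):
                d = np.sqrt(np.sum((g.positions[i] - g.positions[j]) ** 2))
                assert d >= 12.0
        assert np.all(np.linalg.norm(g.positions, axis=1) <= 60.0)
        assert len(set(g.cell_ids)) == 20

    def test_packing_infeasible(self):
        with pytest.raises(PackingInfeasibleError):
            iw.make_islet_geometry(1000, islet_radius=30.0, min_spacing=15.0, seed=0)

    def test_seed_determinism(self):
        a = iw.make_islet_geometry(15, seed=3)
        b = iw.make_islet_geometry(15, seed=3)
        assert np.array_equal(a.positions, b.positions)
        c = iw.make_islet_geometry(15, seed=4)
        assert not np.array_equal(a.positions, c.positions)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            iw.make_islet_geometry(0)
        with pytest.raises(ValueError):
            iw.make_islet_geometry(5, islet_radius=-1)

    def test_json_round_trip(self, geometry):
        back = iw.IsletGeometry.from_json(geometry.to_json())
        assert back.cell_ids == geometry.cell_ids
        assert np.allclose(back.positions, geometry.positions)


class TestSimulationParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(level=5),
            dict(level=3),  # missing velocity
            dict(level=2, wave_velocity=-5.0),
            dict(level=4, wave_velocity=30.0, n_events=1),
            dict(level=0, fps=0.0),
            dict(level=0, n_frames=1),
            dict(level=0, noise_sd=-0.1),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            iw.SimulationParams(**kwargs)


class TestSimulateRecording:
    def test_level0_noiseless_is_constant_baseline(self, geometry):
        p = iw.SimulationParams(level=0, noise_sd=0.0, baseline=1.5, seed=0)
        rec, truth = iw.simulate_recording(geometry, p)
        assert np.all(rec.traces == 1.5)
        assert truth.level == 0
        assert truth.onset_times == {}

    def test_determinism_bit_identical(self, geometry):
        p = iw.SimulationParams(level=3, wave_velocity=40.0, seed=5)
        r1, _ = iw.simulate_recording(geometry, p)
        r2, _ = iw.simulate_recording(geometry, p)
        assert np.array_equal(r1.traces, r2.traces)

    def test_level3_onsets_follow_distance_over_velocity(self, geometry, noiseless_wave):
        rec, truth = noiseless_wave
        v = truth.true_velocity
        start = truth.event_starts[0]
        for cid, pos in zip(geometry.cell_ids, geometry.positions):
            d = np.linalg.norm(pos - truth.origin)
            assert truth.onset_times[cid][0] == pytest.approx(start + d / v)

    def test_level3_half_max_crossing_matches_analytic(self, geometry, noiseless_wave):
        """Detected half-max time = truth onset + the kernel's analytic half-max lag."""
        rec, truth = noiseless_wave
        # independent closed-form half-max lag of A*(1-exp(-t/r))*exp(-t/d)
        from scipy.optimize import brentq, minimize_scalar

        r, d = 0.3, 2.0
        k = lambda t: (1.0 - np.exp(-t / r)) * np.exp(-t / d)
        t_peak = minimize_scalar(lambda t: -k(t), bounds=(0, 10), method="bounded").x
        t_half = brentq(lambda t: k(t) - 0.5 * k(t_peak), 0, t_peak)
        frame = 1.0 / rec.fps
        onsets = iw.detect_onsets(rec)  # unsmoothed, noiseless
        for cid, (t_true, *_) in truth.onset_times.items():
            t_det = onsets.onsets[cid][0]
            assert abs(t_det - (t_true + t_half)) <= frame

    def test_noiseless_level3_equal_peaks_and_ordered_onsets(self, geometry, noiseless_wave):
        rec, truth = noiseless_wave
        peaks = rec.traces.max(axis=1)
        # wave passes every cell once; peaks equal up to frame-sampling of the kernel
        assert np.allclose(peaks, peaks[0], rtol=0.01)
        dists = np.linalg.norm(geometry.positions - truth.origin, axis=1)
        on = np.array([truth.onset_times[c][0] for c in geometry.cell_ids])
        order = np.argsort(dists)
        assert np.all(np.diff(on[order]) >= 0)

    def test_level2_recruits_only_within_radius(self, geometry):
        p = iw.SimulationParams(level=2, wave_velocity=40.0, noise_sd=0.0, seed=2)
        rec, truth = iw.simulate_recording(geometry, p)
        radius = 0.4 * geometry.diameter
        rec_ids = truth.recruited_cells[0]
        assert 0 < len(rec_ids) < geometry.n_cells
        for cid, pos in zip(geometry.cell_ids, geometry.positions):
            d = np.linalg.norm(pos - truth.origin)
            assert (cid in rec_ids) == (d <= radius)

    def test_level1_has_no_spatial_onset_ordering(self, geometry):
        p = iw.SimulationParams(level=1, noise_sd=0.0, seed=9)
        _, truth = iw.simulate_recording(geometry, p)
        assert truth.origin is None
        assert len(truth.recruited_cells[0]) > 0

    def test_level4_repeats_events(self, geometry):
        p = iw.SimulationParams(level=4, wave_velocity=40.0, n_events=3, noise_sd=0.0, seed=2)
        _, truth = iw.simulate_recording(geometry, p)
        assert len(truth.event_starts) == 3
        assert len(truth.recruited_cells) == 3
        for ids in truth.recruited_cells:
            assert ids == frozenset(geometry.cell_ids)


class TestRenderMovie:
    def test_single_cell_constant_trace_peaks_at_cell(self):
        g = iw.IsletGeometry(("a",), np.array([[0.0, 0.0]]), 20.0, 5.0)
        rec = iw.CalciumRecording(np.full((1, 5), 3.0), fps=3.0, cell_ids=("a",))
        stack = iw.render_movie(rec, g, pixel_size=1.0, image_shape=(41, 41))
        assert stack.shape == (5, 41, 41)
        for frame in stack:
            assert np.unravel_index(frame.argmax(), frame.shape) == (20, 20)
            assert frame.max() == pytest.approx(3000, abs=1)  # 1000 counts/unit

    def test_round_trip_extraction_recovers_traces(self, geometry):
        p = iw.SimulationParams(level=3, wave_velocity=40.0, noise_sd=0.0, seed=4)
        rec, _ = iw.simulate_recording(geometry, p)
        stack = iw.render_movie(rec, geometry, pixel_size=2.0, image_shape=(96, 96))
        rois = iw.RoiSet.from_geometry(geometry, diameter=12.0)
        got = iw.extract_roi_traces(stack, rois, fps=rec.fps, pixel_size=2.0)
        for i in range(geometry.n_cells):
            r = np.corrcoef(rec.traces[i], got.traces[i])[0, 1]
            assert r > 0.99

    def test_cell_outside_fov_names_cell(self, geometry):
        with pytest.raises(OutOfBoundsError, match="c0"):
            iw.render_movie(
                iw.CalciumRecording(
                    np.ones((geometry.n_cells, 3)), 3.0, geometry.cell_ids
                ),
                geometry,
                pixel_size=2.0,
                image_shape=(16, 16),
            )

    def test_empty_recording_rejected(self, geometry):
        rec = iw.CalciumRecording(np.ones((geometry.n_cells, 0)), 3.0, geometry.cell_ids)
        with pytest.raises(FormatError):
            iw.render_movie(rec, geometry)


class TestCohort:
    def test_all_level0_design(self):
        design = iw.CohortDesign(
            groups=("sham",),
            weeks=(10,),
            islets_per_group=4,
            level_distributions={"sham": {10: {0: 1.0}}},
            n_frames=60,
        )
        sims = iw.simulate_cohort(design, seed=0)
        assert len(sims) == 4
        assert all(truth.level == 0 for _, truth, _ in sims)

    def test_master_seed_reproducibility(self):
        a = iw.simulate_cohort(_small_design(), seed=5)
        b = iw.simulate_cohort(_small_design(), seed=5)
        assert [r.level_truth for *_, r in a] == [r.level_truth for *_, r in b]
        assert np.array_equal(a[0][0].traces, b[0][0].traces)

    def test_malformed_design_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            iw.CohortDesign(
                groups=("sham",),
                weeks=(0,),
                islets_per_group=2,
                level_distributions={"sham": {0: {0: 0.5, 1: 0.2}}},
            ).validate()
        with pytest.raises(ValueError, match="week"):
            iw.CohortDesign(
                groups=("sham",),
                weeks=(0, 4),
                islets_per_group=2,
                level_distributions={"sham": {0: {0: 1.0}}},
            ).validate()

    def test_default_design_matches_study_shape(self):
        d = iw.DEFAULT_COHORT_DESIGN
        d.validate()
        assert set(d.groups) == {"sham", "VSG"}
        # sham collapses toward inactivity by week 10; VSG reaches waves by week 8
        assert d.level_distributions["sham"][10].get(0, 0) >= 0.5
        vsg8 = d.level_distributions["VSG"][8]
        assert vsg8.get(3, 0) + vsg8.get(4, 0) == pytest.approx(1.0)


def _small_design():
    return iw.CohortDesign(
        groups=("sham", "VSG"),
        weeks=(0, 8),
        islets_per_group=2,
        level_distributions={
            "sham": {0: {2: 1.0}, 8: {0: 0.5, 1: 0.5}},
            "VSG": {0: {2: 1.0}, 8: {3: 0.5, 4: 0.5}},
        },
        n_frames=120,
    )


def test_kernel_half_max_time_matches_root_finding():
    from scipy.optimize import brentq, minimize_scalar

    for r, d in [(0.3, 2.0), (0.1, 1.0), (0.5, 5.0)]:
        k = lambda t: (1.0 - np.exp(-t / r)) * np.exp(-t / d)
        t_peak = minimize_scalar(lambda t: -k(t), bounds=(0, 20 * r), method="bounded").x
        expect = brentq(lambda t: k(t) - 0.5 * k(t_peak), 0, t_peak)
        assert kernel_half_max_time(r, d) == pytest.approx(expect, abs=1e-3)
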