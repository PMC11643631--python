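"""Curve projection, kymograph and phase-profile tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segclock.flow import EmbryoFlowConfig, generate_embryo_flow
from segclock.kymo import (Kymograph, ReferenceCurve, align_segments,
                           build_event_kymograph, project_table,
                           project_to_curve, somite_phase_profile)
from segclock.presets import NormalSpec, get_preset

from conftest import deterministic_preset


ZIGZAG = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 5.0], [35.0, 5.0]])


class TestProjection:
    def test_point_on_curve_projects_to_itself(self):
        arc, off = project_to_curve((5.0, 0.0), ZIGZAG)
        assert off == pytest.approx(0.0)
        assert arc == pytest.approx(5.0)

    def test_equidistant_tie_breaks_to_smaller_arc(self):
        # a straight two-segment line; the point lies exactly above the
        # shared vertex so both segments give the same distance
        curve = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        arc, off = project_to_curve((10.0, 3.0), curve)
        assert off == pytest.approx(3.0)
        assert arc == pytest.approx(10.0)

    def test_matches_dense_resampling_oracle(self, rng):
        # brute force: nearest point over the curve resampled at 0.01 um
        seg = np.diff(ZIGZAG, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        s_dense = np.arange(0.0, cum[-1], 0.01)
        pts = np.array([_point_at(ZIGZAG, cum, lens, s) for s in s_dense])
        for _ in range(50):
            p = rng.uniform([-5, -5], [40, 10])
            arc, off = project_to_curve(p, ZIGZAG)
            d = np.linalg.norm(pts - p, axis=1)
            i = int(np.argmin(d))
            assert off == pytest.approx(d[i], abs=0.02)
            assert arc == pytest.approx(s_dense[i], abs=0.02)

    @settings(deadline=None, max_examples=50)
    @given(x=st.floats(-10, 45), y=st.floats(-10, 15))
    def test_projection_is_idempotent(self, x, y):
        arc, _ = project_to_curve((x, y), ZIGZAG)
        seg = np.diff(ZIGZAG, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        foot = _point_at(ZIGZAG, cum, lens, arc)
        arc2, off2 = project_to_curve(foot, ZIGZAG)
        assert off2 == pytest.approx(0.0, abs=1e-9)
        assert arc2 == pytest.approx(arc, abs=1e-9)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            project_to_curve((0, 0), np.array([[1.0, 1.0], [1.0, 1.0]]))


def _point_at(vertices, cum, lens, s):
    i = min(int(np.searchsorted(cum, s, side="right")) - 1, len(lens) - 1)
    i = max(i, 0)
    t = (s - cum[i]) / lens[i]
    return vertices[i] + t * (vertices[i + 1] - vertices[i])


class TestAlignSegments:
    def _static_projection(self):
        rows = [{"cell_id": f"c{i}", "frame": f, "x": 10.0 * i, "y": 0.0}
                for f in range(3) for i in range(4)]
        curve = ReferenceCurve.static_line(100.0, frames=range(3))
        return project_table(pd.DataFrame(rows), curve)

    def test_static_cells_give_identical_rows(self):
        proj = align_segments(self._static_projection())
        by_frame = proj.groupby("frame")["aligned_arc"].apply(
            lambda s: tuple(np.round(s.to_numpy(), 9)))
        assert len(set(by_frame)) == 1

    def test_uniform_shift_with_matching_anchor_is_invariant(self):
        proj = self._static_projection()
        base = align_segments(proj, anchors={f: 0.0 for f in range(3)})
        shifted = proj.copy()
        shifted["arc_length"] = shifted["arc_length"] + 7.0
        out = align_segments(shifted, anchors={f: 7.0 for f in range(3)})
        np.testing.assert_allclose(out["aligned_arc"], base["aligned_arc"])

    def test_event_front_is_monotone_along_axis(self):
        # generator oracle: as the tail extends, successive arrests occur
        # progressively closer to the final tail tip -- the arrest front
        # moves monotonically along the axis over the kymograph rows
        preset = deterministic_preset(n_peaks=3, first_peak_mean=30.0,
                                      p0=30.0, duration=450.0,
                                      frame_interval=1.5,
                                      imaging_start_offset=0.0)
        curve = ReferenceCurve.static_line(600.0, frames=[0])
        cfg = EmbryoFlowConfig(n_cells=24, advection_speed=1.0,
                               tb_exit_times=NormalSpec(mean=100.0, sd=50.0),
                               lateral_jitter=0.0)
        _, cells = generate_embryo_flow(cfg, preset, curve, seed=4)
        cells = cells.sort_values("arrest_time_true")
        assert (np.diff(cells["arc_at_arrest"].to_numpy()) <= 1e-9).all()


class TestEventKymograph:
    def test_single_event_fills_one_bin(self):
        events = pd.DataFrame({"cell_id": ["a"], "event_time": [100.0],
                               "aligned_arc": [25.0]})
        kym = build_event_kymograph(events, bin_width=10.0)
        assert kym.total_cells == 1
        assert np.nansum(kym.values >= 0) == 1

    def test_bin_mean_of_two_events(self):
        events = pd.DataFrame({"cell_id": ["a", "b"],
                               "event_time": [100.0, 120.0],
                               "aligned_arc": [25.0, 26.0]})
        kym = build_event_kymograph(events, bin_width=10.0, row_interval=1000.0)
        filled = kym.values[~np.isnan(kym.values)]
        assert filled.tolist() == [110.0]

    def test_occupancy_conserved_under_binning(self):
        rng = np.random.default_rng(0)
        events = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(60)],
            "event_time": rng.uniform(0, 300, 60),
            "aligned_arc": rng.uniform(0, 200, 60),
        })
        for bw in (5.0, 10.0, 40.0):
            kym = build_event_kymograph(events, bin_width=bw)
            assert kym.total_cells == 60


class TestPhaseProfile:
    def _cells(self, times):
        n = len(times)
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                             "somite": ["S1"] * n,
                             "arc_length": np.linspace(100, 50, n),
                             "event_time": times})

    def test_simultaneous_arrest_gives_zero_correlation(self):
        profile, rho, _ = somite_phase_profile(self._cells([50.0] * 8))
        assert rho == pytest.approx(0.0)

    def test_single_cell_profile(self):
        profile, rho, n_exc = somite_phase_profile(self._cells([40.0]))
        assert len(profile) == 1 and n_exc == 0

    def test_unlabelled_cells_counted(self):
        cells = self._cells([1.0, 2.0, 3.0])
        cells.loc[1, "somite"] = np.nan
        profile, _, n_exc = somite_phase_profile(cells)
        assert n_exc == 1 and len(profile) == 2

    def test_uniform_advection_gives_monotone_profile(self):
        # anterior (rostral) cells exited the TB earlier and arrest earlier:
        # rank correlation of caudal position vs arrest time is 1 at 0 noise
        preset = deterministic_preset(n_peaks=3, first_peak_mean=30.0,
                                      p0=30.0, duration=450.0,
                                      frame_interval=1.5,
                                      imaging_start_offset=0.0)
        curve = ReferenceCurve.static_line(600.0, frames=[0])
        cfg = EmbryoFlowConfig(n_cells=30, advection_speed=1.0,
                               tb_exit_times=NormalSpec(mean=100.0, sd=40.0),
                               somite_length=1000.0,  # all in one somite bin
                               lateral_jitter=0.0)
        _, cells = generate_embryo_flow(cfg, preset, curve, seed=2)
        cells = cells.rename(columns={"arc_at_arrest": "arc_length",
                                      "arrest_time_true": "event_time"})
        profile, rho, _ = somite_phase_profile(cells)
        assert rho == pytest.approx(1.0)


class TestEmbryoFlow:
    def test_zero_advection_keeps_position(self):
        preset = deterministic_preset(n_peaks=2, duration=200.0,
                                      frame_interval=1.5,
                                      imaging_start_offset=0.0)
        curve = ReferenceCurve.static_line(300.0, frames=[0])
        cfg = EmbryoFlowConfig(n_cells=5, advection_speed=0.0,
                               duration=200.0, lateral_jitter=0.0)
        tracks, _ = generate_embryo_flow(cfg, preset, curve, seed=1)
        for _, grp in tracks.groupby("cell_id"):
            assert grp["x"].nunique() == 1

    def test_identical_exit_time_and_seed_identical_peak_counts(self):
        preset = deterministic_preset(n_peaks=3, duration=300.0,
                                      frame_interval=1.5,
                                      imaging_start_offset=0.0)
        curve = ReferenceCurve.static_line(300.0, frames=[0])
        cfg = EmbryoFlowConfig(n_cells=10, tb_exit_times=NormalSpec(mean=50.0, sd=0.0),
                               duration=300.0)
        _, cells_a = generate_embryo_flow(cfg, preset, curve, seed=3)
        _, cells_b = generate_embryo_flow(cfg, preset, curve, seed=3)
        assert cells_a["n_peaks_true"].nunique() == 1
        pd.testing.assert_frame_equal(cells_a, cells_b)

    def test_later_exit_means_later_arrest_pairwise(self):
        # exhaustive pairwise oracle on a 20-cell noise-free flow
        preset = deterministic_preset(n_peaks=4, duration=600.0,
                                      frame_interval=1.5, p0=30.0,
                                      first_peak_mean=30.0,
                                      imaging_start_offset=0.0)
        curve = ReferenceCurve.static_line(600.0, frames=[0])
        cfg = EmbryoFlowConfig(n_cells=20,
                               tb_exit_times=NormalSpec(mean=80.0, sd=40.0),
                               duration=600.0, lateral_jitter=0.0)
        _, cells = generate_embryo_flow(cfg, preset, curve, seed=9)
        e = cells["tb_exit_time"].to_numpy()
        a = cells["arrest_time_true"].to_numpy()
        for i in range(len(cells)):
            for j in range(len(cells)):
                if e[i] < e[j]:
                    assert a[i] < a[j]

    def test_neighbouring_cells_same_somite_similar_peak_count(self):
        # peak counts vary smoothly along the axis: within a somite,
        # neighbouring arc-length positions differ by at most one peak
        from segclock.presets import get_preset
        preset = get_preset("embryo_psm4")
        curve = ReferenceCurve.static_line(600.0, frames=[0])
        cfg = EmbryoFlowConfig(n_cells=60,
                               tb_exit_times=NormalSpec(mean=90.0, sd=30.0))
        _, cells = generate_embryo_flow(cfg, preset, curve, seed=5)
        for _, grp in cells.groupby("somite"):
            ks = grp.sort_values("arc_at_arrest")["n_peaks_true"].to_numpy()
            assert np.all(np.abs(np.diff(ks)) <= 1)
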