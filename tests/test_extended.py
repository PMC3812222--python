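import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from boltzwalker import (
    BWParameters,
    EmpiricalCDF,
    EmptySectorError,
    SectorPartition,
    SectorStats,
    build_ecdf,
    estimate_sector_stats,
    predict_exit_headings,
    sample_ecdf,
    sample_elliptical,
    sector_of,
    simulate_bw_events,
    simulate_extended_bw,
    wrap_angle,
)
from boltzwalker.extended import mirror_stats
from boltzwalker.segmentation import Segment, SegmentedTrajectory
from boltzwalker.synthetic import segments_from_turning_points


class _FixedRng:
    """Stub generator returning a preset uniform value (interpolation tests)."""

    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        return np.full(1 if size is None else size, self.value)


def _toy_segmented(headings, lengths, dt=1.0):
    segs = []
    x = y = 0.0
    for h, l in zip(headings, lengths):
        nx, ny = x + l * math.cos(h), y + l * math.sin(h)
        segs.append(
            Segment(start=(x, y), end=(nx, ny), length=l, heading=h,
                    duration=dt, point_span=(0, 1))
        )
        x, y = nx, ny
    hs = np.asarray(headings, dtype=float)
    dev = wrap_angle(np.diff(hs)) if len(hs) > 1 else np.empty(0)
    return SegmentedTrajectory(segments=segs, deviations=np.atleast_1d(dev))


class TestSectorOf:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 0), (math.pi, 4), (math.pi / 8, 1)],  # boundary -> upper sector
    )
    def test_assignment(self, theta, expected):
        assert sector_of(theta, SectorPartition(S=8)) == expected

    def test_vectorized_and_wrapping(self):
        part = SectorPartition(S=8)
        th = np.array([0.0, 2 * math.pi, -2 * math.pi, math.pi / 2])
        assert list(sector_of(th, part)) == [0, 0, 0, 2]


class TestEmpiricalCDF:
    def test_endpoint_contract(self):
        F = build_ecdf([1.0, 2.0, 3.0], B=10)
        assert F.values[0] == 0.0 and F.values[-1] == 1.0
        assert F.abscissae[0] == 1.0 and F.abscissae[-1] == 3.0
        assert (np.diff(F.values) >= 0).all()

    def test_dkw_uniform(self, rng):
        x = rng.random(10_000)
        F = build_ecdf(x)
        # grid ECDF of a uniform sample tracks the identity
        assert np.abs(F.values - (F.abscissae - F.abscissae[0])
                      / (F.abscissae[-1] - F.abscissae[0])).max() < 0.03

    def test_degenerate_sample_flagged(self, rng):
        F = build_ecdf([2.0, 2.0, 2.0])
        assert F.degenerate
        assert sample_ecdf(F, rng) == 2.0

    def test_r_zero_returns_lower_endpoint(self):
        F = build_ecdf([1.0, 2.0, 4.0], B=4)
        assert sample_ecdf(F, _FixedRng(0.0)) == F.abscissae[0]

    def test_two_point_interpolation_formula(self):
        F = EmpiricalCDF(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert sample_ecdf(F, _FixedRng(0.25)) == pytest.approx(0.25)

    def test_round_trip_reproduces_distribution(self, rng):
        x = rng.exponential(0.01, 10_000)
        F = build_ecdf(x)
        y = sample_ecdf(F, rng, 10_000)
        assert ks_2samp(x, y).statistic < 0.05


class TestEstimation:
    def test_isotropic_walker_gives_flat_sector_stats(self, rng):
        params = BWParameters(speed=0.015, mean_free_path=0.01, g=0.6)
        walk = simulate_bw_events(params, 10_000, rng)
        stats = estimate_sector_stats(segments_from_turning_points(walk))
        lam_s = stats.mean_free_path
        assert lam_s.max() / lam_s.min() < 1.10
        assert np.allclose(lam_s, 0.01, rtol=0.05)
        assert np.abs(stats.persistence - 0.6).max() < 0.05
        assert stats.heading_frequency.sum() == pytest.approx(1.0)

    def test_one_segment_per_sector(self):
        part = SectorPartition(S=8)
        st = _toy_segmented(part.centers(), [0.02] * 8)
        stats = estimate_sector_stats(st, part)
        assert np.allclose(stats.mean_free_path, 0.02)

    def test_all_uphill_leaves_other_sectors_empty(self):
        st = _toy_segmented([0.0] * 5, [0.01] * 5)
        stats = estimate_sector_stats(st)
        assert stats.heading_frequency[0] == 1.0
        assert set(stats.empty_sectors) == set(range(1, 8))

    def test_deviation_conditions_on_pre_turn_heading(self):
        # two segments: heading 0 then pi/2; the single deviation must land
        # in the sector of the *first* heading
        st = _toy_segmented([0.0, math.pi / 2], [0.01, 0.01])
        stats = estimate_sector_stats(st)
        assert stats.persistence[0] == pytest.approx(math.cos(math.pi / 2))
        assert np.isnan(stats.persistence[2])

    def test_mirror_symmetry_under_reflection(self, rng):
        params = BWParameters(speed=0.015, mean_free_path=0.01, g=0.5)
        walk = simulate_bw_events(params, 3000, rng)
        st = segments_from_turning_points(walk)
        reflected = walk.xy * np.array([-1.0, 1.0])  # x -> -x flips headings
        walk2 = type(walk)(xy=reflected, t=walk.t, meta=dict(walk.meta))
        st2 = segments_from_turning_points(walk2)
        a = estimate_sector_stats(st)
        b = estimate_sector_stats(st2)
        m = mirror_stats(a)
        assert np.allclose(m.mean_free_path, b.mean_free_path, equal_nan=True)
        assert np.allclose(m.persistence, b.persistence, atol=1e-12, equal_nan=True)
        assert np.array_equal(m.counts, b.counts)


class TestSerialization:
    def test_dict_round_trip(self, rng):
        params = BWParameters(speed=0.015, mean_free_path=0.01, g=0.6)
        walk = simulate_bw_events(params, 500, rng)
        stats = estimate_sector_stats(segments_from_turning_points(walk))
        back = SectorStats.from_dict(stats.to_dict())
        assert np.allclose(back.mean_free_path, stats.mean_free_path, equal_nan=True)
        for F1, F2 in zip(back.length_ecdf, stats.length_ecdf):
            assert (F1 is None) == (F2 is None)
            if F1 is not None:
                assert np.allclose(F1.abscissae, F2.abscissae)

    def test_file_round_trip(self, rng, tmp_path):
        params = BWParameters(speed=0.015, mean_free_path=0.01, g=0.6)
        walk = simulate_bw_events(params, 500, rng)
        stats = estimate_sector_stats(segments_from_turning_points(walk))
        stats.save(tmp_path / "s")
        back = SectorStats.load(tmp_path / "s")
        assert np.allclose(back.persistence, stats.persistence, equal_nan=True)
        for F1, F2 in zip(back.deviation_ecdf, stats.deviation_ecdf):
            if F1 is not None:
                assert np.allclose(F1.values, F2.values)


def _toy_stats(lam_by_sector, g=0.6, n=3000, seed=0):
    """SectorStats built from parametric samples, labelled synthetic."""
    rng = np.random.default_rng(seed)
    part = SectorPartition(S=8)
    S = 8
    len_e, dev_e = [], []
    for s in range(S):
        len_e.append(build_ecdf(rng.exponential(lam_by_sector[s], n)))
        dev_e.append(build_ecdf(sample_elliptical(g, rng, n)))
    return SectorStats(
        partition=part,
        mean_speed=np.full(S, 0.015),
        mean_free_path=np.asarray(lam_by_sector, dtype=float),
        persistence=np.full(S, g),
        length_ecdf=len_e,
        deviation_ecdf=dev_e,
        heading_frequency=np.full(S, 1 / 8),
        counts=np.full(S, n),
        meta={"synthetic": True},
    )


class TestExtendedSimulation:
    def test_doubled_vertical_free_paths_elongate_dispersal(self, rng):
        lam = [0.01] * 8
        for s in (0, 4):  # uphill and downhill sectors (the steepest line)
            lam[s] = 0.02
        stats = _toy_stats(lam)
        pts = []
        for _ in range(400):
            _, rec = simulate_extended_bw(stats, rng, radius=0.1)
            pts.append(rec.exit_angle)
        pts = np.asarray(pts)
        # exit heading a sits at position (-R sin a, R cos a)
        y = np.abs(0.1 * np.cos(pts))
        x = np.abs(0.1 * np.sin(pts))
        assert y.mean() > x.mean()
        assert ks_2samp(y, x).pvalue < 0.01

    def test_zero_deviation_mass_goes_straight(self, rng):
        stats = _toy_stats([0.01] * 8)
        for s in range(8):
            stats.deviation_ecdf[s] = build_ecdf([0.0, 0.0, 0.0])
        traj, rec = simulate_extended_bw(stats, rng, radius=0.1)
        d0 = traj.xy[1] - traj.xy[0]
        start_heading = math.atan2(-d0[0], d0[1])
        assert rec.exited
        assert wrap_angle(rec.exit_angle - start_heading) == pytest.approx(0, abs=1e-9)

    def test_empty_sector_aborts(self, rng):
        stats = _toy_stats([0.01] * 8)
        stats.length_ecdf[3] = None
        with pytest.raises(EmptySectorError):
            for _ in range(200):
                simulate_extended_bw(stats, rng, radius=0.1)

    def test_fixed_seed_is_bit_identical(self):
        stats = _toy_stats([0.01] * 8)
        a = predict_exit_headings(stats, np.random.default_rng(9), N=50, radius=0.1)
        b = predict_exit_headings(stats, np.random.default_rng(9), N=50, radius=0.1)
        assert np.array_equal(a, b)

    def test_round_trip_reproduces_msd_per_event(self, rng):
        # standard walker -> exact segments -> sector stats -> extended
        # simulation reproduces the walker's MSD-per-event curve within 5%
        # (runs are unbounded so censoring cannot depress the tail)
        from boltzwalker import crw_msd_oracle, msd_vs_events, simulate_bw_events

        params = BWParameters(speed=0.015, mean_free_path=0.01, g=0.6)
        walk = simulate_bw_events(params, 20_000, rng)
        stats = estimate_sector_stats(segments_from_turning_points(walk))
        sim = []
        for _ in range(500):
            traj, _ = simulate_extended_bw(stats, rng, radius=1e6, max_events=14)
            sim.append(segments_from_turning_points(traj))
        curve = msd_vs_events(sim, 12)
        oracle = crw_msd_oracle(curve.n, 0.01, 0.6)
        assert np.all(np.abs(curve.msd / oracle - 1.0) < 0.05)

    def test_small_radius_exits_along_initial_heading(self, rng):
        # R -> 0: the first free path crosses immediately, so exit headings
        # are the (uniform) initial headings
        stats = _toy_stats([0.01] * 8)
        exits = predict_exit_headings(stats, rng, N=400, radius=1e-6)
        from boltzwalker import hodges_ajne

        _, p = hodges_ajne(exits)
        assert p > 0.01
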