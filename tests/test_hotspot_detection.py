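import math
import warnings

import numpy as np
import pytest

import ectomap as em
from conftest import make_intervals, make_tagset


def brute_force_scan(tags, input_tags, genome, params):
    """Independent per-window recount with the direct z formula."""
    w, W, step = params.target_window_w, params.background_window_W, params.step
    ratio = None
    if input_tags is not None:
        ratio = tags.total_count / input_tags.total_count
    rows = []
    for name in genome:
        L = genome[name]
        chip = [(c, p) for c, p in zip(tags.chrom, tags.pos) if c == name]
        ctrl = (
            [(c, p) for c, p in zip(input_tags.chrom, input_tags.pos) if c == name]
            if input_tags is not None
            else None
        )
        start = 0
        while start <= max(L - w, 0):
            end = min(start + w, L)
            center = (start + end) // 2
            bs = min(max(center - W // 2, 0), L)
            be = min(max(center - W // 2 + W, 0), L)
            obs = sum(1 for _, p in chip if start <= p < end)
            bg = sum(1 for _, p in chip if bs <= p < be)
            if ctrl is not None:
                n_in = sum(1 for _, p in ctrl if start <= p < end)
                obs = max(0.0, obs - n_in * ratio)
            p_frac = (end - start) / (be - bs)
            e = bg * p_frac
            var = bg * p_frac * (1 - p_frac)
            z = (obs - e) / math.sqrt(var) if var > 0 else 0.0
            rows.append((name, start, end, obs, e, z))
            start += step
    return rows


class TestWindowZscore:
    def test_centering(self):
        assert em.window_zscore(5, 1000, 250, 50_000) == 0.0

    def test_direct_arithmetic(self):
        z = em.window_zscore(20, 1000, 250, 50_000)
        assert z == pytest.approx(15 / math.sqrt(1000 * 0.005 * 0.995), abs=1e-12)
        assert z == pytest.approx(6.725, abs=1e-3)

    def test_zero_background(self):
        assert em.window_zscore(0, 0, 250, 50_000) == 0.0

    def test_invalid_windows(self):
        with pytest.raises(em.InvalidParameterError):
            em.window_zscore(1, 10, 500, 500)


class TestNormalizeAndSubtract:
    def test_scaling(self):
        assert em.normalize_and_subtract_input(30, 20, 10**6, 2 * 10**6) == 20.0

    def test_zero_input_count(self):
        assert em.normalize_and_subtract_input(17, 0, 10**6, 10**6) == 17.0

    def test_floor_at_zero(self):
        assert em.normalize_and_subtract_input(5, 8, 10**6, 10**6) == 0.0

    def test_zero_library_size(self):
        with pytest.raises(em.InvalidParameterError):
            em.normalize_and_subtract_input(5, 5, 0, 10**6)


class TestScanWindows:
    def test_no_tags_all_zero(self, genome10k):
        tags = make_tagset(genome10k, [])
        stats = em.scan_windows(tags, None, genome10k, em.HotspotParams())
        assert len(stats) > 0
        assert np.all(stats.z == 0.0)
        assert np.all(stats.obs == 0.0)

    def test_point_mass_gives_global_max(self, genome10k):
        tags = make_tagset(genome10k, [("chr1", 5000, "+")] * 50)
        stats = em.scan_windows(tags, None, genome10k, em.HotspotParams())
        covering = (stats.start <= 5000) & (stats.end > 5000)
        assert stats.z[covering].max() == stats.z.max()

    @pytest.mark.parametrize("with_input", [False, True])
    def test_matches_bruteforce_recount(self, genome10k, with_input):
        rng = np.random.default_rng(3)
        tags = make_tagset(
            genome10k,
            [("chr1", int(p), "+") for p in rng.integers(0, 10_000, 100)],
        )
        ctrl = (
            make_tagset(
                genome10k,
                [("chr1", int(p), "-") for p in rng.integers(0, 10_000, 80)],
            )
            if with_input
            else None
        )
        params = em.HotspotParams(
            target_window_w=250, background_window_W=2000, step=50
        )
        stats = em.scan_windows(tags, ctrl, genome10k, params)
        oracle = brute_force_scan(tags, ctrl, genome10k, params)
        assert len(stats) == len(oracle)
        for i, (name, s, e, obs, exp, z) in enumerate(oracle):
            assert (stats.chrom[i], stats.start[i], stats.end[i]) == (name, s, e)
            assert stats.obs[i] == pytest.approx(obs, abs=1e-9)
            assert stats.expected[i] == pytest.approx(exp, abs=1e-9)
            assert stats.z[i] == pytest.approx(z, abs=1e-9)


@pytest.fixture(scope="module")
def signal_instance():
    genome = em.GenomeDef({"chr1": 500_000})
    hs = make_intervals(
        [("chr1", s, s + 500) for s in range(20_000, 500_000, 25_000)],
        scores=[40.0] * 20,
    )
    truth = em.SimTruth(genome, hs, make_intervals([]), 100_000, 100_000, seed=11)
    chip = em.simulate_tags(truth, "chip", 1)
    ctrl = em.simulate_tags(truth, "input", 2)
    return genome, chip, ctrl


class TestCalibrate:
    def test_threshold_monotone_in_fdr(self, signal_instance):
        genome, chip, ctrl = signal_instance
        thrs = []
        for fdr in (0.5, 0.001):
            params = em.HotspotParams(fdr=fdr, n_null_sims=2, seed=5)
            thrs.append(em.calibrate_fdr_threshold(chip, ctrl, genome, params))
        assert thrs[0] <= thrs[1]

    def test_deterministic_given_seed(self, signal_instance):
        genome, chip, ctrl = signal_instance
        params = em.HotspotParams(n_null_sims=2, seed=5)
        t1 = em.calibrate_fdr_threshold(chip, ctrl, genome, params)
        t2 = em.calibrate_fdr_threshold(chip, ctrl, genome, params)
        assert t1 == t2 and math.isfinite(t1)

    def test_self_null_returns_inf(self):
        genome = em.GenomeDef({"chr1": 200_000})
        truth = em.SimTruth(
            genome, make_intervals([]), make_intervals([]), 50_000, 50_000, seed=13
        )
        chip = em.simulate_tags(truth, "chip", 1)
        params = em.HotspotParams(n_null_sims=2, seed=5)
        with pytest.warns(UserWarning):
            thr = em.calibrate_fdr_threshold(chip, None, genome, params)
        assert thr == math.inf


class TestMergeWindows:
    def _stats(self, windows):
        chrom = np.array([w[0] for w in windows], object)
        start = np.array([w[1] for w in windows])
        end = np.array([w[2] for w in windows])
        z = np.array([w[3] for w in windows], float)
        obs = np.array([w[4] for w in windows], float)
        return em.WindowStats(chrom, start, end, obs, obs, z)

    def test_nothing_passes(self):
        stats = self._stats([("chr1", 0, 250, 1.0, 5.0)])
        assert len(em.merge_windows(stats, threshold=2.0)) == 0

    def test_adjacent_windows_merge(self):
        stats = self._stats(
            [("chr1", 0, 250, 5.0, 10.0), ("chr1", 250, 500, 6.0, 12.0)]
        )
        hs = em.merge_windows(stats, threshold=2.0, merge_gap=0)
        assert len(hs) == 1
        row = hs.df.iloc[0]
        assert (row.start, row.end, row.max_z, row.n_windows) == (0, 500, 6.0, 2)

    @pytest.mark.parametrize("gap,expected", [(100, 2), (300, 1)])
    def test_merge_gap_rule(self, gap, expected):
        stats = self._stats(
            [("chr1", 0, 250, 5.0, 10.0), ("chr1", 500, 750, 5.0, 10.0)]
        )
        assert len(em.merge_windows(stats, 2.0, merge_gap=gap)) == expected

    def test_min_tags_filter(self):
        stats = self._stats(
            [("chr1", 0, 250, 5.0, 3.0), ("chr1", 500, 750, 5.0, 30.0)]
        )
        hs = em.merge_windows(stats, 2.0, min_tags=10)
        assert len(hs) == 1 and hs.df.iloc[0].start == 500

    def test_infinite_threshold_empty(self):
        stats = self._stats([("chr1", 0, 250, 50.0, 10.0)])
        assert len(em.merge_windows(stats, math.inf)) == 0


class TestDetectHotspots:
    def test_deterministic_end_to_end(self, small_landscape):
        truth, chip, ctrl = small_landscape
        params = em.HotspotParams(seed=21)
        a = em.detect_hotspots(chip, ctrl, truth.genome, params)
        b = em.detect_hotspots(chip, ctrl, truth.genome, params)
        assert a.df.equals(b.df)
        assert a.provenance["threshold"] == b.provenance["threshold"]

    def test_planted_landscape_recall_and_purity(self, small_landscape):
        truth, chip, ctrl = small_landscape
        hs = em.detect_hotspots(chip, ctrl, truth.genome, em.HotspotParams(seed=21))
        assert len(hs) > 0
        iv = hs.intervals()
        ms, me = truth.planted_hotspots.merged_per_chrom("chr1")
        called_true = em.overlaps_any(iv.start, iv.end, ms, me)
        cs, ce = iv.merged_per_chrom("chr1")
        planted_found = em.overlaps_any(
            truth.planted_hotspots.start, truth.planted_hotspots.end, cs, ce
        )
        assert planted_found.mean() >= 0.95
        assert (~called_true).mean() <= 0.05

    def test_hotspots_disjoint_sorted_within_bounds(self, small_landscape):
        truth, chip, ctrl = small_landscape
        hs = em.detect_hotspots(chip, ctrl, truth.genome, em.HotspotParams(seed=21))
        df = hs.df
        assert (df.start < df.end).all()
        assert df.start.min() >= 0 and df.end.max() <= truth.genome["chr1"]
        assert (df.start.to_numpy()[1:] > df.end.to_numpy()[:-1]).all()

    def test_null_only_simulation_calls_almost_nothing(self):
        # with no planted signal the call count is Monte-Carlo bounded by
        # fdr x windows scanned (the top observed order statistic can beat
        # a finite null sample's maximum)
        genome = em.GenomeDef({"chr1": 1_000_000})
        truth = em.SimTruth(
            genome, make_intervals([]), make_intervals([]), 200_000, 200_000, seed=17
        )
        chip = em.simulate_tags(truth, "chip", 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hs = em.detect_hotspots(
                chip, None, genome, em.HotspotParams(n_null_sims=2, seed=5)
            )
        assert len(hs) <= 0.001 * hs.provenance["n_windows_scanned"]

    def test_chip_as_own_input_calls_nothing(self, small_landscape):
        truth, chip, _ = small_landscape
        stats = em.scan_windows(chip, chip, truth.genome, em.HotspotParams())
        assert np.all(stats.obs == 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hs = em.detect_hotspots(
                chip, chip, truth.genome, em.HotspotParams(n_null_sims=2, seed=5)
            )
        assert len(hs) == 0

    def test_cnv_only_landscape_calls_nothing(self):
        genome = em.GenomeDef({"chr1": 2_000_000})
        cnv = make_intervals(
            [("chr1", 400_000, 500_000), ("chr1", 1_200_000, 1_300_000)],
            scores=[3.0, 3.0],
        )
        truth = em.SimTruth(genome, make_intervals([]), cnv, 400_000, 400_000, seed=7)
        chip = em.simulate_tags(truth, "chip", 1)
        ctrl = em.simulate_tags(truth, "input", 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hs = em.detect_hotspots(
                chip, ctrl, genome, em.HotspotParams(n_null_sims=3, seed=5)
            )
        assert len(hs) == 0


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"target_window_w": 500, "background_window_W": 400},
            {"step": 300},
            {"fdr": 0.0},
            {"fdr": 1.0},
            {"n_null_sims": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(em.InvalidParameterError):
            em.HotspotParams(**kwargs)
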