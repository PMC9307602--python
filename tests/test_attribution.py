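"""Integrated Gradients: closed-form oracle, completeness, windows, differentials."""

import numpy as np
import pytest

from chromexpr.attribution import (
    AttributionMap,
    IGConfig,
    differential_attribution,
    integrated_gradients,
    mean_profile,
    overlap_permutation_test,
    top_window,
)
from chromexpr.io_formats import RawTrack
from chromexpr.model import ModelConfig, build_model
from chromexpr.preprocess import GeneInput

L, M = 16, 3


class LinearModel:
    """Purpose-built linear network F(x) = sum w_ep*ep + sum w_seq*seq.

    Independent oracle for IG: with a zero baseline and constant gradient,
    attr_j must equal w_j * x_j exactly.
    """

    def __init__(self, w_ep, w_seq):
        self.w_ep, self.w_seq = w_ep, w_seq
        self.L, self.m = w_ep.shape

    def forward(self, ep, seq, train=False, rng=None):
        return np.tensordot(ep, self.w_ep, 2) + np.tensordot(seq, self.w_seq, 2)

    def input_gradients(self, ep, seq):
        n = ep.shape[0]
        return (np.broadcast_to(self.w_ep, (n, *self.w_ep.shape)),
                np.broadcast_to(self.w_seq, (n, *self.w_seq.shape)))


def _gene(seed=0, L_=L, m=M):
    rng = np.random.default_rng(seed)
    ep = rng.random((L_, m)).astype(np.float32)
    onehot = np.zeros((L_, 4), dtype=np.float32)
    onehot[np.arange(L_), rng.integers(0, 4, L_)] = 1
    return GeneInput("g", ep, onehot, 1.0, 1.0, "chr1",
                     np.arange(100, 100 + L_, dtype=np.int64), "+")


class TestIntegratedGradients:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(2)
        lm = LinearModel(rng.normal(size=(L, M)), rng.normal(size=(L, 4)))
        g = _gene(3)
        amap = integrated_gradients(lm, g, IGConfig(steps=16))
        assert np.allclose(amap.epigenetic, lm.w_ep * g.epigenetic, atol=1e-6)
        assert np.allclose(amap.sequence, lm.w_seq * g.sequence, atol=1e-6)
        assert abs(amap.completeness_gap) < 1e-6

    def test_input_equal_baseline_gives_zero(self):
        model = build_model(ModelConfig(l=5, k1=4, k2=6, fusion_kernels=4, pool1=2,
                                        pool2=2, fc_widths=(8, 6, 4, 1), dropout=0.0),
                            L, M, seed=0)
        g = _gene(1)
        zero = GeneInput("z", np.zeros_like(g.epigenetic), np.zeros_like(g.sequence),
                         0.0, 0.0, "chr1", g.coords, "+")
        amap = integrated_gradients(model, zero, IGConfig(steps=8))
        assert np.all(amap.epigenetic == 0) and np.all(amap.sequence == 0)

    def test_completeness_gap_shrinks_with_steps(self):
        model = build_model(ModelConfig(l=5, k1=4, k2=6, fusion_kernels=4, pool1=2,
                                        pool2=2, fc_widths=(8, 6, 4, 1), dropout=0.0),
                            L, M, seed=3)
        gaps = []
        for steps in (10, 200):
            gap = np.mean([abs(integrated_gradients(model, _gene(s), IGConfig(steps=steps)).completeness_gap)
                           for s in range(5)])
            gaps.append(gap)
        # small models are near-linear here, so allow float32 noise on top of
        # the expected decrease
        assert gaps[1] <= gaps[0] + 1e-6

    def test_steps_below_two_rejected(self):
        with pytest.raises(ValueError):
            IGConfig(steps=1)

    def test_custom_baseline_shifts_reference(self):
        rng = np.random.default_rng(4)
        lm = LinearModel(rng.normal(size=(L, M)), np.zeros((L, 4)))
        g = _gene(5)
        base = np.full_like(g.epigenetic, 0.5)
        amap = integrated_gradients(
            lm, g, IGConfig(steps=8, baseline_epigenetic=base,
                            baseline_sequence=np.zeros_like(g.sequence)))
        assert np.allclose(amap.epigenetic, lm.w_ep * (g.epigenetic - base), atol=1e-6)


class TestMeanProfile:
    @staticmethod
    def _map(ep):
        return AttributionMap("g", ep, np.zeros((ep.shape[0], 4)), 0.0, 0.0)

    def test_single_map_is_identity(self):
        ep = np.random.default_rng(0).normal(size=(L, M))
        assert np.array_equal(mean_profile([self._map(ep)]), ep)

    def test_negatives_cancel_and_permutation_invariance(self):
        ep = np.random.default_rng(1).normal(size=(L, M))
        maps = [self._map(ep), self._map(-ep)]
        assert np.allclose(mean_profile(maps), 0)
        assert np.allclose(mean_profile(maps[::-1]), mean_profile(maps))

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            mean_profile([self._map(np.zeros((L, M))), self._map(np.zeros((L + 2, M)))])


TRACKS = ["t0", "t1", "t2"]


class TestTopWindow:
    @staticmethod
    def _map_with_spike(pos, L_=1000, track_idx=0, value=5.0):
        ep = np.zeros((L_, 3))
        ep[pos, track_idx] = value
        return AttributionMap("g", ep, np.zeros((L_, 4)), 0.0, 0.0, "chr1",
                              np.arange(L_, dtype=np.int64))

    def test_spike_gives_101bp_window(self):
        w = top_window(self._map_with_spike(700), "t0", TRACKS)
        assert (w.center, w.start, w.end) == (700, 650, 751)
        assert w.end - w.start == 101

    def test_tie_breaks_leftmost(self):
        ep = np.zeros((1000, 3))
        ep[100, 0] = ep[900, 0] = 7.0
        amap = AttributionMap("g", ep, np.zeros((1000, 4)), 0.0, 0.0)
        assert top_window(amap, "t0", TRACKS).center == 100

    def test_clipping_at_left_edge(self):
        w = top_window(self._map_with_spike(10), "t0", TRACKS)
        assert (w.start, w.end) == (0, 61)

    def test_unknown_track_errors(self):
        with pytest.raises(ValueError):
            top_window(self._map_with_spike(5), "nope", TRACKS)


class TestDifferentialAttribution:
    @staticmethod
    def _map(ep, gid="g"):
        return AttributionMap(gid, ep, np.zeros((ep.shape[0], 4)), 0.0, 0.0)

    def test_identical_conditions_empty(self):
        ep = np.random.default_rng(0).normal(size=(40, 3))
        out = differential_attribution({"g": self._map(ep)}, {"g": self._map(ep.copy())},
                                       ["g"], TRACKS)
        assert out == []

    def test_planted_spike_returned(self):
        ep_a = np.zeros((40, 3))
        ep_b = ep_a.copy()
        ep_b[17, 1] = 3.0
        out = differential_attribution({"g": self._map(ep_a)}, {"g": self._map(ep_b)},
                                       ["g"], TRACKS)
        assert [(r.track, r.start, r.end) for r in out] == [("t1", 17, 18)]

    def test_quantile_arithmetic_selects_exact_top_fraction(self):
        # differences 1..120 over 40x3 sites: the 0.9 quantile is 108.1, so
        # exactly the 12 sites with d in 109..120 pass
        d = np.arange(1, 121, dtype=float).reshape(40, 3)
        out = differential_attribution({"g": self._map(np.zeros((40, 3)))},
                                       {"g": self._map(d)}, ["g"], TRACKS)
        n_sites = sum(r.end - r.start for r in out)
        assert n_sites == 12

    def test_adjacent_sites_merge_into_region(self):
        ep_b = np.zeros((40, 3))
        ep_b[10:15, 2] = 5.0
        out = differential_attribution({"g": self._map(np.zeros((40, 3)))},
                                       {"g": self._map(ep_b)}, ["g"], TRACKS)
        assert [(r.start, r.end) for r in out if r.track == "t2"] == [(10, 15)]

    def test_missing_gene_errors(self):
        with pytest.raises(ValueError, match="missing"):
            differential_attribution({"g": self._map(np.zeros((4, 3)))}, {}, ["g"], TRACKS)


class TestOverlapPermutation:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        regions = [("chr1", 0, 2000)]
        peaks = RawTrack("MYC", "methylation",
                         [("chr1", 500, 600, 90.0), ("chr1", 1500, 1600, 80.0)])
        return regions, peaks, rng

    @staticmethod
    def _win(chrom, s, e):
        from chromexpr.attribution import HighAttributionWindow
        return HighAttributionWindow("g", "t0", 0, 0, e - s, chrom, s, e)

    def test_windows_on_peaks_extreme_p(self):
        regions, peaks, _ = self._setup()
        wins = [self._win("chr1", 500, 600), self._win("chr1", 1500, 1600)]
        p, obs = overlap_permutation_test(wins, peaks, regions, n_perm=99, seed=1)
        assert p == pytest.approx(1.0 / 100.0)
        assert obs == pytest.approx(85.0)

    def test_random_windows_mostly_not_significant(self):
        regions, peaks, rng = self._setup()
        n_sig = 0
        for rep in range(20):
            s = int(rng.integers(0, 1900))
            wins = [self._win("chr1", s, s + 100)]
            p, _ = overlap_permutation_test(wins, peaks, regions, n_perm=99, seed=rep)
            n_sig += p <= 0.05
        assert n_sig <= 4

    def test_zero_permutations_rejected(self):
        regions, peaks, _ = self._setup()
        with pytest.raises(ValueError):
            overlap_permutation_test([self._win("chr1", 0, 50)], peaks, regions, n_perm=0)

    def test_empty_windows_rejected(self):
        regions, peaks, _ = self._setup()
        with pytest.raises(ValueError):
            overlap_permutation_test([], peaks, regions, n_perm=10)
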