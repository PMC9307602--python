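"""Track binning, scaling, one-hot encoding, window assembly, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromexpr.io_formats import GeneAnnotation, RawTrack
from chromexpr.preprocess import (
    RegionSpec,
    assemble_dataset,
    assemble_gene_input,
    build_trackset,
    load_dataset,
    one_hot,
    regionize_track,
    save_dataset,
    scale_methylation,
    scale_pvalue,
    split_dataset,
)


class TestRegionize:
    def test_single_interval_broadcast(self):
        t = RawTrack("x", "pvalue", [("chr1", 0, 40, 0.01)])
        arr = regionize_track(t, {"chr1": 60})["chr1"]
        assert np.allclose(arr[:40], 0.01)
        assert np.allclose(arr[40:], 1.0)  # uncovered p-value region -> p=1

    def test_straddling_intervals_coverage_weighted(self):
        # 12 bases of a=0.2 and 8 bases of b=0.6 in one 20-bp region
        a, b = 0.2, 0.6
        t = RawTrack("x", "pvalue", [("chr1", 0, 12, a), ("chr1", 12, 20, b)])
        arr = regionize_track(t, {"chr1": 20})["chr1"]
        assert np.allclose(arr, (12 * a + 8 * b) / 20)

    def test_uncovered_methylation_is_zero(self):
        t = RawTrack("wgbs", "methylation", [("chr1", 100, 120, 80.0)])
        arr = regionize_track(t, {"chr1": 200})["chr1"]
        assert np.all(arr[:100] == 0.0)
        assert np.allclose(arr[100:120], 80.0)

    def test_piecewise_constant_over_blocks(self):
        rng = np.random.default_rng(3)
        ivs = [("chr1", int(s), int(s) + 13, float(v))
               for s, v in zip(range(0, 400, 27), rng.uniform(0.01, 1, 15))]
        arr = regionize_track(RawTrack("x", "pvalue", ivs), {"chr1": 400})["chr1"]
        blocks = arr.reshape(-1, 20)
        assert np.allclose(blocks, blocks[:, :1])


class TestScaling:
    def test_neglog_minmax(self):
        out = scale_pvalue(np.array([1.0, 0.1, 0.01]))
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_p_equal_one_is_track_minimum(self):
        assert scale_pvalue(np.array([1.0, 0.5]))[0] == 0.0

    def test_constant_track_maps_to_zero(self):
        assert np.all(scale_pvalue(np.full(5, 0.3)) == 0.0)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            scale_pvalue(np.array([0.0, 0.5]))

    @pytest.mark.parametrize("raw,expected", [(50.0, 0.5), (0.0, 0.0), (100.0, 1.0)])
    def test_methylation_percent(self, raw, expected):
        assert scale_methylation(np.array([raw]))[0] == expected

    def test_methylation_out_of_range(self):
        with pytest.raises(ValueError):
            scale_methylation(np.array([101.0]))


class TestOneHot:
    def test_acgt(self):
        assert np.array_equal(one_hot("ACGT"), np.eye(4))

    def test_case_fold(self):
        assert np.array_equal(one_hot("acgt"), one_hot("ACGT"))

    def test_n_gives_zero_row(self):
        m = one_hot("AN")
        assert np.array_equal(m, [[1, 0, 0, 0], [0, 0, 0, 0]])

    def test_invalid_char_errors(self):
        with pytest.raises(ValueError, match="X"):
            one_hot("ACXT")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_rows_sum_to_zero_or_one(self, seq):
        sums = one_hot(seq).sum(axis=1)
        assert set(sums) <= {0.0, 1.0}
        assert np.array_equal(sums == 0, np.array([c == "N" for c in seq]))


def _toy_study(tpm_plus=10.0, tpm_minus=10.0):
    """Two mirror-image genes on a 4000-bp chromosome, one track."""
    spec = RegionSpec(tss_up=200, tss_down=100, tts_up=100, tts_down=100)
    rng = np.random.default_rng(7)
    n_blocks = 4000 // 20
    vals = rng.uniform(0.01, 1.0, n_blocks)
    genome_codes = rng.integers(0, 4, 4000)
    fwd = "".join("ACGT"[c] for c in genome_codes)
    # mirrored chromosome: chr2 = reverse complement of chr1, mirrored track
    rc = fwd[::-1].translate(str.maketrans("ACGT", "TGCA"))
    iv1 = [("chr1", 20 * i, 20 * i + 20, float(v)) for i, v in enumerate(vals)]
    iv2 = [("chr2", 4000 - (20 * i + 20), 4000 - 20 * i, float(v)) for i, v in enumerate(vals)]
    track = RawTrack("H3K4me3", "pvalue", iv1 + iv2)
    gplus = GeneAnnotation("gp", "chr1", 1000, 2500, "+", tpm_plus)
    # mirror of gp on chr2: position x -> 3999 - x
    gminus = GeneAnnotation("gm", "chr2", 3999 - 1000, 3999 - 2500, "-", tpm_minus)
    genome = {"chr1": fwd, "chr2": rc}
    return spec, track, gplus, gminus, genome


class TestAssemble:
    def test_plus_strand_window_coordinates(self):
        spec, track, gplus, gminus, genome = _toy_study()
        ts = build_trackset([track], {c: len(s) for c, s in genome.items()},
                            [gplus, gminus], spec)
        gi = assemble_gene_input(gplus, ts, genome, spec)
        assert gi.epigenetic.shape == (500, 1)
        assert gi.sequence.shape == (500, 4)
        # TSS window rows cover [tss-200, tss+100), then TTS [tts-100, tts+100)
        assert gi.coords[0] == 800 and gi.coords[299] == 1099
        assert gi.coords[300] == 2400 and gi.coords[-1] == 2599
        assert gi.target == pytest.approx(np.log1p(10.0))

    def test_strand_symmetry_mirror_genes_identical(self):
        """A gene and its strand-flipped mirror produce identical inputs."""
        spec, track, gplus, gminus, genome = _toy_study()
        ts = build_trackset([track], {c: len(s) for c, s in genome.items()},
                            [gplus, gminus], spec)
        gi_p = assemble_gene_input(gplus, ts, genome, spec)
        gi_m = assemble_gene_input(gminus, ts, genome, spec)
        assert np.array_equal(gi_p.sequence, gi_m.sequence)
        assert np.allclose(gi_p.epigenetic, gi_m.epigenetic, atol=1e-6)

    def test_out_of_bounds_gene_skipped(self, caplog):
        spec, track, gplus, gminus, genome = _toy_study()
        near_edge = GeneAnnotation("ge", "chr1", 150, 2500, "+", 5.0)
        ts = build_trackset([track], {c: len(s) for c, s in genome.items()},
                            [gplus], spec)
        assert assemble_gene_input(near_edge, ts, genome, spec) is None

    def test_epigenetic_values_in_unit_interval(self):
        spec, track, gplus, gminus, genome = _toy_study()
        ts = build_trackset([track], {c: len(s) for c, s in genome.items()},
                            [gplus, gminus], spec)
        inputs = assemble_dataset([gplus, gminus], ts, genome, spec)
        for gi in inputs:
            assert gi.epigenetic.min() >= 0.0 and gi.epigenetic.max() <= 1.0

    def test_dataset_roundtrip(self, tmp_path):
        spec, track, gplus, gminus, genome = _toy_study()
        ts = build_trackset([track], {c: len(s) for c, s in genome.items()},
                            [gplus, gminus], spec)
        inputs = assemble_dataset([gplus, gminus], ts, genome, spec)
        path = tmp_path / "data.npz"
        save_dataset(inputs, spec, ts, path, seed=11)
        again, sidecar = load_dataset(path)
        assert [g.gene_id for g in again] == [g.gene_id for g in inputs]
        assert np.array_equal(again[0].epigenetic, inputs[0].epigenetic)
        assert sidecar["region_spec"]["tss_up"] == 200
        assert sidecar["track_names"] == ["H3K4me3"]


class TestSplit:
    @staticmethod
    def _inputs(n):
        spec, track, gplus, gminus, genome = _toy_study()
        ts = build_trackset([track], {c: len(s) for c, s in genome.items()}, [gplus], spec)
        gi = assemble_gene_input(gplus, ts, genome, spec)
        out = []
        for i in range(n):
            g = assemble_gene_input(gplus, ts, genome, spec)
            g.gene_id = f"g{i}"
            out.append(g)
        return out

    def test_default_fractions(self):
        split = split_dataset(self._inputs(100), seed=4)
        assert (len(split.train), len(split.validation), len(split.test)) == (60, 20, 20)

    def test_same_seed_same_partition(self):
        inputs = self._inputs(30)
        s1 = split_dataset(inputs, seed=9)
        s2 = split_dataset(inputs, seed=9)
        assert [g.gene_id for g in s1.train] == [g.gene_id for g in s2.train]
        assert [g.gene_id for g in s1.test] == [g.gene_id for g in s2.test]

    def test_partition_disjoint_exhaustive(self):
        inputs = self._inputs(47)
        s = split_dataset(inputs, fractions=(0.5, 0.25, 0.25), seed=2)
        ids = [g.gene_id for part in (s.train, s.validation, s.test) for g in part]
        assert sorted(ids) == sorted(g.gene_id for g in inputs)

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_dataset(self._inputs(8), fractions=(0.5, 0.25, 0.25), seed=0)

    def test_region_spec_length_multiple_of_bin(self):
        with pytest.raises(ValueError, match="multiple"):
            RegionSpec(tss_up=207, tss_down=100, tts_up=100, tts_down=100)
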