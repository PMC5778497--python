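"""Scale factors, corrected pileups, and track output."""

import numpy as np
import pytest

import seqscale as ss
from seqscale.errors import ConfigError
from seqscale.masks import SENTINEL
from seqscale.reads import ReadEvents
from seqscale.scale import ScaledPileup, write_bedgraph, write_bigwig
from seqscale.tabulate import KmerCountTable


def _toy_counts(exp_p, obs_p, exp_m=None, obs_m=None, mask="CN"):
    mask = ss.KmerMask(mask)
    exp_m = exp_p if exp_m is None else exp_m
    obs_m = obs_p if obs_m is None else obs_m
    return KmerCountTable(
        mask=mask, read_length=10,
        expected_plus=np.asarray(exp_p), expected_minus=np.asarray(exp_m),
        observed_plus=np.asarray(obs_p), observed_minus=np.asarray(obs_m),
    )


class TestComputeScaleFactors:
    def test_unbiased_identity(self):
        """Observed frequencies proportional to expected give alpha = 1."""
        counts = _toy_counts([30, 10, 50, 10], [6, 2, 10, 2])
        f = ss.compute_scale_factors(counts)
        np.testing.assert_allclose(f.alpha_plus, 1.0)
        np.testing.assert_allclose(f.alpha_minus, 1.0)

    def test_hand_worked_one_mer(self):
        # expected {A:3, C:1} (M=4), observed {A:1, C:1} (N=2)
        counts = _toy_counts([3, 1, 0, 0], [1, 1, 0, 0])
        f = ss.compute_scale_factors(counts)
        assert f.alpha_plus[0] == pytest.approx(1.5)
        assert f.alpha_plus[1] == pytest.approx(0.5)

    def test_unobserved_kmer_alpha_zero(self):
        counts = _toy_counts([3, 1, 4, 0], [1, 1, 0, 0])
        f = ss.compute_scale_factors(counts)
        assert f.alpha_plus[2] == 0.0
        assert f.undefined_plus[2]

    def test_observed_without_expected_warns_alpha_one(self):
        counts = _toy_counts([3, 1, 0, 0], [1, 1, 2, 0])
        with pytest.warns(UserWarning):
            f = ss.compute_scale_factors(counts)
        assert f.alpha_plus[2] == 1.0

    def test_no_reads_rejected(self):
        counts = _toy_counts([3, 1, 0, 0], [0, 0, 0, 0])
        with pytest.raises(ValueError):
            ss.compute_scale_factors(counts)


@pytest.fixture(scope="module")
def corrected(small_genome, hexamer_mask):
    track = ss.compute_mappability(small_genome, 36)
    table = ss.build_seqtable(small_genome, track, hexamer_mask)
    model = ss.BiasModel.lognormal(hexamer_mask, seed=50)
    events, _ = ss.simulate_cuts(small_genome, model, 3000, 36, seed=51)
    counts = ss.build_counts(table, reads=events)
    factors = ss.compute_scale_factors(counts)
    return table, events, counts, factors


class TestScaleReads:
    def test_no_scale_reproduces_raw_integer_pileup(self, corrected):
        table, events, _, factors = corrected
        raw = ss.scale_reads(table, events, None, no_scale=True)
        assert raw.total_mass() <= 3000
        for plus, minus in raw.contigs.values():
            assert np.array_equal(plus, np.round(plus))
            assert np.array_equal(minus, np.round(minus))
        pos, is_minus = events.contigs["chr1"]
        plus, minus = raw.contigs["chr1"]
        # every plus event with a valid entry contributes exactly 1
        p0 = pos[~is_minus][0]
        assert plus[p0] >= 1

    def test_unbiased_identity_pileup(self, small_genome, hexamer_mask):
        """With observed == expected counts, corrected equals raw."""
        track = ss.compute_mappability(small_genome, 36)
        table = ss.build_seqtable(small_genome, track, hexamer_mask)
        # one read at every mappable plus/minus position: obs == exp
        plus_pos = np.flatnonzero(table.plus("chr1") != SENTINEL)
        minus_pos = np.flatnonzero(table.minus("chr1") != SENTINEL) - 1
        pos = np.concatenate([plus_pos, minus_pos])
        strands = np.concatenate(
            [np.zeros(len(plus_pos), bool), np.ones(len(minus_pos), bool)]
        )
        events = ReadEvents({"chr1": (pos, strands)})
        counts = ss.build_counts(table, reads=events)
        factors = ss.compute_scale_factors(counts)
        np.testing.assert_allclose(factors.alpha_plus[counts.observed_plus > 0], 1.0)
        corrected = ss.scale_reads(table, events, factors)
        raw = ss.scale_reads(table, events, None, no_scale=True)
        for name in corrected.contigs:
            np.testing.assert_allclose(
                corrected.merged(name), raw.merged(name), atol=1e-12
            )

    def test_total_mass_conservation_identity(self, corrected):
        table, events, counts, factors = corrected
        pileup = ss.scale_reads(table, events, factors)
        seen_p = counts.observed_plus > 0
        seen_m = counts.observed_minus > 0
        predicted = (
            counts.n_observed_plus
            * counts.expected_plus[seen_p].sum() / counts.M_plus
            + counts.n_observed_minus
            * counts.expected_minus[seen_m].sum() / counts.M_minus
        )
        assert pileup.total_mass() == pytest.approx(predicted, rel=1e-12)

    def test_linearity_in_reads(self, corrected):
        table, events, _, factors = corrected
        pos, is_minus = events.contigs["chr1"]
        half = len(pos) // 2
        a = ReadEvents({"chr1": (pos[:half], is_minus[:half])})
        b = ReadEvents({"chr1": (pos[half:], is_minus[half:])})
        whole = ss.scale_reads(table, events, factors)
        part = ss.scale_reads(table, a, factors)
        part_b = ss.scale_reads(table, b, factors)
        np.testing.assert_allclose(
            whole.merged("chr1"),
            part.merged("chr1") + part_b.merged("chr1"),
            atol=1e-9,
        )

    def test_shift_counts_collapses_nick(self, corrected):
        table, events, _, factors = corrected
        shifted = ss.scale_reads(table, events, factors, shift_counts=True)
        unshifted = ss.scale_reads(table, events, factors, shift_counts=False)
        plus_s, minus_s = shifted.contigs["chr1"]
        plus_u, minus_u = unshifted.contigs["chr1"]
        np.testing.assert_allclose(plus_s, plus_u)
        # minus contributions move one base right under shift-counts
        np.testing.assert_allclose(minus_s[1:], minus_u[:-1])

    def test_mask_mismatch_rejected(self, corrected, small_genome):
        table, events, counts, _ = corrected
        other = ss.build_seqtable(
            small_genome, ss.compute_mappability(small_genome, 36),
            ss.parse_mask("NNCNN"),
        )
        factors = ss.compute_scale_factors(counts)
        with pytest.raises(ConfigError):
            ss.scale_reads(other, events, factors)

    def test_planted_one_mer_bias_flattened(self):
        """A cut 3x more than C/G/T: corrected per-k-mer mass matches
        genomic frequency within 2 percent at n = 1e5."""
        mask = ss.KmerMask("CN")
        genome = {"chr1": ss.generate_genome(30_000, seed=52)}
        track = ss.compute_mappability(genome, 20)
        table = ss.build_seqtable(genome, track, mask)
        model = ss.BiasModel(mask, np.array([3.0, 1.0, 1.0, 1.0]))
        events, _ = ss.simulate_cuts(genome, model, 100_000, 20, seed=53)
        counts = ss.build_counts(table, reads=events)
        factors = ss.compute_scale_factors(counts)
        mass = counts.observed_plus * factors.alpha_plus
        genomic = counts.expected_plus / counts.M_plus
        np.testing.assert_allclose(
            mass / mass.sum(), genomic, rtol=0.02
        )
        # and the raw pileup is visibly biased (A >> others)
        raw_freq = counts.observed_plus / counts.n_observed_plus
        assert raw_freq[0] > 2 * raw_freq[1]


class TestTracks:
    def test_bedgraph_line_format(self, tmp_path):
        pileup = ScaledPileup({"c": (np.array([0, 0, 0, 0, 0, 2.5]),
                                     np.zeros(6))})
        path = tmp_path / "out.bedgraph"
        write_bedgraph(pileup, path)
        assert path.read_text() == "c\t5\t6\t2.5\n"

    def test_bigwig_round_trip(self, tmp_path, corrected):
        import pyBigWig

        table, events, _, factors = corrected
        pileup = ss.scale_reads(table, events, factors)
        bw_path = tmp_path / "out.bw"
        sizes = {"chr1": len(pileup.merged("chr1"))}
        write_bigwig(pileup, sizes, bw_path)
        merged = pileup.merged("chr1")
        with pyBigWig.open(str(bw_path)) as bw:
            values = np.nan_to_num(np.array(bw.values("chr1", 0, len(merged))))
        np.testing.assert_allclose(values, merged, rtol=1e-6, atol=1e-6)

    def test_bed_and_bedgraph_agree(self, tmp_path, corrected):
        table, events, _, factors = corrected
        pileup = ss.scale_reads(table, events, factors)
        bed = tmp_path / "out.bed"
        bg = tmp_path / "out.bedgraph"
        ss.write_tracks(pileup, {"chr1": 2000}, bed_path=bed, bedgraph_path=bg)
        bed_rows = [line.split("\t") for line in bed.read_text().splitlines()]
        bg_rows = [line.split("\t") for line in bg.read_text().splitlines()]
        assert [(r[0], r[1], r[2], r[4]) for r in bed_rows] == \
            [(r[0], r[1], r[2], r[3]) for r in bg_rows]

    def test_empty_pileup_valid_files(self, tmp_path):
        pileup = ScaledPileup({"c": (np.zeros(10), np.zeros(10))})
        bg = tmp_path / "empty.bedgraph"
        bw = tmp_path / "empty.bw"
        ss.write_tracks(pileup, {"c": 10}, bedgraph_path=bg, bigwig_path=bw)
        assert bg.read_text() == ""
        import pyBigWig

        with pyBigWig.open(str(bw)) as handle:
            assert handle.chroms()["c"] == 10

    def test_unknown_contig_rejected(self, tmp_path):
        pileup = ScaledPileup({"c": (np.ones(4), np.zeros(4))})
        with pytest.raises(ValueError):
            write_bigwig(pileup, {"other": 4}, tmp_path / "x.bw")

    def test_merge_bedgraphs_adds_values(self, tmp_path):
        a = tmp_path / "a.bedgraph"
        b = tmp_path / "b.bedgraph"
        a.write_text("c\t1\t2\t1.5\nc\t4\t5\t2\n")
        b.write_text("c\t1\t2\t0.5\nc\t7\t8\t1\n")
        out = tmp_path / "m.bedgraph"
        ss.merge_bedgraphs([a, b], out)
        assert out.read_text() == "c\t1\t2\t2\nc\t4\t5\t2\nc\t7\t8\t1\n"

    def test_separate_strands_tracks(self, tmp_path, corrected):
        table, events, _, factors = corrected
        pileup = ss.scale_reads(table, events, factors)
        paths = write_bedgraph(pileup, tmp_path / "out.bedgraph",
                               separate_strands=True)
        assert len(paths) == 2
        total = 0.0
        for p in paths:
            for line in open(p):
                total += float(line.split("\t")[3])
        assert total == pytest.approx(pileup.total_mass(), rel=1e-4)
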