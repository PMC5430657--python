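"""Hotspot generation, pair enumeration, and splice-site resolution."""

import numpy as np
import pytest

from oracles import exhaustive_splice_scan
from seedsplice import MapperConfig
from seedsplice.formats_io import Genome, Read
from seedsplice.reference_index import build_seed_index
from seedsplice.spliced_mapper import (
    HotspotPair,
    enumerate_pairs,
    generate_hotspots,
    map_spliced,
    resolve_splice_site,
)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="module")
def junction_genome():
    """One GT-AG intron of length 200 between two 300 nt exons."""
    rng = np.random.default_rng(21)
    e1 = _random_seq(rng, 300)
    e2 = _random_seq(rng, 300)
    intron = "GT" + _random_seq(rng, 196) + "AG"
    pad = _random_seq(rng, 200)
    seq = pad + e1 + intron + e2 + pad
    genome = Genome({"c": seq})
    donor = len(pad) + len(e1)
    return genome, e1, e2, donor, donor + 200


class TestHotspots:
    def test_exact_substring_gives_one_hotspot_of_three_seeds(self, junction_genome):
        genome, e1, *_ = junction_genome
        index = build_seed_index(genome.contigs, 14)
        read = Read("r", e1[:42])
        hs = [h for h in generate_hotspots(read, index, MapperConfig()) if h.strand == "+"]
        assert len(hs) == 1 and hs[0].n_seeds == 3

    def test_split_read_gives_two_hotspots(self, junction_genome):
        genome, e1, e2, *_ = junction_genome
        index = build_seed_index(genome.contigs, 14)
        read = Read("r", e1[-28:] + e2[:14])
        hs = sorted(
            (h for h in generate_hotspots(read, index, MapperConfig()) if h.strand == "+"),
            key=lambda h: h.read_span,
        )
        assert [h.n_seeds for h in hs] == [2, 1]

    def test_all_n_read_no_hotspots(self, junction_genome):
        genome, *_ = junction_genome
        index = build_seed_index(genome.contigs, 14)
        read = Read("r", "N" * 50)
        assert generate_hotspots(read, index, MapperConfig()) == []

    def test_error_destroyed_middle_seed_still_one_hotspot(self, junction_genome):
        genome, e1, *_ = junction_genome
        index = build_seed_index(genome.contigs, 14)
        frag = list(e1[:56])
        frag[20] = "A" if frag[20] != "A" else "C"  # kill seed 1
        hs = [
            h
            for h in generate_hotspots(Read("r", "".join(frag)), index, MapperConfig())
            if h.strand == "+"
        ]
        assert len(hs) == 1 and hs[0].n_seeds == 3  # seeds 0, 2, 3 merged across the gap


class TestEnumeratePairs:
    def _hotspot(self, diag, span, n):
        from seedsplice.spliced_mapper import Hotspot

        return Hotspot("c", "+", diag, span, n)

    def test_score_is_seed_sum(self):
        h1 = self._hotspot(0, (0, 28), 3)
        h2 = self._hotspot(1000, (28, 42), 1)
        (pair,) = enumerate_pairs([h1, h2], MapperConfig())
        assert pair.score == 4 and pair.gap == 1000

    def test_gap_below_min_intron_rejected(self):
        h1 = self._hotspot(0, (0, 28), 2)
        h2 = self._hotspot(10, (28, 42), 1)
        assert enumerate_pairs([h1, h2], MapperConfig()) == []

    def test_gap_above_max_intron_rejected(self):
        h1 = self._hotspot(0, (0, 28), 2)
        h2 = self._hotspot(600_000, (28, 42), 1)
        assert enumerate_pairs([h1, h2], MapperConfig()) == []

    def test_sorted_by_score_then_shorter_gap(self):
        a = self._hotspot(0, (0, 28), 2)
        b = self._hotspot(5000, (28, 56), 2)
        c = self._hotspot(200, (28, 42), 1)
        pairs = enumerate_pairs([a, b, c], MapperConfig())
        assert [p.score for p in pairs] == sorted((p.score for p in pairs), reverse=True)
        same_score = [p.gap for p in pairs if p.score == pairs[0].score]
        assert same_score == sorted(same_score)


class TestResolveSpliceSite:
    def _pair_for(self, read, genome, config):
        index = build_seed_index(genome.contigs, config.seed_length)
        pairs = enumerate_pairs(generate_hotspots(read, index, config), config)
        assert pairs
        return pairs[0]

    def test_error_free_junction_read_recovers_exact_site(self, junction_genome):
        genome, e1, e2, donor, acceptor = junction_genome
        cfg = MapperConfig()
        read = Read("r", e1[-21:] + e2[:21])
        pair = self._pair_for(read, genome, cfg)
        aln = resolve_splice_site(read, pair, genome, cfg)
        assert aln is not None
        assert aln.intron == (donor, acceptor)
        assert aln.motif_class == "GT-AG" and aln.n_errors == 0
        assert aln.cigar == "21M200N21M"

    def test_over_budget_read_rejected(self, junction_genome):
        genome, e1, e2, *_ = junction_genome
        cfg = MapperConfig(max_errors=2)
        frag = list(e1[-30:] + e2[:30])
        rng = np.random.default_rng(3)
        for p in rng.choice(len(frag), 8, replace=False):
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        read = Read("r", "".join(frag))
        index = build_seed_index(genome.contigs, cfg.seed_length)
        pairs = enumerate_pairs(generate_hotspots(read, index, cfg), cfg)
        for pair in pairs:
            assert resolve_splice_site(read, pair, genome, cfg) is None

    def test_matches_exhaustive_oracle_on_noisy_reads(self, junction_genome):
        genome, e1, e2, donor, acceptor = junction_genome
        cfg = MapperConfig()
        rng = np.random.default_rng(4)
        n_checked = 0
        for _ in range(60):
            lflank = int(rng.integers(15, 60))
            rflank = int(rng.integers(15, 60))
            frag = list(e1[-lflank:] + e2[:rflank])
            for i in range(len(frag)):
                if rng.random() < 0.02:
                    frag[i] = "ACGT"[int(rng.integers(0, 4))]
            read = Read("r", "".join(frag))
            index = build_seed_index(genome.contigs, cfg.seed_length)
            pairs = enumerate_pairs(generate_hotspots(read, index, cfg), cfg)
            if not pairs:
                continue
            pair = pairs[0]
            aln = resolve_splice_site(read, pair, genome, cfg)
            oracle = exhaustive_splice_scan(
                read.sequence,
                genome["c"],
                pair.left.diagonal,
                pair.right.diagonal,
                max_errors=cfg.max_errors,
                min_intron=cfg.min_intron,
                max_intron=cfg.max_intron,
                min_anchor=cfg.min_anchor,
            )
            if oracle is None:
                assert aln is None
            else:
                assert aln is not None
                assert aln.n_errors == oracle[0]
                n_checked += 1
        assert n_checked >= 40


def make_shift_ambiguous_fixture(rng):
    """Genome with a junction whose breakpoint can shift one nt either way
    at equal cost; only the annotated placement is GT-AG."""
    A = _random_seq(rng, 40)
    B = _random_seq(rng, 38)
    e1 = A[:-2] + "CG"  # allows left shift (ends G), blocks shift -2 (C != A)
    e2 = "GA" + B  # allows right shift (starts G), blocks +2 (A != T)
    intron = "GT" + _random_seq(rng, 85) + "CAG"
    pad1, pad2 = _random_seq(rng, 120), _random_seq(rng, 120)
    genome = Genome({"c": pad1 + e1 + intron + e2 + pad2})
    donor = len(pad1) + len(e1)
    acceptor = donor + len(intron)
    read = Read("r", e1 + e2)
    return genome, read, donor, acceptor


class TestMotifGuidance:
    def test_guidance_picks_canonical_site_among_equal_cost_shifts(self):
        rng = np.random.default_rng(17)
        genome, read, donor, acceptor = make_shift_ambiguous_fixture(rng)
        cfg = MapperConfig()
        index = build_seed_index(genome.contigs, cfg.seed_length)
        aln = map_spliced(read, index, genome, cfg)
        assert aln is not None
        assert aln.intron == (donor, acceptor)
        assert aln.motif_class == "GT-AG"

    def test_without_guidance_leftmost_equal_cost_site_wins(self):
        rng = np.random.default_rng(17)
        genome, read, donor, acceptor = make_shift_ambiguous_fixture(rng)
        cfg = MapperConfig(motif_guidance=False)
        index = build_seed_index(genome.contigs, cfg.seed_length)
        aln = map_spliced(read, index, genome, cfg)
        assert aln is not None
        assert aln.n_errors == 0
        assert aln.intron == (donor - 1, acceptor - 1)  # shifted, non-canonical

    def test_canonical_only_rejects_noncanonical_intron(self):
        rng = np.random.default_rng(19)
        # pin exon edges so no equal-cost breakpoint shift exists
        e1 = _random_seq(rng, 58) + "TT"
        e2 = "AA" + _random_seq(rng, 58)
        intron = "CC" + _random_seq(rng, 96) + "GG"
        genome = Genome({"c": _random_seq(rng, 100) + e1 + intron + e2 + _random_seq(rng, 100)})
        read = Read("r", e1[-25:] + e2[:25])
        index = build_seed_index(genome.contigs, 14)
        strict = map_spliced(read, index, genome, MapperConfig(canonical_only=True))
        lenient = map_spliced(read, index, genome, MapperConfig())
        assert strict is None
        assert lenient is not None and lenient.motif_class == "noncanonical"


class TestMapSpliced:
    def test_unique_spliced_alignment_from_single_locus(self, junction_genome):
        genome, e1, e2, donor, acceptor = junction_genome
        cfg = MapperConfig()
        index = build_seed_index(genome.contigs, 14)
        read = Read("r", e1[-30:] + e2[:30])
        aln = map_spliced(read, index, genome, cfg)
        assert aln is not None and aln.unique and aln.intron == (donor, acceptor)

    def test_duplicated_flanks_not_unique(self):
        rng = np.random.default_rng(23)
        e1, e2 = _random_seq(rng, 100), _random_seq(rng, 100)
        intron = "GT" + _random_seq(rng, 96) + "AG"
        unit = e1 + intron + e2
        genome = Genome(
            {"c": _random_seq(rng, 100) + unit + _random_seq(rng, 300) + unit + _random_seq(rng, 100)}
        )
        index = build_seed_index(genome.contigs, 14)
        read = Read("r", e1[-30:] + e2[:30])
        aln = map_spliced(read, index, genome, MapperConfig())
        assert aln is not None and not aln.unique

    def test_purely_exonic_read_not_spliced(self, junction_genome):
        genome, e1, *_ = junction_genome
        index = build_seed_index(genome.contigs, 14)
        read = Read("r", e1[10:90])
        aln = map_spliced(read, index, genome, MapperConfig())
        assert aln is None or not aln.introns

    def test_intron_bounds_respected(self, sim_small_run, default_config):
        _, alignments, junctions, _ = sim_small_run
        for j in junctions:
            length = j.intron[1] - j.intron[0]
            assert default_config.min_intron <= length <= default_config.max_intron
        for a in alignments:
            assert a.n_errors <= default_config.max_errors
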