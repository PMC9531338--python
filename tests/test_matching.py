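"""K-mer matching profiles, KMAPQ and the false-positive filter."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raremark.alignment import PafAlignment
from raremark.kmer_index import GenomeSequences, KmerParams, build_rare_index, revcomp
from raremark.matching import (
    InternalConsistencyError,
    MissingSequenceError,
    ScoredAlignment,
    chain_candidates,
    expected_matches,
    filter_alignments,
    find_matches_anchored,
    find_matches_cigar,
    kmapq,
    score_alignments,
    write_filtered_paf,
)
from raremark.kmer_index import RareKmerIndex, rare_in_interval

from _oracles import brute_force_chains, brute_force_matches, random_genome

K = 21


def slice_alignment(genome_seq, start, end, *, strand="+", qname="q1", snps=()):
    """Alignment of a (possibly substituted) copy of genome[start:end]."""
    qseq = list(genome_seq[start:end])
    for off in snps:
        qseq[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[qseq[off]]
    qseq = "".join(qseq)
    qlen = end - start
    if strand == "-":
        qseq = revcomp(qseq)
    a = PafAlignment(
        qname=qname, qlen=qlen, qstart=0, qend=qlen, strand=strand,
        tname="s1", tlen=len(genome_seq), tstart=start, tend=end,
        n_match=qlen - len(snps), aln_len=qlen, mapq=60,
        tags=(("cg", "Z", f"{qlen}M"),),
    )
    return a, qseq


@pytest.fixture(scope="module")
def unique_genome():
    """A 2 kb random genome in which (checked) every 21-mer is unique."""
    rng = np.random.default_rng(1234)
    seq = random_genome(rng, 2000)
    genome = GenomeSequences([("s1", seq)])
    index = build_rare_index(genome, KmerParams(k=K, max_count=1))
    assert len(index.positions["s1"]) == 2000 - K + 1  # all windows rare
    return genome, index


class TestKmapq:
    @pytest.mark.parametrize("m,e,score", [(73, 73, 60), (0, 50, 0), (3, 4, 45)])
    def test_defined_values(self, m, e, score):
        assert kmapq(m, e) == score

    def test_half_up_rounding(self):
        assert kmapq(1, 8) == 8  # 7.5 rounds up
        assert kmapq(29, 120) == 15  # 14.5 rounds up

    def test_e_zero_scores_zero(self):
        assert kmapq(0, 0) == 0
        assert kmapq(5, 0) == 0

    @given(st.integers(0, 1000), st.integers(1, 1000))
    @settings(derandomize=True, max_examples=200)
    def test_bounded_and_matches_float_halfup(self, m, e):
        s = kmapq(m, e)
        assert 0 <= s <= 60
        import math
        assert s == min(60, math.floor(60 * m / e + 0.5))


class TestExpectedMatches:
    def test_counts_windows_inside_interval(self):
        idx = RareKmerIndex(
            k=4, max_count=1, positions={"t1": [2, 10, 50]},
            codes={"t1": [0, 1, 2]}, seq_lengths={"t1": 100}, genome_total_rare=3,
        )
        a = PafAlignment("q", 20, 0, 14, "+", "t1", 100, 0, 14, 14, 14, 60)
        assert expected_matches(a, idx) == 2

    def test_unknown_target_errors(self):
        idx = RareKmerIndex(4, 1, {}, {}, {}, 0)
        a = PafAlignment("q", 20, 0, 14, "+", "nope", 100, 0, 14, 14, 14, 60)
        with pytest.raises(KeyError):
            expected_matches(a, idx)


class TestFindMatchesCigar:
    def test_perfect_copy_matches_every_window(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequence("s1")
        a, qseq = slice_alignment(seq, 400, 500)
        matches = find_matches_cigar(a, qseq, seq, index)
        assert len(matches) == 100 - K + 1 == 80
        assert [m.tpos for m in matches] == list(range(400, 480))
        assert [m.qpos for m in matches] == list(range(0, 80))

    def test_single_substitution_removes_k_matches(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequence("s1")
        a, qseq = slice_alignment(seq, 400, 500, snps=(50,))
        matches = find_matches_cigar(a, qseq, seq, index)
        assert len(matches) == 80 - K == 59
        snp = 400 + 50
        alive = {m.tpos for m in matches}
        # exactly the windows covering the substituted base are gone
        assert alive == {t for t in range(400, 480) if not (snp - K < t <= snp)}

    def test_no_markers_no_matches(self):
        genome = GenomeSequences([("s1", "A" * 100)])
        index = build_rare_index(genome, KmerParams(k=4, max_count=1))
        a, qseq = slice_alignment("A" * 100, 10, 60)
        assert find_matches_cigar(a, qseq, "A" * 100, index) == []

    def test_minus_strand_profile(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequence("s1")
        a, qseq = slice_alignment(seq, 400, 500, strand="-")
        matches = find_matches_cigar(a, qseq, seq, index)
        assert len(matches) == 80
        assert [m.tpos for m in matches] == list(range(400, 480))
        # qpos strictly decreasing on minus strand
        qps = [m.qpos for m in matches]
        assert all(x > y for x, y in zip(qps, qps[1:]))

    def test_agrees_with_brute_force_on_random_alignments(self):
        """The block-walk implementation equals a per-base projection +
        string-comparison oracle on 50 random simulated alignments."""
        from _oracles import random_alignment

        rng = np.random.default_rng(321)
        for _ in range(50):
            a, qseq, tseq = random_alignment(rng)
            genome = GenomeSequences([("t", tseq)])
            k = 5
            index = build_rare_index(genome, KmerParams(k=k, max_count=2))
            got = find_matches_cigar(a, qseq, tseq, index)
            expected = brute_force_matches(
                a, qseq, tseq, index.positions["t"], k
            )
            assert [(m.qpos, m.tpos) for m in got] == expected

    def test_rc_symmetry(self, unique_genome):
        """Reverse-complementing the query and flipping strand leaves m (and
        the matched target positions) unchanged."""
        genome, index = unique_genome
        seq = genome.sequence("s1")
        plus, qseq_p = slice_alignment(seq, 300, 520, snps=(17, 100, 190))
        minus, qseq_m = slice_alignment(seq, 300, 520, strand="-", snps=(17, 100, 190))
        mp = find_matches_cigar(plus, qseq_p, seq, index)
        mm = find_matches_cigar(minus, qseq_m, seq, index)
        assert len(mp) == len(mm)
        assert [m.tpos for m in mp] == [m.tpos for m in mm]
        assert {m.qpos for m in mm} == {plus.qlen - m.qpos - K for m in mp}

    def test_monotone_degradation_in_snp_count(self, unique_genome):
        """m is non-increasing in substitutions; each isolated extra
        substitution (>= 2k apart, k from the edges) removes exactly k."""
        genome, index = unique_genome
        seq = genome.sequence("s1")
        start, end = 200, 1400
        snp_sites = [60, 160, 300, 444, 600, 777]  # pairwise >= 2K apart
        prev_m = None
        for s in range(len(snp_sites) + 1):
            a, qseq = slice_alignment(seq, start, end, snps=tuple(snp_sites[:s]))
            m = len(find_matches_cigar(a, qseq, seq, index))
            if prev_m is not None:
                assert m == prev_m - K
            prev_m = m


class TestFindMatchesAnchored:
    def test_chain_example(self):
        assert chain_candidates([(0, 10), (5, 2), (8, 20)], "+") == [(0, 10), (8, 20)]

    def test_zero_candidates(self):
        assert chain_candidates([], "+") == []

    def test_collinear_input_fully_retained(self):
        cands = [(0, 5), (3, 9), (7, 30)]
        assert chain_candidates(cands, "+") == cands

    def test_chain_is_a_maximum_chain(self):
        rng = np.random.default_rng(8)
        for strand in "+-":
            for _ in range(30):
                n = int(rng.integers(0, 9))
                cands = list(
                    {(int(rng.integers(0, 40)), int(rng.integers(0, 40)))
                     for _ in range(n)}
                )
                got = chain_candidates(cands, strand)
                best = brute_force_chains(cands, strand)
                assert len(got) == len(best[0])
                assert got in best

    def test_anchored_equals_cigar_on_clean_copy(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequence("s1")
        a, qseq = slice_alignment(seq, 400, 500, snps=(50,))
        no_cg = replace(a, tags=())
        anchored = find_matches_anchored(no_cg, qseq, seq, index)
        cigar = find_matches_cigar(a, qseq, seq, index)
        assert [(m.qpos, m.tpos) for m in anchored] == [
            (m.qpos, m.tpos) for m in cigar
        ]

    def test_anchored_minus_strand(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequence("s1")
        a, qseq = slice_alignment(seq, 400, 500, strand="-")
        no_cg = replace(a, tags=())
        matches = find_matches_anchored(no_cg, qseq, seq, index)
        assert len(matches) == 80
        qps = [m.qpos for m in matches]
        assert all(x > y for x, y in zip(qps, qps[1:]))


class TestScoreAndFilter:
    def test_empty_paf(self, unique_genome):
        genome, index = unique_genome
        assert score_alignments([], genome, genome, index) == []

    def test_order_preserved_and_self_alignment_maximal(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequence("s1")
        a1, q1 = slice_alignment(seq, 0, 2000, qname="s1")  # full self-alignment
        a2, q2 = slice_alignment(seq, 100, 300, qname="q2")
        queries = GenomeSequences([("q2", q2)])
        scored = score_alignments([a1, a2], genome, queries, index)
        assert [s.alignment.qname for s in scored] == ["s1", "q2"]
        assert scored[0].m == scored[0].e and scored[0].kmapq == 60

    def test_m_equals_e_gives_60(self, unique_genome):
        genome, index = unique_genome
        seq = genome.sequence("s1")
        a, qseq = slice_alignment(seq, 700, 950)
        s = score_alignments([a], genome, GenomeSequences([("q1", qseq)]), index)[0]
        assert s.m == s.e > 0
        assert s.kmapq == 60 and not s.uninformative

    def test_missing_sequence_names_id(self, unique_genome):
        genome, index = unique_genome
        a, _ = slice_alignment(genome.sequence("s1"), 0, 100, qname="ghost")
        with pytest.raises(MissingSequenceError, match="ghost"):
            score_alignments([a], genome, GenomeSequences([("x", "ACGT")]), index)

    def test_consistency_error_when_m_exceeds_e(self):
        a = PafAlignment("q", 10, 0, 10, "+", "t", 10, 0, 10, 10, 10, 60)
        with pytest.raises(InternalConsistencyError):
            ScoredAlignment.build(a, [object(), object()], e=1, method="cigar")

    def test_identity_filter_keeps_all(self, repeat_scenario):
        kept, removed = filter_alignments(repeat_scenario["scored"], 0, 0)
        assert len(removed) == 0
        assert len(kept) == len(repeat_scenario["scored"])

    def test_high_mapq_zero_kmapq_removed(self, repeat_scenario):
        """An alignment with maximal aligner MAPQ but no rare k-mer support is
        the canonical false positive and must be removed at min_kmapq=30."""
        kept, removed = filter_alignments(repeat_scenario["scored"], 0, 30)
        assert len(removed) == 1
        assert removed[0].alignment.mapq == 60 and removed[0].kmapq < 30
        src_copy = repeat_scenario["truth"].contig[0]
        src_interval = repeat_scenario["truth"].copies[src_copy]
        assert kept[0].alignment.tstart == src_interval[0]

    def test_uninformative_kept_and_labeled(self):
        a = PafAlignment("q", 10, 0, 10, "+", "t", 10, 0, 10, 10, 10, 60)
        s = ScoredAlignment.build(a, [], e=0, method="cigar")
        assert s.uninformative
        kept, removed = filter_alignments([s], min_mapq=0, min_kmapq=30)
        assert kept == [s] and removed == []

    def test_filtered_paf_has_km_ke_tags(self, repeat_scenario, tmp_path):
        kept, removed = filter_alignments(repeat_scenario["scored"], 0, 30)
        out = tmp_path / "kept.paf"
        write_filtered_paf(kept, removed, out)
        kept_line = out.read_text().splitlines()[0]
        assert "km:i:60" in kept_line and "ke:i:" in kept_line
        removed_lines = (tmp_path / "kept.removed.paf").read_text().splitlines()
        assert len(removed_lines) == 1 and "km:i:" in removed_lines[0]


class TestDiscrimination:
    def test_source_copy_outscores_other_copy(self):
        """Contig from copy A scores strictly higher against copy A than
        against copy B in at least 19 of 20 seeded trials (smoke-scale; the
        acceptance suite runs 100)."""
        from raremark.synthetic import RepeatSimConfig, simulate_scenario

        wins = 0
        for seed in range(20):
            g, t, c, paf = simulate_scenario(RepeatSimConfig(seed=seed))
            index = build_rare_index(g, KmerParams(k=K, max_count=1))
            scored = score_alignments(paf, g, c, index)
            src = t.contig[0]
            by_copy = {s.alignment.tstart: s for s in scored}
            s_src = by_copy[t.copies[src][0]]
            s_other = next(
                s for s in scored if s.alignment.tstart != t.copies[src][0]
            )
            wins += s_src.kmapq > s_other.kmapq
        assert wins >= 19
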