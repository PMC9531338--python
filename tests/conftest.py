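import numpy as np
import pytest

from raremark.kmer_index import GenomeSequences, KmerParams, build_rare_index
from raremark.matching import score_alignments
from raremark.synthetic import RepeatSimConfig, simulate_scenario

from _oracles import random_alignment


@pytest.fixture(scope="session")
def repeat_scenario():
    """The reference two-copy scenario: 2.8 kb copies, 1% divergence, contig
    from copy 0, truth PAF with MAPQ 60 on both records."""
    config = RepeatSimConfig(seed=42)
    genome, truth, contig, paf = simulate_scenario(config)
    index = build_rare_index(genome, KmerParams(k=21, max_count=1))
    scored = score_alignments(paf, genome, contig, index)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "contig": contig,
        "paf": paf,
        "index": index,
        "scored": scored,
    }


@pytest.fixture(scope="session")
def scored_fixture_100():
    """100 random scored alignments over one synthetic genome, for format and
    lookup tests."""
    rng = np.random.default_rng(314)
    records = []
    for i in range(100):
        a, qseq, tseq = random_alignment(rng)
        records.append((a, qseq, tseq, i))
    # give records distinct names so index lookups are meaningful
    from dataclasses import replace

    from raremark.matching import KmerMatch, ScoredAlignment, kmapq

    scored = []
    for a, qseq, tseq, i in records:
        a = replace(a, qname=f"q{i % 17}", tname=f"t{i % 7}")
        m = int(rng.integers(0, 4))
        e = m + int(rng.integers(0, 4))
        matches = [
            KmerMatch(qpos=int(rng.integers(0, 50)), tpos=int(rng.integers(0, 50)),
                      code=int(rng.integers(0, 4**10)))
            for _ in range(m)
        ]
        scored.append(
            ScoredAlignment(
                alignment=a, matches=matches, m=m, e=e, kmapq=kmapq(m, e),
                uninformative=(e == 0), method="cigar",
            )
        )
    return scored


def make_genome(seq: str, seq_id: str = "s1") -> GenomeSequences:
    return GenomeSequences([(seq_id, seq)])
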