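"""Rare k-mer matching profiles, the KMAPQ score, and false-positive filtering.

An alignment between two different copies of a near-identical repeat can carry
the aligner's maximum mapping quality and still be wrong. The adjudicating
evidence is copy-specific: rare k-mers of the target genome that fall inside
the aligned target interval. For a true alignment the query carries the same
markers at the corresponding positions; for a false positive it does not.

For each alignment we compute

* ``e`` — the number of rare k-mers whose window lies fully inside the aligned
  target interval (the markers the alignment is *expected* to match), and
* ``m`` — how many of them actually match the query at the aligned position
  (each match is one "red line" in the rendered profile),

and score ``KMAPQ = round(60 * m / e)`` (half-up, clipped to [0, 60]) so that a
perfect copy-specific alignment scores 60 on the familiar MAPQ scale. An
alignment over a region with no markers at all (``e = 0``) is *uninformative*:
it cannot be adjudicated and is flagged rather than scored down.

Two match-finding paths are provided: an exact one that projects every marker
through the CIGAR (used whenever ``cg:Z`` is present) and an anchor-chaining
fallback for plain 12-column PAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import PafAlignment, aligned_blocks, write_paf
from .kmer_index import (
    GenomeSequences,
    KmerParams,
    RareKmerIndex,
    canonical_code,
    rare_in_interval,
    revcomp,
    _scan_codes,
)

__all__ = [
    "KmerMatch",
    "ScoredAlignment",
    "InternalConsistencyError",
    "MissingSequenceError",
    "expected_matches",
    "find_matches_cigar",
    "find_matches_anchored",
    "chain_candidates",
    "kmapq",
    "score_alignments",
    "filter_alignments",
    "write_filtered_paf",
]

KMAPQ_MAX = 60


class InternalConsistencyError(RuntimeError):
    """More matches than expected markers under the CIGAR path."""


class MissingSequenceError(KeyError):
    """A PAF record names a sequence absent from the provided FASTA sets."""


@dataclass(frozen=True)
class KmerMatch:
    """One matching rare k-mer pair: query start (original strand), target
    start, and the canonical integer code of the marker."""

    qpos: int
    tpos: int
    code: int


@dataclass
class ScoredAlignment:
    """An alignment with its rare k-mer matching profile and KMAPQ score."""

    alignment: PafAlignment
    matches: list[KmerMatch]
    m: int
    e: int
    kmapq: int
    uninformative: bool = False
    method: str = "cigar"  # which match-finding path produced the profile

    @classmethod
    def build(
        cls, alignment: PafAlignment, matches: list[KmerMatch], e: int, method: str
    ) -> "ScoredAlignment":
        m = len(matches)
        if method == "cigar" and m > e:
            raise InternalConsistencyError(
                f"record {alignment.qname}->{alignment.tname}: {m} matches exceed "
                f"{e} expected rare k-mers"
            )
        return cls(
            alignment=alignment,
            matches=matches,
            m=m,
            e=e,
            kmapq=kmapq(m, e),
            uninformative=(e == 0),
            method=method,
        )


def kmapq(m: int, e: int) -> int:
    """KMAPQ = round(60*m/e) with half-up rounding, clipped to [0, 60].

    ``e = 0`` scores 0; the caller flags such alignments uninformative.
    Integer arithmetic keeps the rounding platform-stable.
    """
    if m < 0 or e < 0:
        raise ValueError("m and e must be non-negative")
    if e == 0:
        return 0
    return min(KMAPQ_MAX, (2 * KMAPQ_MAX * m + e) // (2 * e))


def expected_matches(a: PafAlignment, index: RareKmerIndex) -> int:
    """Number of rare k-mers whose window lies fully inside the aligned target
    interval — the denominator of KMAPQ."""
    return len(rare_in_interval(index, a.tname, a.tstart, a.tend))


def find_matches_cigar(
    a: PafAlignment,
    qseq: str,
    tseq: str,
    index: RareKmerIndex,
    params: KmerParams | None = None,
) -> list[KmerMatch]:
    """Exact matching profile via CIGAR projection.

    For every rare target k-mer in the aligned interval, the window is
    projected onto the query; it matches iff the projection is co-linear (no
    indel inside the window) and the query window's sequence equals the target
    window (reverse-complement equality on - strand). Sequence equality is
    always re-checked from the sequences, never assumed from ``=`` runs.
    """
    k = index.k
    blocks = aligned_blocks(a)
    matches: list[KmerMatch] = []
    minus = a.strand == "-"
    for p in rare_in_interval(index, a.tname, a.tstart, a.tend):
        qf = _frame_pos_of_window(blocks, p, k)
        if qf is None:
            continue
        qpos = qf if not minus else a.qlen - qf - k
        qwin = qseq[qpos : qpos + k]
        twin = tseq[p : p + k]
        if (revcomp(qwin) if minus else qwin) == twin:
            matches.append(KmerMatch(qpos=qpos, tpos=p, code=canonical_code(twin)))
    return matches


def _frame_pos_of_window(blocks, p: int, k: int) -> int | None:
    """CIGAR-frame query start of the window aligned to target [p, p+k), or
    None unless the whole window sits inside one co-linear block."""
    for q0, t0, length in blocks:
        if t0 <= p and p + k <= t0 + length:
            return q0 + (p - t0)
        if t0 > p:
            break
    return None


def find_matches_anchored(
    a: PafAlignment,
    qseq: str,
    tseq: str,
    index: RareKmerIndex,
    params: KmerParams | None = None,
) -> list[KmerMatch]:
    """Matching profile without a CIGAR (plain 12-column PAF).

    Candidate anchors are rare k-mers occurring exactly once in the aligned
    target interval and exactly once in the aligned query interval with the
    same canonical code (canonical coding makes the comparison strand-aware).
    The profile is the longest strictly monotone chain of anchors: query and
    target positions both increasing on +, target increasing with query
    decreasing on -. Among equal-length chains the one with the earliest query
    positions is chosen.
    """
    k = index.k
    # target side: rare occurrences unique within the interval
    t_by_code: dict[int, list[int]] = {}
    for pos, code in index.interval_entries(a.tname, a.tstart, a.tend):
        t_by_code.setdefault(code, []).append(pos)
    t_single = {code: pos[0] for code, pos in t_by_code.items() if len(pos) == 1}
    if not t_single:
        return []
    # query side: windows unique within the interval, restricted to codes seen
    # on the target side
    q_by_code: dict[int, list[int]] = {}
    for off, code in _scan_codes(qseq[a.qstart : a.qend], k):
        if code in t_single:
            q_by_code.setdefault(code, []).append(a.qstart + off)
    candidates = [
        (qpos[0], t_single[code], code)
        for code, qpos in q_by_code.items()
        if len(qpos) == 1
    ]
    chained = chain_candidates(
        [(q, t) for q, t, _ in candidates], strand=a.strand
    )
    code_of = {(q, t): c for q, t, c in candidates}
    matches = [KmerMatch(qpos=q, tpos=t, code=code_of[(q, t)]) for q, t in chained]
    matches.sort(key=lambda m: m.tpos)
    return matches


def chain_candidates(
    candidates: list[tuple[int, int]], strand: str = "+"
) -> list[tuple[int, int]]:
    """Longest strictly monotone chain of (qpos, tpos) anchor pairs.

    On + both coordinates must strictly increase along the chain; on - the
    target increases while the query decreases. Ties between equal-length
    chains are broken toward the earliest query positions, deterministically.
    """
    if not candidates:
        return []
    cand = sorted(candidates)  # by (qpos, tpos)
    n = len(cand)
    if strand == "+":
        def compat(j: int, i: int) -> bool:
            return cand[j][0] < cand[i][0] and cand[j][1] < cand[i][1]
    else:
        def compat(j: int, i: int) -> bool:
            # walking in increasing qpos means tpos must strictly decrease
            return cand[j][0] < cand[i][0] and cand[j][1] > cand[i][1]

    best = [1] * n
    pred = [-1] * n
    for i in range(n):
        for j in range(i):
            if compat(j, i) and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                pred[i] = j  # first j attaining the max wins: earliest qpos
    end = max(range(n), key=lambda i: (best[i], -cand[i][0], -cand[i][1]))
    chain = []
    while end != -1:
        chain.append(cand[end])
        end = pred[end]
    return chain[::-1]


def score_alignments(
    paf: list[PafAlignment],
    target_genome: GenomeSequences,
    query_seqs: GenomeSequences,
    index: RareKmerIndex,
    params: KmerParams | None = None,
) -> list[ScoredAlignment]:
    """Score every alignment, preserving input order.

    Uses the CIGAR path when the record carries ``cg:Z``, the anchored path
    otherwise. Query sequences are looked up in ``query_seqs`` first, then in
    ``target_genome`` (genome self-alignments are legitimate input).
    """
    scored = []
    for a in paf:
        tseq = _resolve(a.tname, target_genome, query_seqs)
        qseq = _resolve(a.qname, query_seqs, target_genome)
        e = expected_matches(a, index)
        if a.cigar is not None:
            matches = find_matches_cigar(a, qseq, tseq, index, params)
            method = "cigar"
        else:
            matches = find_matches_anchored(a, qseq, tseq, index, params)
            method = "anchored"
        scored.append(ScoredAlignment.build(a, matches, e, method))
    return scored


def _resolve(seq_id: str, primary: GenomeSequences, fallback: GenomeSequences) -> str:
    if seq_id in primary:
        return primary.sequence(seq_id)
    if seq_id in fallback:
        return fallback.sequence(seq_id)
    raise MissingSequenceError(f"no sequence available for id {seq_id!r}")


def filter_alignments(
    scored: list[ScoredAlignment], min_mapq: int = 0, min_kmapq: int = 0
) -> tuple[list[ScoredAlignment], list[ScoredAlignment]]:
    """Split alignments into (kept, removed) by the two quality scores.

    Kept iff ``mapq >= min_mapq`` and ``kmapq >= min_kmapq``. Uninformative
    alignments (e = 0, no markers to adjudicate) bypass the KMAPQ threshold:
    they are kept — carrying their flag — rather than silently removed.
    """
    if not (0 <= min_mapq <= 255):
        raise ValueError(f"min_mapq {min_mapq} outside [0,255]")
    if not (0 <= min_kmapq <= KMAPQ_MAX):
        raise ValueError(f"min_kmapq {min_kmapq} outside [0,{KMAPQ_MAX}]")
    kept, removed = [], []
    for s in scored:
        ok_mapq = s.alignment.mapq >= min_mapq
        ok_kmapq = s.uninformative or s.kmapq >= min_kmapq
        (kept if ok_mapq and ok_kmapq else removed).append(s)
    return kept, removed


def write_filtered_paf(
    kept: list[ScoredAlignment], removed: list[ScoredAlignment], path
) -> None:
    """Write kept records to ``path`` and removed ones to a sibling
    ``.removed.paf``, each with ``km:i`` (KMAPQ) and ``ke:i`` (expected
    markers) tags appended."""
    path = str(path)
    base = path[: -len(".paf")] if path.endswith(".paf") else path
    write_paf([_tagged(s) for s in kept], path)
    write_paf([_tagged(s) for s in removed], base + ".removed.paf")


def _tagged(s: ScoredAlignment) -> PafAlignment:
    return s.alignment.with_tags(("km", "i", str(s.kmapq)), ("ke", "i", str(s.e)))
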