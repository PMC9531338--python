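"""Independent brute-force oracles and random-input generators for the tests.

Everything here deliberately avoids the package's own rolling-code scanner,
block-based projection and chaining code paths: counting is by string slicing
into a dictionary, projection is a per-base CIGAR expansion, and chaining is
exhaustive subset enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np

from raremark.alignment import PafAlignment, parse_cigar

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = "ACGT"


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_kmer_counts(seqs: list[str], k: int, canonical: bool = True) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            key = min(w, rc(w)) if canonical else w
            counts[key] = counts.get(key, 0) + 1
    return counts


def naive_rare_positions(
    seqs: dict[str, str], k: int, max_count: int
) -> dict[str, list[int]]:
    counts = naive_kmer_counts(list(seqs.values()), k)
    out: dict[str, list[int]] = {}
    for sid, seq in seqs.items():
        out[sid] = [
            i
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
            and counts[min(seq[i : i + k], rc(seq[i : i + k]))] <= max_count
        ]
    return out


def random_genome(rng: np.random.Generator, n: int, n_prob: float = 0.0) -> str:
    out = []
    for b in rng.integers(0, 4, size=n):
        if n_prob and rng.random() < n_prob:
            out.append("N")
        else:
            out.append(BASES[b])
    return "".join(out)


def coordinate_pairs(a: PafAlignment) -> list[tuple[int, int]]:
    """All aligned (original-strand query pos, target pos) pairs, by per-base
    CIGAR expansion — an independent re-statement of the projection contract."""
    qf = a.qstart if a.strand == "+" else a.qlen - a.qend
    t = a.tstart
    pairs = []
    for length, op in parse_cigar(a.cigar):
        for _ in range(length):
            if op in "M=X":
                qp = qf if a.strand == "+" else a.qlen - 1 - qf
                pairs.append((qp, t))
                qf += 1
                t += 1
            elif op == "I":
                qf += 1
            else:
                t += 1
    return pairs


def brute_force_matches(
    a: PafAlignment, qseq: str, tseq: str, rare_positions: list[int], k: int
) -> list[tuple[int, int]]:
    """(qpos, tpos) matches by projecting every rare target window per base."""
    t2q = dict((t, q) for q, t in coordinate_pairs(a))
    out = []
    for p in rare_positions:
        if not (a.tstart <= p and p + k <= a.tend):
            continue
        qps = [t2q.get(p + i) for i in range(k)]
        if any(q is None for q in qps):
            continue
        if a.strand == "+":
            if qps != list(range(qps[0], qps[0] + k)):
                continue
            qpos = qps[0]
            if qseq[qpos : qpos + k] == tseq[p : p + k]:
                out.append((qpos, p))
        else:
            if qps != list(range(qps[0], qps[0] - k, -1)):
                continue
            qpos = qps[-1]
            if rc(qseq[qpos : qpos + k]) == tseq[p : p + k]:
                out.append((qpos, p))
    return sorted(out, key=lambda m: m[1])


def brute_force_chains(
    candidates: list[tuple[int, int]], strand: str
) -> list[list[tuple[int, int]]]:
    """All maximum-length strictly monotone chains, by subset enumeration."""
    best: list[list[tuple[int, int]]] = []
    for r in range(len(candidates), 0, -1):
        for combo in itertools.combinations(sorted(candidates), r):
            qs = [c[0] for c in combo]
            ts = [c[1] for c in combo]
            inc_q = all(x < y for x, y in zip(qs, qs[1:]))
            inc_t = all(x < y for x, y in zip(ts, ts[1:]))
            dec_t = all(x > y for x, y in zip(ts, ts[1:]))
            if strand == "+" and inc_q and inc_t:
                best.append(list(combo))
            if strand == "-" and inc_q and dec_t:
                best.append(list(combo))
        if best:
            return best
    return [[]]


def random_alignment(
    rng: np.random.Generator, *, ops: str = "=XID", max_runs: int = 12
) -> tuple[PafAlignment, str, str]:
    """A random consistent (alignment, query seq, target seq) triple.

    The target is random; the query is derived by walking the CIGAR (copy on
    '=', mutate on 'X', insert on 'I', skip on 'D'), then reverse-complemented
    for minus-strand records, with random padding outside [qstart, qend).
    """
    n_runs = int(rng.integers(1, max_runs + 1))
    runs: list[tuple[int, str]] = []
    for i in range(n_runs):
        if i == 0 or i == n_runs - 1:
            op = "="
        else:
            op = ops[int(rng.integers(0, len(ops)))]
            if runs and runs[-1][1] == op:
                op = "="
        runs.append((int(rng.integers(1, 30)), op))
    tlen_consumed = sum(n for n, op in runs if op in "=XMDN")
    tstart = int(rng.integers(0, 20))
    tpad_right = int(rng.integers(0, 20))
    tseq = random_genome(rng, tstart + tlen_consumed + tpad_right)

    qf_parts = []
    t = tstart
    for length, op in runs:
        if op in "=M":
            qf_parts.append(tseq[t : t + length])
            t += length
        elif op == "X":
            for i in range(length):
                ref = tseq[t + i]
                alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
                qf_parts.append(alt)
            t += length
        elif op == "I":
            qf_parts.append(random_genome(rng, length))
        else:
            t += length
    qf_core = "".join(qf_parts)
    pad_l = int(rng.integers(0, 15))
    pad_r = int(rng.integers(0, 15))
    qf_full = random_genome(rng, pad_l) + qf_core + random_genome(rng, pad_r)
    qlen = len(qf_full)
    qs_f, qe_f = pad_l, pad_l + len(qf_core)

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        qseq, qstart, qend = qf_full, qs_f, qe_f
    else:
        qseq, qstart, qend = rc(qf_full), qlen - qe_f, qlen - qs_f
    cigar = "".join(f"{n}{op}" for n, op in runs)
    n_eq = sum(n for n, op in runs if op == "=")
    a = PafAlignment(
        qname="q",
        qlen=qlen,
        qstart=qstart,
        qend=qend,
        strand=strand,
        tname="t",
        tlen=len(tseq),
        tstart=tstart,
        tend=t,
        n_match=n_eq,
        aln_len=sum(n for n, _ in runs),
        mapq=int(rng.integers(0, 61)),
        tags=(("cg", "Z", cigar),),
    )
    a.validate()
    return a, qseq, tseq
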