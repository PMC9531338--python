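"""Synthetic repeat genomes with ground truth, for hermetic end-to-end testing.

The scenario being emulated: a genome contains several near-identical copies of
an interspersed repeat, differing only by sparse substitutions (and optionally
1-bp indels); a contig sampled from one copy aligns convincingly to *every*
copy, all with maximal aligner MAPQ. Only the copy-specific rare k-mers reveal
which alignment is real.

The simulator plants ``n_copies`` mutated instances of one random ancestral
repeat into an i.i.d. uniform A/C/G/T background, records every edit, extracts
a contig from a chosen copy (optionally reverse-complemented), and emits truth
PAF records — one per copy, with exact CIGAR and NM computed from the edit
lists, MAPQ fixed at 60 on all records to reproduce the "aligner quality is
uninformative here" premise. No external aligner is involved, so tests are
fully reproducible from the seed.

Edit positions are drawn disjoint across copies, which makes pairwise
differences exactly the union of the two copies' edit lists and keeps truth
CIGARs/NM values exactly recomputable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .alignment import PafAlignment
from .kmer_index import GenomeSequences, revcomp

__all__ = [
    "Edit",
    "RepeatSimConfig",
    "RepeatTruth",
    "simulate_repeat_genome",
    "extract_contig",
    "emit_truth_paf",
    "simulate_scenario",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Edit:
    """One planted edit in ancestor coordinates.

    ``kind``: 'sub' (replace base), 'ins' (insert ``alt`` after position
    ``pos``), 'del' (remove the base at ``pos``).
    """

    pos: int
    kind: str
    ref: str
    alt: str


@dataclass(frozen=True)
class RepeatSimConfig:
    """Study conditions for one simulated repeat scenario.

    Defaults model an interspersed repeat at the scale where aligner MAPQ
    stops being informative: two 2.8 kb copies at 1% pairwise divergence,
    substitutions only, inside a 20 kb genome.
    """

    seed: int = 0
    genome_length: int = 20_000
    n_copies: int = 2
    copy_length: int = 2_800
    divergence: float = 0.01  # expected pairwise substitutions per bp
    indel_rate: float = 0.0  # expected 1-bp indels per bp, per copy
    contig_source_copy: int = 0
    contig_offset: int = 0
    contig_length: int | None = None  # None = to the end of the copy
    contig_strand: str = "+"
    genome_id: str = "genome1"
    contig_id: str = "contig1"

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("n_copies must be >= 2 (a repeat needs copies)")
        if not (0 <= self.divergence < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.copy_length < 1 or self.genome_length < 1:
            raise ValueError("lengths must be positive")
        if self.contig_strand not in "+-":
            raise ValueError("contig_strand must be + or -")
        if not (0 <= self.contig_source_copy < self.n_copies):
            raise ValueError("contig_source_copy out of range")


@dataclass
class RepeatTruth:
    """Ground truth of a simulated scenario."""

    ancestor: str
    copies: list[tuple[int, int]]  # genome coordinates of each planted copy
    edits: list[list[Edit]]  # per copy, sorted by ancestor position
    contig: tuple[int, tuple[int, int], str] | None = None  # (copy, local iv, strand)

    def copy_sequence(self, genome: GenomeSequences, genome_id: str, i: int) -> str:
        s, e = self.copies[i]
        return genome.sequence(genome_id)[s:e]

    def to_json(self, path) -> None:
        doc = {
            "ancestor": self.ancestor,
            "copies": self.copies,
            "edits": [[asdict(e) for e in lst] for lst in self.edits],
            "contig": self.contig,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RepeatTruth":
        with open(path) as fh:
            doc = json.load(fh)
        contig = doc["contig"]
        if contig is not None:
            contig = (contig[0], tuple(contig[1]), contig[2])
        return cls(
            ancestor=doc["ancestor"],
            copies=[tuple(c) for c in doc["copies"]],
            edits=[[Edit(**e) for e in lst] for lst in doc["edits"]],
            contig=contig,
        )


def apply_edits(ancestor: str, edits: list[Edit]) -> str:
    """Rebuild a copy from the ancestor and its edit list."""
    sub = {e.pos: e.alt for e in edits if e.kind == "sub"}
    ins = {e.pos: e.alt for e in edits if e.kind == "ins"}
    dels = {e.pos for e in edits if e.kind == "del"}
    out = []
    for i, ch in enumerate(ancestor):
        if i not in dels:
            out.append(sub.get(i, ch))
        if i in ins:
            out.append(ins[i])
    return "".join(out)


def _copy_coord_map(anc_len: int, edits: list[Edit]) -> list[int]:
    """ancestor position -> copy-local position (-1 where deleted)."""
    ins_after = {e.pos for e in edits if e.kind == "ins"}
    dels = {e.pos for e in edits if e.kind == "del"}
    cmap = []
    c = 0
    for i in range(anc_len):
        if i in dels:
            cmap.append(-1)
        else:
            cmap.append(c)
            c += 1
        if i in ins_after:
            c += 1
    return cmap


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, size=n))


def simulate_repeat_genome(
    config: RepeatSimConfig,
) -> tuple[GenomeSequences, RepeatTruth]:
    """Plant ``n_copies`` mutated instances of one ancestral repeat into a
    random background genome; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    anc = _random_seq(rng, config.copy_length)

    # disjoint edit positions across copies: pairwise Hamming distance equals
    # the union of the two edit lists, and per-copy substitution rate
    # divergence/2 gives the configured expected pairwise divergence
    pool = list(rng.permutation(config.copy_length))
    edits: list[list[Edit]] = []
    for _ in range(config.n_copies):
        n_sub = int(rng.binomial(config.copy_length, config.divergence / 2))
        n_indel = int(rng.binomial(config.copy_length, config.indel_rate))
        if n_sub + n_indel > len(pool):
            raise ValueError(
                "edit rates too high for disjoint placement across copies"
            )
        copy_edits = []
        for _ in range(n_sub):
            p = int(pool.pop())
            ref = anc[p]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            copy_edits.append(Edit(pos=p, kind="sub", ref=ref, alt=alt))
        for _ in range(n_indel):
            p = int(pool.pop())
            if rng.random() < 0.5:
                copy_edits.append(
                    Edit(pos=p, kind="ins", ref="", alt=_BASES[int(rng.integers(0, 4))])
                )
            else:
                copy_edits.append(Edit(pos=p, kind="del", ref=anc[p], alt=""))
        copy_edits.sort(key=lambda e: e.pos)
        edits.append(copy_edits)

    copy_seqs = [apply_edits(anc, el) for el in edits]
    total_copy = sum(len(s) for s in copy_seqs)
    free = config.genome_length - total_copy
    if free < 0:
        raise ValueError(
            f"copies ({total_copy} bp) cannot be placed in a "
            f"{config.genome_length} bp genome without overlap"
        )
    gaps = rng.multinomial(free, [1.0 / (config.n_copies + 1)] * (config.n_copies + 1))
    background = _random_seq(rng, free)

    parts = []
    coords = []
    cursor = 0  # genome coordinate
    bg_cursor = 0
    for i, cseq in enumerate(copy_seqs):
        g = int(gaps[i])
        parts.append(background[bg_cursor : bg_cursor + g])
        bg_cursor += g
        cursor += g
        coords.append((cursor, cursor + len(cseq)))
        parts.append(cseq)
        cursor += len(cseq)
    parts.append(background[bg_cursor:])
    genome = GenomeSequences([(config.genome_id, "".join(parts))])
    truth = RepeatTruth(ancestor=anc, copies=coords, edits=edits)
    return genome, truth


def extract_contig(
    genome: GenomeSequences, truth: RepeatTruth, config: RepeatSimConfig
) -> GenomeSequences:
    """Sample the contig from its source copy; records provenance in truth."""
    ci = config.contig_source_copy
    cs, ce = truth.copies[ci]
    copy_len = ce - cs
    offset = config.contig_offset
    length = config.contig_length if config.contig_length is not None else copy_len - offset
    if not (0 <= offset and offset + length <= copy_len and length > 0):
        raise ValueError(
            f"contig interval [{offset},{offset + length}) outside copy of "
            f"length {copy_len}"
        )
    seq = genome.sequence(config.genome_id)[cs + offset : cs + offset + length]
    if config.contig_strand == "-":
        seq = revcomp(seq)
    truth.contig = (ci, (offset, offset + length), config.contig_strand)
    return GenomeSequences([(config.contig_id, seq)])


def emit_truth_paf(
    genome: GenomeSequences,
    truth: RepeatTruth,
    contig: GenomeSequences,
    config: RepeatSimConfig,
) -> list[PafAlignment]:
    """Truth alignments of the contig to the homologous interval of EVERY copy.

    CIGAR and NM are composed exactly from the edit lists through the ancestor
    coordinate system; MAPQ is 60 on every record (the ambiguous-repeat
    premise: aligner quality cannot distinguish the copies).
    """
    if truth.contig is None:
        raise ValueError("extract_contig must be called before emit_truth_paf")
    src, (lo, hi), strand = truth.contig
    contig_id, contig_seq = contig.records[0]
    qlen = len(contig_seq)
    anc_len = len(truth.ancestor)
    tlen = len(genome.sequence(config.genome_id))

    a_map = _copy_coord_map(anc_len, truth.edits[src])
    a_sub = {e.pos: e.alt for e in truth.edits[src] if e.kind == "sub"}
    a_ins = {e.pos: e.alt for e in truth.edits[src] if e.kind == "ins"}
    # ancestor positions whose copy-local image falls in the contig window
    anc_positions = [p for p in range(anc_len) if a_map[p] != -1 and lo <= a_map[p] < hi]
    if not anc_positions:
        raise ValueError("contig window contains no ancestor-derived bases")
    anc_first, anc_last = anc_positions[0], anc_positions[-1]

    records = []
    for b in range(len(truth.copies)):
        b_map = _copy_coord_map(anc_len, truth.edits[b])
        b_sub = {e.pos: e.alt for e in truth.edits[b] if e.kind == "sub"}
        b_ins = {e.pos: e.alt for e in truth.edits[b] if e.kind == "ins"}
        b_del = {e.pos for e in truth.edits[b] if e.kind == "del"}
        a_del = {e.pos for e in truth.edits[src] if e.kind == "del"}

        # columns: (op, a_local, b_local); locals are -1 when not consumed
        cols: list[tuple[str, int, int]] = []
        nm = 0
        n_match = 0
        b_cursor = None
        for p in range(anc_first, anc_last + 1):
            a_has = p not in a_del
            b_has = p not in b_del
            if a_has and b_has:
                base_a = a_sub.get(p, truth.ancestor[p])
                base_b = b_sub.get(p, truth.ancestor[p])
                if base_a != base_b:
                    nm += 1
                else:
                    n_match += 1
                cols.append(("M", a_map[p], b_map[p]))
            elif a_has:
                nm += 1
                cols.append(("I", a_map[p], -1))
            elif b_has:
                nm += 1
                cols.append(("D", -1, b_map[p]))
            # insertions attached after p; edit positions are disjoint across
            # copies, so both fire together only when b is the source copy
            # itself (the same insertion on both sides: an aligned column)
            if p == anc_last:
                continue  # trailing indels are outside the alignment
            a_local = a_map[p] + 1 if p in a_ins and a_map[p] != -1 else -1
            a_fires = a_local != -1 and lo <= a_local < hi
            b_fires = p in b_ins
            if a_fires and b_fires:
                if a_ins[p] == b_ins[p]:
                    n_match += 1
                else:
                    nm += 1
                cols.append(("M", a_local, b_map[p] + 1))
            elif a_fires:
                nm += 1
                cols.append(("I", a_local, -1))
            elif b_fires:
                nm += 1
                cols.append(("D", -1, b_map[p] + 1))

        # trim boundary indel columns (alignments must start/end aligned)
        while cols and cols[0][0] != "M":
            op, _, _ = cols.pop(0)
            nm -= 1
        while cols and cols[-1][0] != "M":
            cols.pop()
            nm -= 1
        if not cols:
            raise ValueError("no aligned columns between contig and copy")

        qs_local = cols[0][1]  # slice-frame (copy-local minus lo applied below)
        qe_local = next(c[1] for c in reversed(cols) if c[1] != -1) + 1
        ts_local = next(c[2] for c in cols if c[2] != -1)
        te_local = next(c[2] for c in reversed(cols) if c[2] != -1) + 1
        qs_f, qe_f = qs_local - lo, qe_local - lo  # frame = contig as sequenced from +
        if strand == "+":
            qstart, qend = qs_f, qe_f
        else:
            qstart, qend = qlen - qe_f, qlen - qs_f
        tstart = truth.copies[b][0] + ts_local
        tend = truth.copies[b][0] + te_local

        cigar = _runs_to_cigar([op for op, _, _ in cols])
        rec = PafAlignment(
            qname=contig_id,
            qlen=qlen,
            qstart=qstart,
            qend=qend,
            strand=strand,
            tname=config.genome_id,
            tlen=tlen,
            tstart=tstart,
            tend=tend,
            n_match=n_match,
            aln_len=len(cols),
            mapq=60,
            tags=(("NM", "i", str(nm)), ("cg", "Z", cigar)),
        )
        rec.validate()
        records.append(rec)
    return records


def _runs_to_cigar(ops: list[str]) -> str:
    runs = []
    for op in ops:
        if runs and runs[-1][1] == op:
            runs[-1][0] += 1
        else:
            runs.append([1, op])
    return "".join(f"{n}{op}" for n, op in runs)


def simulate_scenario(
    config: RepeatSimConfig,
) -> tuple[GenomeSequences, RepeatTruth, GenomeSequences, list[PafAlignment]]:
    """Convenience: genome + truth + contig + truth PAF in one call."""
    genome, truth = simulate_repeat_genome(config)
    contig = extract_contig(genome, truth, config)
    paf = emit_truth_paf(genome, truth, contig, config)
    return genome, truth, contig, paf
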