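"""Rare k-mer indexing over genome sequences.

Near-identical repeat copies defeat alignment-level mapping quality: a read or
contig aligns equally well to every copy. K-mers that occur at most ``max_count``
times in the whole target genome ("rare" k-mers; "unique" when ``max_count`` is 1)
act as copy-specific markers — inside a repeat family, the only rare k-mers are
the windows that overlap a position where the copies differ. This module counts
canonical k-mers genome-wide, selects the rare ones, and indexes their positions
for interval queries by downstream scoring.

Coordinates are 0-based, half-open throughout. Counting is canonical by default
(a k-mer and its reverse complement share one key) so that markers survive
minus-strand alignments. Windows containing ``N`` are never counted or indexed.
"""

from __future__ import annotations

import gzip
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "AmbiguousKmerError",
    "DuplicateIdError",
    "GenomeSequences",
    "KmerParams",
    "RareKmerIndex",
    "read_fasta",
    "revcomp",
    "canonical_kmer",
    "kmer_code",
    "canonical_code",
    "code_to_kmer",
    "count_kmers",
    "build_rare_index",
    "rare_in_interval",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEC = "ACGT"


class AmbiguousKmerError(ValueError):
    """A k-mer window contains an ambiguous base (N) and cannot be encoded."""


class DuplicateIdError(ValueError):
    """Two FASTA records share an identifier."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerParams:
    """Marker-selection parameters.

    Parameters
    ----------
    k : window length in bp. 21 is a standard marker size at which almost every
        non-repetitive window of a eukaryote-sized genome is unique. Capped at
        31 so a 2-bit encoding fits in 62 bits.
    max_count : rarity threshold R; a k-mer is rare when its genome-wide
        canonical count is <= R. R=1 selects unique k-mers.
    canonical : count a k-mer and its reverse complement as one key.
    """

    k: int = 21
    max_count: int = 1
    canonical: bool = True

    def __post_init__(self) -> None:
        if not (2 <= self.k <= 31):
            raise ValueError(f"k must be in [2, 31], got {self.k}")
        if self.max_count < 1:
            raise ValueError(f"max_count must be >= 1, got {self.max_count}")


class GenomeSequences:
    """An ordered set of named DNA sequences (uppercase, over {A,C,G,T,N}).

    Lowercase input is uppercased; IUPAC ambiguity codes other than N are
    mapped to N; any non-alphabetic character is rejected.
    """

    def __init__(self, records: list[tuple[str, str]]):
        self.records: list[tuple[str, str]] = []
        self._by_id: dict[str, str] = {}
        for seq_id, seq in records:
            norm = self._normalize(seq_id, seq)
            if seq_id in self._by_id:
                raise DuplicateIdError(f"duplicate sequence id: {seq_id!r}")
            self._by_id[seq_id] = norm
            self.records.append((seq_id, norm))

    @staticmethod
    def _normalize(seq_id: str, seq: str) -> str:
        if not seq:
            raise ValueError(f"empty sequence for record {seq_id!r}")
        s = seq.upper()
        if not s.isalpha():
            bad = next(c for c in s if not c.isalpha())
            raise ValueError(f"record {seq_id!r}: invalid character {bad!r}")
        # non-ACGT IUPAC codes carry no usable k-mer information here
        cleaned = "".join(c if c in "ACGTN" else "N" for c in s)
        return cleaned

    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, seq_id: str) -> str:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id: {seq_id!r}") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSequences) and self.records == other.records

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.records}

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.records:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> GenomeSequences:
    """Read a FASTA file into :class:`GenomeSequences`.

    Record ids are the header token before the first whitespace. Duplicate ids
    and empty records are errors.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return GenomeSequences(records)


def kmer_code(kmer: str) -> int:
    """2-bit integer encoding (A=0, C=1, G=2, T=3) of a k-mer without N."""
    code = 0
    for ch in kmer:
        b = _ENC.get(ch)
        if b is None:
            raise AmbiguousKmerError(f"ambiguous base {ch!r} in k-mer {kmer!r}")
        code = (code << 2) | b
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_DEC[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Raises :class:`AmbiguousKmerError` if the k-mer contains N; callers skip
    such windows.
    """
    if "N" in kmer:
        raise AmbiguousKmerError(f"ambiguous base in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def canonical_code(kmer: str) -> int:
    """Integer code of the canonical form of ``kmer``.

    Because A<C<G<T matches the numeric base order, the numeric minimum of the
    forward and reverse-complement codes equals the lexicographic minimum.
    """
    fwd = kmer_code(kmer)
    return min(fwd, kmer_code(revcomp(kmer)))


def _scan_codes(seq: str, k: int, canonical: bool = True):
    """Yield ``(pos, code)`` for every N-free window of ``seq``, rolling."""
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = 0
    rc = 0
    valid = 0  # consecutive unambiguous bases ending at i
    for i, ch in enumerate(seq):
        b = _ENC.get(ch)
        if b is None:
            valid = 0
            fwd = 0
            rc = 0
            continue
        fwd = ((fwd << 2) | b) & mask
        rc = (rc >> 2) | ((3 - b) << shift)
        valid += 1
        if valid >= k:
            yield i - k + 1, (min(fwd, rc) if canonical else fwd)


def count_kmers(genome: GenomeSequences, params: KmerParams) -> dict[int, int]:
    """Count every N-free k-mer window in the genome under its canonical key."""
    counts: dict[int, int] = {}
    longest = max((len(s) for _, s in genome.records), default=0)
    if params.k > longest:
        warnings.warn(
            f"k={params.k} exceeds the longest sequence ({longest} bp); "
            "no k-mers counted",
            stacklevel=2,
        )
        return counts
    for _, seq in genome.records:
        for _, code in _scan_codes(seq, params.k, params.canonical):
            counts[code] = counts.get(code, 0) + 1
    return counts


@dataclass
class RareKmerIndex:
    """Positions of rare k-mers per sequence, with their canonical codes.

    ``positions[seq_id]`` is strictly increasing; ``codes[seq_id]`` is the
    parallel list of canonical integer codes (the k-mer string itself is never
    stored). ``genome_total_rare`` counts distinct rare k-mers genome-wide.
    """

    k: int
    max_count: int
    positions: dict[str, list[int]]
    codes: dict[str, list[int]]
    seq_lengths: dict[str, int]
    genome_total_rare: int
    _code_set: set[int] | None = field(default=None, repr=False, compare=False)

    def rare_code_set(self) -> set[int]:
        if self._code_set is None:
            s: set[int] = set()
            for lst in self.codes.values():
                s.update(lst)
            self._code_set = s
        return self._code_set

    def interval_entries(self, seq_id: str, start: int, end: int) -> list[tuple[int, int]]:
        """(position, code) pairs whose full window lies inside [start, end)."""
        pos = self._seq_positions(seq_id, start, end)
        lo = bisect_left(pos, start)
        hi = bisect_right(pos, end - self.k)
        codes = self.codes[seq_id]
        return [(pos[i], codes[i]) for i in range(lo, hi)]

    def _seq_positions(self, seq_id: str, start: int, end: int) -> list[int]:
        if seq_id not in self.positions:
            raise KeyError(f"sequence id {seq_id!r} not in index")
        length = self.seq_lengths[seq_id]
        if not (0 <= start <= end <= length):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {seq_id!r} "
                f"(length {length})"
            )
        return self.positions[seq_id]

    # --- persistence: plain TSV sidecar -----------------------------------

    def save(self, path) -> None:
        """Write the index as a TSV sidecar (`.rki`)."""
        with open(path, "w") as fh:
            fh.write(f"#rki\tk={self.k}\tR={self.max_count}\n")
            for seq_id in self.positions:
                fh.write(f"#seq\t{seq_id}\t{self.seq_lengths[seq_id]}\n")
            for seq_id, pos in self.positions.items():
                codes = self.codes[seq_id]
                for p, c in zip(pos, codes):
                    fh.write(f"{seq_id}\t{p}\t{c}\n")

    @classmethod
    def load(cls, path) -> "RareKmerIndex":
        opener = gzip.open if _is_gzip(path) else open
        with opener(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "#rki":
                raise ValueError(f"{path}: not a rare k-mer index file")
            kv = dict(part.split("=", 1) for part in header[1:])
            k = int(kv["k"])
            max_count = int(kv["R"])
            positions: dict[str, list[int]] = {}
            codes: dict[str, list[int]] = {}
            seq_lengths: dict[str, int] = {}
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "#seq":
                    seq_lengths[fields[1]] = int(fields[2])
                    positions.setdefault(fields[1], [])
                    codes.setdefault(fields[1], [])
                else:
                    sid, p, c = fields
                    positions[sid].append(int(p))
                    codes[sid].append(int(c))
        distinct: set[int] = set()
        for lst in codes.values():
            distinct.update(lst)
        return cls(k, max_count, positions, codes, seq_lengths, len(distinct))


def _is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def build_rare_index(genome: GenomeSequences, params: KmerParams) -> RareKmerIndex:
    """Select k-mers with genome-wide canonical count <= ``max_count`` and
    index every occurrence position."""
    counts = count_kmers(genome, params)
    positions: dict[str, list[int]] = {sid: [] for sid, _ in genome.records}
    codes: dict[str, list[int]] = {sid: [] for sid, _ in genome.records}
    rare_codes: set[int] = set()
    for seq_id, seq in genome.records:
        for pos, code in _scan_codes(seq, params.k, params.canonical):
            if counts[code] <= params.max_count:
                positions[seq_id].append(pos)
                codes[seq_id].append(code)
                rare_codes.add(code)
    return RareKmerIndex(
        k=params.k,
        max_count=params.max_count,
        positions=positions,
        codes=codes,
        seq_lengths=genome.lengths,
        genome_total_rare=len(rare_codes),
    )


def rare_in_interval(index: RareKmerIndex, seq_id: str, start: int, end: int) -> list[int]:
    """Sorted rare-k-mer start positions whose full window fits in [start, end)."""
    pos = index._seq_positions(seq_id, start, end)
    lo = bisect_left(pos, start)
    hi = bisect_right(pos, end - index.k)
    return pos[lo:hi]
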