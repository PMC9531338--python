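"""PAF alignment records and strand-aware CIGAR coordinate projection.

PAF (Pairwise mApping Format, the default minimap2 output) carries 12 mandatory
tab-separated columns plus SAM-style typed tags; the ``cg:Z`` tag holds a CIGAR
over the operators M/=/X (both sequences), I (query only) and D/N (target only).
Minus-strand convention follows minimap2: ``qstart``/``qend`` are coordinates on
the original query strand, while the CIGAR describes the reverse-complemented
query walked against the forward target.

Projection between query and target coordinates through the CIGAR is what lets
a k-mer match be placed on both sequence axes at base resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "PafFormatError",
    "CigarError",
    "MissingCigarError",
    "PafAlignment",
    "parse_cigar",
    "read_paf",
    "write_paf",
    "project_query_to_target",
    "project_target_to_query",
    "window_projectable",
]


class PafFormatError(ValueError):
    """A PAF line or record violates the format contract."""


class CigarError(ValueError):
    """A CIGAR string is malformed or uses an unsupported operator."""


class MissingCigarError(ValueError):
    """An operation requiring base-level projection was called without cg:Z."""


_CIGAR_RE = re.compile(r"(\d+)([A-Za-z=])")
_QUERY_OPS = frozenset("M=XI")
_TARGET_OPS = frozenset("M=XDN")
_ALL_OPS = _QUERY_OPS | _TARGET_OPS


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) runs.

    Supported operators: M, =, X (consume both), I (query), D, N (target).
    Clip operators (S/H) are rejected: minimap2 PAF cg tags never carry clips.
    """
    runs = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in runs) != cigar or not runs:
        raise CigarError(f"malformed CIGAR: {cigar!r}")
    parsed = []
    for n, op in runs:
        if op not in _ALL_OPS:
            raise CigarError(f"unsupported CIGAR operator {op!r} in {cigar!r}")
        length = int(n)
        if length <= 0:
            raise CigarError(f"zero-length run in CIGAR {cigar!r}")
        parsed.append((length, op))
    return parsed


@dataclass(frozen=True)
class PafAlignment:
    """One PAF record: 12 mandatory fields plus optional typed tags.

    ``tags`` preserves input order and raw string values so that a parsed
    record writes back byte-identically.
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_match: int
    aln_len: int
    mapq: int
    tags: tuple[tuple[str, str, str], ...] = ()

    def tag(self, name: str) -> str | None:
        for tag, _, value in self.tags:
            if tag == name:
                return value
        return None

    @property
    def cigar(self) -> str | None:
        return self.tag("cg")

    @property
    def cigar_ops(self) -> list[tuple[int, str]]:
        cg = self.cigar
        if cg is None:
            raise MissingCigarError(
                f"record {self.qname}->{self.tname}: projection requires CIGAR (cg:Z tag)"
            )
        return parse_cigar(cg)

    @property
    def nm(self) -> int | None:
        v = self.tag("NM")
        return None if v is None else int(v)

    def with_tags(self, *extra: tuple[str, str, str]) -> "PafAlignment":
        """Copy with tags appended, replacing same-name tags already present."""
        names = {t[0] for t in extra}
        kept = tuple(t for t in self.tags if t[0] not in names)
        return replace(self, tags=kept + tuple(extra))

    def validate(self) -> None:
        ident = f"record {self.qname}->{self.tname}"
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise PafFormatError(
                f"{ident}: query interval [{self.qstart},{self.qend}) "
                f"invalid for length {self.qlen}"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise PafFormatError(
                f"{ident}: target interval [{self.tstart},{self.tend}) "
                f"invalid for length {self.tlen}"
            )
        if self.strand not in "+-":
            raise PafFormatError(f"{ident}: strand must be + or -, got {self.strand!r}")
        if not (0 <= self.mapq <= 255):
            raise PafFormatError(f"{ident}: mapq {self.mapq} outside [0,255]")
        if self.cigar is not None:
            ops = self.cigar_ops
            qlen = sum(n for n, op in ops if op in _QUERY_OPS)
            tlen = sum(n for n, op in ops if op in _TARGET_OPS)
            if qlen != self.qend - self.qstart:
                raise PafFormatError(
                    f"{ident}: CIGAR consumes {qlen} query bases but interval "
                    f"spans {self.qend - self.qstart}"
                )
            if tlen != self.tend - self.tstart:
                raise PafFormatError(
                    f"{ident}: CIGAR consumes {tlen} target bases but interval "
                    f"spans {self.tend - self.tstart}"
                )

    # --- serialization -----------------------------------------------------

    def to_line(self) -> str:
        cols = [
            self.qname,
            str(self.qlen),
            str(self.qstart),
            str(self.qend),
            self.strand,
            self.tname,
            str(self.tlen),
            str(self.tstart),
            str(self.tend),
            str(self.n_match),
            str(self.aln_len),
            str(self.mapq),
        ]
        cols.extend(f"{tag}:{typ}:{val}" for tag, typ, val in self.tags)
        return "\t".join(cols)

    @classmethod
    def from_line(cls, line: str, lineno: int | None = None) -> "PafAlignment":
        where = f"line {lineno}: " if lineno is not None else ""
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise PafFormatError(
                f"{where}expected >=12 tab-separated columns, got {len(fields)}"
            )
        try:
            rec = cls(
                qname=fields[0],
                qlen=int(fields[1]),
                qstart=int(fields[2]),
                qend=int(fields[3]),
                strand=fields[4],
                tname=fields[5],
                tlen=int(fields[6]),
                tstart=int(fields[7]),
                tend=int(fields[8]),
                n_match=int(fields[9]),
                aln_len=int(fields[10]),
                mapq=int(fields[11]),
                tags=tuple(_parse_tag(f, where) for f in fields[12:]),
            )
        except ValueError as exc:
            if isinstance(exc, PafFormatError):
                raise
            raise PafFormatError(f"{where}non-integer mandatory column ({exc})") from None
        try:
            rec.validate()
        except (PafFormatError, CigarError) as exc:
            raise PafFormatError(f"{where}{exc}") from None
        return rec


def _parse_tag(raw: str, where: str) -> tuple[str, str, str]:
    parts = raw.split(":", 2)
    if len(parts) != 3 or not parts[0] or not parts[1]:
        raise PafFormatError(f"{where}malformed tag {raw!r}")
    return (parts[0], parts[1], parts[2])


def read_paf(path) -> list[PafAlignment]:
    """Read a PAF file; every record is validated (including CIGAR/interval
    length consistency when cg:Z is present)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            records.append(PafAlignment.from_line(line, lineno))
    return records


def write_paf(records, path) -> None:
    """Write PAF records; round-trips byte-identically through :func:`read_paf`."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


# --- coordinate projection --------------------------------------------------


def aligned_blocks(a: PafAlignment) -> list[tuple[int, int, int]]:
    """Co-linear blocks ``(q0, t0, length)`` of the alignment in CIGAR frame.

    The CIGAR-frame query coordinate runs over the original query for + strand
    and over the reverse-complemented query for - strand (minimap2 dialect);
    within a block, query and target advance together.
    """
    q = a.qstart if a.strand == "+" else a.qlen - a.qend
    t = a.tstart
    blocks: list[tuple[int, int, int]] = []
    for length, op in a.cigar_ops:
        if op in "M=X":
            # adjacent M/=/X runs are contiguous in both coordinates: merge,
            # so a block is a maximal indel-free stretch
            if blocks and blocks[-1][0] + blocks[-1][2] == q and blocks[-1][1] + blocks[-1][2] == t:
                q0, t0, l0 = blocks[-1]
                blocks[-1] = (q0, t0, l0 + length)
            else:
                blocks.append((q, t, length))
            q += length
            t += length
        elif op == "I":
            q += length
        else:  # D or N
            t += length
    return blocks


def _to_frame(a: PafAlignment, qp: int) -> int:
    """Original-strand query position -> CIGAR-frame position."""
    return qp if a.strand == "+" else a.qlen - 1 - qp


def project_query_to_target(a: PafAlignment, qp: int) -> int | None:
    """Target position aligned to query position ``qp``, or None if ``qp``
    falls inside an insertion (no target image).

    ``qp`` is on the original query strand; on - strand it is first mapped to
    the reverse-complement frame (``qlen - 1 - qp``) before walking the CIGAR.
    """
    if not (a.qstart <= qp < a.qend):
        raise ValueError(
            f"query position {qp} outside aligned interval [{a.qstart},{a.qend})"
        )
    qf = _to_frame(a, qp)
    for q0, t0, length in aligned_blocks(a):
        if q0 <= qf < q0 + length:
            return t0 + (qf - q0)
    return None  # inside an insertion


def project_target_to_query(a: PafAlignment, tp: int) -> int | None:
    """Original-strand query position aligned to target position ``tp``, or
    None if ``tp`` falls inside a deletion (no query image)."""
    if not (a.tstart <= tp < a.tend):
        raise ValueError(
            f"target position {tp} outside aligned interval [{a.tstart},{a.tend})"
        )
    for q0, t0, length in aligned_blocks(a):
        if t0 <= tp < t0 + length:
            qf = q0 + (tp - t0)
            return qf if a.strand == "+" else a.qlen - 1 - qf
    return None  # inside a deletion


def window_projectable(a: PafAlignment, qp: int, k: int) -> bool:
    """True iff query window [qp, qp+k) is fully aligned with no indel inside,
    i.e. all k positions map to consecutive target positions."""
    if not (a.qstart <= qp < a.qend):
        raise ValueError(
            f"query position {qp} outside aligned interval [{a.qstart},{a.qend})"
        )
    lo = qp if a.strand == "+" else a.qlen - qp - k
    for q0, _, length in aligned_blocks(a):
        if q0 <= lo and lo + k <= q0 + length:
            return True
    return False
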