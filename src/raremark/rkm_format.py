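"""The `.rkm` intermediate file: alignment areas, k-mer positions and matches.

Scoring a large PAF against a genome-scale k-mer index is the expensive step,
so its result is persisted once and re-read many times (to filter, to draw one
pair, to draw everything). The file is plain TSV:

* one header line ``H  k=<k>  R=<R>  version=<v>  target=<fasta name>``
* per alignment, one A-line (scores + the verbatim PAF fields) followed by
  exactly ``m`` K-lines, one per k-mer match, holding positions and the
  canonical integer code — never the k-mer string itself.

Two sidecar indexes, ``<file>.qidx`` and ``<file>.tidx``, map query and target
sequence ids to the byte offsets of the A-lines mentioning them, so all
alignments of one sequence are retrieved by seeking, without scanning the file.
Offsets (not line numbers) survive file copies and allow constant-time access.
Gzip-compressed ``.rkm`` files are accepted transparently on read.

Column orders are documented in FORMAT.md at the repository root.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

from . import __version__
from .alignment import PafAlignment
from .matching import KmerMatch, ScoredAlignment

__all__ = ["RkmFormatError", "RkmHeader", "write_rkm", "read_rkm", "lookup"]


class RkmFormatError(ValueError):
    """The file is not a valid .rkm document (corruption, wrong parameters)."""


@dataclass(frozen=True)
class RkmHeader:
    k: int
    max_count: int
    version: str
    target: str


def _open_maybe_gzip(path, binary: bool = False):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rb" if binary else "rt")
    return open(path, "rb" if binary else "r")


def write_rkm(
    scored: list[ScoredAlignment], path, *, k: int, max_count: int, target: str = ""
) -> tuple[str, str, str]:
    """Write scored alignments plus the two offset indexes.

    Returns the three paths written: ``(path, path + '.qidx', path + '.tidx')``.
    """
    path = str(path)
    qidx: dict[str, list[int]] = {}
    tidx: dict[str, list[int]] = {}
    with open(path, "wb") as fh:
        fh.write(
            f"H\tk={k}\tR={max_count}\tversion={__version__}\ttarget={target}\n".encode()
        )
        for s in scored:
            offset = fh.tell()
            a = s.alignment
            qidx.setdefault(a.qname, []).append(offset)
            tidx.setdefault(a.tname, []).append(offset)
            fh.write(
                (
                    f"A\t{s.m}\t{s.e}\t{s.kmapq}\t{int(s.uninformative)}\t{s.method}\t"
                    + a.to_line()
                    + "\n"
                ).encode()
            )
            for km in s.matches:
                fh.write(f"K\t{km.qpos}\t{km.tpos}\t{km.code}\n".encode())
    qpath, tpath = path + ".qidx", path + ".tidx"
    for idx_path, idx in ((qpath, qidx), (tpath, tidx)):
        with open(idx_path, "w") as fh:
            for seq_id in sorted(idx):
                for off in idx[seq_id]:
                    fh.write(f"{seq_id}\t{off}\n")
    return path, qpath, tpath


def read_header(path) -> RkmHeader:
    with _open_maybe_gzip(path) as fh:
        line = fh.readline().rstrip("\n")
    return _parse_header(line, path)


def _parse_header(line: str, path) -> RkmHeader:
    fields = line.split("\t")
    if not fields or fields[0] != "H":
        raise RkmFormatError(f"{path}: missing H header line")
    kv = dict(part.split("=", 1) for part in fields[1:])
    try:
        return RkmHeader(
            k=int(kv["k"]),
            max_count=int(kv["R"]),
            version=kv.get("version", ""),
            target=kv.get("target", ""),
        )
    except KeyError as exc:
        raise RkmFormatError(f"{path}: header missing field {exc}") from None


def _parse_a_line(fields: list[str], offset: int, path) -> ScoredAlignment:
    if len(fields) < 18:  # A + 5 score cols + 12 PAF cols
        raise RkmFormatError(f"{path}: truncated A-line at offset {offset}")
    m, e, km, uninf, method = (
        int(fields[1]),
        int(fields[2]),
        int(fields[3]),
        bool(int(fields[4])),
        fields[5],
    )
    paf = PafAlignment.from_line("\t".join(fields[6:]))
    return ScoredAlignment(
        alignment=paf,
        matches=[],
        m=m,
        e=e,
        kmapq=km,
        uninformative=uninf,
        method=method,
    )


def _read_blocks(
    fh,
    path,
    *,
    first_line: str | None = None,
    limit: int | None = None,
    base_offset: int = 0,
):
    """Parse consecutive A/K blocks from the current position of ``fh``.

    ``base_offset`` seeds the running byte offset used in corruption messages
    (tell() cannot be called while iterating a text file).
    """
    out: list[ScoredAlignment] = []
    pending: ScoredAlignment | None = None
    offset = base_offset

    def close(block: ScoredAlignment | None):
        if block is not None:
            if len(block.matches) != block.m:
                raise RkmFormatError(
                    f"{path}: K-line count {len(block.matches)} != m={block.m} "
                    f"near offset {offset} (truncated or corrupt)"
                )
            out.append(block)

    lines = iter(fh) if first_line is None else _chain_first(first_line, fh)
    for raw in lines:
        line = raw.rstrip("\n")
        if not line:
            offset += len(raw.encode())
            continue
        fields = line.split("\t")
        if fields[0] == "A":
            close(pending)
            if limit is not None and len(out) >= limit:
                return out
            pending = _parse_a_line(fields, offset, path)
        elif fields[0] == "K":
            if pending is None:
                raise RkmFormatError(f"{path}: K-line before any A-line")
            pending.matches.append(
                KmerMatch(qpos=int(fields[1]), tpos=int(fields[2]), code=int(fields[3]))
            )
        else:
            raise RkmFormatError(f"{path}: unknown record type {fields[0]!r}")
        offset += len(raw.encode())
    close(pending)
    return out


def _chain_first(first, rest):
    # plain loop, not `yield from`: delegation would propagate close() to the
    # underlying file when the generator is abandoned after an early return
    yield first
    for item in rest:
        yield item


def read_rkm(path, expect_k: int | None = None) -> list[ScoredAlignment]:
    """Read the whole document back; inverse of :func:`write_rkm`.

    ``expect_k`` cross-checks the header against the caller's k (e.g. the k of
    a separately built index) and refuses on mismatch.
    """
    with _open_maybe_gzip(path) as fh:
        raw = fh.readline()
        header = _parse_header(raw.rstrip("\n"), path)
        if expect_k is not None and header.k != expect_k:
            raise RkmFormatError(
                f"{path}: file was built with k={header.k}, requested k={expect_k}"
            )
        return _read_blocks(fh, path, base_offset=len(raw.encode()))


def lookup(path, role: str, seq_id: str) -> list[ScoredAlignment]:
    """All alignments mentioning ``seq_id`` as ``role`` ('query' or 'target'),
    retrieved by seeking to indexed byte offsets (never a full scan).

    An id absent from the index yields an empty list.
    """
    if role not in ("query", "target"):
        raise ValueError(f"role must be 'query' or 'target', got {role!r}")
    idx_path = str(path) + (".qidx" if role == "query" else ".tidx")
    offsets = []
    with open(idx_path) as fh:
        for line in fh:
            sid, off = line.rstrip("\n").split("\t")
            if sid == seq_id:
                offsets.append(int(off))
    if not offsets:
        return []
    out: list[ScoredAlignment] = []
    with _open_maybe_gzip(path) as fh:
        for off in offsets:
            fh.seek(off)
            first = fh.readline()
            if not first.startswith("A\t"):
                raise RkmFormatError(
                    f"{path}: index offset {off} does not point at an A-line"
                )
            blocks = _read_blocks(fh, path, first_line=first, limit=1, base_offset=off)
            out.extend(blocks)
    return out
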