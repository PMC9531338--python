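"""Static SVG rendering of alignments and their rare k-mer matching profiles.

Each figure shows horizontal sequence tracks; every kept alignment is a grey
quadrilateral spanning its query interval on one track and its target interval
on the other, and (optionally) one red segment per matching rare k-mer pair
connecting the two positions. On a minus-strand alignment the quadrilateral's
side edges cross, making inverted alignments visually obvious.

Three modes:

* ``pair`` — two sequence ids, all alignments between them;
* ``one_vs_all`` — one focal id, every partner on its own lane;
* ``global`` — every kept alignment, paginated ``per_page`` panels per page.

Output is deterministic SVG 1.1 text: a fixed 1200-unit-wide canvas, 80 units
per lane, linear bp scaling, no timestamps — identical input gives
byte-identical output. Zooming is a region parameter that rescales one track
and clips or drops elements, replacing interactive pan/zoom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .matching import ScoredAlignment, filter_alignments

__all__ = [
    "RenderOptions",
    "Track",
    "AlnArea",
    "MatchSeg",
    "Scene",
    "build_pair_scene",
    "build_one_vs_all_scene",
    "apply_zoom",
    "scene_to_svg",
    "render_pair",
    "render_one_vs_all",
    "render_global",
]

CANVAS_WIDTH = 1200.0
LANE_HEIGHT = 80.0
BAR_HEIGHT = 10.0
MARGIN_LEFT = 140.0
MARGIN_RIGHT = 30.0
MARGIN_TOP = 30.0
AREA_FILL = "#808080"
MATCH_STROKE = "#cc0000"


@dataclass(frozen=True)
class RenderOptions:
    """Drawing options shared by the three modes."""

    mode: str = "pair"
    show_kmers: bool = True
    min_mapq: int = 0
    min_kmapq: int = 0
    region: tuple[str, int, int] | None = None  # (seq_id, start, end) zoom
    per_page: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("pair", "one_vs_all", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.per_page < 1:
            raise ValueError("per_page must be >= 1")
        if self.region is not None and self.mode == "global":
            raise ValueError("region zoom is only valid in pair/one_vs_all modes")


@dataclass
class Track:
    seq_id: str
    length: int
    y: float
    label: str
    view: tuple[int, int]  # visible bp window [start, end)


@dataclass
class AlnArea:
    """One grey alignment quadrilateral between two tracks (bp coordinates)."""

    top: int  # track index
    bottom: int
    top_iv: tuple[int, int]
    bottom_iv: tuple[int, int]
    strand: str
    mapq: int
    kmapq: int
    uninformative: bool = False


@dataclass
class MatchSeg:
    """One red k-mer match segment between two tracks (bp coordinates)."""

    top: int
    bottom: int
    top_pos: int
    bottom_pos: int


@dataclass
class Scene:
    tracks: list[Track]
    areas: list[AlnArea]
    segs: list[MatchSeg]
    title: str = ""


# --- scene construction ------------------------------------------------------


def _lengths_of(scored: list[ScoredAlignment]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for s in scored:
        a = s.alignment
        lengths[a.qname] = a.qlen
        lengths[a.tname] = a.tlen
    return lengths


def _require_known(seq_id: str, lengths: dict[str, int]) -> None:
    if seq_id not in lengths:
        raise KeyError(f"unknown sequence id: {seq_id!r}")


def _track_y(i: int) -> float:
    return MARGIN_TOP + i * LANE_HEIGHT


def build_pair_scene(
    scored: list[ScoredAlignment], qname: str, tname: str, options: RenderOptions
) -> Scene:
    """Scene for all alignments with query ``qname`` and target ``tname``."""
    lengths = _lengths_of(scored)
    _require_known(qname, lengths)
    _require_known(tname, lengths)
    kept, _ = filter_alignments(scored, options.min_mapq, options.min_kmapq)
    tracks = [
        Track(qname, lengths[qname], _track_y(0), f"{qname} (query)", (0, lengths[qname])),
        Track(tname, lengths[tname], _track_y(1), f"{tname} (target)", (0, lengths[tname])),
    ]
    areas: list[AlnArea] = []
    segs: list[MatchSeg] = []
    for s in kept:
        a = s.alignment
        if a.qname != qname or a.tname != tname:
            continue
        idx = len(areas)
        areas.append(
            AlnArea(
                top=0,
                bottom=1,
                top_iv=(a.qstart, a.qend),
                bottom_iv=(a.tstart, a.tend),
                strand=a.strand,
                mapq=a.mapq,
                kmapq=s.kmapq,
                uninformative=s.uninformative,
            )
        )
        if options.show_kmers:
            segs.extend(
                MatchSeg(top=0, bottom=1, top_pos=km.qpos, bottom_pos=km.tpos)
                for km in s.matches
            )
    scene = Scene(tracks, areas, segs, title=f"{qname} vs {tname}")
    if options.region is not None:
        scene = apply_zoom(scene, options.region)
    return scene


def build_one_vs_all_scene(
    scored: list[ScoredAlignment], seq_id: str, options: RenderOptions
) -> Scene:
    """Scene with the focal sequence on top and one lane per (partner, role).

    A partner aligned to the focal sequence both as query and as target gets
    two lanes, labeled with the relation.
    """
    lengths = _lengths_of(scored)
    _require_known(seq_id, lengths)
    kept, _ = filter_alignments(scored, options.min_mapq, options.min_kmapq)
    related = [
        s for s in kept if seq_id in (s.alignment.qname, s.alignment.tname)
    ]
    # lane key: (partner id, partner role); sorted for deterministic layout
    lane_keys = sorted(
        {
            (
                s.alignment.tname if s.alignment.qname == seq_id else s.alignment.qname,
                "target" if s.alignment.qname == seq_id else "query",
            )
            for s in related
        }
    )
    tracks = [Track(seq_id, lengths[seq_id], _track_y(0), seq_id, (0, lengths[seq_id]))]
    lane_index: dict[tuple[str, str], int] = {}
    for i, (pid, role) in enumerate(lane_keys, start=1):
        lane_index[(pid, role)] = i
        tracks.append(
            Track(pid, lengths[pid], _track_y(i), f"{pid} (as {role})", (0, lengths[pid]))
        )
    areas: list[AlnArea] = []
    segs: list[MatchSeg] = []
    for s in related:
        a = s.alignment
        focal_is_query = a.qname == seq_id
        if focal_is_query:
            lane = lane_index[(a.tname, "target")]
            top_iv, bottom_iv = (a.qstart, a.qend), (a.tstart, a.tend)
        else:
            lane = lane_index[(a.qname, "query")]
            top_iv, bottom_iv = (a.tstart, a.tend), (a.qstart, a.qend)
        areas.append(
            AlnArea(
                top=0,
                bottom=lane,
                top_iv=top_iv,
                bottom_iv=bottom_iv,
                strand=a.strand,
                mapq=a.mapq,
                kmapq=s.kmapq,
                uninformative=s.uninformative,
            )
        )
        if options.show_kmers:
            for km in s.matches:
                tp, bp = (km.qpos, km.tpos) if focal_is_query else (km.tpos, km.qpos)
                segs.append(MatchSeg(top=0, bottom=lane, top_pos=tp, bottom_pos=bp))
    scene = Scene(tracks, areas, segs, title=f"{seq_id} vs all")
    if options.region is not None:
        scene = apply_zoom(scene, options.region)
    return scene


def apply_zoom(scene: Scene, region: tuple[str, int, int]) -> Scene:
    """Restrict the view of one track to ``region``; clip attached areas and
    drop elements wholly outside. Other tracks are unaffected."""
    seq_id, start, end = region
    track_idx = next(
        (i for i, t in enumerate(scene.tracks) if t.seq_id == seq_id), None
    )
    if track_idx is None:
        raise KeyError(f"region sequence {seq_id!r} is not drawn in this scene")
    track = scene.tracks[track_idx]
    start = max(0, start)
    end = min(track.length, end)
    if start >= end:
        warnings.warn(
            f"zoom region empty after clipping to {seq_id!r}; nothing to draw",
            stacklevel=2,
        )
        tracks = [replace(t) for t in scene.tracks]
        return Scene(tracks, [], [], scene.title)
    tracks = [
        replace(t, view=(start, end)) if i == track_idx else replace(t)
        for i, t in enumerate(scene.tracks)
    ]
    areas: list[AlnArea] = []
    for ar in scene.areas:
        if track_idx not in (ar.top, ar.bottom):
            areas.append(ar)
            continue
        iv = ar.top_iv if ar.top == track_idx else ar.bottom_iv
        lo, hi = max(iv[0], start), min(iv[1], end)
        if lo >= hi:
            continue  # wholly outside
        if ar.top == track_idx:
            areas.append(replace(ar, top_iv=(lo, hi)))
        else:
            areas.append(replace(ar, bottom_iv=(lo, hi)))
    segs = [
        sg
        for sg in scene.segs
        if track_idx not in (sg.top, sg.bottom)
        or start <= (sg.top_pos if sg.top == track_idx else sg.bottom_pos) < end
    ]
    return Scene(tracks, areas, segs, scene.title)


# --- SVG serialization -------------------------------------------------------


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _x(track: Track, pos: int) -> float:
    v0, v1 = track.view
    span = max(v1 - v0, 1)
    inner = CANVAS_WIDTH - MARGIN_LEFT - MARGIN_RIGHT
    return MARGIN_LEFT + (pos - v0) / span * inner


def scene_to_svg(scene: Scene) -> str:
    """Serialize a scene to deterministic SVG 1.1 text."""
    height = MARGIN_TOP + len(scene.tracks) * LANE_HEIGHT + MARGIN_TOP
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(CANVAS_WIDTH)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(CANVAS_WIDTH)} {_fmt(height)}">',
        f'<title>{_esc(scene.title)}</title>',
    ]
    for ar in scene.areas:
        top, bot = scene.tracks[ar.top], scene.tracks[ar.bottom]
        y_top = top.y + BAR_HEIGHT
        y_bot = bot.y
        xt_s, xt_e = _x(top, ar.top_iv[0]), _x(top, ar.top_iv[1])
        xb_s, xb_e = _x(bot, ar.bottom_iv[0]), _x(bot, ar.bottom_iv[1])
        if ar.strand == "+":
            # simple trapezoid: top L->R, bottom R->L
            pts = [(xt_s, y_top), (xt_e, y_top), (xb_e, y_bot), (xb_s, y_bot)]
        else:
            # crossed side edges signal the strand flip
            pts = [(xt_s, y_top), (xt_e, y_top), (xb_s, y_bot), (xb_e, y_bot)]
        points = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        out.append(
            f'<polygon class="aln-area" data-strand="{ar.strand}" '
            f'data-mapq="{ar.mapq}" data-kmapq="{ar.kmapq}" '
            f'points="{points}" fill="{AREA_FILL}" fill-opacity="0.45" stroke="none"/>'
        )
    for sg in scene.segs:
        top, bot = scene.tracks[sg.top], scene.tracks[sg.bottom]
        out.append(
            f'<line class="kmer-match" '
            f'x1="{_fmt(_x(top, sg.top_pos))}" y1="{_fmt(top.y + BAR_HEIGHT)}" '
            f'x2="{_fmt(_x(bot, sg.bottom_pos))}" y2="{_fmt(bot.y)}" '
            f'stroke="{MATCH_STROKE}" stroke-width="0.8"/>'
        )
    for t in scene.tracks:
        out.append(
            f'<rect class="track" x="{_fmt(MARGIN_LEFT)}" y="{_fmt(t.y)}" '
            f'width="{_fmt(CANVAS_WIDTH - MARGIN_LEFT - MARGIN_RIGHT)}" '
            f'height="{_fmt(BAR_HEIGHT)}" fill="#333333"/>'
        )
        out.append(
            f'<text class="label" x="5" y="{_fmt(t.y + BAR_HEIGHT)}" '
            f'font-family="monospace" font-size="11">{_esc(t.label)} '
            f"[{t.view[0]}-{t.view[1]}]</text>"
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _esc(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


# --- the three modes ---------------------------------------------------------


def render_pair(
    scored: list[ScoredAlignment], qname: str, tname: str, options: RenderOptions
) -> str:
    """SVG document of all alignments between two sequence ids."""
    return scene_to_svg(build_pair_scene(scored, qname, tname, options))


def render_one_vs_all(
    scored: list[ScoredAlignment], seq_id: str, options: RenderOptions
) -> str:
    """SVG document of all alignments related to one focal sequence id."""
    return scene_to_svg(build_one_vs_all_scene(scored, seq_id, options))


def render_global(scored: list[ScoredAlignment], options: RenderOptions) -> list[str]:
    """One SVG document per page of ``per_page`` alignment panels.

    Kept alignments are ordered by (target, target start, query, query start);
    each gets its own two-track panel.
    """
    kept, _ = filter_alignments(scored, options.min_mapq, options.min_kmapq)
    kept = sorted(
        kept,
        key=lambda s: (
            s.alignment.tname,
            s.alignment.tstart,
            s.alignment.qname,
            s.alignment.qstart,
        ),
    )
    if not kept:
        warnings.warn("no alignments pass the filters; no pages rendered", stacklevel=2)
        return []
    pages = []
    n_pages = math.ceil(len(kept) / options.per_page)
    for page in range(n_pages):
        chunk = kept[page * options.per_page : (page + 1) * options.per_page]
        tracks: list[Track] = []
        areas: list[AlnArea] = []
        segs: list[MatchSeg] = []
        for s in chunk:
            a = s.alignment
            i = len(tracks)
            tracks.append(
                Track(a.qname, a.qlen, _track_y(i), f"{a.qname} (query)", (0, a.qlen))
            )
            tracks.append(
                Track(a.tname, a.tlen, _track_y(i + 1), f"{a.tname} (target)", (0, a.tlen))
            )
            areas.append(
                AlnArea(
                    top=i,
                    bottom=i + 1,
                    top_iv=(a.qstart, a.qend),
                    bottom_iv=(a.tstart, a.tend),
                    strand=a.strand,
                    mapq=a.mapq,
                    kmapq=s.kmapq,
                    uninformative=s.uninformative,
                )
            )
            if options.show_kmers:
                segs.extend(
                    MatchSeg(top=i, bottom=i + 1, top_pos=km.qpos, bottom_pos=km.tpos)
                    for km in s.matches
                )
        pages.append(
            scene_to_svg(
                Scene(tracks, areas, segs, title=f"all alignments, page {page + 1}/{n_pages}")
            )
        )
    return pages
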