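"""Per-repertoire diversity and composition statistics.

D75 is the percentage of unique clonotypes needed to account for 75% of a
repertoire's reads — low values mean strong clonal focusing. The
accumulated top-N frequency is the cumulative read share of the N most
prevalent clonotypes. Both are computed at a declared aggregation level
(nucleotide clonotypes by default, amino-acid on request).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GdrepError, Repertoire
from .junctions import NonCanonicalJunctionError, cdr3_core_length


class EmptyResultError(GdrepError):
    pass


@dataclass(frozen=True)
class RankedClonotype:
    rank: int
    sequence: str
    count: int
    frequency: float
    cumulative: float


@dataclass
class RankedClonotypes:
    level: str  # "nt" | "aa"
    entries: list[RankedClonotype]

    @property
    def richness(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DiversityMetrics:
    d75: float
    top_n_accumulated: float
    richness: int
    level: str
    top_n: int = 10
    threshold: float = 0.75


def rank_clonotypes(repertoire: Repertoire, level: str = "nt") -> RankedClonotypes:
    """Clonotypes sorted by descending count, ties by ascending sequence.

    At ``aa`` level, nucleotide variants of the same amino-acid sequence
    are first merged with summed counts.
    """
    if not repertoire.records:
        raise EmptyResultError(f"{repertoire.donor_id}: empty repertoire")
    if level == "aa":
        counts = repertoire.aa_counts()
    elif level == "nt":
        counts = {r.junction_nt: r.read_count for r in repertoire.records}
        # records are unique on (nt, v, j); merge residual nt duplicates
        counts = {}
        for r in repertoire.records:
            counts[r.junction_nt] = counts.get(r.junction_nt, 0) + r.read_count
    else:
        raise ValueError(f"unknown level {level!r}")
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = []
    cum = 0
    for rank, (seq, count) in enumerate(ordered, start=1):
        cum += count
        entries.append(
            RankedClonotype(rank, seq, count, count / total, cum / total)
        )
    return RankedClonotypes(level=level, entries=entries)


def accumulated_top_n(ranked: RankedClonotypes, n: int = 10) -> float:
    """Percentage of reads occupied by the ``n`` most prevalent clonotypes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = min(n, ranked.richness) - 1
    return 100.0 * ranked.entries[idx].cumulative


def d75(ranked: RankedClonotypes, threshold: float = 0.75) -> float:
    """Percentage of clonotypes required to occupy ``threshold`` of reads.

    k is the first rank whose cumulative frequency reaches the threshold;
    the metric is 100·k / richness.
    """
    if not ranked.entries:
        raise EmptyResultError("empty ranking")
    for entry in ranked.entries:
        if entry.cumulative >= threshold - 1e-12:
            return 100.0 * entry.rank / ranked.richness
    return 100.0


def diversity_metrics(
    repertoire: Repertoire,
    level: str = "nt",
    top_n: int = 10,
    threshold: float = 0.75,
) -> DiversityMetrics:
    ranked = rank_clonotypes(repertoire, level)
    return DiversityMetrics(
        d75=d75(ranked, threshold),
        top_n_accumulated=accumulated_top_n(ranked, top_n),
        richness=ranked.richness,
        level=level,
        top_n=top_n,
        threshold=threshold,
    )


@dataclass
class Spectratype:
    fractions: dict[int, float]  # core length -> fraction
    weighting: str  # "reads" | "unique"
    n_excluded: int = 0


def spectratype(repertoire: Repertoire, weighting: str = "reads") -> Spectratype:
    """CDR3 core-length distribution; non-canonical records are excluded."""
    if weighting not in ("reads", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    weights: dict[int, float] = {}
    excluded = 0
    for r in repertoire.records:
        try:
            length = cdr3_core_length(r.junction_aa)
        except NonCanonicalJunctionError:
            excluded += 1
            continue
        w = r.read_count if weighting == "reads" else 1
        weights[length] = weights.get(length, 0) + w
    total = sum(weights.values())
    if total == 0:
        raise EmptyResultError("no canonical records for spectratype")
    return Spectratype(
        fractions={k: v / total for k, v in sorted(weights.items())},
        weighting=weighting,
        n_excluded=excluded,
    )


@dataclass
class SegmentUsage:
    family: str  # "V" | "J"
    fractions: dict[str, float]


def segment_usage(repertoire: Repertoire, family: str = "V") -> SegmentUsage:
    """Read-weighted segment usage within one gene family (V or J)."""
    if family not in ("V", "J"):
        raise ValueError("family must be 'V' or 'J'")
    attr = "v_call" if family == "V" else "j_call"
    weights: dict[str, float] = {}
    for r in repertoire.records:
        name = getattr(r, attr)
        if not name or "," in name:  # multi-valued calls excluded
            continue
        weights[name] = weights.get(name, 0) + r.read_count
    total = sum(weights.values())
    if total == 0:
        return SegmentUsage(family=family, fractions={})
    return SegmentUsage(
        family=family,
        fractions={k: v / total for k, v in sorted(weights.items())},
    )


# ---------------------------------------------------------------------------
# Squarified treemap layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreemapRect:
    clonotype_id: str
    v_call: str
    x: float
    y: float
    w: float
    h: float

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass
class TreemapLayout:
    rects: list[TreemapRect]
    canvas_w: float
    canvas_h: float


def _worst_ratio(row: list[float], side: float) -> float:
    total = sum(row)
    mx, mn = max(row), min(row)
    return max(side * side * mx / (total * total), total * total / (side * side * mn))


def _squarify(sizes: list[float], x: float, y: float, w: float, h: float):
    """Squarified treemap (Bruls-style): areas in ``sizes`` tile (x,y,w,h).

    ``sizes`` must already be scaled so sum(sizes) == w*h and sorted
    descending for good aspect ratios; returns one (x, y, w, h) per size,
    in input order.
    """
    rects: list[tuple[float, float, float, float]] = []
    i = 0
    while i < len(sizes):
        side = min(w, h)
        row = [sizes[i]]
        j = i + 1
        while j < len(sizes):
            if _worst_ratio(row + [sizes[j]], side) <= _worst_ratio(row, side):
                row.append(sizes[j])
                j += 1
            else:
                break
        row_area = sum(row)
        if w >= h:  # lay the row vertically along the left edge
            row_w = row_area / h if h > 0 else 0.0
            yy = y
            for s in row:
                hh = s / row_w if row_w > 0 else 0.0
                rects.append((x, yy, row_w, hh))
                yy += hh
            x += row_w
            w -= row_w
        else:  # lay the row horizontally along the top edge
            row_h = row_area / w if w > 0 else 0.0
            xx = x
            for s in row:
                ww = s / row_h if row_h > 0 else 0.0
                rects.append((xx, y, ww, row_h))
                xx += ww
            y += row_h
        i = j
    return rects


def treemap_layout(
    repertoire: Repertoire,
    canvas_w: float = 100.0,
    canvas_h: float = 100.0,
) -> TreemapLayout:
    """Tile the canvas with one rectangle per clonotype, grouped by V call.

    The top level partitions the canvas by V segment (area proportional to
    the segment's summed read share); clonotype rectangles nest inside
    their segment's region with area proportional to clonotype frequency.
    """
    if canvas_w <= 0 or canvas_h <= 0:
        raise ValueError("canvas dimensions must be positive")
    if not repertoire.records:
        raise EmptyResultError("empty repertoire")
    total = repertoire.total_reads
    groups: dict[str, list] = {}
    for r in repertoire.records:
        groups.setdefault(r.v_call, []).append(r)
    group_names = sorted(
        groups, key=lambda g: (-sum(r.read_count for r in groups[g]), g)
    )
    group_sizes = [
        sum(r.read_count for r in groups[g]) / total * canvas_w * canvas_h
        for g in group_names
    ]
    group_rects = _squarify(group_sizes, 0.0, 0.0, canvas_w, canvas_h)
    rects: list[TreemapRect] = []
    for g, (gx, gy, gw, gh) in zip(group_names, group_rects):
        members = sorted(groups[g], key=lambda r: (-r.read_count, r.junction_nt))
        garea = gw * gh
        gtotal = sum(r.read_count for r in members)
        sizes = [r.read_count / gtotal * garea for r in members]
        for r, (x, y, w, h) in zip(members, _squarify(sizes, gx, gy, gw, gh)):
            rects.append(
                TreemapRect(
                    clonotype_id=r.junction_nt, v_call=r.v_call, x=x, y=y, w=w, h=h
                )
            )
    return TreemapLayout(rects=rects, canvas_w=canvas_w, canvas_h=canvas_h)
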