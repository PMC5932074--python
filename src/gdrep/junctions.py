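"""CDR3 junction decomposition and physicochemical profiling.

A junction (the CDR3 nucleotide sequence including both anchor codons) is
split into a V-templated prefix, optional P nucleotides, non-templated N
nucleotides, zero to two D-templated blocks, and a J-templated suffix.
The decomposition objective, applied in order:

1. maximise total germline-templated nucleotides (V + D + J);
2. among ties, minimise the number of D segments used;
3. among ties, minimise total trimming;
4. among ties, prefer the V-proximal D placement, then the encoding with
   the least V trimming, breaking any residue lexicographically.

P nucleotides are only assigned adjacent to an *untrimmed* segment end and
must extend the palindrome: each P base equals the complement of the
corresponding terminal base of the segment, read outward. Everything still
unassigned is N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    Chain,
    GdrepError,
    GermlineReference,
    GermlineSegment,
    translate_nt,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: physicochemical partition of the 20 standard residues
ACIDIC = frozenset("DE")
BASIC = frozenset("RKH")
HYDROPHOBIC = frozenset("ACFILMPVW")
NEUTRAL = frozenset("NQSGTY")  # Q grouped neutral to complete the 20-letter partition


class DecompositionError(GdrepError):
    """The junction is incompatible with the declared V segment."""


class NonCanonicalJunctionError(GdrepError):
    """Junction lacks the conserved Cys...Phe anchors."""


translate = translate_nt


def cdr3_core_length(junction_aa: str) -> int:
    """Number of residues strictly between the Cys and Phe anchors.

    The CDR3 length convention counts only the amino acids between the
    conserved anchors, so a canonical junction of length L has core L − 2.
    """
    if not (
        len(junction_aa) >= 2
        and junction_aa.startswith("C")
        and junction_aa.endswith("F")
    ):
        raise NonCanonicalJunctionError(
            f"junction {junction_aa!r} lacks C...F anchors"
        )
    return len(junction_aa) - 2


def residue_class(residue: str) -> str:
    if residue in ACIDIC:
        return "acidic"
    if residue in BASIC:
        return "basic"
    if residue in HYDROPHOBIC:
        return "hydrophobic"
    if residue in NEUTRAL:
        return "neutral"
    raise GdrepError(f"non-standard residue {residue!r}")


def position5(junction_aa: str) -> tuple[str, str]:
    """Residue and physicochemical class at core position 5.

    Position 5 is 1-based within the core (anchors excluded); defined only
    when the core has at least five residues.
    """
    core_len = cdr3_core_length(junction_aa)
    if core_len < 5:
        raise NonCanonicalJunctionError(
            f"core length {core_len} < 5: position 5 undefined"
        )
    residue = junction_aa[5]  # core position 5 == junction index 5 (0-based)
    return residue, residue_class(residue)


@dataclass(frozen=True)
class Cdr3Profile:
    core_length: int
    position5_residue: str | None
    position5_class: str | None
    hydrophobic5_flag: bool

    @classmethod
    def from_junction_aa(cls, junction_aa: str) -> "Cdr3Profile":
        core_len = cdr3_core_length(junction_aa)
        if core_len >= 5:
            res, klass = position5(junction_aa)
            return cls(core_len, res, klass, res in HYDROPHOBIC)
        return cls(core_len, None, None, False)


def n_count_by_affix(junction_nt: str, germline_junction_nt: str) -> int:
    """N-nucleotide count by affix comparison against a zero-N reference.

    Returns ``max(0, len(junction) − LCP − LCS)`` where LCP/LCS are the
    longest common prefix/suffix with the germline junction, capped so
    LCP + LCS never exceeds the junction length. This mirrors how added
    nucleotides are counted against a known germline-encoded junction.
    """
    n = len(junction_nt)
    m = len(germline_junction_nt)
    lcp = 0
    while lcp < min(n, m) and junction_nt[lcp] == germline_junction_nt[lcp]:
        lcp += 1
    lcs = 0
    while (
        lcs < min(n, m)
        and junction_nt[n - 1 - lcs] == germline_junction_nt[m - 1 - lcs]
    ):
        lcs += 1
    lcs = min(lcs, n - lcp)
    return max(0, n - lcp - lcs)


@dataclass(frozen=True)
class DecomposeOptions:
    max_anchor_mismatch: int = 0
    min_d_match: int = 3
    max_p: int = 3
    max_d_segments: int = 2


@dataclass(frozen=True)
class DPart:
    d_name: str
    d_contrib: int
    d5_trim: int
    d3_trim: int
    p5: str
    p3: str


@dataclass
class JunctionDecomposition:
    junction_nt: str
    v_name: str
    j_name: str
    v_contrib: int
    v_trim: int
    p_v: str
    n_regions: list[str]
    d_parts: list[DPart]
    p_j: str
    j_trim: int
    j_contrib: int
    #: junction-coordinate layout for reconstruction: ordered (label, string)
    layout: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(len(s) for s in self.n_regions)

    @property
    def p_total(self) -> int:
        return (
            len(self.p_v)
            + len(self.p_j)
            + sum(len(d.p5) + len(d.p3) for d in self.d_parts)
        )

    @property
    def is_germline(self) -> bool:
        trims = self.v_trim + self.j_trim + sum(
            d.d5_trim + d.d3_trim for d in self.d_parts
        )
        return self.n_total == 0 and trims == 0

    def reconstruct(self) -> str:
        return "".join(part for _, part in self.layout)


def classify_recombination(decomposition: JunctionDecomposition) -> str:
    """``germline`` for untrimmed zero-N joints, else ``convergent_candidate``.

    Any nucleotide variant of a shared amino-acid sequence that is not a
    pure germline joint is a candidate product of convergent recombination.
    """
    return "germline" if decomposition.is_germline else "convergent_candidate"


def _common_prefix_len(a: str, b: str) -> int:
    i = 0
    while i < min(len(a), len(b)) and a[i] == b[i]:
        i += 1
    return i


def _d_maximal_runs(junction: str, d_segs: list[GermlineSegment], min_len: int):
    """All maximal contiguous matches of each D segment against the junction.

    Yields (order_index, name, seg_len, j_start, d_start, length) tuples in
    junction coordinates.
    """
    runs = []
    for seg in d_segs:
        d = seg.sequence
        for diag in range(-len(d) + 1, len(junction)):
            j = max(0, diag)
            k = j - diag
            while j < len(junction) and k < len(d):
                if junction[j] != d[k]:
                    j += 1
                    k += 1
                    continue
                start_j, start_k = j, k
                while j < len(junction) and k < len(d) and junction[j] == d[k]:
                    j += 1
                    k += 1
                if j - start_j >= min_len:
                    runs.append(
                        (seg.order_index, seg.name, len(d), start_j, start_k, j - start_j)
                    )
    return runs


def _clip_run(run, lo: int, hi: int, min_len: int):
    """Clip a run to junction interval [lo, hi); None if too short."""
    order, name, seg_len, j_start, d_start, length = run
    new_start = max(j_start, lo)
    new_end = min(j_start + length, hi)
    if new_end - new_start < min_len:
        return None
    shift = new_start - j_start
    return (order, name, seg_len, new_start, d_start + shift, new_end - new_start)


def _greedy_p(
    gap: str,
    left_terminal: str | None,
    right_terminal: str | None,
    max_p: int,
) -> tuple[str, str, str]:
    """Split a gap into (left P, N, right P).

    ``left_terminal`` is the adjacent segment's sequence read backwards from
    its (untrimmed) 3' end; ``right_terminal`` the next segment's sequence
    read forwards from its (untrimmed) 5' end; None when the end is trimmed
    (no P possible there). Left-end P is assigned first.
    """
    left_p = 0
    if left_terminal:
        while (
            left_p < min(max_p, len(gap), len(left_terminal))
            and gap[left_p] == _COMPLEMENT[left_terminal[left_p]]
        ):
            left_p += 1
    right_p = 0
    if right_terminal:
        avail = len(gap) - left_p
        while (
            right_p < min(max_p, avail, len(right_terminal))
            and gap[len(gap) - 1 - right_p] == _COMPLEMENT[right_terminal[right_p]]
        ):
            right_p += 1
    return gap[:left_p], gap[left_p : len(gap) - right_p], gap[len(gap) - right_p :]


def decompose(
    junction_nt: str,
    v_name: str,
    j_name: str,
    reference: GermlineReference,
    options: DecomposeOptions = DecomposeOptions(),
) -> JunctionDecomposition:
    """Best decomposition of a junction under the stated objective.

    The search enumerates every (V contribution, J contribution) pair
    compatible with the germline prefixes/suffixes and, for each resulting
    gap, every selection of up to ``options.max_d_segments`` non-overlapping
    D matches in genomic order with at least ``options.min_d_match``
    contiguous nucleotides each.
    """
    junction = junction_nt.upper()
    v_seg = reference[v_name]
    j_seg = reference[j_name]
    v_region = v_seg.junction_region
    j_region = j_seg.junction_region

    anchor = v_region[:3]
    mismatches = sum(1 for a, b in zip(junction[:3], anchor) if a != b)
    if len(junction) < 3 or mismatches > options.max_anchor_mismatch:
        raise DecompositionError(
            f"junction prefix {junction[:3]!r} incompatible with "
            f"{v_name} anchor codon {anchor!r}"
        )

    lcp = _common_prefix_len(junction, v_region)
    lcs = _common_prefix_len(junction[::-1], j_region[::-1])
    lcp = max(lcp, 3)  # anchor codon always assigned to V (mismatch-tolerated)

    chain = reference.chain_of(v_name)
    d_segs = reference.by_type("D", Chain.delta) if chain is Chain.delta else []
    if options.max_d_segments == 0:
        d_segs = []
    all_runs = _d_maximal_runs(junction, d_segs, options.min_d_match)

    best_key = None
    best = None  # (v, j, selected runs)
    for v in range(3, lcp + 1):
        for j in range(0, min(lcs, len(junction) - v) + 1):
            gap_lo, gap_hi = v, len(junction) - j
            clipped = []
            for run in all_runs:
                c = _clip_run(run, gap_lo, gap_hi, options.min_d_match)
                if c is not None:
                    clipped.append(c)
            # candidate D selections: none, single, ordered pairs
            selections: list[tuple] = [()]
            selections.extend((c,) for c in clipped)
            if options.max_d_segments >= 2:
                for a in clipped:
                    for b in clipped:
                        if a[0] >= b[0]:  # strict genomic order
                            continue
                        # resolve overlap by shrinking the later run's left edge
                        overlap = (a[3] + a[5]) - b[3]
                        if overlap > 0:
                            b2 = _clip_run(b, a[3] + a[5], gap_hi, options.min_d_match)
                            if b2 is None:
                                continue
                            b = b2
                        selections.append((a, b))
            for sel in selections:
                coverage = v + j + sum(r[5] for r in sel)
                trim = (
                    (len(v_region) - v)
                    + (len(j_region) - j)
                    + sum(r[4] + (r[2] - r[4] - r[5]) for r in sel)
                )
                d_starts = tuple(r[3] for r in sel)
                key = (
                    -coverage,
                    len(sel),
                    trim,
                    d_starts,
                    tuple(r[4] for r in sel),  # then least D 5' trimming
                    len(v_region) - v,  # then least V trimming
                    tuple(r[1] for r in sel),
                )
                if best_key is None or key < best_key:
                    best_key = key
                    best = (v, j, sel)

    v, j, sel = best
    v_trim = len(v_region) - v
    j_trim = len(j_region) - j

    # assemble blocks in junction order; classify gap nt as P then N
    blocks = [("V", 0, v, v_seg, v_trim == 0, None)]
    for r in sel:
        order, name, seg_len, j_start, d_start, length = r
        seg = reference[name]
        d5_trim = d_start
        d3_trim = seg_len - d_start - length
        blocks.append(("D", j_start, j_start + length, seg, d5_trim == 0, d3_trim == 0))
    blocks.append(("J", len(junction) - j, len(junction), j_seg, None, j_trim == 0))

    layout: list[tuple[str, str]] = []
    n_regions: list[str] = []
    p_v = ""
    p_j = ""
    d_parts: list[DPart] = []
    d_p: list[list[str]] = [["", ""] for _ in sel]

    for idx in range(len(blocks) - 1):
        kind, start, end, seg, left_ok5, left_ok3 = blocks[idx]
        kind2, start2, end2, seg2, right_ok5, right_ok3 = blocks[idx + 1]
        if kind == "V":
            layout.append(("V", junction[start:end]))
        gap = junction[end:start2]
        # terminal sequences for palindrome checks
        if kind == "V":
            left_untrimmed = v_trim == 0
            left_term = v_region[::-1] if left_untrimmed else None
        else:  # D
            dpart_idx = idx - 1
            left_untrimmed = left_ok3
            left_term = seg.sequence[::-1] if left_untrimmed else None
        if kind2 == "J":
            right_untrimmed = j_trim == 0
            right_term = j_region if right_untrimmed else None
        else:  # D
            right_untrimmed = right_ok5
            right_term = seg2.sequence if right_untrimmed else None
        lp, nn, rp = _greedy_p(gap, left_term, right_term, options.max_p)
        if kind == "V":
            p_v = lp
        else:
            d_p[idx - 1][1] = lp
        if kind2 == "J":
            p_j = rp
        else:
            d_p[idx][0] = rp
        if lp:
            layout.append(("P", lp))
        if nn:
            n_regions.append(nn)
            layout.append(("N", nn))
        if rp:
            layout.append(("P", rp))
        if kind2 == "D":
            layout.append(("D", junction[start2:end2]))
        else:
            layout.append(("J", junction[start2:end2]))

    for i, r in enumerate(sel):
        order, name, seg_len, j_start, d_start, length = r
        d_parts.append(
            DPart(
                d_name=name,
                d_contrib=length,
                d5_trim=d_start,
                d3_trim=seg_len - d_start - length,
                p5=d_p[i][0],
                p3=d_p[i][1],
            )
        )

    return JunctionDecomposition(
        junction_nt=junction,
        v_name=v_name,
        j_name=j_name,
        v_contrib=v,
        v_trim=v_trim,
        p_v=p_v,
        n_regions=n_regions,
        d_parts=d_parts,
        p_j=p_j,
        j_trim=j_trim,
        j_contrib=j,
        layout=layout,
    )
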