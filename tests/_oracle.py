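"""Independent brute-force decomposition oracle.

Enumerates every (V contribution, J contribution, single-D placement)
combination by direct substring comparison — no diagonal-run machinery —
and ranks candidates with the same objective ordering the production
decomposer declares. Used only to cross-check `gdrep.junctions.decompose`.
"""

from __future__ import annotations


def _lcp(a: str, b: str) -> int:
    i = 0
    while i < min(len(a), len(b)) and a[i] == b[i]:
        i += 1
    return i


def brute_force_decompose(junction, v_name, j_name, reference, min_d_match=3, max_d=1):
    """Returns (v_contrib, j_contrib, d_placements) of the optimal candidate.

    d_placements is a tuple of (d_name, junction_start, d_start, length).
    """
    v_region = reference[v_name].junction_region
    j_region = reference[j_name].junction_region
    from gdrep.core import Chain

    chain = reference.chain_of(v_name)
    d_segs = reference.by_type("D", Chain.delta) if chain is Chain.delta else []

    lcp = max(_lcp(junction, v_region), 3)
    lcs = _lcp(junction[::-1], j_region[::-1])

    best_key = None
    best = None
    for v in range(3, lcp + 1):
        for j in range(0, min(lcs, len(junction) - v) + 1):
            gap_lo, gap_hi = v, len(junction) - j
            candidates = [()]
            if max_d >= 1:
                for seg in d_segs:
                    d = seg.sequence
                    for start in range(gap_lo, gap_hi):
                        for length in range(min_d_match, gap_hi - start + 1):
                            sub = junction[start : start + length]
                            pos = d.find(sub)
                            while pos != -1:
                                candidates.append(
                                    ((seg.name, start, pos, length),)
                                )
                                pos = d.find(sub, pos + 1)
            for sel in candidates:
                d_len = sum(p[3] for p in sel)
                coverage = v + j + d_len
                d_trim = sum(
                    p[2] + (len(reference[p[0]].sequence) - p[2] - p[3])
                    for p in sel
                )
                trim = (len(v_region) - v) + (len(j_region) - j) + d_trim
                key = (
                    -coverage,
                    len(sel),
                    trim,
                    tuple(p[1] for p in sel),
                    tuple(p[2] for p in sel),
                    len(v_region) - v,
                    tuple(p[0] for p in sel),
                )
                if best_key is None or key < best_key:
                    best_key = key
                    best = (v, j, sel)
    return best
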