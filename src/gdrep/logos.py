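"""Length-stratified position frequency matrices and Shannon logo heights.

For a position with residue frequencies f_a (no pseudocounts), the
information content is I_p = log2(20) + Σ_a f_a·log2(f_a), and each
residue's bar height is f_a·I_p. Mixed-length pooling is handled either
per exact length (default, no alignment) or by an anchor-split policy that
left-aligns the first half of the columns and right-aligns the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import GdrepError, Repertoire
from .junctions import (
    NonCanonicalJunctionError,
    cdr3_core_length,
    residue_class,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(20)


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies for one stratum of sequences."""

    columns: list[dict[str, float]]
    stratum: str
    n_sequences: int

    @property
    def length(self) -> int:
        return len(self.columns)


@dataclass
class LogoColumn:
    information_bits: float
    heights: dict[str, float]  # residue -> f_a * I_p
    classes: dict[str, str]


@dataclass
class LogoMatrix:
    columns: list[LogoColumn]
    stratum: str


def select_stratum(
    repertoire: Repertoire,
    j_segment: str,
    length_range: tuple[int, int],
    top_k: int = 10,
) -> list[str]:
    """The top-k most abundant aa clonotypes with matching J and core length.

    Returns the core sequences (anchors stripped); fewer than ``top_k``
    when the stratum is smaller. Abundance is read-weighted at the
    amino-acid level within the stratum; ties break by sequence.
    """
    lo, hi = length_range
    counts: dict[str, int] = {}
    for rec in repertoire.records:
        if rec.j_call != j_segment:
            continue
        try:
            core_len = cdr3_core_length(rec.junction_aa)
        except NonCanonicalJunctionError:
            continue
        if not (lo <= core_len <= hi):
            continue
        counts[rec.junction_aa] = counts.get(rec.junction_aa, 0) + rec.read_count
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return [aa[1:-1] for aa, _ in ranked]


def frequency_matrix(
    sequences: list[str],
    length_policy: str = "per_length",
    stratum: str = "",
) -> PositionFrequencyMatrix | list[PositionFrequencyMatrix]:
    """Position frequency matrix (or matrices) without pseudocounts.

    ``per_length`` builds one matrix per exact length and returns a list
    (a single matrix when all sequences share one length).
    ``single`` requires uniform length. ``anchor_split`` pools mixed
    lengths by left-aligning the first ⌈L/2⌉ columns of each sequence and
    right-aligning the remainder onto the longest length.
    """
    if not sequences:
        raise GdrepError("empty selection")
    lengths = sorted({len(s) for s in sequences})
    if length_policy == "single":
        if len(lengths) > 1:
            raise GdrepError(
                f"mixed lengths {lengths} under a single-matrix request"
            )
        return _pfm_uniform(sequences, stratum)
    if length_policy == "per_length":
        if len(lengths) == 1:
            return _pfm_uniform(sequences, stratum)
        return [
            _pfm_uniform(
                [s for s in sequences if len(s) == L],
                f"{stratum}|L={L}" if stratum else f"L={L}",
            )
            for L in lengths
        ]
    if length_policy == "anchor_split":
        return _pfm_anchor_split(sequences, stratum)
    raise ValueError(f"unknown length policy {length_policy!r}")


def _pfm_uniform(sequences: list[str], stratum: str) -> PositionFrequencyMatrix:
    L = len(sequences[0])
    columns: list[dict[str, float]] = []
    for pos in range(L):
        counts: dict[str, int] = {}
        for s in sequences:
            counts[s[pos]] = counts.get(s[pos], 0) + 1
        total = len(sequences)
        columns.append({a: c / total for a, c in sorted(counts.items())})
    return PositionFrequencyMatrix(
        columns=columns, stratum=stratum, n_sequences=len(sequences)
    )


def _pfm_anchor_split(sequences: list[str], stratum: str) -> PositionFrequencyMatrix:
    L = max(len(s) for s in sequences)
    col_counts: list[dict[str, int]] = [{} for _ in range(L)]
    col_n = [0] * L
    for s in sequences:
        split = (len(s) + 1) // 2
        for i in range(split):
            col_counts[i][s[i]] = col_counts[i].get(s[i], 0) + 1
            col_n[i] += 1
        for i in range(split, len(s)):
            pos = L - (len(s) - i)
            col_counts[pos][s[i]] = col_counts[pos].get(s[i], 0) + 1
            col_n[pos] += 1
    columns = [
        {a: c / n for a, c in sorted(counts.items())} if n else {}
        for counts, n in zip(col_counts, col_n)
    ]
    return PositionFrequencyMatrix(
        columns=columns,
        stratum=f"{stratum}|anchor_split" if stratum else "anchor_split",
        n_sequences=len(sequences),
    )


def shannon_information(frequencies: dict[str, float]) -> float:
    """I_p = log2(20) + Σ f·log2(f), with 0·log(0) = 0."""
    entropy = -sum(f * math.log2(f) for f in frequencies.values() if f > 0)
    return MAX_BITS - entropy


def shannon_heights(pfm: PositionFrequencyMatrix) -> LogoMatrix:
    """Shannon-format logo: per-residue bar heights f_a × I_p per column."""
    columns = []
    for freqs in pfm.columns:
        info = shannon_information(freqs)
        columns.append(
            LogoColumn(
                information_bits=info,
                heights={a: f * info for a, f in freqs.items()},
                classes={a: residue_class(a) for a in freqs},
            )
        )
    return LogoMatrix(columns=columns, stratum=pfm.stratum)


class_partition = residue_class
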