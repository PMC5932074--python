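"""Cross-donor sharing, overlap, convergent recombination and pseudoclonotypes.

A clonotype is *public* when its CDR3 amino-acid sequence occurs in more
than one unrelated donor. Publicity in γ9 repertoires arises both from
pure germline joints (no trimming, no N addition) and from convergent
recombination — distinct nucleotide rearrangements encoding the same
amino-acid sequence. Sharing statistics are always computed at the
amino-acid level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Cohort, GdrepError, SingleCellRecord, translate_nt
from .junctions import JunctionDecomposition, classify_recombination


@dataclass
class SharingReport:
    donor_id: str
    fraction: float
    min_other_donors: int
    weighting: str  # "unique" | "reads"
    n_clonotypes: int


def sharing_fraction(
    cohort: Cohort,
    donor_id: str,
    min_other_donors: int = 1,
    weighting: str = "unique",
) -> SharingReport:
    """Fraction of a donor's aa clonotypes found in >= min_other_donors others.

    With ``weighting='reads'`` the fraction is read-weighted instead of
    counting unique amino-acid clonotypes once each.
    """
    rep = cohort.get(donor_id)
    own = rep.aa_counts()
    if not own:
        raise GdrepError(f"{donor_id}: no clonotypes")
    others = [r.aa_set() for r in cohort.repertoires if r.donor_id != donor_id]
    if not others:
        raise GdrepError("sharing requires >= 2 donors")
    shared_w = 0.0
    total_w = 0.0
    for aa, count in own.items():
        w = count if weighting == "reads" else 1
        total_w += w
        if sum(1 for s in others if aa in s) >= min_other_donors:
            shared_w += w
    return SharingReport(
        donor_id=donor_id,
        fraction=shared_w / total_w,
        min_other_donors=min_other_donors,
        weighting=weighting,
        n_clonotypes=len(own),
    )


@dataclass
class OverlapMatrix:
    donor_ids: list[str]
    values: np.ndarray
    metric: str

    def pair(self, a: str, b: str) -> float:
        return float(
            self.values[self.donor_ids.index(a), self.donor_ids.index(b)]
        )


def overlap_matrix(cohort: Cohort, metric: str = "shared_over_min") -> OverlapMatrix:
    """Pairwise overlap of unique aa clonotype sets.

    Default metric: |A ∩ B| / min(|A|, |B|) ("relative publicity");
    ``jaccard`` (|A ∩ B| / |A ∪ B|) is also available.
    """
    if len(cohort.repertoires) < 2:
        raise GdrepError("overlap requires >= 2 donors")
    sets = [r.aa_set() for r in cohort.repertoires]
    n = len(sets)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            if metric == "shared_over_min":
                denom = min(len(sets[i]), len(sets[j]))
            elif metric == "jaccard":
                denom = len(sets[i] | sets[j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            values[i, j] = values[j, i] = inter / denom if denom else 0.0
    return OverlapMatrix(
        donor_ids=cohort.donor_ids(), values=values, metric=metric
    )


@dataclass(frozen=True)
class PublicClonotype:
    junction_aa: str
    n_donors: int
    mean_frequency: float
    per_donor_frequency: dict[str, float]
    inclusion: str  # "top10" | "amplified"


@dataclass
class PublicClonotypeTable:
    entries: list[PublicClonotype]
    top_n: int
    share_threshold_donors: int
    amplified_min_freq: float


def top_shared_hierarchy(
    cohort: Cohort,
    n: int = 10,
    share_threshold_donors: int = 2,
    amplified_min_freq: float = 0.10,
) -> PublicClonotypeTable:
    """Hierarchy of the most prevalent shared aa clonotypes.

    Each donor contributes its top-``n`` amino-acid clonotypes by
    frequency; sequences present in more than ``share_threshold_donors``
    donors are kept and ordered by mean frequency across the donors that
    possess them. Uncommon but highly amplified sequences (frequency above
    ``amplified_min_freq`` in some donor) are appended as flagged
    exceptions even when outside every donor's top-``n``.
    """
    donor_freqs: dict[str, dict[str, float]] = {}
    for rep in cohort.repertoires:
        counts = rep.aa_counts()
        total = sum(counts.values())
        donor_freqs[rep.donor_id] = {aa: c / total for aa, c in counts.items()}

    top_union: set[str] = set()
    for freqs in donor_freqs.values():
        ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
        top_union.update(aa for aa, _ in ranked)

    occurrence: dict[str, list[str]] = {}
    for donor, freqs in donor_freqs.items():
        for aa in freqs:
            occurrence.setdefault(aa, []).append(donor)

    entries: list[PublicClonotype] = []
    kept: set[str] = set()
    for aa in top_union:
        donors = occurrence[aa]
        if len(donors) > share_threshold_donors:
            per = {d: donor_freqs[d][aa] for d in donors}
            entries.append(
                PublicClonotype(
                    junction_aa=aa,
                    n_donors=len(donors),
                    mean_frequency=sum(per.values()) / len(per),
                    per_donor_frequency=per,
                    inclusion="top10",
                )
            )
            kept.add(aa)
    entries.sort(key=lambda e: (-e.mean_frequency, e.junction_aa))

    amplified: list[PublicClonotype] = []
    for aa, donors in occurrence.items():
        if aa in kept:
            continue
        per = {d: donor_freqs[d][aa] for d in donors}
        if max(per.values()) >= amplified_min_freq:
            amplified.append(
                PublicClonotype(
                    junction_aa=aa,
                    n_donors=len(donors),
                    mean_frequency=sum(per.values()) / len(per),
                    per_donor_frequency=per,
                    inclusion="amplified",
                )
            )
    amplified.sort(key=lambda e: (-e.mean_frequency, e.junction_aa))
    return PublicClonotypeTable(
        entries=entries + amplified,
        top_n=n,
        share_threshold_donors=share_threshold_donors,
        amplified_min_freq=amplified_min_freq,
    )


@dataclass
class ConvergenceGroup:
    junction_aa: str
    variants: list[tuple[str, str, list[str]]]  # (nt, label, donors)

    @property
    def is_convergent(self) -> bool:
        return len(self.variants) >= 2

    @property
    def n_germline(self) -> int:
        return sum(1 for _, label, _ in self.variants if label == "germline")


@dataclass
class ConvergenceReport:
    groups: dict[str, ConvergenceGroup]

    @property
    def n_convergent(self) -> int:
        return sum(1 for g in self.groups.values() if g.is_convergent)


def convergence_report(
    cohort: Cohort,
    decompositions: dict[str, JunctionDecomposition],
) -> ConvergenceReport:
    """Group nucleotide variants by amino-acid translation.

    ``decompositions`` maps junction_nt to its decomposition; each variant
    is labelled germline or convergent_candidate. A group with two or more
    distinct nucleotide variants is a convergent-recombination group.
    """
    by_aa: dict[str, dict[str, list[str]]] = {}
    for rep in cohort.repertoires:
        for rec in rep.records:
            by_aa.setdefault(rec.junction_aa, {}).setdefault(
                rec.junction_nt, []
            ).append(rep.donor_id)
    groups: dict[str, ConvergenceGroup] = {}
    for aa, variants in by_aa.items():
        entries = []
        for nt in sorted(variants):
            if translate_nt(nt) != aa:
                raise GdrepError(
                    f"variant {nt} grouped under {aa} does not translate to it"
                )
            if nt not in decompositions:
                raise GdrepError(f"no decomposition available for {nt}")
            label = classify_recombination(decompositions[nt])
            entries.append((nt, label, sorted(set(variants[nt]))))
        groups[aa] = ConvergenceGroup(junction_aa=aa, variants=entries)
    return ConvergenceReport(groups=groups)


@dataclass
class PseudoclonotypeEntry:
    donor_id: str
    gamma_aa: str
    delta_partners: list[str]

    @property
    def partner_count(self) -> int:
        return len(self.delta_partners)

    @property
    def is_pseudoclonotype(self) -> bool:
        return self.partner_count > 1


@dataclass
class PseudoclonotypeReport:
    entries: list[PseudoclonotypeEntry]
    n_cells_missing_delta: int = 0
    n_cells_missing_gamma: int = 0

    def get(self, donor_id: str, gamma_aa: str) -> PseudoclonotypeEntry:
        for e in self.entries:
            if e.donor_id == donor_id and e.gamma_aa == gamma_aa:
                return e
        raise KeyError((donor_id, gamma_aa))


def pseudoclonotype_report(cells: list[SingleCellRecord]) -> PseudoclonotypeReport:
    """Count distinct δ-chain partners per (donor, γ aa) among single cells.

    The same γ-chain CDR3 amino-acid sequence paired with several distinct
    δ chains in one donor marks independently generated clones sharing one
    public γ sequence (a pseudoclonotype). Cells missing either chain are
    excluded from counting and tallied.
    """
    partners: dict[tuple[str, str], set[str]] = {}
    missing_delta = 0
    missing_gamma = 0
    for cell in cells:
        if cell.gamma is None:
            missing_gamma += 1
            continue
        if cell.delta is None:
            missing_delta += 1
            continue
        key = (cell.donor_id, cell.gamma.junction_aa)
        partners.setdefault(key, set()).add(cell.delta.junction_aa)
    entries = [
        PseudoclonotypeEntry(donor_id=d, gamma_aa=g, delta_partners=sorted(p))
        for (d, g), p in sorted(partners.items())
    ]
    return PseudoclonotypeReport(
        entries=entries,
        n_cells_missing_delta=missing_delta,
        n_cells_missing_gamma=missing_gamma,
    )


def dominant_clone_fraction(cells: list[SingleCellRecord]) -> float:
    """Fraction of cells carrying the most frequent paired clonotype."""
    counts: dict[tuple, int] = {}
    for cell in cells:
        key = (
            cell.gamma.junction_nt if cell.gamma else None,
            cell.delta.junction_nt if cell.delta else None,
        )
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise GdrepError("no cells")
    return max(counts.values()) / sum(counts.values())
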