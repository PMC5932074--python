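"""Domain types and I/O for clonotype tables, single-cell tables and germline references.

The on-disk dialect follows the AIRR Rearrangement column names
(``junction``, ``junction_aa``, ``v_call``, ``d_call``, ``j_call``,
``duplicate_count``); a column-mapping dict supports other dialects.
All sequence coordinates are 0-based, half-open, top strand; junctions are
given in reading orientation and include both anchor codons (the conserved
Cys of the V segment and the conserved Phe of the J segment).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq


class GdrepError(Exception):
    """Base class for package errors."""


class FormatError(GdrepError):
    """A table or FASTA file does not match the expected dialect."""


class EmptyRepertoireError(GdrepError):
    """A clonotype table contained no usable rows."""


class ReferenceError_(GdrepError):
    """A germline reference failed validation."""


NUCLEOTIDES = frozenset("ACGT")

#: canonical AIRR Rearrangement column names used throughout
AIRR_COLUMNS = {
    "junction": "junction",
    "junction_aa": "junction_aa",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "duplicate_count": "duplicate_count",
}


class Chain(str, enum.Enum):
    gamma = "gamma"
    delta = "delta"


class Compartment(str, enum.Enum):
    adult_blood = "adult_blood"
    cord_blood = "cord_blood"
    liver = "liver"
    other = "other"


def translate_nt(junction_nt: str) -> str:
    """Standard-code translation of an in-frame nucleotide string.

    Raises :class:`FormatError` when the length is not a multiple of 3 or
    the string contains characters outside A/C/G/T. Stop codons translate
    to ``*`` (callers flag such records non-canonical).
    """
    if len(junction_nt) % 3 != 0:
        raise FormatError(
            f"junction length {len(junction_nt)} is not a multiple of 3"
        )
    if not set(junction_nt) <= NUCLEOTIDES:
        bad = sorted(set(junction_nt) - NUCLEOTIDES)
        raise FormatError(f"junction contains non-ACGT characters: {bad}")
    return str(Seq(junction_nt).translate())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype: junction sequences, segment calls and abundance.

    ``d_call`` may be empty or comma-separated multi-valued (e.g.
    ``"TRDD1,TRDD3"``). ``canonical`` is False when the junction lacks the
    conserved Cys...Phe anchors or contains a stop codon.
    """

    junction_nt: str
    junction_aa: str
    v_call: str
    j_call: str
    read_count: int
    chain: Chain
    d_call: str = ""
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise FormatError("read_count must be >= 1")

    @property
    def key(self) -> tuple[str, str, str]:
        """Clonotype identity: (junction_nt, v_call, j_call)."""
        return (self.junction_nt, self.v_call, self.j_call)

    @staticmethod
    def is_canonical_aa(junction_aa: str) -> bool:
        return (
            len(junction_aa) >= 2
            and junction_aa.startswith("C")
            and junction_aa.endswith("F")
            and "*" not in junction_aa
        )


def validate_record(junction_nt: str, junction_aa: str) -> tuple[bool, str]:
    """Check nt/aa consistency; returns (ok, reason)."""
    if not junction_nt or not junction_aa:
        return False, "missing junction sequence"
    if not set(junction_nt) <= NUCLEOTIDES:
        return False, "ambiguous or invalid nucleotides"
    if len(junction_nt) != 3 * len(junction_aa):
        return False, "junction_nt length is not 3x junction_aa length"
    try:
        if translate_nt(junction_nt) != junction_aa:
            return False, "translation mismatch"
    except FormatError as exc:
        return False, str(exc)
    return True, ""


@dataclass
class IngestReport:
    """Accounting for rows seen, merged and rejected during ingest."""

    n_rows: int = 0
    n_accepted: int = 0
    n_invalid: int = 0
    invalid_reasons: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class Repertoire:
    """A per-donor clonotype collection with read-count normalisation."""

    donor_id: str
    records: list[ClonotypeRecord]
    chain: Chain
    compartment: Compartment = Compartment.other
    subset_label: str = ""
    ingest: IngestReport | None = None

    @property
    def total_reads(self) -> int:
        return sum(r.read_count for r in self.records)

    @property
    def richness(self) -> int:
        return len(self.records)

    def frequencies(self) -> dict[tuple[str, str, str], float]:
        total = self.total_reads
        return {r.key: r.read_count / total for r in self.records}

    def aa_counts(self, canonical_only: bool = False) -> dict[str, int]:
        """Read counts re-aggregated at the amino-acid level."""
        out: dict[str, int] = {}
        for r in self.records:
            if canonical_only and not r.canonical:
                continue
            out[r.junction_aa] = out.get(r.junction_aa, 0) + r.read_count
        return out

    def aa_set(self, canonical_only: bool = False) -> frozenset[str]:
        return frozenset(self.aa_counts(canonical_only))

    @classmethod
    def from_records(
        cls,
        donor_id: str,
        records: Iterable[ClonotypeRecord],
        chain: Chain,
        **kw,
    ) -> "Repertoire":
        """Aggregate records sharing (junction_nt, v_call, j_call)."""
        merged: dict[tuple[str, str, str], ClonotypeRecord] = {}
        for r in records:
            if r.key in merged:
                prev = merged[r.key]
                merged[r.key] = ClonotypeRecord(
                    junction_nt=prev.junction_nt,
                    junction_aa=prev.junction_aa,
                    v_call=prev.v_call,
                    j_call=prev.j_call,
                    d_call=prev.d_call,
                    read_count=prev.read_count + r.read_count,
                    chain=prev.chain,
                    canonical=prev.canonical,
                )
            else:
                merged[r.key] = r
        return cls(donor_id=donor_id, records=list(merged.values()), chain=chain, **kw)


@dataclass
class Cohort:
    """Repertoires from several donors, each with a group label."""

    repertoires: list[Repertoire]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.repertoires) != len(self.groups):
            raise ValueError("one group label per repertoire required")
        seen: dict[str, set[str]] = {}
        for rep, grp in zip(self.repertoires, self.groups):
            if rep.donor_id in seen.setdefault(grp, set()):
                raise ValueError(
                    f"duplicate donor_id {rep.donor_id!r} in group {grp!r}"
                )
            seen[grp].add(rep.donor_id)

    def donor_ids(self) -> list[str]:
        return [r.donor_id for r in self.repertoires]

    def get(self, donor_id: str) -> Repertoire:
        for r in self.repertoires:
            if r.donor_id == donor_id:
                return r
        raise KeyError(f"no donor {donor_id!r} in cohort")


@dataclass(frozen=True)
class ChainJunction:
    """One chain of a single cell (γ has no D call)."""

    junction_nt: str
    junction_aa: str
    v_call: str
    j_call: str
    d_call: str = ""


@dataclass(frozen=True)
class SingleCellRecord:
    cell_id: str
    donor_id: str
    gamma: ChainJunction | None = None
    delta: ChainJunction | None = None

    def __post_init__(self) -> None:
        if self.gamma is None and self.delta is None:
            raise FormatError(f"cell {self.cell_id}: no chain present")


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V/D/J gene segment with optional anchor annotation.

    ``anchor_offset`` is the 0-based offset of the first nt of the conserved
    Cys codon (V) or Phe codon (J); absent (None) for D segments, which
    instead carry a genomic ``order_index``.
    """

    name: str
    segment_type: str  # "V" | "D" | "J"
    sequence: str
    anchor_offset: int | None = None
    order_index: int | None = None

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "D", "J"):
            raise ReferenceError_(f"bad segment type {self.segment_type!r}")
        if not set(self.sequence) <= NUCLEOTIDES:
            raise ReferenceError_(f"{self.name}: non-ACGT reference sequence")
        if self.segment_type in ("V", "J"):
            off = self.anchor_offset
            if off is None or off < 0 or off + 3 > len(self.sequence):
                raise ReferenceError_(f"{self.name}: anchor offset out of bounds")
            codon = self.sequence[off : off + 3]
            aa = translate_nt(codon)
            want = "C" if self.segment_type == "V" else "F"
            if aa != want:
                raise ReferenceError_(
                    f"{self.name}: anchor codon {codon} translates to {aa}, "
                    f"expected {want}"
                )

    @property
    def junction_region(self) -> str:
        """The part of the segment that can appear inside a junction.

        For V: from the Cys codon to the 3' end. For J: from the 5' end
        through the Phe codon. For D: the whole segment.
        """
        if self.segment_type == "V":
            return self.sequence[self.anchor_offset :]
        if self.segment_type == "J":
            return self.sequence[: self.anchor_offset + 3]
        return self.sequence


def _chain_of(name: str) -> Chain:
    if name.startswith("TRG"):
        return Chain.gamma
    if name.startswith("TRD"):
        return Chain.delta
    raise ReferenceError_(
        f"cannot infer chain for segment {name!r} (expected TRG*/TRD* name)"
    )


@dataclass
class GermlineReference:
    """Named germline segments partitioned into γ and δ sets."""

    segments: dict[str, GermlineSegment]

    def __post_init__(self) -> None:
        for name, seg in self.segments.items():
            if name != seg.name:
                raise ReferenceError_("segment keyed under wrong name")
            chain = _chain_of(name)
            if seg.segment_type == "D" and chain is not Chain.delta:
                raise ReferenceError_(f"{name}: D segments belong to the δ set")
            if seg.segment_type == "D" and seg.order_index is None:
                raise ReferenceError_(f"{name}: D segment lacks genomic order index")

    def __getitem__(self, name: str) -> GermlineSegment:
        try:
            return self.segments[name]
        except KeyError:
            raise ReferenceError_(f"segment {name!r} not in reference") from None

    def by_type(self, segment_type: str, chain: Chain | None = None) -> list[GermlineSegment]:
        out = [
            s
            for s in self.segments.values()
            if s.segment_type == segment_type
            and (chain is None or _chain_of(s.name) is chain)
        ]
        if segment_type == "D":
            out.sort(key=lambda s: s.order_index)
        else:
            out.sort(key=lambda s: s.name)
        return out

    def chain_of(self, name: str) -> Chain:
        return _chain_of(self[name].name)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_clonotype_table(
    path: str | Path,
    chain: Chain,
    donor_id: str,
    column_map: Mapping[str, str] | None = None,
    compartment: Compartment = Compartment.other,
    subset_label: str = "",
) -> Repertoire:
    """Read an AIRR-style clonotype TSV into an aggregated :class:`Repertoire`.

    Rows with identical (junction, v_call, j_call) are merged with summed
    counts. Malformed rows (translation mismatch, ambiguity codes, bad
    counts) are excluded from the aggregate but counted in the attached
    :class:`IngestReport`, never silently dropped.
    """
    cols = dict(AIRR_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path}: empty clonotype table") from None
    required = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]
    for key in required:
        if cols[key] not in df.columns:
            raise FormatError(f"{path}: missing required column {cols[key]!r}")
    if len(df) == 0:
        raise EmptyRepertoireError(f"{path}: clonotype table has no data rows")

    report = IngestReport(n_rows=len(df))
    records: list[ClonotypeRecord] = []
    has_d = cols["d_call"] in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        nt = row[cols["junction"]].strip().upper()
        aa = row[cols["junction_aa"]].strip().upper()
        ok, reason = validate_record(nt, aa)
        if not ok:
            report.n_invalid += 1
            report.invalid_reasons.append((i, reason))
            continue
        try:
            count = int(row[cols["duplicate_count"]])
        except ValueError:
            report.n_invalid += 1
            report.invalid_reasons.append((i, "non-integer duplicate_count"))
            continue
        if count < 1:
            report.n_invalid += 1
            report.invalid_reasons.append((i, "duplicate_count < 1"))
            continue
        records.append(
            ClonotypeRecord(
                junction_nt=nt,
                junction_aa=aa,
                v_call=row[cols["v_call"]].strip(),
                j_call=row[cols["j_call"]].strip(),
                d_call=row[cols["d_call"]].strip() if has_d else "",
                read_count=count,
                chain=chain,
                canonical=ClonotypeRecord.is_canonical_aa(aa),
            )
        )
    report.n_accepted = len(records)
    rep = Repertoire.from_records(
        donor_id,
        records,
        chain,
        compartment=compartment,
        subset_label=subset_label,
    )
    rep.ingest = report
    return rep


def write_clonotype_table(repertoire: Repertoire, path: str | Path) -> None:
    """Write a Repertoire back to AIRR-style TSV, sorted by junction_nt.

    The fixed sort makes output byte-stable, so read(write(r)) reproduces
    r's aggregated content exactly.
    """
    rows = sorted(repertoire.records, key=lambda r: (r.junction_nt, r.v_call, r.j_call))
    df = pd.DataFrame(
        {
            "junction": [r.junction_nt for r in rows],
            "junction_aa": [r.junction_aa for r in rows],
            "v_call": [r.v_call for r in rows],
            "d_call": [r.d_call for r in rows],
            "j_call": [r.j_call for r in rows],
            "duplicate_count": [r.read_count for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_single_cell_table(path: str | Path) -> list[SingleCellRecord]:
    """Read a single-cell table: one row per chain, shared ``cell_id``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path}: empty single-cell table") from None
    required = ["cell_id", "donor_id", "chain", "junction", "junction_aa", "v_call", "j_call"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    cells: dict[str, dict] = {}
    for row in df.to_dict("records"):
        cj = ChainJunction(
            junction_nt=row["junction"].strip().upper(),
            junction_aa=row["junction_aa"].strip().upper(),
            v_call=row["v_call"].strip(),
            j_call=row["j_call"].strip(),
            d_call=row.get("d_call", "").strip(),
        )
        entry = cells.setdefault(
            row["cell_id"], {"donor_id": row["donor_id"], "gamma": None, "delta": None}
        )
        entry[row["chain"]] = cj
    return [
        SingleCellRecord(cell_id=cid, donor_id=e["donor_id"], gamma=e["gamma"], delta=e["delta"])
        for cid, e in cells.items()
    ]


def write_single_cell_table(cells: list[SingleCellRecord], path: str | Path) -> None:
    rows = []
    for cell in cells:
        for chain_name in ("gamma", "delta"):
            cj: ChainJunction | None = getattr(cell, chain_name)
            if cj is None:
                continue
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "donor_id": cell.donor_id,
                    "chain": chain_name,
                    "junction": cj.junction_nt,
                    "junction_aa": cj.junction_aa,
                    "v_call": cj.v_call,
                    "d_call": cj.d_call,
                    "j_call": cj.j_call,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_germline_reference(path: str | Path) -> GermlineReference:
    """Load a germline FASTA with ``>NAME|TYPE|anchor=N|order=K`` headers.

    ``anchor`` is required for V and J entries, ``order`` for D entries.
    Anchor codons are verified to translate to Cys (V) / Phe (J).
    """
    from Bio import SeqIO

    segments: dict[str, GermlineSegment] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 2:
            raise FormatError(f"bad germline header {rec.id!r}")
        name, seg_type = fields[0], fields[1]
        anchor = None
        order = None
        for extra in fields[2:]:
            if extra.startswith("anchor="):
                anchor = int(extra.split("=", 1)[1])
            elif extra.startswith("order="):
                order = int(extra.split("=", 1)[1])
        if name in segments:
            raise ReferenceError_(f"duplicate segment name {name!r}")
        segments[name] = GermlineSegment(
            name=name,
            segment_type=seg_type,
            sequence=str(rec.seq).upper(),
            anchor_offset=anchor,
            order_index=order,
        )
    if not segments:
        raise ReferenceError_(f"{path}: no segments in reference")
    return GermlineReference(segments=segments)


def write_germline_reference(reference: GermlineReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference.segments):
            seg = reference.segments[name]
            header = f">{name}|{seg.segment_type}"
            if seg.anchor_offset is not None:
                header += f"|anchor={seg.anchor_offset}"
            if seg.order_index is not None:
                header += f"|order={seg.order_index}"
            fh.write(header + "\n" + seg.sequence + "\n")
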