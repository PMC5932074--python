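"""Generative V(D)J cohort simulator with per-clone ground truth.

Each clone's junction is built the way recombination builds it: choose
segments, trim their ends with a truncated geometric distribution, add
palindromic P nucleotides at untrimmed ends, fill the gaps with
non-templated N nucleotides of Poisson-distributed length, and reject
out-of-frame or stop-containing joints. Public amino-acid sequences enter
the cohort through two channels that mirror the biology: pure germline
joints (zero trim, zero N) that any donor can produce, and cohort-wide
seed clonotypes injected into each donor with probability ``p_public``.

The bundled default germline reference is synthetic (3 Vγ, 3 Jγ, 1 Vδ,
3 Dδ, 4 Jδ with anchor annotations); its Vγ9/JγP pair concatenates to the
canonical germline CALWEVQELGKKIKVF junction. An IMGT-derived reference
can be substituted through the same FASTA interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    Chain,
    ChainJunction,
    ClonotypeRecord,
    Cohort,
    GdrepError,
    GermlineReference,
    GermlineSegment,
    Repertoire,
    SingleCellRecord,
    translate_nt,
    write_clonotype_table,
    write_germline_reference,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationError(GdrepError):
    pass


def default_reference() -> GermlineReference:
    """Small synthetic γ/δ germline set used by default.

    Segment bodies are inventions chosen so that every V/J junction region
    is stop-free and a codon multiple, and the Vγ9/JγP germline joint
    reproduces the canonical public CALWEVQELGKKIKVF junction.
    """
    segs = [
        # name, type, pad5 + junction region (+ pad3 for J), anchor, order
        GermlineSegment("TRGV9", "V", "GGAGAA" + "TGTGCCTTGTGGGAGGTG", 6, None),
        GermlineSegment("TRGV5", "V", "GGAGAA" + "TGTGCCACCTGGGAC", 6, None),
        GermlineSegment("TRGV8", "V", "GGAGAA" + "TGTGCCGTGTGGATT", 6, None),
        GermlineSegment("TRGJP", "J", "CAAGAGTTGGGCAAAAAAATCAAGGTATTT" + "GGTAAA", 27, None),
        GermlineSegment("TRGJ1", "J", "AATTATTATAAGAAACTCTTT" + "GGTAAA", 18, None),
        GermlineSegment("TRGJ2", "J", "AGTTATTGGGACACGTTT" + "GGTAAA", 15, None),
        GermlineSegment("TRDV2", "V", "GGAGAA" + "TGTGCCTGTGACACC", 6, None),
        GermlineSegment("TRDD1", "D", "GAAATAGT", None, 1),
        GermlineSegment("TRDD2", "D", "CCTTCCTAC", None, 2),
        GermlineSegment("TRDD3", "D", "ACTGGGGGATACG", None, 3),
        GermlineSegment("TRDJ1", "J", "ACCGATAAACTCATCTTT" + "GGTAAA", 15, None),
        GermlineSegment("TRDJ2", "J", "TCCTGGGACACCCGACAGATGTTT" + "GGTAAA", 21, None),
        GermlineSegment("TRDJ3", "J", "GACTCCTCCGATAAGCTCATCTTT" + "GGTAAA", 21, None),
        GermlineSegment("TRDJ4", "J", "CCTCTCATCTTT" + "GGTAAA", 9, None),
    ]
    return GermlineReference(segments={s.name: s for s in segs})


@dataclass
class RecombinationModel:
    """Generative parameters for one cohort.

    Probability dicts are per chain; segment names must exist in the
    reference. Trims are geometric(p_trim) per end, truncated so every
    retained segment keeps at least ``min_keep`` nucleotides (the V/J
    anchor codons and a detectable D core). λ_n is the Poisson mean of
    each N region's length. P nucleotides appear at an untrimmed end with
    probability ``p_p``, with geometric(0.5) length capped at ``max_p``.
    """

    reference: GermlineReference = field(default_factory=default_reference)
    gamma_v_probs: dict[str, float] = field(
        default_factory=lambda: {"TRGV9": 0.8, "TRGV5": 0.1, "TRGV8": 0.1}
    )
    gamma_j_probs: dict[str, float] = field(
        default_factory=lambda: {"TRGJP": 0.7, "TRGJ1": 0.2, "TRGJ2": 0.1}
    )
    delta_v_probs: dict[str, float] = field(default_factory=lambda: {"TRDV2": 1.0})
    delta_j_probs: dict[str, float] = field(
        default_factory=lambda: {"TRDJ1": 0.55, "TRDJ3": 0.3, "TRDJ2": 0.1, "TRDJ4": 0.05}
    )
    d_count_probs: dict[int, float] = field(default_factory=lambda: {1: 0.85, 2: 0.15})
    p_trim: float = 0.35
    lambda_n: float = 2.0
    n_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.2, "C": 0.3, "G": 0.3, "T": 0.2}
    )
    p_p: float = 0.3
    max_p: int = 3
    p_public: float = 0.2
    n_public_seeds: int = 5
    zipf_alpha: float = 1.5
    clones_per_donor: int = 1000
    min_keep: int = 3
    max_retries: int = 1000

    def __post_init__(self) -> None:
        for name, probs in [
            ("gamma_v_probs", self.gamma_v_probs),
            ("gamma_j_probs", self.gamma_j_probs),
            ("delta_v_probs", self.delta_v_probs),
            ("delta_j_probs", self.delta_j_probs),
            ("d_count_probs", self.d_count_probs),
            ("n_composition", self.n_composition),
        ]:
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"{name} sums to {total}, expected 1")
        if self.lambda_n < 0 or not (0 <= self.p_public <= 1):
            raise SimulationError("invalid lambda_n or p_public")


@dataclass
class ChainTruth:
    """Ground-truth parts of one simulated chain rearrangement."""

    chain: Chain
    v_name: str
    j_name: str
    d_names: list[str]
    v_trim: int
    j_trim: int
    d5_trims: list[int]
    d3_trims: list[int]
    p_v: str
    p_j: str
    d_p5: list[str]
    d_p3: list[str]
    n_regions: list[str]
    junction_nt: str
    junction_aa: str

    @property
    def n_total(self) -> int:
        return sum(len(s) for s in self.n_regions)

    @property
    def is_germline_joint(self) -> bool:
        trims = self.v_trim + self.j_trim + sum(self.d5_trims) + sum(self.d3_trims)
        return trims == 0 and self.n_total == 0

    def reconstruct(self, reference: GermlineReference) -> str:
        v = reference[self.v_name].junction_region
        j = reference[self.j_name].junction_region
        parts = [v[: len(v) - self.v_trim], self.p_v]
        for i, dn in enumerate(self.d_names):
            d = reference[dn].sequence
            parts.append(self.n_regions[i])
            parts.append(self.d_p5[i])
            parts.append(d[self.d5_trims[i] : len(d) - self.d3_trims[i]])
            parts.append(self.d_p3[i])
        parts.append(self.n_regions[-1])
        parts.append(self.p_j)
        parts.append(j[self.j_trim :])
        return "".join(parts)


@dataclass
class CloneTruth:
    clone_id: str
    donor_id: str
    size: int
    gamma: ChainTruth
    delta: ChainTruth
    public_seed: bool


@dataclass
class SimulatedTruth:
    clones: list[CloneTruth]
    public_seeds: list[ChainTruth]


@dataclass
class SimulationResult:
    gamma: Cohort
    delta: Cohort
    truth: SimulatedTruth
    model: RecombinationModel


def _choice(rng: np.random.Generator, probs: dict) -> object:
    keys = sorted(probs, key=str)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _trunc_geometric(rng: np.random.Generator, p: float, max_value: int) -> int:
    if max_value <= 0:
        return 0
    return min(int(rng.geometric(p)) - 1, max_value)


def _sample_p(
    rng: np.random.Generator, terminal: str, p_p: float, max_p: int,
    prepend: bool = False,
) -> str:
    """Palindromic extension of a segment end; ``terminal`` reads outward.

    For P placed *before* a segment (``prepend``) the string is reversed so
    that the base adjacent to the segment complements its first base.
    """
    if rng.random() >= p_p:
        return ""
    length = min(int(rng.geometric(0.5)), max_p, len(terminal))
    p = "".join(_COMPLEMENT[terminal[i]] for i in range(length))
    return p[::-1] if prepend else p


def _sample_n(rng: np.random.Generator, model: RecombinationModel) -> str:
    length = int(rng.poisson(model.lambda_n))
    bases = sorted(model.n_composition)
    p = np.array([model.n_composition[b] for b in bases])
    return "".join(bases[int(i)] for i in rng.choice(4, size=length, p=p / p.sum()))


def sample_rearrangement(
    model: RecombinationModel,
    rng: np.random.Generator,
    chain: Chain,
    force_germline: bool = False,
) -> ChainTruth:
    """Draw one in-frame, stop-free rearrangement for the given chain.

    ``force_germline`` produces a zero-trim, zero-N, zero-P V–J joint
    (the germline channel of publicity); only γ joints are guaranteed
    in-frame by construction, so forcing is restricted to γ.
    """
    ref = model.reference
    if chain is Chain.gamma:
        v_probs, j_probs = model.gamma_v_probs, model.gamma_j_probs
    else:
        v_probs, j_probs = model.delta_v_probs, model.delta_j_probs

    for _ in range(model.max_retries):
        v_name = str(_choice(rng, v_probs))
        j_name = str(_choice(rng, j_probs))
        v = ref[v_name].junction_region
        j = ref[j_name].junction_region
        if force_germline:
            truth = ChainTruth(
                chain=chain, v_name=v_name, j_name=j_name, d_names=[],
                v_trim=0, j_trim=0, d5_trims=[], d3_trims=[],
                p_v="", p_j="", d_p5=[], d_p3=[], n_regions=[""],
                junction_nt="", junction_aa="",
            )
        else:
            v_trim = _trunc_geometric(rng, model.p_trim, len(v) - model.min_keep)
            j_trim = _trunc_geometric(rng, model.p_trim, len(j) - model.min_keep)
            d_names: list[str] = []
            d5_trims: list[int] = []
            d3_trims: list[int] = []
            if chain is Chain.delta:
                n_d = int(_choice(rng, model.d_count_probs))
                d_segs = ref.by_type("D", Chain.delta)
                idx = sorted(
                    rng.choice(len(d_segs), size=min(n_d, len(d_segs)), replace=False)
                )
                for i in idx:
                    d = d_segs[int(i)]
                    budget = len(d.sequence) - model.min_keep
                    t5 = _trunc_geometric(rng, model.p_trim, budget)
                    t3 = _trunc_geometric(rng, model.p_trim, budget - t5)
                    d_names.append(d.name)
                    d5_trims.append(t5)
                    d3_trims.append(t3)
            p_v = (
                _sample_p(rng, v[::-1], model.p_p, model.max_p) if v_trim == 0 else ""
            )
            p_j = (
                _sample_p(rng, j, model.p_p, model.max_p, prepend=True)
                if j_trim == 0
                else ""
            )
            d_p5 = []
            d_p3 = []
            for dn, t5, t3 in zip(d_names, d5_trims, d3_trims):
                d = ref[dn].sequence
                d_p5.append(
                    _sample_p(rng, d, model.p_p, model.max_p, prepend=True)
                    if t5 == 0
                    else ""
                )
                d_p3.append(
                    _sample_p(rng, d[::-1], model.p_p, model.max_p) if t3 == 0 else ""
                )
            n_regions = [_sample_n(rng, model) for _ in range(len(d_names) + 1)]
            truth = ChainTruth(
                chain=chain, v_name=v_name, j_name=j_name, d_names=d_names,
                v_trim=v_trim, j_trim=j_trim, d5_trims=d5_trims, d3_trims=d3_trims,
                p_v=p_v, p_j=p_j, d_p5=d_p5, d_p3=d_p3, n_regions=n_regions,
                junction_nt="", junction_aa="",
            )
        junction = truth.reconstruct(ref)
        if len(junction) % 3 != 0:
            continue
        aa = translate_nt(junction)
        if "*" in aa or not (aa.startswith("C") and aa.endswith("F")):
            continue
        truth.junction_nt = junction
        truth.junction_aa = aa
        return truth
    raise SimulationError(
        f"no viable {chain.value} junction in {model.max_retries} tries "
        f"(p_trim={model.p_trim}, lambda_n={model.lambda_n})"
    )


def sample_clone(
    model: RecombinationModel,
    rng: np.random.Generator,
    public_gamma: ChainTruth | None = None,
) -> tuple[ChainTruth, ChainTruth]:
    """One paired clone: a γ rearrangement (possibly a shared public seed)
    and an independently drawn δ rearrangement."""
    gamma = public_gamma if public_gamma is not None else sample_rearrangement(
        model, rng, Chain.gamma
    )
    delta = sample_rearrangement(model, rng, Chain.delta)
    return gamma, delta


def draw_public_seeds(
    model: RecombinationModel, rng: np.random.Generator
) -> list[ChainTruth]:
    """Cohort-wide public γ seeds: distinct germline joints first, then
    distinct ordinary rearrangements if the germline combinations run out."""
    seeds: list[ChainTruth] = []
    seen: set[str] = set()
    stale = 0
    while len(seeds) < model.n_public_seeds and stale < 50:
        t = sample_rearrangement(model, rng, Chain.gamma, force_germline=True)
        if t.junction_nt in seen:
            stale += 1
            continue
        seen.add(t.junction_nt)
        seeds.append(t)
        stale = 0
    while len(seeds) < model.n_public_seeds:
        t = sample_rearrangement(model, rng, Chain.gamma)
        if t.junction_nt in seen:
            continue
        seen.add(t.junction_nt)
        seeds.append(t)
    return seeds


def simulate_cohort(
    model: RecombinationModel,
    n_donors: int,
    clones_per_donor: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulationResult:
    """Simulate per-donor γ and δ repertoires plus full ground truth.

    Public seeds are drawn once; each clone's γ chain is replaced by a
    uniformly chosen seed with probability ``p_public``. Clone sizes are
    Zipf(α)-distributed, truncated at ``clones_per_donor``.
    """
    if n_donors < 1:
        raise SimulationError("n_donors must be >= 1")
    if clones_per_donor is None:
        clones_per_donor = model.clones_per_donor
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seeds = draw_public_seeds(model, rng) if model.p_public > 0 else []

    clones: list[CloneTruth] = []
    gamma_reps: list[Repertoire] = []
    delta_reps: list[Repertoire] = []
    for d in range(n_donors):
        donor_id = f"sim{d + 1:02d}"
        g_records: list[ClonotypeRecord] = []
        d_records: list[ClonotypeRecord] = []
        for c in range(clones_per_donor):
            is_public = bool(seeds) and rng.random() < model.p_public
            seed = seeds[int(rng.integers(len(seeds)))] if is_public else None
            gamma, delta = sample_clone(model, rng, public_gamma=seed)
            size = min(int(rng.zipf(model.zipf_alpha)), clones_per_donor)
            clones.append(
                CloneTruth(
                    clone_id=f"{donor_id}.c{c + 1}",
                    donor_id=donor_id,
                    size=size,
                    gamma=gamma,
                    delta=delta,
                    public_seed=is_public,
                )
            )
            g_records.append(
                ClonotypeRecord(
                    junction_nt=gamma.junction_nt, junction_aa=gamma.junction_aa,
                    v_call=gamma.v_name, j_call=gamma.j_name,
                    read_count=size, chain=Chain.gamma,
                )
            )
            d_records.append(
                ClonotypeRecord(
                    junction_nt=delta.junction_nt, junction_aa=delta.junction_aa,
                    v_call=delta.v_name, j_call=delta.j_name,
                    d_call=",".join(delta.d_names), read_count=size,
                    chain=Chain.delta,
                )
            )
        gamma_reps.append(
            Repertoire.from_records(donor_id, g_records, Chain.gamma, subset_label="Vg9")
        )
        delta_reps.append(
            Repertoire.from_records(donor_id, d_records, Chain.delta, subset_label="Vd2")
        )

    groups = ["simulated"] * n_donors
    return SimulationResult(
        gamma=Cohort(gamma_reps, groups),
        delta=Cohort(delta_reps, groups),
        truth=SimulatedTruth(clones=clones, public_seeds=seeds),
        model=model,
    )


def sample_single_cells(
    truth: SimulatedTruth,
    n_cells: int,
    rng: np.random.Generator | int | None = None,
    donor_id: str | None = None,
) -> list[SingleCellRecord]:
    """Draw single cells without replacement, proportional to clone size."""
    if n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clones = [
        c for c in truth.clones if donor_id is None or c.donor_id == donor_id
    ]
    pool = np.repeat(np.arange(len(clones)), [c.size for c in clones])
    if n_cells > len(pool):
        raise SimulationError(f"only {len(pool)} cells available, asked {n_cells}")
    picks = rng.choice(pool, size=n_cells, replace=False)
    cells = []
    for i, idx in enumerate(picks):
        clone = clones[int(idx)]
        cells.append(
            SingleCellRecord(
                cell_id=f"cell{i + 1:04d}",
                donor_id=clone.donor_id,
                gamma=ChainJunction(
                    junction_nt=clone.gamma.junction_nt,
                    junction_aa=clone.gamma.junction_aa,
                    v_call=clone.gamma.v_name,
                    j_call=clone.gamma.j_name,
                ),
                delta=ChainJunction(
                    junction_nt=clone.delta.junction_nt,
                    junction_aa=clone.delta.junction_aa,
                    v_call=clone.delta.v_name,
                    j_call=clone.delta.j_name,
                    d_call=",".join(clone.delta.d_names),
                ),
            )
        )
    return cells


def write_cohort(result: SimulationResult, out_dir: str | Path) -> None:
    """Write per-donor AIRR TSVs, the truth table and the germline FASTA."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rep in result.gamma.repertoires:
        write_clonotype_table(rep, out / f"{rep.donor_id}_gamma.tsv")
    for rep in result.delta.repertoires:
        write_clonotype_table(rep, out / f"{rep.donor_id}_delta.tsv")
    write_germline_reference(result.model.reference, out / "germline.fasta")
    import pandas as pd

    rows = []
    for c in result.truth.clones:
        for chain_name, t in (("gamma", c.gamma), ("delta", c.delta)):
            rows.append(
                {
                    "clone_id": c.clone_id, "donor_id": c.donor_id,
                    "chain": chain_name, "size": c.size,
                    "public_seed": c.public_seed, "v_name": t.v_name,
                    "d_names": ",".join(t.d_names), "j_name": t.j_name,
                    "v_trim": t.v_trim, "j_trim": t.j_trim,
                    "d5_trims": ",".join(map(str, t.d5_trims)),
                    "d3_trims": ",".join(map(str, t.d3_trims)),
                    "p_v": t.p_v, "p_j": t.p_j,
                    "n_regions": ",".join(t.n_regions),
                    "junction": t.junction_nt, "junction_aa": t.junction_aa,
                }
            )
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
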