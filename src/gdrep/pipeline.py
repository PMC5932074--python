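"""End-to-end orchestration: junction → stats → publicity → logo on a cohort directory.

A cohort directory holds per-donor AIRR TSVs named ``<donor>_gamma.tsv`` /
``<donor>_delta.tsv`` plus a ``germline.fasta`` reference. Each stage
writes one TSV; a run manifest records the config snapshot, seed and
per-stage record counts. All randomness flows from the single recorded
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (
    Chain,
    GdrepError,
    Cohort,
    load_germline_reference,
    read_clonotype_table,
)
from .junctions import DecomposeOptions, decompose
from .logos import frequency_matrix, select_stratum, shannon_heights
from .publicity import (
    convergence_report,
    overlap_matrix,
    sharing_fraction,
    top_shared_hierarchy,
)
from .stats import diversity_metrics, segment_usage, spectratype, treemap_layout

log = logging.getLogger("gdrep")


class PipelineError(GdrepError):
    pass


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "out"
    level: str = "nt"
    top_n: int = 10
    d75_threshold: float = 0.75
    min_other_donors: int = 1
    share_threshold_donors: int = 2
    amplified_min_freq: float = 0.10
    logo_chain: str = "delta"
    logo_j: str = "TRDJ1"
    logo_lengths: tuple[int, int] = (14, 16)
    logo_top_k: int = 10
    min_d_match: int = 3
    max_p: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.d75_threshold <= 1):
            raise PipelineError("d75_threshold must lie in (0, 1]")
        if self.top_n < 1 or self.logo_top_k < 1:
            raise PipelineError("top_n and logo_top_k must be >= 1")
        if not (0 <= self.amplified_min_freq <= 1):
            raise PipelineError("amplified_min_freq must lie in [0, 1]")
        if self.level not in ("nt", "aa"):
            raise PipelineError(f"unknown analysis level {self.level!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["logo_lengths"] = list(self.logo_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "logo_lengths" in data:
            data["logo_lengths"] = tuple(data["logo_lengths"])
        return cls(**data)


def load_cohort_dir(input_dir: str | Path, chain: Chain) -> Cohort:
    suffix = f"_{chain.value}.tsv"
    paths = sorted(Path(input_dir).glob(f"*{suffix}"))
    if not paths:
        raise PipelineError(f"no *{suffix} tables in {input_dir}")
    reps = [
        read_clonotype_table(p, chain, donor_id=p.name[: -len(suffix)])
        for p in paths
    ]
    return Cohort(reps, ["cohort"] * len(reps))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "load"
    try:
        gamma = load_cohort_dir(config.input_dir, Chain.gamma)
        delta = load_cohort_dir(config.input_dir, Chain.delta)
        reference = load_germline_reference(Path(config.input_dir) / "germline.fasta")
        manifest["stages"]["load"] = {
            "donors": gamma.donor_ids(),
            "gamma_records": sum(r.richness for r in gamma.repertoires),
            "delta_records": sum(r.richness for r in delta.repertoires),
        }

        stage = "junction"
        opts = DecomposeOptions(min_d_match=config.min_d_match, max_p=config.max_p)
        rows = []
        for cohort in (gamma, delta):
            for rep in cohort.repertoires:
                for rec in rep.records:
                    d = decompose(rec.junction_nt, rec.v_call, rec.j_call, reference, opts)
                    rows.append(
                        {
                            "donor_id": rep.donor_id,
                            "chain": rec.chain.value,
                            "junction": rec.junction_nt,
                            "junction_aa": rec.junction_aa,
                            "v_call": rec.v_call,
                            "j_call": rec.j_call,
                            "v_trim": d.v_trim,
                            "p_v": d.p_v,
                            "n_regions": ",".join(d.n_regions),
                            "d_parts": ";".join(
                                f"{p.d_name}:{p.d_contrib}:{p.d5_trim}:{p.d3_trim}"
                                for p in d.d_parts
                            ),
                            "p_j": d.p_j,
                            "j_trim": d.j_trim,
                            "n_total": d.n_total,
                            "p_total": d.p_total,
                            "is_germline": d.is_germline,
                        }
                    )
        junctions_df = pd.DataFrame(rows)
        junctions_df.to_csv(out / "junctions.tsv", sep="\t", index=False)
        manifest["stages"]["junction"] = {"rows": len(rows)}

        stage = "stats"
        rows = []
        for cohort, chain in ((gamma, "gamma"), (delta, "delta")):
            for rep in cohort.repertoires:
                m = diversity_metrics(
                    rep, config.level, config.top_n, config.d75_threshold
                )
                spec = spectratype(rep)
                usage_j = segment_usage(rep, "J")
                rows.append(
                    {
                        "donor_id": rep.donor_id,
                        "chain": chain,
                        "richness": m.richness,
                        "d75": m.d75,
                        "top_n_accumulated": m.top_n_accumulated,
                        "level": m.level,
                        "spectratype": ";".join(
                            f"{k}:{v:.6f}" for k, v in spec.fractions.items()
                        ),
                        "j_usage": ";".join(
                            f"{k}:{v:.6f}" for k, v in usage_j.fractions.items()
                        ),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "stats.tsv", sep="\t", index=False)
        manifest["stages"]["stats"] = {"rows": len(rows)}

        stage = "treemap"
        rows = []
        for rep in gamma.repertoires:
            layout = treemap_layout(rep)
            for r in layout.rects:
                rows.append(
                    {
                        "donor_id": rep.donor_id,
                        "id": r.clonotype_id,
                        "v_call": r.v_call,
                        "x": round(r.x, 6),
                        "y": round(r.y, 6),
                        "w": round(r.w, 6),
                        "h": round(r.h, 6),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "treemap.tsv", sep="\t", index=False)
        manifest["stages"]["treemap"] = {"rows": len(rows)}

        stage = "publicity"
        sharing_rows = []
        for cohort, chain in ((gamma, "gamma"), (delta, "delta")):
            for donor in cohort.donor_ids():
                rep_share = sharing_fraction(
                    cohort, donor, min_other_donors=config.min_other_donors
                )
                sharing_rows.append(
                    {
                        "donor_id": donor,
                        "chain": chain,
                        "sharing_fraction": rep_share.fraction,
                        "min_other_donors": rep_share.min_other_donors,
                        "weighting": rep_share.weighting,
                    }
                )
        pd.DataFrame(sharing_rows).to_csv(out / "sharing.tsv", sep="\t", index=False)

        om = overlap_matrix(gamma)
        pd.DataFrame(om.values, index=om.donor_ids, columns=om.donor_ids).to_csv(
            out / "overlap.tsv", sep="\t"
        )
        hierarchy = top_shared_hierarchy(
            gamma,
            n=config.top_n,
            share_threshold_donors=config.share_threshold_donors,
            amplified_min_freq=config.amplified_min_freq,
        )
        pd.DataFrame(
            [
                {
                    "junction_aa": e.junction_aa,
                    "n_donors": e.n_donors,
                    "mean_frequency": e.mean_frequency,
                    "inclusion": e.inclusion,
                }
                for e in hierarchy.entries
            ]
        ).to_csv(out / "hierarchy.tsv", sep="\t", index=False)

        conv_rows = []
        decompositions = {}
        for rep in gamma.repertoires:
            for rec in rep.records:
                if rec.junction_nt not in decompositions:
                    decompositions[rec.junction_nt] = decompose(
                        rec.junction_nt, rec.v_call, rec.j_call, reference, opts
                    )
        conv = convergence_report(gamma, decompositions)
        for aa, group in sorted(conv.groups.items()):
            conv_rows.append(
                {
                    "junction_aa": aa,
                    "n_variants": len(group.variants),
                    "is_convergent": group.is_convergent,
                    "n_germline": group.n_germline,
                }
            )
        pd.DataFrame(conv_rows).to_csv(out / "convergence.tsv", sep="\t", index=False)
        manifest["stages"]["publicity"] = {
            "sharing_rows": len(sharing_rows),
            "hierarchy_rows": len(hierarchy.entries),
            "convergent_groups": conv.n_convergent,
        }

        stage = "logo"
        rows = []
        cohort = delta if config.logo_chain == "delta" else gamma
        for rep in cohort.repertoires:
            seqs = select_stratum(
                rep, config.logo_j, config.logo_lengths, config.logo_top_k
            )
            if not seqs:
                continue
            pfms = frequency_matrix(seqs, "per_length", stratum=rep.donor_id)
            if not isinstance(pfms, list):
                pfms = [pfms]
            for pfm in pfms:
                logo = shannon_heights(pfm)
                for pos, col in enumerate(logo.columns, start=1):
                    for res, h in sorted(col.heights.items()):
                        rows.append(
                            {
                                "donor_id": rep.donor_id,
                                "stratum": pfm.stratum,
                                "position": pos,
                                "residue": res,
                                "frequency": pfm.columns[pos - 1][res],
                                "height_bits": h,
                                "class": col.classes[res],
                            }
                        )
        pd.DataFrame(rows).to_csv(out / "logo.tsv", sep="\t", index=False)
        manifest["stages"]["logo"] = {"rows": len(rows)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        failed_marker.write_text(f"{stage}: {exc}\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
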