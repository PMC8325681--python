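"""End-to-end orchestration: synteny -> duplicate modes -> Ks -> dating ->
tree topology -> karyotype, with one seeded config and a JSON report.

The pipeline runs either on user-supplied files (gene positions, pairs
with Ks or CDS FASTA, Newick trees) or, by default, on a self-contained
simulation whose ground truth is folded into the report.  Reports are
hash-stable for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import (
    chromosome_evolution,
    dup_classifier,
    io_formats,
    kaks,
    ks_distribution,
    synteny,
    synthetic_data,
    tree_topology,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated run configuration; unset paths mean 'simulate'."""

    seed: int = 1
    output_dir: str = "paleowgd_out"
    # input paths (all optional; simulation fills the gaps)
    genome_path: str | None = None
    pairs_path: str | None = None
    cds_path: str | None = None
    trees_dir: str | None = None
    species: str = "Cs"
    # simulation plan overrides
    simulate: dict[str, Any] = field(default_factory=dict)
    divergence_ks: float = 0.781
    partner_rate_factor: float = 1.25
    # synteny parameters
    max_gap: int = 25
    min_block_size: int = 5
    # Ks distribution
    ks_lo: float = 0.01
    ks_hi: float = 3.0
    peak_method: str = "gmm"
    k_max: int = 4
    # calibration (Ks_cal, T_cal in MY); None skips dating
    calibration: tuple[float, float] | None = (0.781, 118.0)
    # tree classification
    focal: str = "Cs"
    partners: tuple[str, ...] = ("Ac", "Rs")
    outgroups: tuple[str, ...] = ("Vv",)
    n_trees: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "calibration" in raw and raw["calibration"] is not None:
            raw["calibration"] = tuple(raw["calibration"])
        for key in ("partners", "outgroups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if cfg.seed is None:
            raise ValueError("config must set a seed")
        for key in ("genome_path", "pairs_path", "cds_path", "trees_dir"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{key} does not exist: {p}")
        return cfg


def _report_hash(report: dict) -> str:
    canonical = json.dumps(report, sort_keys=True).encode()
    return hashlib.sha256(canonical).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the full JSON report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed}

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        simulated = config.genome_path is None
        if simulated:
            plan = synthetic_data.SimulationPlan(
                seed=config.seed, species=config.species, **config.simulate
            )
            genome, pairs, truth = synthetic_data.simulate_wgd_genome(plan)
            outgroup, ortho_pairs = synthetic_data.simulate_outgroup_genome(
                plan, config.divergence_ks
            )
            report["inputs"] = {
                "mode": "simulated",
                "n_genes": len(genome),
                "n_chromosomes": len(genome.chromosomes),
                "n_pairs": len(pairs),
                "truth": {
                    "n_ancestral": truth.n_ancestral,
                    "n_fissions": truth.n_fissions,
                    "n_fusions": truth.n_fusions,
                    "n_extant": truth.n_extant,
                    "n_retained_wgd_pairs": truth.n_retained_wgd_pairs,
                },
            }
        else:
            genome = io_formats.read_gene_positions(
                config.genome_path,
                species=config.species,
                dialect="tsv" if str(config.genome_path).endswith(".tsv") else "gff3",
            )
            pairs = io_formats.read_pairs(config.pairs_path)
            outgroup = None
            ortho_pairs = None
            truth = None
            report["inputs"] = {
                "mode": "files",
                "n_genes": len(genome),
                "n_chromosomes": len(genome.chromosomes),
                "n_pairs": len(pairs),
            }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: synteny ------------------------------------------------
    stage = "synteny"
    try:
        self_blocks = synteny.self_synteny(
            genome,
            pairs,
            max_gap=config.max_gap,
            min_block_size=config.min_block_size,
        )
        n_anchors = sum(len(b) for b in self_blocks)
        synteny.blocks_table(self_blocks).to_csv(
            outdir / "self_blocks.tsv", sep="\t", index=False
        )
        self_depth = synteny.depth_profile(self_blocks, genome)
        report["synteny"] = {
            "n_self_blocks": len(self_blocks),
            "n_self_anchors": n_anchors,
            "modal_self_depth": self_depth.modal_depth,
        }
        if outgroup is not None:
            cross_anchors = synteny.anchors_from_id_pairs(
                ortho_pairs, outgroup, genome
            )
            cross_blocks = synteny.chain_anchors(
                cross_anchors,
                max_gap=config.max_gap,
                min_block_size=config.min_block_size,
            )
            report["synteny"]["n_cross_blocks"] = len(cross_blocks)
            report["synteny"]["modal_depth_outgroup_vs_query"] = (
                synteny.depth_profile(cross_blocks, outgroup).modal_depth
            )
            report["synteny"]["modal_depth_query_vs_outgroup"] = (
                synteny.depth_profile(cross_blocks, genome).modal_depth
            )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: duplicate modes ---------------------------------------
    stage = "dup_classifier"
    try:
        dup_pairs = dup_classifier.classify_pairs(genome, pairs, self_blocks)
        report["duplicate_modes"] = dup_classifier.mode_summary(dup_pairs)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: Ks -----------------------------------------------------
    stage = "ks_distribution"
    try:
        ks_by_pair: dict[tuple[str, str], float | None] = {}
        if config.cds_path is not None:
            cds = io_formats.read_fasta(config.cds_path)
            results = kaks.compute_kaks_batch(
                [(p[0], p[1]) for p in pairs], cds
            )
            ks_by_pair = {
                tuple(sorted((r.id_a, r.id_b))): r.ks for r in results
            }
        else:
            for p in pairs:
                key = tuple(sorted((p[0], p[1])))
                ks_by_pair[key] = p[2] if len(p) > 2 else None
        wgd_ks = [
            ks_by_pair.get(tuple(sorted((d.gene_a.gene_id, d.gene_b.gene_id))))
            for d in dup_pairs
            if d.mode == "wgd"
        ]
        sample = ks_distribution.build_ks_sample(
            wgd_ks, label=f"{config.species}-wgd", lo=config.ks_lo, hi=config.ks_hi
        )
        peak = ks_distribution.estimate_peak(
            sample, method=config.peak_method, k_max=config.k_max, seed=config.seed
        )
        report["ks"] = {
            "n_wgd_ks": len(sample),
            "wgd_peak": peak.mode,
            "peak_method": peak.method,
            "n_components": peak.n_components,
        }
        if ortho_pairs is not None:
            split_sample = ks_distribution.build_ks_sample(
                [p[2] for p in ortho_pairs],
                label=f"{config.species}-{config.outgroups[0]}-split",
                lo=config.ks_lo,
                hi=config.ks_hi,
            )
            split_peak = ks_distribution.estimate_peak(
                split_sample, method="kde", seed=config.seed
            )
            report["ks"]["split_peak"] = split_peak.mode
            # rate correction exercised against a faster partner lineage
            partner_split, partner_wgd = synthetic_data.simulate_rate_shifted_split(
                plan, config.divergence_ks, config.partner_rate_factor
            )
            partner_split_peak = ks_distribution.estimate_peak(
                ks_distribution.build_ks_sample(
                    partner_split, label="partner-split",
                    lo=config.ks_lo, hi=config.ks_hi,
                ),
                method="kde",
                seed=config.seed,
            )
            corr = ks_distribution.rate_correction(split_peak, partner_split_peak)
            corrected = ks_distribution.apply_correction(
                ks_distribution.build_ks_sample(
                    partner_wgd, label="partner-wgd",
                    lo=config.ks_lo, hi=config.ks_hi,
                ),
                corr,
            )
            corrected_peak = ks_distribution.estimate_peak(
                corrected, method="kde", seed=config.seed
            )
            report["ks"]["correction_coefficient"] = corr.coefficient
            report["ks"]["partner_wgd_peak_corrected"] = corrected_peak.mode
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: dating -------------------------------------------------
    stage = "dating"
    if config.calibration is None:
        report["dating"] = {"skipped": True}
    else:
        try:
            dating = ks_distribution.date_event(
                report["ks"]["wgd_peak"], config.calibration
            )
            report["dating"] = {
                "calibration_ks": config.calibration[0],
                "calibration_t_mya": config.calibration[1],
                "r_per_my": dating.r,
                "wgd_age_mya": dating.t,
            }
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # ---- stage: tree topology -----------------------------------------
    stage = "tree_topology"
    try:
        if config.trees_dir is not None:
            trees = [
                tree_topology.GeneTree(
                    tree=io_formats.read_newick(p), tree_id=p.stem
                )
                for p in sorted(Path(config.trees_dir).glob("*.nwk"))
            ]
        else:
            trees, _ = synthetic_data.simulate_gene_trees(
                config.n_trees,
                p_shared=(
                    plan.p_shared_topology if simulated else 0.5
                ),
                focal=config.focal,
                partners=config.partners,
                outgroups=config.outgroups,
                seed=config.seed + 3,
            )
        calls = [
            tree_topology.classify_wgd_topology(
                t, config.focal, set(config.partners), set(config.outgroups)
            )
            for t in trees
        ]
        summary = tree_topology.summarize_calls(calls)
        report["tree_topology"] = {
            "n_total": summary.n_total,
            "n_shared": summary.n_shared,
            "n_independent": summary.n_independent,
            "n_other": summary.n_other,
            "pct_shared_of_total": summary.pct_shared_of_total,
            "pct_independent_of_total": summary.pct_independent_of_total,
            "shared_ratio_pct": summary.shared_ratio,
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- stage: karyotype ---------------------------------------------
    stage = "chromosome_evolution"
    try:
        graph = chromosome_evolution.build_segment_graph(
            self_blocks, genome, min_anchors=config.min_block_size
        )
        n_ancestral, groups = chromosome_evolution.infer_ancestral_count(graph)
        karyotype: dict[str, Any] = {
            "n_segments": len(graph.segments),
            "n_ancestral_inferred": n_ancestral,
            "n_extant": len(genome.chromosomes),
        }
        if truth is not None:
            model = chromosome_evolution.account_events(
                truth.n_ancestral,
                truth.n_extant,
                truth.n_fissions,
                truth.n_fusions,
            )
            karyotype["balance"] = {
                "n_ancestral": model.n_ancestral,
                "n_post_wgd": model.n_post_wgd,
                "n_fissions": model.n_fissions,
                "n_fusions": model.n_fusions,
                "n_extant": model.n_extant,
            }
        report["karyotype"] = karyotype
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    report["report_hash"] = _report_hash(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable one-page summary of a pipeline report."""
    lines = [f"paleowgd report (seed {report.get('seed')})"]
    syn = report.get("synteny", {})
    lines.append(
        f"  synteny: {syn.get('n_self_blocks')} self blocks, "
        f"{syn.get('n_self_anchors')} anchors, modal self depth "
        f"{syn.get('modal_self_depth')}"
    )
    if "modal_depth_outgroup_vs_query" in syn:
        lines.append(
            f"  depth ratio vs outgroup: "
            f"{syn['modal_depth_outgroup_vs_query']}:"
            f"{syn['modal_depth_query_vs_outgroup']}"
        )
    modes = report.get("duplicate_modes", {})
    lines.append(
        "  duplicate modes: "
        + ", ".join(f"{k}={v}" for k, v in sorted(modes.items()))
    )
    ks = report.get("ks", {})
    if ks:
        lines.append(
            f"  Ks: WGD peak {ks.get('wgd_peak'):.3f} "
            f"({ks.get('peak_method')}, n={ks.get('n_wgd_ks')})"
        )
        if "split_peak" in ks:
            lines.append(f"  split peak vs outgroup: {ks['split_peak']:.3f}")
        if "correction_coefficient" in ks:
            lines.append(
                f"  rate correction C={ks['correction_coefficient']:.3f}, "
                f"partner WGD peak after correction "
                f"{ks['partner_wgd_peak_corrected']:.3f}"
            )
    dating = report.get("dating", {})
    if dating and not dating.get("skipped"):
        lines.append(
            f"  dating: r={dating['r_per_my']:.5f}/site/MY, "
            f"WGD age ~{dating['wgd_age_mya']:.1f} MYA"
        )
    tt = report.get("tree_topology", {})
    if tt:
        lines.append(
            f"  trees: {tt['n_shared']} shared / {tt['n_independent']} "
            f"independent / {tt['n_other']} other of {tt['n_total']}; "
            f"shared ratio {tt['shared_ratio_pct']:.1f}%"
        )
    kt = report.get("karyotype", {})
    if kt:
        lines.append(
            f"  karyotype: {kt.get('n_ancestral_inferred')} ancestral "
            f"chromosomes inferred, {kt.get('n_extant')} extant"
        )
        if "balance" in kt:
            b = kt["balance"]
            lines.append(
                f"    balance: 2x{b['n_ancestral']} + {b['n_fissions']} "
                f"fissions - {b['n_fusions']} fusions = {b['n_extant']}"
            )
    lines.append(f"  report hash: {report.get('report_hash')}")
    return "\n".join(lines) + "\n"
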