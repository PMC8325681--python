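"""Simulators with known ground truth for every stage of the pipeline.

The generator emulates the history the analysis is designed to detect: a
diploid ancestor, one whole-genome duplication with partial duplicate
retention, post-WGD chromosome fissions/fusions/inversions, paralog Ks
values drawn from a lognormal around the WGD peak plus an exponential
background of small-scale duplicates, divergence Ks against an outgroup
that missed the WGD, and rooted gene trees with a set fraction of
duplication-before-speciation topologies.

Default plan values mirror the tea-plant scenario: 9 ancestral
chromosomes, 3 fissions + 6 fusions (so 2x9 + 3 - 6 = 15 extant
chromosomes), a WGD Ks peak at 0.425, an outgroup split peak at 0.781,
and 50% duplicate retention.  Everything is driven by one integer seed;
identical plans give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    CodingSequencePair,
    GeneRecord,
    GenomeAnnotation,
    assign_ranks,
)
from .kaks import BASES, CODON_TABLE, STOP_CODONS
from .tree_topology import GeneTree
from . import io_formats

SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)


@dataclass(frozen=True)
class SimulationPlan:
    """Ground-truth parameters of one simulated WGD history."""

    seed: int
    n_chromosomes: int = 9
    genes_per_chromosome: int = 200
    wgd_retention: float = 0.5
    ks_wgd: tuple[float, float] = (0.425, 0.2)  # (peak, sigma) on log scale
    ks_background_rate: float = 1.0  # exponential rate for small-scale pairs
    n_fissions: int = 3
    n_fusions: int = 6
    n_inversions: int = 2
    p_shared_topology: float = 0.685
    n_tandem_pairs: int = 30
    n_proximal_pairs: int = 30
    n_dispersed_pairs: int = 30
    species: str = "Cs"
    outgroup_species: str = "Vv"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 < self.wgd_retention <= 1.0):
            raise ValueError("wgd_retention must be in (0, 1]")
        if not (0.0 <= self.p_shared_topology <= 1.0):
            raise ValueError("p_shared_topology must be in [0, 1]")
        for name in ("n_chromosomes", "genes_per_chromosome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_fissions", "n_fusions", "n_inversions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ks_wgd[0] <= 0 or self.ks_wgd[1] <= 0:
            raise ValueError("ks_wgd peak and sigma must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, keyed the way the pipeline reports."""

    pair_modes: dict[tuple[str, str], str] = field(default_factory=dict)
    pair_ks: dict[tuple[str, str], float] = field(default_factory=dict)
    n_ancestral: int = 0
    n_fissions: int = 0
    n_fusions: int = 0
    n_inversions: int = 0
    n_extant: int = 0
    n_retained_wgd_pairs: int = 0
    tree_classes: list[str] = field(default_factory=list)


def _gene_positions(genes_in_order: list[str], chrom: str, species: str) -> list[GeneRecord]:
    spacing, length = 2000, 1200
    out = []
    for i, gid in enumerate(genes_in_order):
        start = i * spacing + 1
        out.append(
            GeneRecord(
                gene_id=gid,
                species=species,
                chrom=chrom,
                start=start,
                end=start + length - 1,
                strand="+",
            )
        )
    return out


def _build_extant_chromosomes(
    plan: SimulationPlan, rng: np.random.Generator
) -> tuple[list[list[str]], dict[str, str], dict[str, list[str]]]:
    """Post-WGD chromosome layout.

    Returns (chromosome gene-id lists, gene -> ancestor-gene map,
    ancestor-gene -> surviving copy ids map).  Copy "a" of every ancestral
    chromosome is kept complete; copy "b" genes are each deleted with
    probability 1 - retention.  Fissions, fusions then inversions are
    applied to the 2n chromosome units, preferring units not already hit
    so the event ledger stays interpretable.
    """
    ancestor = [
        [f"anc{c:02d}_{i:04d}" for i in range(plan.genes_per_chromosome)]
        for c in range(plan.n_chromosomes)
    ]
    units: list[list[str]] = []
    gene_to_anc: dict[str, str] = {}
    anc_copies: dict[str, list[str]] = {}
    for chrom_genes in ancestor:
        copy_a = []
        for anc_id in chrom_genes:
            gid = f"{plan.species}_{anc_id}a"
            copy_a.append(gid)
            gene_to_anc[gid] = anc_id
            anc_copies[anc_id] = [gid]
        units.append(copy_a)
    for chrom_genes in ancestor:
        copy_b = []
        for anc_id in chrom_genes:
            if rng.random() < plan.wgd_retention:
                gid = f"{plan.species}_{anc_id}b"
                copy_b.append(gid)
                gene_to_anc[gid] = anc_id
                anc_copies[anc_id].append(gid)
        if copy_b:
            units.append(copy_b)

    touched: set[int] = set()

    def pick_unit(min_len: int = 1) -> int:
        fresh = [i for i in range(len(units)) if i not in touched and len(units[i]) >= min_len]
        pool = fresh or [i for i in range(len(units)) if len(units[i]) >= min_len]
        return int(pool[rng.integers(len(pool))])

    for _ in range(plan.n_fissions):
        i = pick_unit(min_len=2)
        touched.add(i)
        unit = units[i]
        cut = int(rng.integers(1, len(unit)))
        units[i] = unit[:cut]
        units.append(unit[cut:])
        touched.add(len(units) - 1)
    for _ in range(plan.n_fusions):
        if len(units) < 2:
            break
        i = pick_unit()
        j = i
        while j == i:
            j = pick_unit()
        touched.add(i)
        units[i] = units[i] + units[j]
        del units[j]
        touched = {k if k < j else k - 1 for k in touched if k != j}
        touched.add(i if i < j else i - 1)
    for _ in range(plan.n_inversions):
        i = pick_unit(min_len=2)
        unit = units[i]
        lo = int(rng.integers(0, len(unit) - 1))
        hi = int(rng.integers(lo + 1, len(unit)))
        units[i] = unit[:lo] + unit[lo : hi + 1][::-1] + unit[hi + 1 :]

    return units, gene_to_anc, anc_copies


def simulate_wgd_genome(
    plan: SimulationPlan,
) -> tuple[GenomeAnnotation, list[tuple[str, str, float]], GroundTruth]:
    """Simulate a post-WGD genome with its homolog pair list and truth.

    Returns the annotated genome, pairs as (id_a, id_b, ks) with WGD pairs'
    Ks lognormal around the plan's WGD peak and small-scale pairs' Ks
    exponential, and the :class:`GroundTruth` ledger.
    """
    rng = np.random.default_rng(plan.seed)
    units, gene_to_anc, anc_copies = _build_extant_chromosomes(plan, rng)

    genes: list[GeneRecord] = []
    for idx, unit in enumerate(units):
        chrom = f"chr{idx + 1:02d}"
        genes.extend(_gene_positions(unit, chrom, plan.species))
    genome = GenomeAnnotation(species=plan.species, genes=assign_ranks(genes))

    truth = GroundTruth(
        n_ancestral=plan.n_chromosomes,
        n_fissions=plan.n_fissions,
        n_fusions=plan.n_fusions,
        n_inversions=plan.n_inversions,
        n_extant=len(units),
    )
    log_peak, sigma = math.log(plan.ks_wgd[0]), plan.ks_wgd[1]
    pairs: list[tuple[str, str, float]] = []
    for anc_id in sorted(anc_copies):
        copies = anc_copies[anc_id]
        if len(copies) == 2:
            ks = float(np.exp(rng.normal(log_peak, sigma)))
            a, b = sorted(copies)
            pairs.append((a, b, ks))
            truth.pair_modes[(a, b)] = "wgd"
            truth.pair_ks[(a, b)] = ks
    truth.n_retained_wgd_pairs = len(pairs)

    # Small-scale duplicates: sample endpoint genes without replacement so
    # no planted pair perturbs another's mode (no boundary ambiguity).
    used = {g for pair in pairs for g in pair[:2]}
    by_chrom = {c: genome.chromosome_genes(c) for c in genome.chromosomes}
    chrom_names = sorted(by_chrom)

    def draw_ks() -> float:
        return float(rng.exponential(1.0 / plan.ks_background_rate))

    def plant(mode: str, n_wanted: int) -> None:
        attempts = 0
        planted = 0
        while planted < n_wanted and attempts < 50 * n_wanted:
            attempts += 1
            if mode == "dispersed":
                if len(chrom_names) < 2:
                    break  # cross-chromosome pairs need two chromosomes
                ca, cb = rng.choice(chrom_names, size=2, replace=False)
                ga = by_chrom[ca][int(rng.integers(len(by_chrom[ca])))]
                gb = by_chrom[cb][int(rng.integers(len(by_chrom[cb])))]
            else:
                ca = chrom_names[int(rng.integers(len(chrom_names)))]
                chrom_genes = by_chrom[ca]
                delta = 1 if mode == "tandem" else int(rng.integers(2, 11))
                if len(chrom_genes) <= delta:
                    continue
                i = int(rng.integers(0, len(chrom_genes) - delta))
                ga, gb = chrom_genes[i], chrom_genes[i + delta]
            if ga.gene_id in used or gb.gene_id in used:
                continue
            key = tuple(sorted((ga.gene_id, gb.gene_id)))
            ks = draw_ks()
            pairs.append((key[0], key[1], ks))
            truth.pair_modes[key] = mode
            truth.pair_ks[key] = ks
            used.update(key)
            planted += 1

    plant("tandem", plan.n_tandem_pairs)
    plant("proximal", plan.n_proximal_pairs)
    plant("dispersed", plan.n_dispersed_pairs)
    return genome, pairs, truth


def simulate_outgroup_genome(
    plan: SimulationPlan, divergence_ks: float
) -> tuple[GenomeAnnotation, list[tuple[str, str, float]]]:
    """An outgroup that never duplicated, plus orthologs to the WGD genome.

    The outgroup is the pre-WGD ancestor itself (one gene per ancestral
    gene, ancestral chromosome order).  Every surviving copy of an
    ancestral gene in the WGD genome gets an ortholog pair with Ks drawn
    lognormal (sigma 0.15) around ``divergence_ks`` — the cross-species
    divergence peak used for rate calibration.
    """
    if divergence_ks <= 0:
        raise ValueError("divergence_ks must be positive")
    rng = np.random.default_rng(plan.seed + 1)
    _, _, anc_copies = _build_extant_chromosomes(
        plan, np.random.default_rng(plan.seed)
    )

    genes: list[GeneRecord] = []
    for c in range(plan.n_chromosomes):
        chrom_ids = [
            f"{plan.outgroup_species}_anc{c:02d}_{i:04d}"
            for i in range(plan.genes_per_chromosome)
        ]
        genes.extend(_gene_positions(chrom_ids, f"vchr{c + 1:02d}", plan.outgroup_species))
    outgroup = GenomeAnnotation(
        species=plan.outgroup_species, genes=assign_ranks(genes)
    )

    log_div = math.log(divergence_ks)
    ortholog_pairs: list[tuple[str, str, float]] = []
    for anc_id in sorted(anc_copies):
        out_id = f"{plan.outgroup_species}_{anc_id}"
        for copy_id in anc_copies[anc_id]:
            ks = float(np.exp(rng.normal(log_div, 0.15)))
            ortholog_pairs.append((out_id, copy_id, ks))
    return outgroup, ortholog_pairs


def simulate_rate_shifted_split(
    plan: SimulationPlan,
    divergence_ks: float,
    rate_factor: float,
    n_pairs: int = 2000,
) -> tuple[list[float], list[float]]:
    """Ks samples for a partner lineage evolving ``rate_factor`` times faster.

    Returns (partner-vs-outgroup split Ks values, partner within-genome WGD
    Ks values), both inflated by ``rate_factor`` relative to the focal
    lineage's scales — the input situation for the correction coefficient
    C = reference_split_peak / partner_split_peak = 1 / rate_factor.
    """
    if rate_factor <= 0:
        raise ValueError("rate_factor must be positive")
    rng = np.random.default_rng(plan.seed + 2)
    split = np.exp(
        rng.normal(math.log(divergence_ks * rate_factor), 0.15, size=n_pairs)
    )
    wgd = np.exp(
        rng.normal(
            math.log(plan.ks_wgd[0] * rate_factor), plan.ks_wgd[1], size=n_pairs
        )
    )
    return [float(v) for v in split], [float(v) for v in wgd]


def _random_sense_sequence(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[int(i)] for i in idx]


def _proportion_from_distance(d: float) -> float:
    """Forward Jukes–Cantor: expected difference proportion at distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def evolve_codon_pairs(
    n_pairs: int,
    n_codons: int,
    target_ks: float,
    target_ka: float,
    seed: int,
) -> list[CodingSequencePair]:
    """Codon pairs whose NG86 estimates center on the targets.

    The target distances are JC-inverted to difference proportions
    ps/pn, and each position of each codon of one copy is mutated
    synonymously with probability ps x (its synonymous site fraction) and
    nonsynonymously with probability pn x (its nonsynonymous fraction), so
    the NG86 counting applied downstream is unbiased in expectation.
    Mutations that would create stop codons are not introduced.
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("targets must be >= 0")
    ps = _proportion_from_distance(target_ks)
    pn = _proportion_from_distance(target_ka)
    if ps >= 0.7 or pn >= 0.7:
        raise ValueError(
            f"saturation risk: difference proportions ps={ps:.3f}, pn={pn:.3f} "
            "must stay below 0.7"
        )
    rng = np.random.default_rng(seed)
    out: list[CodingSequencePair] = []
    for p in range(n_pairs):
        codons_a = _random_sense_sequence(n_codons, rng)
        codons_b = []
        for codon in codons_a:
            current = codon
            for pos in range(3):
                syn, nonsyn = [], []
                aa = CODON_TABLE[current]
                for base in BASES:
                    if base == current[pos]:
                        continue
                    mutant = current[:pos] + base + current[pos + 1 :]
                    if mutant in STOP_CODONS:
                        continue
                    (syn if CODON_TABLE[mutant] == aa else nonsyn).append(mutant)
                f_syn = len(syn) / 3.0
                f_non = 1.0 - f_syn
                u = rng.random()
                if syn and u < ps * f_syn:
                    current = syn[int(rng.integers(len(syn)))]
                elif nonsyn and u >= ps * f_syn and u < ps * f_syn + pn * f_non:
                    current = nonsyn[int(rng.integers(len(nonsyn)))]
            codons_b.append(current)
        out.append(
            CodingSequencePair(
                id_a=f"pair{p:04d}_a",
                id_b=f"pair{p:04d}_b",
                seq_a="".join(codons_a),
                seq_b="".join(codons_b),
            )
        )
    return out


def simulate_gene_trees(
    n: int,
    p_shared: float,
    focal: str = "Cs",
    partners: tuple[str, ...] = ("Ac", "Rs"),
    outgroups: tuple[str, ...] = ("Vv",),
    seed: int = 0,
    noise: float = 0.0,
) -> tuple[list[GeneTree], list[str]]:
    """Rooted gene trees with known shared/independent WGD topology.

    A shared-WGD tree is ``((F1,P1),(F2,P2)),O`` (duplication precedes the
    focal-partner speciation); an independent-WGD tree is
    ``(((F1,F2),P),O)``.  With probability ``noise`` two random non-
    outgroup tip labels are swapped, scrambling the topology.
    """
    if not (0.0 <= p_shared <= 1.0):
        raise ValueError("p_shared must be in [0, 1]")
    rng = np.random.default_rng(seed)
    trees: list[GeneTree] = []
    truth: list[str] = []
    for i in range(n):
        shared = bool(rng.random() < p_shared)
        partner = partners[int(rng.integers(len(partners)))]
        outgroup = outgroups[int(rng.integers(len(outgroups)))]
        f1, f2 = f"{focal}_t{i:05d}x", f"{focal}_t{i:05d}y"
        p1, p2 = f"{partner}_t{i:05d}x", f"{partner}_t{i:05d}y"
        o = f"{outgroup}_t{i:05d}o"
        if shared:
            newick = f"((({f1},{p1}),({f2},{p2})),{o});"
        else:
            newick = f"((({f1},{f2}),{p1}),{o});"
        if noise > 0 and rng.random() < noise:
            tips = [f1, f2, p1, p2] if shared else [f1, f2, p1]
            a, b = rng.choice(len(tips), size=2, replace=False)
            ta, tb = tips[int(a)], tips[int(b)]
            newick = (
                newick.replace(ta, "@TMP@").replace(tb, ta).replace("@TMP@", tb)
            )
        tree = io_formats.read_newick_string(newick)
        trees.append(GeneTree(tree=tree, tree_id=f"tree{i:05d}"))
        truth.append("shared" if shared else "independent")
    return trees, truth


def write_simulation(
    plan: SimulationPlan,
    outdir,
    divergence_ks: float = 0.781,
    n_trees: int = 200,
) -> dict:
    """Emit a full simulated dataset as plain-text files; returns a manifest."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, pairs, truth = simulate_wgd_genome(plan)
    outgroup, ortho_pairs = simulate_outgroup_genome(plan, divergence_ks)
    io_formats.write_gene_positions(genome, outdir / "genome.tsv")
    io_formats.write_gene_positions(outgroup, outdir / "outgroup.tsv")
    io_formats.write_pairs(pairs, outdir / "pairs.tsv")
    io_formats.write_pairs(ortho_pairs, outdir / "ortholog_pairs.tsv")
    trees, tree_truth = simulate_gene_trees(
        n_trees, plan.p_shared_topology, seed=plan.seed + 3
    )
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    for t in trees:
        io_formats.write_newick(t.tree, tree_dir / f"{t.tree_id}.nwk")
    truth_json = {
        "n_ancestral": truth.n_ancestral,
        "n_fissions": truth.n_fissions,
        "n_fusions": truth.n_fusions,
        "n_inversions": truth.n_inversions,
        "n_extant": truth.n_extant,
        "n_retained_wgd_pairs": truth.n_retained_wgd_pairs,
        "pair_modes": {f"{a}|{b}": m for (a, b), m in truth.pair_modes.items()},
        "tree_truth": tree_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    return truth_json
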