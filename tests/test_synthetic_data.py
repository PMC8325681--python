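"""Generator contracts: determinism, retention statistics, estimator
recovery, tree truth, and file round-trips."""

import math

import numpy as np
import pytest

from paleowgd import io_formats
from paleowgd.kaks import compute_kaks
from paleowgd.ks_distribution import build_ks_sample, estimate_peak
from paleowgd.synthetic_data import (
    SimulationPlan,
    evolve_codon_pairs,
    simulate_gene_trees,
    simulate_outgroup_genome,
    simulate_wgd_genome,
    write_simulation,
)


def test_plan_validation():
    with pytest.raises(ValueError):
        SimulationPlan(seed=1, wgd_retention=0.0)
    with pytest.raises(ValueError):
        SimulationPlan(seed=1, p_shared_topology=1.5)
    with pytest.raises(ValueError):
        SimulationPlan(seed=1, n_fissions=-1)


def test_identical_plans_are_byte_identical():
    plan = SimulationPlan(seed=123)
    g1, p1, t1 = simulate_wgd_genome(plan)
    g2, p2, t2 = simulate_wgd_genome(plan)
    assert p1 == p2
    assert [(g.gene_id, g.chrom, g.start, g.rank) for g in g1.genes] == [
        (g.gene_id, g.chrom, g.start, g.rank) for g in g2.genes
    ]
    assert t1.pair_modes == t2.pair_modes


def test_retention_controls_pair_count_binomially():
    plan = SimulationPlan(
        seed=1, wgd_retention=0.3, n_tandem_pairs=0, n_proximal_pairs=0,
        n_dispersed_pairs=0,
    )
    _, pairs, truth = simulate_wgd_genome(plan)
    n_genes = plan.n_chromosomes * plan.genes_per_chromosome
    expected = 0.3 * n_genes
    sd = math.sqrt(n_genes * 0.3 * 0.7)
    assert abs(truth.n_retained_wgd_pairs - expected) <= 3 * sd
    assert len(pairs) == truth.n_retained_wgd_pairs


def test_full_retention_no_rearrangement_geometry():
    plan = SimulationPlan(
        seed=2, wgd_retention=1.0, n_fissions=0, n_fusions=0, n_inversions=0
    )
    genome, pairs, truth = simulate_wgd_genome(plan)
    assert truth.n_extant == 18
    assert truth.n_retained_wgd_pairs == 1800
    from paleowgd.synteny import depth_profile, self_synteny

    blocks = self_synteny(genome, pairs)
    assert depth_profile(blocks, genome).modal_depth == 1
    # 9 disjoint duplicate chromosome pairs
    chrom_pairs = {(b.chrom_a, b.chrom_b) for b in blocks}
    assert len(chrom_pairs) == 9
    assert len({c for p in chrom_pairs for c in p}) == 18


def test_event_counts_produce_expected_extant_chromosomes():
    plan = SimulationPlan(seed=3, wgd_retention=1.0)  # 3 fissions, 6 fusions
    _, _, truth = simulate_wgd_genome(plan)
    assert truth.n_extant == 2 * 9 + 3 - 6 == 15


def test_wgd_ks_values_cluster_at_plan_peak():
    plan = SimulationPlan(seed=4)
    _, pairs, truth = simulate_wgd_genome(plan)
    wgd_ks = [k for key, k in truth.pair_ks.items() if truth.pair_modes[key] == "wgd"]
    peak = estimate_peak(build_ks_sample(wgd_ks), method="kde")
    assert abs(peak.mode - plan.ks_wgd[0]) <= 0.05


def test_outgroup_orthologs_peak_at_divergence_ks():
    plan = SimulationPlan(seed=5)
    _, ortho = simulate_outgroup_genome(plan, divergence_ks=0.781)
    peak = estimate_peak(build_ks_sample([p[2] for p in ortho]), method="kde")
    assert abs(peak.mode - 0.781) <= 0.05
    with pytest.raises(ValueError):
        simulate_outgroup_genome(plan, divergence_ks=0.0)


# ------------------------------------------------------------- codon pairs
def test_zero_targets_give_identical_sequences():
    pairs = evolve_codon_pairs(5, 100, 0.0, 0.0, seed=1)
    for p in pairs:
        assert p.seq_a == p.seq_b
        res = compute_kaks(p)
        assert res.ka == 0.0 and res.ks == 0.0


@pytest.mark.parametrize("target", [0.2, 0.4, 0.8])
def test_ng86_recovers_target_ks(target):
    pairs = evolve_codon_pairs(200, 300, target, 0.0, seed=int(target * 100))
    estimates = [compute_kaks(p).ks for p in pairs]
    assert None not in estimates
    assert abs(np.mean(estimates) - target) <= 0.1 * target


def test_ng86_recovers_target_ka():
    pairs = evolve_codon_pairs(200, 300, 0.0, 0.05, seed=55)
    estimates = [compute_kaks(p).ka for p in pairs]
    assert abs(np.mean(estimates) - 0.05) <= 0.005


def test_saturating_targets_rejected():
    with pytest.raises(ValueError, match="saturation"):
        evolve_codon_pairs(1, 100, 3.0, 0.0, seed=1)


# ------------------------------------------------------------------- trees
def test_all_shared_when_p_is_one():
    from paleowgd.tree_topology import classify_wgd_topology

    trees, truth = simulate_gene_trees(10, p_shared=1.0, seed=6)
    assert truth == ["shared"] * 10
    calls = [
        classify_wgd_topology(t, "Cs", {"Ac", "Rs"}, {"Vv"}).call for t in trees
    ]
    assert calls == truth


def test_emitted_files_readable_and_consistent(tmp_path):
    plan = SimulationPlan(seed=7)
    manifest = write_simulation(plan, tmp_path, n_trees=20)
    genome = io_formats.read_gene_positions(
        tmp_path / "genome.tsv", species="Cs", dialect="tsv"
    )
    assert len(genome.chromosomes) == manifest["n_extant"]
    pairs = io_formats.read_pairs(tmp_path / "pairs.tsv")
    assert len(pairs) == len(manifest["pair_modes"])
    trees = sorted((tmp_path / "trees").glob("*.nwk"))
    assert len(trees) == 20
    tree = io_formats.read_newick(trees[0])
    assert len(tree.leaf_nodes()) >= 4
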