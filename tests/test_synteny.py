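"""Synteny chaining tests: hand cases, an exhaustive-search oracle, and
depth-ratio recovery on simulated WGD histories."""

from itertools import combinations

import numpy as np
import pytest

from paleowgd.io_formats import GeneRecord
from paleowgd.synteny import (
    AnchorPair,
    chain_anchors,
    depth_profile,
    dotplot_table,
    self_synteny,
    anchors_from_id_pairs,
)
from paleowgd.synthetic_data import SimulationPlan, simulate_outgroup_genome, simulate_wgd_genome

from conftest import make_genome


def anchor(ra: int, rb: int, ca: str = "c1", cb: str = "c2") -> AnchorPair:
    return AnchorPair(
        GeneRecord(f"a{ca}{ra}", "A", ca, ra * 10 + 1, ra * 10 + 5, "+", ra),
        GeneRecord(f"b{cb}{rb}", "B", cb, rb * 10 + 1, rb * 10 + 5, "+", rb),
    )


def test_perfect_collinear_run_is_one_block():
    anchors = [anchor(i, i) for i in range(5)]
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert len(blocks[0]) == 5
    assert blocks[0].orientation == "collinear"


def test_gap_constraint_excludes_outlier():
    anchors = [anchor(i, i) for i in range(5)] + [anchor(2, 400)]
    blocks = chain_anchors(anchors, max_gap=25)
    assert len(blocks) == 1
    assert len(blocks[0]) == 5
    assert all(a.gene_b.rank <= 4 for a in blocks[0].anchors)


def test_inverted_run_detected():
    anchors = [anchor(i, 9 - i) for i in range(6)]
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"


def test_blocks_are_monotone_and_disjoint():
    rng = np.random.default_rng(3)
    anchors = [
        anchor(int(ra), int(rb))
        for ra, rb in zip(rng.integers(0, 60, 80), rng.integers(0, 60, 80))
    ]
    blocks = chain_anchors(anchors, max_gap=25, min_block_size=3)
    seen = set()
    for b in blocks:
        ras = [a.gene_a.rank for a in b.anchors]
        rbs = [a.gene_b.rank for a in b.anchors]
        assert ras == sorted(ras) and len(set(ras)) == len(ras)
        if b.orientation == "collinear":
            assert rbs == sorted(rbs)
        else:
            assert rbs == sorted(rbs, reverse=True)
        for a in b.anchors:
            assert id(a) not in seen
            seen.add(id(a))


def _oracle_max_chain(anchors, max_gap):
    """Exhaustive maximum chain over all subsets (feasible for <= 12)."""
    def valid(subset):
        subset = sorted(subset, key=lambda a: a.gene_a.rank)
        ras = [a.gene_a.rank for a in subset]
        rbs = [a.gene_b.rank for a in subset]
        if len(set(ras)) != len(ras):
            return False
        inc = all(y > x and y - x <= max_gap for x, y in zip(rbs, rbs[1:]))
        dec = all(y < x and x - y <= max_gap for x, y in zip(rbs, rbs[1:]))
        gaps_a = all(y - x <= max_gap for x, y in zip(ras, ras[1:]))
        return gaps_a and (inc or dec) and len(set(rbs)) == len(rbs)

    best = 0
    for k in range(len(anchors), 0, -1):
        if k <= best:
            break
        for subset in combinations(anchors, k):
            if valid(list(subset)):
                best = k
                break
    return best


def test_chaining_equals_exhaustive_search_on_small_instances():
    """DP chaining finds the maximum-anchor chain on every random <=12-anchor
    instance of a seeded suite."""
    rng = np.random.default_rng(11)
    for trial in range(40):
        n = int(rng.integers(4, 13))
        anchors = [
            anchor(int(ra), int(rb))
            for ra, rb in zip(rng.integers(0, 30, n), rng.integers(0, 30, n))
        ]
        max_gap = int(rng.integers(3, 26))
        blocks = chain_anchors(anchors, max_gap=max_gap, min_block_size=1)
        got = max((len(b) for b in blocks), default=0)
        expected = _oracle_max_chain(anchors, max_gap)
        assert got == expected, f"trial {trial}"


def test_self_synteny_finds_duplicated_chromosome(two_chrom_genome):
    pairs = [(f"c1_g{i}", f"c2_g{i}") for i in range(20)]
    blocks = self_synteny(two_chrom_genome, pairs)
    assert len(blocks) == 1
    assert len(blocks[0]) == 20


def test_tandem_array_suppressed_by_diagonal_rule():
    genome = make_genome({"c1": 30})
    pairs = [(f"c1_g{i}", f"c1_g{i+1}") for i in range(0, 20, 2)]
    blocks = self_synteny(genome, pairs)
    assert blocks == []


def test_depth_profile_modal_depths():
    genome = make_genome({"c1": 20, "c2": 20}, species="Q")
    target = make_genome({"t1": 20}, species="T")
    # both query chromosomes map onto the single target chromosome: 2:1
    pairs = [(f"t1_g{i}", f"c1_g{i}") for i in range(20)]
    pairs += [(f"t1_g{i}", f"c2_g{i}") for i in range(20)]
    anchors = anchors_from_id_pairs(pairs, target, genome)
    blocks = chain_anchors(anchors)
    assert depth_profile(blocks, target).modal_depth == 2
    assert depth_profile(blocks, genome).modal_depth == 1


def test_simulated_wgd_vs_outgroup_shows_two_to_one_signature():
    plan = SimulationPlan(seed=9)
    genome, pairs, _ = simulate_wgd_genome(plan)
    outgroup, ortho = simulate_outgroup_genome(plan, divergence_ks=0.781)
    anchors = anchors_from_id_pairs(ortho, outgroup, genome)
    blocks = chain_anchors(anchors)
    assert depth_profile(blocks, outgroup).modal_depth == 2
    assert depth_profile(blocks, genome).modal_depth == 1
    self_blocks = self_synteny(genome, pairs)
    assert depth_profile(self_blocks, genome).modal_depth == 1


def test_dotplot_table_rows_and_block_ids():
    anchors = [anchor(i, i) for i in range(5)]
    anchors += [anchor(i + 40, i + 40) for i in range(5)]
    blocks = chain_anchors(anchors, max_gap=10)
    table = dotplot_table(blocks)
    assert len(table) == 10
    assert set(table["block_id"]) == {0, 1}
    assert dotplot_table([]).empty
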