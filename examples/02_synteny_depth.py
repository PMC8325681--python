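"""Syntenic depth ratios as WGD evidence.

Simulates a genome that went through one WGD (plus fissions, fusions and
inversions) and an outgroup that did not.  Every outgroup region should
then be covered by two syntenic blocks of the query (a 2:1 depth ratio),
while within the query each region has exactly one WGD partner.
"""

from paleowgd import SimulationPlan, simulate_wgd_genome, simulate_outgroup_genome
from paleowgd.synteny import (
    anchors_from_id_pairs,
    chain_anchors,
    depth_profile,
    self_synteny,
)

plan = SimulationPlan(seed=42)
genome, pairs, truth = simulate_wgd_genome(plan)
outgroup, orthologs = simulate_outgroup_genome(plan, divergence_ks=0.781)
print(f"simulated {len(genome)} genes on {truth.n_extant} chromosomes "
      f"({truth.n_retained_wgd_pairs} retained WGD pairs)")

self_blocks = self_synteny(genome, pairs)
print(f"self-synteny: {len(self_blocks)} blocks, "
      f"{sum(len(b) for b in self_blocks)} anchors, "
      f"modal depth {depth_profile(self_blocks, genome).modal_depth} "
      f"(each region has one WGD partner)")

cross = chain_anchors(anchors_from_id_pairs(orthologs, outgroup, genome))
d_out = depth_profile(cross, outgroup).modal_depth
d_query = depth_profile(cross, genome).modal_depth
print(f"cross-species depth: outgroup side {d_out}, query side {d_query} "
      f"-> {d_out}:{d_query} signature of one extra WGD in the query")
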