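"""Ancestral karyotype reconstruction from within-genome synteny.

A WGD doubles every chromosome, so each ancestral chromosome survives as a
*pair* of homologous chromosome fragments in the extant genome.  Large
self-synteny blocks identify such duplicated fragments.  The reconstruction
here is a deliberate heuristic, not a full multi-genome ancestral-genome
method:

1. every sufficiently large self-synteny block contributes its two rank
   intervals as *segments* of a graph, linked by an edge weighted by the
   block's anchor count (overlapping segments on one chromosome merge);
2. maximum-weight matching pairs segments into duplicate pairs — one pair
   per surviving ancestral fragment;
3. matched pairs whose segments sit side by side on one chromosome are
   candidates for having been split by a post-WGD *fission* of the other
   copy, and are merged into one ancestral linkage group.

Step 3 must not also merge across *fusion* seams.  From a single genome's
self-synteny a fission junction and a fusion junction look alike, so
segment size breaks the tie under an equal-ancestral-size assumption.
Sizes are measured in *ancestral extent*: each matched segment pair
("tile") spans one ancestral fragment, whose gene count is approximated
by its fuller copy (duplicate deletion thins one copy, so the longer
segment is the better estimate).  Two tiles split by a fission are
complementary pieces of one ancestral chromosome, so their extents sum
to about one typical tile extent (75th percentile of all tiles); a
fusion seam joins pieces of two ancestral chromosomes, summing to ~1.5-2
typical extents.  A junction is merged only when the combined extent
stays below ``fusion_length_factor`` (default 1.25) times typical.

Event bookkeeping follows the balance
``n_extant = 2 * n_ancestral + n_fissions - n_fusions``.
"""

from __future__ import annotations

from dataclasses import dataclass
import networkx as nx
import numpy as np

from .io_formats import GenomeAnnotation
from .synteny import SyntenyBlock


class KaryotypeError(ValueError):
    pass


@dataclass(frozen=True)
class KaryotypeModel:
    """Chromosome-number ledger across a WGD and later rearrangements."""

    n_ancestral: int
    n_fissions: int
    n_fusions: int

    @property
    def n_post_wgd(self) -> int:
        return 2 * self.n_ancestral

    @property
    def n_extant(self) -> int:
        return self.n_post_wgd + self.n_fissions - self.n_fusions


@dataclass(frozen=True)
class Segment:
    """A rank interval (inclusive) on one chromosome."""

    chrom: str
    lo: int
    hi: int

    def __len__(self) -> int:
        return self.hi - self.lo + 1

    def overlap(self, other: "Segment") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.hi, other.hi) - max(self.lo, other.lo) + 1)


@dataclass
class SegmentGraph:
    """Duplicated chromosome segments linked by self-synteny evidence."""

    graph: nx.Graph  # nodes: Segment; edges carry weight = anchor count
    chrom_lengths: dict[str, int]  # genes per chromosome

    @property
    def segments(self) -> list[Segment]:
        return list(self.graph.nodes)


def _merge_segments(segments: list[Segment]) -> dict[Segment, Segment]:
    """Map each segment to its merged representative (overlap > 50% rule)."""
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    mapping: dict[Segment, Segment] = {}
    for chrom_segments in by_chrom.values():
        chrom_segments.sort(key=lambda s: (s.lo, s.hi))
        clusters: list[list[Segment]] = []
        for s in chrom_segments:
            placed = False
            for cluster in clusters:
                rep = cluster[-1]
                if s.overlap(rep) > 0.5 * min(len(s), len(rep)):
                    cluster.append(s)
                    placed = True
                    break
            if not placed:
                clusters.append([s])
        for cluster in clusters:
            merged = Segment(
                chrom=cluster[0].chrom,
                lo=min(s.lo for s in cluster),
                hi=max(s.hi for s in cluster),
            )
            for s in cluster:
                mapping[s] = merged
    return mapping


def build_segment_graph(
    blocks: list[SyntenyBlock],
    genome: GenomeAnnotation,
    min_anchors: int = 5,
) -> SegmentGraph:
    """Segment graph from self-synteny blocks with >= ``min_anchors`` anchors."""
    big = [b for b in blocks if len(b) >= min_anchors]
    if not big:
        raise KaryotypeError(
            f"no self-synteny block with >= {min_anchors} anchors"
        )
    raw_segments: list[Segment] = []
    edges: list[tuple[Segment, Segment, int]] = []
    for b in big:
        sa = Segment(b.chrom_a, *b.span_a)
        sb = Segment(b.chrom_b, *b.span_b)
        raw_segments.extend([sa, sb])
        edges.append((sa, sb, len(b)))
    mapping = _merge_segments(raw_segments)
    g = nx.Graph()
    for s in set(mapping.values()):
        g.add_node(s)
    for sa, sb, w in edges:
        ma, mb = mapping[sa], mapping[sb]
        if ma == mb:
            continue
        if g.has_edge(ma, mb):
            g[ma][mb]["weight"] += w
        else:
            g.add_edge(ma, mb, weight=w)
    chrom_lengths = {
        chrom: len(genome.chromosome_genes(chrom)) for chrom in genome.chromosomes
    }
    return SegmentGraph(graph=g, chrom_lengths=chrom_lengths)


def infer_ancestral_count(
    graph: SegmentGraph,
    fusion_length_factor: float = 1.25,
) -> tuple[int, list[set[Segment]]]:
    """Estimate the pre-WGD chromosome number from the segment graph.

    Segments are paired into tiles by maximum-weight matching; two tiles
    adjacent on a chromosome merge into one ancestral linkage group only
    when their combined ancestral extent stays below
    ``fusion_length_factor`` times the typical tile extent — larger
    junctions are fusion seams.  Unmatched segments remain as singleton
    groups.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        raise KaryotypeError("empty segment graph")

    matching = nx.max_weight_matching(g, maxcardinality=True)
    pair_of: dict[Segment, int] = {}
    groups: list[set[Segment]] = []
    for sa, sb in sorted(
        matching,
        key=lambda e: min((e[0].chrom, e[0].lo), (e[1].chrom, e[1].lo)),
    ):
        idx = len(groups)
        groups.append({sa, sb})
        pair_of[sa] = idx
        pair_of[sb] = idx
    for node in sorted(g.nodes, key=lambda s: (s.chrom, s.lo)):
        if node not in pair_of:
            pair_of[node] = len(groups)
            groups.append({node})

    # ancestral extent of a tile = gene count of its fuller copy
    tile_extent = [max(len(s) for s in members) for members in groups]
    typical = float(np.percentile(tile_extent, 75)) if tile_extent else 0.0

    by_chrom: dict[str, list[Segment]] = {}
    for s in g.nodes:
        by_chrom.setdefault(s.chrom, []).append(s)

    parent = list(range(len(groups)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def partner_of(tile_idx: int, seg: Segment) -> Segment:
        members = groups[tile_idx]
        others = [s for s in members if s != seg]
        return others[0] if others else seg

    for chrom, segs in sorted(by_chrom.items()):
        segs.sort(key=lambda s: s.lo)
        for s1, s2 in zip(segs, segs[1:]):
            t1, t2 = pair_of[s1], pair_of[s2]
            if t1 == t2:
                continue
            p1, p2 = partner_of(t1, s1), partner_of(t2, s2)
            if p1.chrom == p2.chrom:
                # both partners on one chromosome: the same duplicated
                # region fragmented (inversion/retention gaps), not an event
                mergeable = True
            else:
                # fission test: partners are pure fission products (their
                # chromosomes carry nothing else) and the two tiles jointly
                # span about one ancestral chromosome
                pure = (
                    len(by_chrom.get(p1.chrom, [])) == 1
                    and len(by_chrom.get(p2.chrom, [])) == 1
                )
                small = (
                    not typical
                    or tile_extent[t1] + tile_extent[t2]
                    <= fusion_length_factor * typical
                )
                mergeable = pure and small
            if not mergeable:
                continue  # fusion seam: adjacency here is not a fission signal
            g1, g2 = find(t1), find(t2)
            if g1 != g2:
                parent[g2] = g1

    merged: dict[int, set[Segment]] = {}
    for idx, members in enumerate(groups):
        merged.setdefault(find(idx), set()).update(members)
    final_groups = sorted(
        merged.values(), key=lambda s: min((x.chrom, x.lo) for x in s)
    )
    return len(final_groups), final_groups


def account_events(
    n_ancestral: int,
    n_extant: int,
    n_fissions: int,
    n_fusions: int,
) -> KaryotypeModel:
    """Validate the chromosome-number balance and return the ledger.

    Checks ``n_extant == 2*n_ancestral + n_fissions - n_fusions`` and
    raises :class:`KaryotypeError` naming both sides otherwise.
    """
    for name, v in (
        ("n_ancestral", n_ancestral),
        ("n_extant", n_extant),
        ("n_fissions", n_fissions),
        ("n_fusions", n_fusions),
    ):
        if v < 0:
            raise KaryotypeError(f"{name} must be >= 0, got {v}")
    expected = 2 * n_ancestral + n_fissions - n_fusions
    if expected != n_extant:
        raise KaryotypeError(
            f"inconsistent karyotype: 2*{n_ancestral} + {n_fissions} - "
            f"{n_fusions} = {expected}, but n_extant = {n_extant}"
        )
    return KaryotypeModel(
        n_ancestral=n_ancestral, n_fissions=n_fissions, n_fusions=n_fusions
    )
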