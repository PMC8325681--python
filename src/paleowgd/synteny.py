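"""Collinear synteny-block detection in gene-rank space.

Homolog pairs are chained per chromosome pair by dynamic programming over
gene ranks (MCScanX/DAGchainer-style): a chain must be strictly increasing
in rank on chromosome a and strictly monotone on chromosome b (increasing
for collinear blocks, decreasing for inverted ones), with consecutive
anchors at most ``max_gap`` ranks apart on both axes.  Non-overlapping
chains are extracted greedily in descending score order (score = anchor
count), so output is deterministic.

Syntenic *depth* — how many blocks of the other genome cover each gene —
is the classic dosage signal: a genome carrying one extra WGD relative to
its comparator shows a 2:1 depth ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GenomeAnnotation, GeneRecord


@dataclass(frozen=True)
class AnchorPair:
    """A homologous gene pair, the unit of synteny evidence."""

    gene_a: GeneRecord
    gene_b: GeneRecord
    ks: float | None = None


@dataclass
class SyntenyBlock:
    """A maximal collinear (or inverted) chain of anchors."""

    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # "collinear" | "inverted"
    block_id: int = -1

    @property
    def score(self) -> float:
        return float(len(self.anchors))

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.gene_a.rank for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.gene_b.rank for a in self.anchors]
        return min(ranks), max(ranks)

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class DepthProfile:
    """Per-gene block coverage for a query genome, with its modal depth."""

    depths: dict[str, int]  # gene_id -> number of covering blocks
    histogram: dict[int, int] = field(default_factory=dict)
    modal_depth: int = 0  # modal nonzero depth (0 if nothing covered)

    @classmethod
    def from_depths(cls, depths: dict[str, int]) -> "DepthProfile":
        hist: dict[int, int] = {}
        for d in depths.values():
            hist[d] = hist.get(d, 0) + 1
        nonzero = {d: c for d, c in hist.items() if d > 0}
        modal = max(nonzero, key=lambda d: (nonzero[d], -d)) if nonzero else 0
        return cls(depths=depths, histogram=hist, modal_depth=modal)


def _best_chain(
    anchors: list[AnchorPair], max_gap: int, inverted: bool
) -> list[int]:
    """Indices of the maximum-anchor chain under the gap constraint.

    O(n^2) DP; anchors must share one (chrom_a, chrom_b) group.  Ties are
    broken toward the chain whose anchor index sequence is lexicographically
    smallest after sorting anchors by (rank_a, rank_b), which makes block
    extraction deterministic.
    """
    n = len(anchors)
    order = sorted(
        range(n), key=lambda i: (anchors[i].gene_a.rank, anchors[i].gene_b.rank)
    )
    ra = [anchors[i].gene_a.rank for i in order]
    rb = [anchors[i].gene_b.rank for i in order]
    dp = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if ra[j] >= ra[i] or ra[i] - ra[j] > max_gap:
                continue
            if inverted:
                if rb[j] <= rb[i] or rb[j] - rb[i] > max_gap:
                    continue
            else:
                if rb[j] >= rb[i] or rb[i] - rb[j] > max_gap:
                    continue
            if dp[j] + 1 > dp[i] or (dp[j] + 1 == dp[i] and j < prev[i]):
                dp[i] = dp[j] + 1
                prev[i] = j
    if not dp:
        return []
    best = max(range(n), key=lambda i: (dp[i], -ra[i], -rb[i]))
    chain = []
    while best != -1:
        chain.append(order[best])
        best = prev[best]
    chain.reverse()
    return chain


def chain_anchors(
    pairs: list[AnchorPair], max_gap: int = 25, min_block_size: int = 5
) -> list[SyntenyBlock]:
    """Partition anchors into maximal non-overlapping collinear chains.

    Both collinear and inverted chains are reported; each anchor joins at
    most one block.  Blocks are extracted greedily by descending score with
    a deterministic positional tie-break.
    """
    if max_gap <= 0 or min_block_size <= 0:
        raise ValueError("max_gap and min_block_size must be positive")
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for p in pairs:
        groups.setdefault((p.gene_a.chrom, p.gene_b.chrom), []).append(p)

    blocks: list[SyntenyBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        remaining = list(group)
        while len(remaining) >= min_block_size:
            candidates = []
            for inverted in (False, True):
                idx = _best_chain(remaining, max_gap, inverted)
                if len(idx) >= min_block_size:
                    chain = [remaining[i] for i in idx]
                    key = (
                        -len(chain),
                        ca,
                        min(a.gene_a.rank for a in chain),
                        cb,
                        min(a.gene_b.rank for a in chain),
                        inverted,
                    )
                    candidates.append((key, chain, inverted))
            if not candidates:
                break
            _, chain, inverted = min(candidates, key=lambda c: c[0])
            blocks.append(
                SyntenyBlock(
                    anchors=chain,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation="inverted" if inverted else "collinear",
                )
            )
            chosen = set(id(a) for a in chain)
            remaining = [a for a in remaining if id(a) not in chosen]

    blocks.sort(
        key=lambda b: (-b.score, b.chrom_a, b.span_a[0], b.chrom_b, b.span_b[0])
    )
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks


def anchors_from_id_pairs(
    pairs: list[tuple[str, str]] | list[tuple[str, str, float | None]],
    genome_a: GenomeAnnotation,
    genome_b: GenomeAnnotation,
) -> list[AnchorPair]:
    """Resolve id pairs against two annotations; ids absent from either are skipped."""
    out = []
    for pair in pairs:
        id_a, id_b = pair[0], pair[1]
        if id_a in genome_a and id_b in genome_b:
            out.append(AnchorPair(genome_a.gene(id_a), genome_b.gene(id_b)))
    return out


def self_synteny(
    genome: GenomeAnnotation,
    pairs: list[tuple[str, str]] | list[tuple[str, str, float | None]],
    max_gap: int = 25,
    min_block_size: int = 5,
    diagonal_window: int = 10,
) -> list[SyntenyBlock]:
    """Within-genome synteny blocks (the WGD paralogon signal).

    Each unordered pair is oriented so gene_a precedes gene_b in (chrom,
    rank) order; trivial self-matches and blocks hugging the main diagonal
    of a single chromosome are suppressed.  The suppression window is
    ``max(min_block_size, diagonal_window)`` ranks: runs of tandem or
    proximal duplicates are small-scale by definition and must not pose
    as WGD paralogons.
    """
    anchors: list[AnchorPair] = []
    for pair in pairs:
        id_a, id_b = pair[0], pair[1]
        if id_a == id_b or id_a not in genome or id_b not in genome:
            continue
        ga, gb = genome.gene(id_a), genome.gene(id_b)
        if (gb.chrom, gb.rank) < (ga.chrom, ga.rank):
            ga, gb = gb, ga
        anchors.append(AnchorPair(ga, gb))
    blocks = chain_anchors(anchors, max_gap=max_gap, min_block_size=min_block_size)
    window = max(min_block_size, diagonal_window)
    kept = []
    for b in blocks:
        if b.chrom_a == b.chrom_b:
            near_diag = all(
                abs(a.gene_a.rank - a.gene_b.rank) <= window
                for a in b.anchors
            )
            if near_diag:
                continue
        kept.append(b)
    for i, b in enumerate(kept):
        b.block_id = i
    return kept


def depth_profile(
    blocks: list[SyntenyBlock], query_genome: GenomeAnnotation
) -> DepthProfile:
    """Syntenic depth of every query gene: blocks whose rank span covers it.

    A block contributes coverage on whichever of its two sides lies in the
    query genome (both sides for self-synteny of that genome).
    """
    spans: list[tuple[str, int, int]] = []
    species = query_genome.species
    for b in blocks:
        if b.anchors and b.anchors[0].gene_a.species == species:
            lo, hi = b.span_a
            spans.append((b.chrom_a, lo, hi))
        if b.anchors and b.anchors[0].gene_b.species == species:
            lo, hi = b.span_b
            spans.append((b.chrom_b, lo, hi))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, lo, hi in spans:
        by_chrom.setdefault(chrom, []).append((lo, hi))
    depths: dict[str, int] = {}
    for g in query_genome.genes:
        depths[g.gene_id] = sum(
            1 for lo, hi in by_chrom.get(g.chrom, []) if lo <= g.rank <= hi
        )
    return DepthProfile.from_depths(depths)


def dotplot_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """One row per anchor for dot-plot rendering."""
    rows = []
    for b in blocks:
        for a in b.anchors:
            rows.append(
                {
                    "chrom_a": a.gene_a.chrom,
                    "rank_a": a.gene_a.rank,
                    "chrom_b": a.gene_b.chrom,
                    "rank_b": a.gene_b.rank,
                    "block_id": b.block_id,
                    "orientation": b.orientation,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom_a", "rank_a", "chrom_b", "rank_b", "block_id", "orientation"],
    )


def blocks_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Block summary table (the CLI's blocks TSV)."""
    rows = []
    for b in blocks:
        (sa, ea), (sb, eb) = b.span_a, b.span_b
        rows.append(
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a,
                "start_rank_a": sa,
                "end_rank_a": ea,
                "chrom_b": b.chrom_b,
                "start_rank_b": sb,
                "end_rank_b": eb,
                "n_anchors": len(b),
                "orientation": b.orientation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "chrom_a",
            "start_rank_a",
            "end_rank_a",
            "chrom_b",
            "start_rank_b",
            "end_rank_b",
            "n_anchors",
            "orientation",
        ],
    )
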