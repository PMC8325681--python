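"""Duplicate-gene mode classification (WGD / tandem / proximal / dispersed).

Ks distributions used for WGD dating must be built from WGD-derived pairs
only; small-scale duplicates (tandem arrays, nearby copies, dispersed
relocations) carry unrelated, typically younger, Ks values.  Pairs are
classified with the precedence wgd > tandem > proximal > dispersed:

* wgd — the pair is an anchor inside a within-genome synteny block;
* tandem — same chromosome, adjacent ranks (or separated only by members
  of the same homolog family, the default array-aware rule);
* proximal — same chromosome, rank distance <= ``proximal_window`` (10);
* dispersed — everything else.

Transposed duplicates (which need an outgroup genome) are not separated
out; such pairs land in "dispersed".
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GenomeAnnotation, GeneRecord
from .synteny import SyntenyBlock

MODES = ("wgd", "tandem", "proximal", "dispersed")


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: GeneRecord
    gene_b: GeneRecord
    mode: str
    ks: float | None = None


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _families(pairs: list[tuple[str, str]]) -> dict[str, str]:
    """Homolog families as connected components of the pair graph."""
    uf = _UnionFind()
    for a, b in pairs:
        uf.union(a, b)
    return {g: uf.find(g) for g in uf.parent}


def classify_pairs(
    genome: GenomeAnnotation,
    homolog_pairs: list[tuple[str, str]] | list[tuple[str, str, float | None]],
    self_blocks: list[SyntenyBlock],
    proximal_window: int = 10,
    strict_tandem: bool = False,
) -> list[DuplicatePair]:
    """Assign one duplication mode to every within-genome homolog pair.

    ``self_blocks`` must come from :func:`paleowgd.synteny.self_synteny` on
    the same pair set.  With ``strict_tandem`` a tandem pair must be rank-
    adjacent; by default genes separated only by other members of their own
    family still count as tandem (array-aware rule).
    """
    id_pairs = [(p[0], p[1]) for p in homolog_pairs if p[0] != p[1]]
    for a, b in id_pairs:
        if genome.gene(a).species != genome.gene(b).species:
            raise ValueError(f"pair {a}/{b} spans two species")

    anchor_keys = set()
    for block in self_blocks:
        for anchor in block.anchors:
            key = tuple(sorted((anchor.gene_a.gene_id, anchor.gene_b.gene_id)))
            anchor_keys.add(key)

    fam = _families(id_pairs)
    genes_by_chrom: dict[str, dict[int, str]] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.chrom, {})[g.rank] = g.gene_id

    out: list[DuplicatePair] = []
    for a, b in id_pairs:
        ga, gb = genome.gene(a), genome.gene(b)
        key = tuple(sorted((a, b)))
        if key in anchor_keys:
            mode = "wgd"
        elif ga.chrom == gb.chrom:
            lo, hi = sorted((ga.rank, gb.rank))
            delta = hi - lo
            if delta == 1:
                mode = "tandem"
            elif not strict_tandem and all(
                fam.get(genes_by_chrom[ga.chrom].get(r, ""), object())
                == fam.get(a)
                for r in range(lo + 1, hi)
            ):
                mode = "tandem"
            elif delta <= proximal_window:
                mode = "proximal"
            else:
                mode = "dispersed"
        else:
            mode = "dispersed"
        out.append(DuplicatePair(gene_a=ga, gene_b=gb, mode=mode))
    return out


def mode_summary(pairs: list[DuplicatePair]) -> dict[str, int]:
    """Counts per duplication mode (always includes all four keys)."""
    counts = {m: 0 for m in MODES}
    for p in pairs:
        counts[p.mode] += 1
    return counts
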