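"""Readers and writers for the formats the pipeline touches.

Coding sequences arrive as FASTA, gene coordinates as a GFF3 subset or a
plain TSV, homolog pairs as two/three-column TSV, and gene trees as Newick.
Everything is validated on the way in and mapped onto the package's domain
types (:class:`GeneRecord`, :class:`GenomeAnnotation`,
:class:`CodingSequencePair`).

Coordinates are kept 1-based inclusive (GFF3 native).  All synteny math runs
in *rank* space: the 0-based index of a gene along its chromosome after
sorting by start coordinate (ties broken by gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its genomic position and rank along its chromosome."""

    gene_id: str
    species: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    rank: int = -1  # 0-based order along the chromosome, assigned on load

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """An ordered gene set for one species, with dense per-chromosome ranks."""

    species: str
    genes: list[GeneRecord] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise FormatError(f"duplicate gene ids in genome {self.species}")

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def chromosome_genes(self, chrom: str) -> list[GeneRecord]:
        """Genes of one chromosome in rank order."""
        return sorted(
            (g for g in self.genes if g.chrom == chrom), key=lambda g: g.rank
        )


@dataclass(frozen=True)
class CodingSequencePair:
    """A codon-aligned pair of coding sequences (gaps allowed, codon-wise)."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise FormatError(
                f"{self.id_a}/{self.id_b}: unequal aligned lengths "
                f"{len(a)} vs {len(b)}"
            )
        if len(a) % 3 != 0:
            raise FormatError(f"{self.id_a}/{self.id_b}: length not divisible by 3")
        allowed = set("ACGT-")
        if (set(a) | set(b)) - allowed:
            raise FormatError(
                f"{self.id_a}/{self.id_b}: alphabet outside {{A,C,G,T,-}}"
            )
        for seq in (a, b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise FormatError(
                        f"{self.id_a}/{self.id_b}: codon {codon!r} mixes gap and base"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


def assign_ranks(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Assign dense 0-based ranks per chromosome, sorting by (start, gene_id)."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneRecord] = []
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(chrom_genes):
            out.append(
                GeneRecord(
                    gene_id=g.gene_id,
                    species=g.species,
                    chrom=g.chrom,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    rank=rank,
                )
            )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{id: uppercased sequence}``.

    Duplicate ids and empty files are format errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key] = value
    return out


def read_gene_positions(
    path: str | Path,
    species: str,
    dialect: str = "gff3",
    feature_type: str = "gene",
) -> GenomeAnnotation:
    """Load gene coordinates into a rank-annotated :class:`GenomeAnnotation`.

    Parameters
    ----------
    dialect
        ``"gff3"`` — standard 9-column GFF3; only lines whose type equals
        ``feature_type`` are used, ids from the ``ID`` attribute.
        ``"tsv"`` — columns gene_id, chrom, start, end, strand (no header).
    """
    raw: list[GeneRecord] = []
    if dialect == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                seqid, _, ftype, start, end, _, strand, _, attrs = fields
                if ftype != feature_type:
                    continue
                attr = _parse_gff3_attributes(attrs)
                gene_id = attr.get("ID")
                if not gene_id:
                    raise FormatError(f"{path}:{lineno}: missing ID attribute")
                raw.append(
                    GeneRecord(
                        gene_id=gene_id,
                        species=species,
                        chrom=seqid,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                    )
                )
    elif dialect == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise FormatError(f"{path}:{lineno}: expected 5 TSV columns")
                gene_id, chrom, start, end, strand = fields
                raw.append(
                    GeneRecord(
                        gene_id=gene_id,
                        species=species,
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                    )
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return GenomeAnnotation(species=species, genes=assign_ranks(raw))


def write_gene_positions(genome: GenomeAnnotation, path: str | Path) -> None:
    """Write a genome annotation as the 5-column TSV dialect, in rank order."""
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            for g in genome.chromosome_genes(chrom):
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree, preserving tip labels verbatim."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick in {path}: {exc}") from exc
    return tree


def read_newick_string(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick string: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_pairs(
    path: str | Path, header: bool = False
) -> list[tuple[str, str, float | None]]:
    """Read a homolog-pair TSV (2 or 3 columns: id_a, id_b[, score]).

    Pairs are order-normalised (id_a < id_b) and deduplicated; self-pairs are
    dropped with a logged warning.
    """
    seen: dict[tuple[str, str], float | None] = {}
    with open(path) as fh:
        lines = fh.readlines()
    if header:
        lines = lines[1:]
    for lineno, line in enumerate(lines, 2 if header else 1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 TSV columns")
        a, b = fields[0], fields[1]
        score = float(fields[2]) if len(fields) == 3 else None
        if a == b:
            logger.warning("%s:%d: dropping self-pair %s", path, lineno, a)
            continue
        key = (a, b) if a < b else (b, a)
        if key not in seen:
            seen[key] = score
    return [(a, b, s) for (a, b), s in seen.items()]


def write_pairs(
    pairs: Iterable[tuple[str, str] | tuple[str, str, float | None]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for pair in pairs:
            if len(pair) == 3 and pair[2] is not None:
                fh.write(f"{pair[0]}\t{pair[1]}\t{pair[2]}\n")
            else:
                fh.write(f"{pair[0]}\t{pair[1]}\n")
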