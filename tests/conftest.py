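import pytest

from paleowgd.io_formats import GeneRecord, GenomeAnnotation, assign_ranks


def make_genome(layout: dict[str, int], species: str = "Sp") -> GenomeAnnotation:
    """Toy genome: {chromosome: gene count}; ids '<chrom>_g<i>' in order."""
    genes = []
    for chrom, n in layout.items():
        for i in range(n):
            start = i * 1000 + 1
            genes.append(
                GeneRecord(
                    gene_id=f"{chrom}_g{i}",
                    species=species,
                    chrom=chrom,
                    start=start,
                    end=start + 500,
                )
            )
    return GenomeAnnotation(species=species, genes=assign_ranks(genes))


@pytest.fixture
def two_chrom_genome():
    return make_genome({"c1": 20, "c2": 20})
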