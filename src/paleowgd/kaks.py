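"""Nei–Gojobori (1986) Ka/Ks estimation for codon-aligned pairs.

The NG86 method counts synonymous (S) and nonsynonymous (N) *sites* per
codon from the fraction of single-nucleotide changes that preserve the
encoded amino acid, counts observed synonymous/nonsynonymous *differences*
by averaging over all mutational pathways between two codons, and corrects
the raw proportions ps = Sd/S and pn = Nd/N for multiple hits with the
Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p).

Conventions:

* standard nuclear genetic code (NCBI translation table 1);
* changes that create a stop codon count as nonsynonymous in site counts;
* pathways through stop codons are excluded from the difference average,
  unless every pathway does, in which case all are kept with equal weight;
* sites are averaged over the two sequences;
* Ks (or Ka) is undefined when its JC log argument is <= 0 ("saturated")
  or when the corresponding site count is zero; undefined results are
  returned flagged, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from .io_formats import CodingSequencePair

BASES = "ACGT"

# Standard genetic code, table 1.
CODON_TABLE: dict[str, str] = {}
_AAS = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_B1 = "TTTTTTTTTTTTTTTTCCCCCCCCCCCCCCCCAAAAAAAAAAAAAAAAGGGGGGGGGGGGGGGG"
_B2 = "TTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGGTTTTCCCCAAAAGGGG"
_B3 = "TCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAGTCAG"
for _i in range(64):
    CODON_TABLE[_B1[_i] + _B2[_i] + _B3[_i]] = _AAS[_i]

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


class CodonError(ValueError):
    """Raised for stop codons or non-ACGT bases where a sense codon is required."""


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CodonError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon {codon!r}")


def count_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    Each position contributes (synonymous changes among its 3 possible
    single-nucleotide changes) / 3 to s; s + n == 3 exactly.
    """
    _check_codon(codon)
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            # a change to a stop codon is nonsynonymous by convention
            if CODON_TABLE[mutant] == aa and mutant not in STOP_CODONS:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    For codons differing at k positions, every one of the k! orderings of
    single changes is walked; steps that keep the amino acid are synonymous.
    Pathways passing through a stop codon are dropped from the average; if
    all pathways hit stops, all are kept with equal weight.
    """
    _check_codon(codon_a)
    _check_codon(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        sd = nd = 0.0
        current = codon_a
        hit_stop = False
        for pos in order:
            mutant = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if mutant in STOP_CODONS:
                hit_stop = True
            if CODON_TABLE[current] == CODON_TABLE[mutant] and not (
                mutant in STOP_CODONS or current in STOP_CODONS
            ):
                sd += 1.0
            else:
                nd += 1.0
            current = mutant
        return sd, nd, hit_stop

    results = [walk(order) for order in permutations(diff_pos)]
    clean = [(sd, nd) for sd, nd, stop in results if not stop]
    if not clean:
        clean = [(sd, nd) for sd, nd, _ in results]
    sd = sum(x for x, _ in clean) / len(clean)
    nd = sum(y for _, y in clean) / len(clean)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when out of domain (p >= 3/4)."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


@dataclass(frozen=True)
class KaKsResult:
    """NG86 estimates for one pair; Nones are flagged undefined values."""

    id_a: str
    id_b: str
    ka: float | None
    ks: float | None
    ratio: float | None
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    n_codons_used: int
    status: str  # "ok", "ks_saturated", "ka_saturated", "no_synonymous_sites", ...


def _usable_codons(pair: CodingSequencePair) -> list[tuple[str, str]]:
    """Drop, pairwise, codons with gaps, ambiguity or stops in either sequence."""
    usable = []
    for ca, cb in pair.codons():
        if "-" in ca or "-" in cb:
            continue
        if any(b not in BASES for b in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        usable.append((ca, cb))
    return usable


def compute_kaks(pair: CodingSequencePair) -> KaKsResult:
    """NG86 Ka/Ks with JC correction for one codon-aligned pair.

    Sites are averaged over the two sequences; undefined Ks/Ka are carried
    as None with a status code rather than raised.
    """
    codons = _usable_codons(pair)
    if not codons:
        raise ValueError(f"{pair.id_a}/{pair.id_b}: no usable codons")

    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    for ca, cb in codons:
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = count_differences(ca, cb)
        s_diffs += sd
        n_diffs += nd

    status = "ok"
    ks: float | None
    ka: float | None
    if s_sites <= 0.0:
        ks = None
        status = "no_synonymous_sites"
    else:
        ks = jukes_cantor(s_diffs / s_sites)
        if ks is None:
            status = "ks_saturated"
    if n_sites <= 0.0:
        ka = None
        if status == "ok":
            status = "no_nonsynonymous_sites"
    else:
        ka = jukes_cantor(n_diffs / n_sites)
        if ka is None and status == "ok":
            status = "ka_saturated"

    ratio = None
    if ka is not None and ks is not None and ks > 0.0:
        ratio = ka / ks

    return KaKsResult(
        id_a=pair.id_a,
        id_b=pair.id_b,
        ka=ka,
        ks=ks,
        ratio=ratio,
        s_sites=s_sites,
        n_sites=n_sites,
        s_diffs=s_diffs,
        n_diffs=n_diffs,
        n_codons_used=len(codons),
        status=status,
    )


def compute_kaks_batch(
    pairs: list[tuple[str, str]], cds: dict[str, str]
) -> list[KaKsResult]:
    """Run :func:`compute_kaks` over id pairs resolved against a CDS dict.

    Sequences are paired codon-by-codon as given (the pipeline's inputs are
    pre-aligned CDS); pairs with missing ids raise KeyError.
    """
    out = []
    for id_a, id_b in pairs:
        pair = CodingSequencePair(id_a, id_b, cds[id_a], cds[id_b])
        out.append(compute_kaks(pair))
    return out
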