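"""IUPAC/spaced-dimer scanning, fraction tests, central enrichment, mutagenesis."""

import numpy as np
import pytest
from scipy import stats

from tisschip.core import GenomeAssembly, GenomicInterval, ValidationError
from tisschip.motifs import (
    IUPAC,
    IUPACPattern,
    Match,
    MotifLibrary,
    central_enrichment,
    compare_fractions,
    count_substitutions,
    mutate_sites,
    peak_motif_fraction,
    reverse_complement,
    scan,
)

SD = IUPACPattern.parse("GGAATG", name="Sd")
HTH = IUPACPattern.parse("TGAY[N0-2]TGAY", name="Hth-Exd")


def scan_oracle(seq, pattern, both_strands=True):
    """Exhaustive sliding-window oracle over all spacers and strands."""
    def matches_at(s, symbols, i):
        if i + len(symbols) > len(s):
            return False
        for sym, base in zip(symbols, s[i:i + len(symbols)]):
            if base == "N":
                if sym != "N":
                    return False
            elif base not in IUPAC[sym]:
                return False
        return True

    found = set()
    for symbols in pattern.expansions():
        m = len(symbols)
        for i in range(len(seq) - m + 1):
            if matches_at(seq, symbols, i):
                found.add(Match(i, i + m, "+"))
        if both_strands:
            rc = reverse_complement(seq)
            for i in range(len(rc) - m + 1):
                if matches_at(rc, symbols, i):
                    found.add(Match(len(seq) - i - m, len(seq) - i, "-"))
    return sorted(found, key=lambda x: (x.start, x.end, x.strand))


def test_scan_literal_match():
    matches = scan("AAGGAATGAA", SD, both_strands=False)
    assert matches == [Match(2, 8, "+")]


def test_scan_dimer_spacer_zero():
    # TGAC + TGAT: Y = {C, T}, spacer 0
    matches = scan("TGACTGAT", HTH)
    assert Match(0, 8, "+") in matches


def test_scan_dimer_spacers():
    # spacer 2 between half-sites
    assert any(m.start == 0 and m.end == 10 for m in scan("TGACGGTGAT", HTH))
    # spacer 3 is not admissible
    assert not scan("TGACGGGTGAT", HTH, both_strands=False)


def test_scan_minus_strand_mapping():
    seq = "AACATTCCAA"  # revcomp contains GGAATG
    (m,) = scan(seq, SD)
    assert m.strand == "-"
    assert reverse_complement(seq[m.start:m.end]) == "GGAATG"


def test_sequence_n_matches_only_pattern_n():
    assert not scan("GGANTG", SD)
    assert scan("GGANTG", IUPACPattern.parse("GGANTG"), both_strands=False)


def test_invalid_iupac_rejected():
    with pytest.raises(ValidationError):
        IUPACPattern.parse("GGXATG")
    with pytest.raises(ValidationError):
        scan("ACGU", SD)


@pytest.mark.parametrize("pattern", [SD, HTH, IUPACPattern.parse("RGAATG"),
                                     IUPACPattern.parse("WGAY[N0-2]WGAY")])
def test_scan_matches_bruteforce_oracle(pattern):
    rng = np.random.default_rng(5)
    for _ in range(150):
        seq = "".join(rng.choice(list("ACGTN"), size=60, p=[.24, .24, .24, .24, .04]))
        assert scan(seq, pattern) == scan_oracle(seq, pattern)


def test_scan_strand_symmetry():
    rng = np.random.default_rng(6)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        rc = reverse_complement(seq)
        fwd = {(m.start, m.end, m.strand) for m in scan(seq, HTH)}
        mirrored = {(len(seq) - m.end, len(seq) - m.start,
                     "+" if m.strand == "-" else "-") for m in scan(rc, HTH)}
        assert fwd == mirrored


def test_peak_motif_fraction_extremes():
    asm = GenomeAssembly(chrom_sizes={"c": 60},
                         sequence={"c": "AAAAAGGAATGAAAAACCCCCCCCCCCCCCCCCCCC" + "C" * 24})
    with_site = [GenomicInterval("c", 0, 20)]
    without = [GenomicInterval("c", 20, 50)]
    assert peak_motif_fraction(with_site, asm, SD).fraction == 1.0
    assert peak_motif_fraction(without, asm, SD).fraction == 0.0
    fr = peak_motif_fraction(with_site + without, asm, SD)
    assert (fr.numerator, fr.denominator) == (1, 2)


# ---------------------------------------------------------------------------
# Fraction comparison (Fisher exact, two-sided)
# ---------------------------------------------------------------------------


def fisher_oracle(a, b, c, d):
    """Enumerate all tables at fixed margins; sum probabilities <= observed."""
    from math import comb
    n1, n2, m1 = a + b, c + d, a + c
    total = comb(n1 + n2, m1)

    def pr(x):
        return comb(n1, x) * comb(n2, m1 - x) / total

    p_obs = pr(a)
    return sum(pr(x) for x in range(max(0, m1 - n2), min(n1, m1) + 1)
               if pr(x) <= p_obs * (1 + 1e-12))


def test_compare_fractions_examples():
    assert compare_fractions(8, 10, 2, 10) == pytest.approx(0.02301413756522116, rel=1e-10)
    assert compare_fractions(5, 10, 5, 10) == 1.0
    assert compare_fractions(10, 10, 0, 10) == pytest.approx(1.082508822446903e-05,
                                                             rel=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_compare_fractions_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = int(rng.integers(1, 100)), int(rng.integers(1, 100))
    a, c = int(rng.integers(0, n_a + 1)), int(rng.integers(0, n_b + 1))
    assert compare_fractions(a, n_a, c, n_b) == pytest.approx(
        fisher_oracle(a, n_a - a, c, n_b - c), rel=1e-10)


def test_compare_fractions_rejects_bad_input():
    with pytest.raises(ValidationError):
        compare_fractions(1, 0, 1, 10)
    with pytest.raises(ValidationError):
        compare_fractions(11, 10, 1, 10)


# ---------------------------------------------------------------------------
# Central enrichment
# ---------------------------------------------------------------------------


def _planted_seqs(n, length, motif, positions, rng, alphabet="CG"):
    """Motif-free background (C/G only) with one motif copy per sequence."""
    seqs = []
    for i in range(n):
        s = list(rng.choice(list(alphabet), size=length))
        p = positions[i]
        s[p:p + len(motif)] = list(motif)
        seqs.append("".join(s))
    return seqs


def test_central_enrichment_closed_form():
    """All best matches dead-centre, one window of fraction 0.2."""
    rng = np.random.default_rng(0)
    length, motif = 53, "TTTTTTTT"  # t = 46 candidate starts
    n = 40
    center_start = (length - len(motif)) // 2
    seqs = _planted_seqs(n, length, motif, [center_start] * n, rng)
    lib = MotifLibrary(motifs=[IUPACPattern.parse(motif, name="m")])
    # single window of 10 of 46 positions -> no multiple-window adjustment
    (r,) = central_enrichment(seqs, lib, window_widths=[10])
    assert r.count_in_window == n and r.n_sequences == n
    assert r.p_value == pytest.approx((10 / 46) ** n, rel=1e-9)
    assert r.e_value == pytest.approx(r.p_value)  # library of 1: E = p
    assert r.significant


def test_central_enrichment_library_multiplier():
    rng = np.random.default_rng(1)
    length, motif = 53, "TTTTTTTT"
    seqs = _planted_seqs(30, length, motif, [22] * 30, rng)
    solo = MotifLibrary(motifs=[IUPACPattern.parse(motif, name="m")])
    trio = MotifLibrary(motifs=[IUPACPattern.parse(motif, name="m"),
                                IUPACPattern.parse("TATATATA", name="d1"),
                                IUPACPattern.parse("TTAATTAA", name="d2")])
    (r1,) = central_enrichment(seqs, solo, window_widths=[10])
    r3 = [r for r in central_enrichment(seqs, trio, window_widths=[10])
          if r.motif == "m"][0]
    assert r3.e_value == pytest.approx(3 * r1.p_value)
    # motifs with no matches report p = 1
    dummy = [r for r in central_enrichment(seqs, trio, window_widths=[10])
             if r.motif == "d1"][0]
    assert dummy.n_sequences == 0 and dummy.p_value == 1.0


def test_central_enrichment_rejects_ragged_input():
    with pytest.raises(ValidationError):
        central_enrichment(["ACGT", "ACGTA"],
                           MotifLibrary(motifs=[IUPACPattern.parse("AC")]))


def test_central_enrichment_uniform_null_not_significant():
    rng = np.random.default_rng(2)
    length, motif = 208, "TTTTTTTT"
    t = length - len(motif) + 1
    es = []
    for _ in range(20):
        pos = rng.integers(0, t, size=100)
        seqs = _planted_seqs(100, length, motif, list(pos), rng)
        lib = MotifLibrary(motifs=[IUPACPattern.parse(motif, name="m")])
        (r,) = central_enrichment(seqs, lib)
        es.append(r.p_value)
    # Bonferroni-adjusted best-window p under the null is rarely tiny
    assert np.median(es) > 0.05


# ---------------------------------------------------------------------------
# Mutagenesis utilities
# ---------------------------------------------------------------------------


def test_count_substitutions():
    assert count_substitutions("GACAG", "GGGGG") == 3
    assert count_substitutions("TGAT", "GGGG") == 3
    assert count_substitutions("ACGT", "ACGT") == 0
    with pytest.raises(ValidationError):
        count_substitutions("ACG", "ACGT")


def test_mutate_sites_removes_matches():
    hth_site = IUPACPattern.parse("GACAG")
    seq = "TTTTGACAGTTTT"
    matches = scan(seq, hth_site, both_strands=False)
    mutant, n_subs = mutate_sites(seq, matches, "GGGGG")
    assert n_subs == 3
    assert not scan(mutant, hth_site, both_strands=False)


def test_mutate_seven_sites():
    rng = np.random.default_rng(3)
    spacer = "".join(rng.choice(list("C"), size=10))
    seq = ("CCCCC" + "GGAATG" + spacer) * 7 + "CCCCC"
    matches = [m for m in scan(seq, SD) if m.strand == "+"]
    assert len(matches) == 7
    mutant, n_subs = mutate_sites(seq, matches, "CCCCCC")
    assert not scan(mutant, SD)
    assert n_subs == 7 * count_substitutions("GGAATG", "CCCCCC")


def test_mutate_sites_edge_cases():
    assert mutate_sites("ACGT", [], []) == ("ACGT", 0)
    with pytest.raises(ValidationError, match="overlap"):
        mutate_sites("AAAAAA", [Match(0, 4, "+"), Match(2, 6, "+")], "TTTT")
    with pytest.raises(ValidationError, match="length"):
        mutate_sites("AAAAAA", [Match(0, 4, "+")], "TT")
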