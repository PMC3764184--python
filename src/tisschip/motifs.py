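"""Degenerate-consensus and spaced-dimer motif scanning and enrichment.

Consensus matching is binary IUPAC class membership on both strands; a
spaced dimer like TGAY[N0-2]TGAY matches for every admissible spacer
length (0, 1 or 2 unconstrained bases between the half-sites).  An ``N``
in the *sequence* is treated as unknown and matches only the pattern
symbol ``N``.  Central enrichment tests whether a motif's best match per
peak concentrates near peak centres, with a binomial upper tail per
centre-symmetric window, a Bonferroni adjustment over the windows tested,
and an E-value equal to the adjusted p times the motif-library size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .core import GenomeAssembly, ScoredPeak, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# symbol -> bool mask over codes (A,C,G,T,N); sequence N matches only pattern N
_SYMBOL_MASK = {}
for _sym, _bases in IUPAC.items():
    _mask = np.zeros(5, dtype=bool)
    for _b in _bases:
        _mask[_BASE_CODE[_b]] = True
    _mask[4] = _sym == "N"
    _SYMBOL_MASK[_sym] = _mask


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate consensus, optionally two half-sites with a spacer range.

    ``TGAY[N0-2]TGAY`` is ``IUPACPattern("TGAY", "TGAY", 0, 2)``: half-sites
    separated by 0-2 unconstrained bases, half-site placements never
    overlapping.
    """

    half_site_1: str
    half_site_2: str | None = None
    spacer_min: int = 0
    spacer_max: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        for site in (self.half_site_1, self.half_site_2 or ""):
            bad = set(site.upper()) - set(IUPAC)
            if bad:
                raise ValidationError(f"invalid IUPAC symbols {sorted(bad)} in {site!r}")
        if not self.half_site_1:
            raise ValidationError("empty half-site")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValidationError("need 0 <= spacer_min <= spacer_max")
        object.__setattr__(self, "half_site_1", self.half_site_1.upper())
        if self.half_site_2 is not None:
            object.__setattr__(self, "half_site_2", self.half_site_2.upper())

    @property
    def is_dimer(self) -> bool:
        return self.half_site_2 is not None

    def expansions(self) -> list[str]:
        """Concrete symbol strings, one per admissible spacer length."""
        if not self.is_dimer:
            return [self.half_site_1]
        return [self.half_site_1 + "N" * s + self.half_site_2
                for s in range(self.spacer_min, self.spacer_max + 1)]

    @classmethod
    def parse(cls, text: str, name: str = "") -> "IUPACPattern":
        """Parse ``GGAATG`` or dimer syntax ``TGAY[N0-2]TGAY``."""
        m = re.fullmatch(r"([A-Za-z]+)\[N(\d+)-(\d+)\]([A-Za-z]+)", text)
        if m:
            return cls(m.group(1), m.group(4), int(m.group(2)), int(m.group(3)),
                       name=name or text)
        return cls(text, name=name or text)


@dataclass(frozen=True)
class Match:
    """A motif occurrence: forward-strand half-open extent plus strand."""

    start: int
    end: int
    strand: str


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    table = np.full(256, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
    out = table[codes]
    if (out < 0).any():
        bad = chr(codes[int(np.argmax(out < 0))])
        raise ValidationError(f"sequence contains non-ACGTN character {bad!r}")
    return out


def _scan_codes(codes: np.ndarray, symbols: str) -> np.ndarray:
    m = len(symbols)
    n = codes.size - m + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    valid = np.ones(n, dtype=bool)
    for j, sym in enumerate(symbols):
        valid &= _SYMBOL_MASK[sym][codes[j : j + n]]
        if not valid.any():
            break
    return np.flatnonzero(valid)


def scan(sequence: str, pattern: IUPACPattern, both_strands: bool = True) -> list[Match]:
    """All motif occurrences in ``sequence``.

    Minus-strand matches are found by scanning the reverse complement and
    mapping coordinates back to the forward strand.  Matches are unique by
    (start, end, strand) and sorted by position.
    """
    codes = _encode(sequence)
    length = codes.size
    found: set[Match] = set()
    strands = [("+", codes)]
    if both_strands:
        strands.append(("-", _encode(reverse_complement(sequence))))
    for strand, arr in strands:
        for symbols in pattern.expansions():
            m = len(symbols)
            for p in _scan_codes(arr, symbols):
                p = int(p)
                if strand == "+":
                    found.add(Match(p, p + m, "+"))
                else:
                    found.add(Match(length - p - m, length - p, "-"))
    return sorted(found, key=lambda x: (x.start, x.end, x.strand))


@dataclass(frozen=True)
class FractionResult:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator if self.denominator else float("nan")


def peak_motif_fraction(
    peaks: Sequence,
    assembly: GenomeAssembly,
    pattern: IUPACPattern,
    both_strands: bool = True,
) -> FractionResult:
    """Fraction of peaks containing >=1 motif match within the peak interval."""
    hits = 0
    for p in peaks:
        iv = p.interval if isinstance(p, ScoredPeak) else p
        if scan(assembly.fetch(iv), pattern, both_strands):
            hits += 1
    return FractionResult(hits, len(peaks))


def compare_fractions(hits_a: int, n_a: int, hits_b: int, n_b: int) -> float:
    """Two-sided Fisher's exact p for a difference in motif fractions."""
    if n_a == 0 or n_b == 0:
        raise ValidationError("compare_fractions needs non-empty groups")
    if not (0 <= hits_a <= n_a and 0 <= hits_b <= n_b):
        raise ValidationError("hits must satisfy 0 <= hits <= n")
    table = [[hits_a, n_a - hits_a], [hits_b, n_b - hits_b]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Motif libraries and central enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PWM:
    """Position-weight matrix (probabilities, rows = positions, cols ACGT)."""

    name: str
    matrix: tuple[tuple[float, ...], ...]

    def log_odds(self, background: float = 0.25, pseudo: float = 1e-3) -> np.ndarray:
        m = np.asarray(self.matrix, dtype=float)
        return np.log((m + pseudo) / (1 + 4 * pseudo)) - np.log(background)

    def __len__(self) -> int:
        return len(self.matrix)


@dataclass
class MotifLibrary:
    """Consensus and/or PWM motifs; ``size`` multiplies enrichment p-values."""

    motifs: list  # IUPACPattern | PWM

    @property
    def size(self) -> int:
        return len(self.motifs)


def read_meme(path) -> MotifLibrary:
    """Minimal MEME-format PWM reader (letter-probability matrices)."""
    motifs = []
    name, rows, expect = None, [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                name = parts[1] if len(parts) > 1 else f"motif{len(motifs) + 1}"
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                expect = int(m.group(1)) if m else 0
                rows = []
            elif name is not None and expect and line and line[0] in "0123456789.":
                vals = tuple(float(x) for x in line.split())
                if len(vals) != 4:
                    raise ValidationError(f"{path}: expected 4 probabilities per row, got {line!r}")
                rows.append(vals)
                if len(rows) == expect:
                    motifs.append(PWM(name=name, matrix=tuple(rows)))
                    name, rows, expect = None, [], 0
    return MotifLibrary(motifs=motifs)


def read_consensus_list(path) -> MotifLibrary:
    """Plain-text consensus list: one ``name<TAB>pattern`` (or pattern) per line."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                motifs.append(IUPACPattern.parse(parts[1], name=parts[0]))
            else:
                motifs.append(IUPACPattern.parse(parts[0]))
    return MotifLibrary(motifs=motifs)


@dataclass(frozen=True)
class CentralEnrichmentResult:
    motif: str
    window_width: int
    count_in_window: int
    n_sequences: int
    n_candidate_positions: int
    p_value: float
    e_value: float
    significant: bool


def _best_match_positions_consensus(seqs, pattern) -> tuple[np.ndarray, int]:
    m = min(len(e) for e in pattern.expansions())
    t = len(seqs[0]) - m + 1
    center = (t - 1) / 2
    best = []
    for seq in seqs:
        matches = scan(seq, pattern)
        if not matches:
            best.append(-1)
            continue
        # position of a match = its start; ties toward centre then leftmost
        starts = sorted({mt.start for mt in matches})
        best.append(min(starts, key=lambda s: (abs(s - center), s)))
    return np.asarray(best), t


def _best_match_positions_pwm(seqs, pwm: PWM) -> tuple[np.ndarray, int]:
    lo = pwm.log_odds()
    m = len(pwm)
    t = len(seqs[0]) - m + 1
    center = (t - 1) / 2
    cols = np.arange(m)
    best = []
    for seq in seqs:
        codes = _encode(seq)
        rc = _encode(reverse_complement(seq))
        scores = np.full(t, -np.inf)
        for strand_codes, is_rc in ((codes, False), (rc, True)):
            windows = np.lib.stride_tricks.sliding_window_view(strand_codes, m)
            ok = (windows < 4).all(axis=1)
            s = np.full(t, -np.inf)
            safe = np.where(windows < 4, windows, 0)
            s[ok] = lo[cols, safe[ok]].sum(axis=1)
            if is_rc:
                s = s[::-1]
            scores = np.maximum(scores, s)
        if not np.isfinite(scores).any():
            best.append(-1)
            continue
        top = scores.max()
        cands = np.flatnonzero(scores == top)
        best.append(int(min(cands, key=lambda i: (abs(i - center), i))))
    return np.asarray(best), t


def central_enrichment(
    peak_sequences: Sequence[str],
    library: MotifLibrary,
    window_widths: Iterable[int] | None = None,
    e_threshold: float = 10.0,
) -> list[CentralEnrichmentResult]:
    """Centre-symmetric window enrichment of best matches, per library motif.

    Sequences must share one length L (peaks resized around their centres
    upstream).  For each motif, the single best match per sequence is
    taken (PWM: top log-odds score; consensus: any match), ties broken
    toward the centre then leftmost.  Each candidate window is tested by a
    binomial upper tail with success probability = window positions /
    total admissible positions; the best window's p is Bonferroni-adjusted
    by the number of windows tested, and E = p x library size.  Results
    are sorted by E-value.
    """
    lengths = {len(s) for s in peak_sequences}
    if len(lengths) != 1:
        raise ValidationError(f"peak sequences must share one length, got {sorted(lengths)}")
    out = []
    for motif in library.motifs:
        if isinstance(motif, IUPACPattern):
            positions, t = _best_match_positions_consensus(peak_sequences, motif)
            label = motif.name or "/".join(motif.expansions()[:1])
        else:
            positions, t = _best_match_positions_pwm(peak_sequences, motif)
            label = motif.name
        positions = positions[positions >= 0]
        n = positions.size
        if window_widths is None:
            widths = list(range(1 if t % 2 else 2, t + 1, 2))
        else:
            widths = [w for w in window_widths if 0 < w <= t and (t - w) % 2 == 0]
        if n == 0 or not widths:
            out.append(CentralEnrichmentResult(label, 0, 0, n, t, 1.0,
                                               float(library.size), False))
            continue
        best = None
        for w in widths:
            lo_edge = (t - w) // 2
            k = int(((positions >= lo_edge) & (positions < lo_edge + w)).sum())
            p = float(stats.binom.sf(k - 1, n, w / t))
            if best is None or p < best[0]:
                best = (p, w, k)
        p_adj = min(1.0, best[0] * len(widths))
        e_value = p_adj * library.size
        out.append(CentralEnrichmentResult(
            motif=label, window_width=best[1], count_in_window=best[2],
            n_sequences=n, n_candidate_positions=t, p_value=p_adj,
            e_value=e_value, significant=e_value <= e_threshold))
    return sorted(out, key=lambda r: r.e_value)


# ---------------------------------------------------------------------------
# Mutagenesis utilities
# ---------------------------------------------------------------------------


def count_substitutions(wild: str, mutant: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(wild) != len(mutant):
        raise ValidationError("sequences differ in length")
    return sum(a != b for a, b in zip(wild.upper(), mutant.upper()))


def mutate_sites(
    sequence: str,
    matches: Sequence[Match],
    replacement_policy: str | Sequence[str] | Callable[[Match, str], str],
) -> tuple[str, int]:
    """Replace motif sites in a sequence; returns (mutant, substitutions).

    ``replacement_policy`` is a single replacement string (applied to every
    site; lengths must agree), one string per site, or a callable
    ``(match, wild_site) -> replacement``.  Replacements are forward-strand
    strings.  Overlapping sites are an error.
    """
    sites = sorted(matches, key=lambda m: m.start)
    for a, b in zip(sites, sites[1:]):
        if b.start < a.end:
            raise ValidationError(f"overlapping replacement sites at {a.start} and {b.start}")
    if callable(replacement_policy):
        repl = [replacement_policy(m, sequence[m.start : m.end]) for m in sites]
    elif isinstance(replacement_policy, str):
        repl = [replacement_policy] * len(sites)
    else:
        repl = list(replacement_policy)
        if len(repl) != len(sites):
            raise ValidationError("one replacement per site required")
    out = list(sequence)
    total = 0
    for m, r in zip(sites, repl):
        wild = sequence[m.start : m.end]
        if len(r) != len(wild):
            raise ValidationError(f"replacement {r!r} length != site length {len(wild)}")
        total += count_substitutions(wild, r)
        out[m.start : m.end] = r
    return "".join(out), total
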