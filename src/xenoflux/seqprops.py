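"""Sequence- and biophysics-level property calculators for orthologous enzymes.

This module covers the per-protein descriptors used throughout the analysis:
codon-usage signatures of a reference ORF and deterministic back-translation,
GC content of the adapted DNA sequences, Henderson-Hasselbalch net charge,
global-alignment percent identity, the codon adaptation index (CAI), the
coordinates of the mRNA-folding window around the start codon, and apparent
melting temperatures from calorimetric thermograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "CodonUsageTable",
    "Thermogram",
    "SequencePair",
    "DEFAULT_PKA",
    "codon_frequencies",
    "back_translate",
    "gc_content",
    "net_charge",
    "percent_identity",
    "cai",
    "cai_weights",
    "mrna_window",
    "tm_from_thermogram",
]

_DNA_ALPHABET = frozenset("ACGT")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
_STOP_SYMBOL = "*"

# codon -> amino acid (one-letter), stops mapped to "*"
_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({c: _STOP_SYMBOL for c in standard_dna_table.stop_codons})

# amino acid -> synonymous family
_FAMILY: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    _FAMILY.setdefault(_aa, []).append(_codon)

# Side-chain pKa values (EMBOSS defaults).  Basic groups: K, R, H (+ N-terminus);
# acidic: D, E, C, Y (+ C-terminus).  Shipped table is versioned here; any op
# accepts an override.
DEFAULT_PKA: dict[str, float] = {
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "Nterm": 8.6,
    "Cterm": 3.6,
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("K", "R", "H")


class InvalidAlphabetError(ValueError):
    """Sequence contains a character outside the declared alphabet."""


class FrameError(ValueError):
    """DNA length is not a multiple of three."""


class MissingCodonError(KeyError):
    """An amino acid has no observed codon in the usage table."""


class CoordinateError(ValueError):
    """Requested window falls outside the construct."""


class NoTransitionError(ValueError):
    """Thermogram has no discernible peak after baseline subtraction."""


def _check_dna(dna: str) -> str:
    seq = dna.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise InvalidAlphabetError(f"non-ACGT characters in DNA: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon counts of a reference ORF with within-family frequencies.

    ``family_freq`` normalizes counts within each synonymous family of the
    standard genetic code, so it is a per-amino-acid distribution.
    ``argmax_codon`` is the family-maximal codon per amino acid (ties broken
    alphabetically), i.e. the "codon signature" used for back-translation.
    """

    codon_counts: dict[str, int]
    family_freq: dict[str, float] = field(default_factory=dict)
    argmax_codon: dict[str, str] = field(default_factory=dict)

    @property
    def amino_acids(self) -> set[str]:
        return set(self.argmax_codon)


@dataclass(frozen=True)
class Thermogram:
    """A DSC-style scan: differential power vs temperature (strictly increasing)."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("temperature and signal must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class SequencePair:
    query: str
    reference: str
    identity_percent: float


def codon_frequencies(orf_dna: str) -> CodonUsageTable:
    """Tally codons of an ORF and compute within-family frequencies.

    Raises
    ------
    InvalidAlphabetError
        on non-ACGT characters.
    FrameError
        if the length is not a multiple of 3.
    """
    seq = _check_dna(orf_dna)
    if len(seq) % 3 != 0:
        raise FrameError(f"ORF length {len(seq)} is not a multiple of 3")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1

    family_freq: dict[str, float] = {}
    argmax: dict[str, str] = {}
    for aa, codons in _FAMILY.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        best = None
        for c in codons:  # codons sorted alphabetically at module init
            n = counts.get(c, 0)
            if n:
                family_freq[c] = n / total
            if best is None or counts.get(c, 0) > counts.get(best, 0):
                best = c
        argmax[aa] = best
    return CodonUsageTable(codon_counts=counts, family_freq=family_freq, argmax_codon=argmax)


def back_translate(aa_seq: str, table: CodonUsageTable) -> str:
    """Convert a protein to DNA using the family-maximal codon per residue.

    A trailing ``*`` emits the table's stop codon.  Deterministic: ties in the
    usage table were already resolved alphabetically when the table was built.
    """
    seq = aa_seq.upper()
    out: list[str] = []
    for i, aa in enumerate(seq):
        if aa == _STOP_SYMBOL:
            if i != len(seq) - 1:
                raise InvalidAlphabetError("internal stop symbol in protein sequence")
        elif aa not in _AA_ALPHABET:
            raise InvalidAlphabetError(f"unknown residue {aa!r} at position {i}")
        if aa not in table.argmax_codon:
            raise MissingCodonError(
                f"no codon observed for residue {aa!r} in the usage table"
            )
        out.append(table.argmax_codon[aa])
    return "".join(out)


def gc_content(dna: str) -> float:
    """Percent G+C of a DNA sequence."""
    seq = _check_dna(dna)
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def net_charge(
    aa_seq: str,
    ph: float = 7.0,
    pka: dict[str, float] | None = None,
    include_termini: bool = False,
) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH.

    Each basic group contributes ``+1/(1+10^(pH-pKa))``, each acidic group
    ``-1/(1+10^(pKa-pH))``; side chains only unless ``include_termini``.
    Additive over concatenation (termini off) and monotone decreasing in pH.
    """
    table = DEFAULT_PKA if pka is None else pka
    seq = aa_seq.upper()
    bad = set(seq) - _AA_ALPHABET
    if bad:
        raise InvalidAlphabetError(f"unknown residues: {sorted(bad)}")
    q = 0.0
    for aa in seq:
        if aa in _BASIC:
            q += 1.0 / (1.0 + 10.0 ** (ph - table[aa]))
        elif aa in _ACIDIC:
            q -= 1.0 / (1.0 + 10.0 ** (table[aa] - ph))
    if include_termini and seq:
        q += 1.0 / (1.0 + 10.0 ** (ph - table["Nterm"]))
        q -= 1.0 / (1.0 + 10.0 ** (table["Cterm"] - ph))
    return q


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def percent_identity(query: str, reference: str) -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    BLOSUM62, gap open 11 / extend 1.  The denominator counts alignment
    columns including internal gaps but excluding terminal-gap overhangs,
    so identical sequences score exactly 100.
    """
    q, r = query.upper(), reference.upper()
    if not q or not r:
        raise ValueError("empty sequence")
    for s in (q, r):
        bad = set(s) - _AA_ALPHABET
        if bad:
            raise InvalidAlphabetError(f"unknown residues: {sorted(bad)}")
    aln = _make_aligner().align(q, r)[0]
    a, b = str(aln[0]), str(aln[1])
    # trim terminal-gap columns (overhang of either sequence)
    start = 0
    end = len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[start:end], b[start:end]) if x == y and x != "-")
    return 100.0 * matches / cols


def cai_weights(table: CodonUsageTable) -> dict[str, float]:
    """Relative adaptiveness w = family_freq / max family_freq per family."""
    weights: dict[str, float] = {}
    for aa, codons in _FAMILY.items():
        freqs = {c: table.family_freq.get(c, 0.0) for c in codons}
        top = max(freqs.values(), default=0.0)
        if top <= 0:
            continue
        for c, f in freqs.items():
            weights[c] = f / top
    return weights


def cai(dna: str, weights: dict[str, float], zero_floor: float = 0.01) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Single-codon families (ATG, TGG) and stop codons are uninformative and
    excluded; codons with zero weight in the reference set are floored at
    ``zero_floor`` before the geometric mean.
    """
    seq = _check_dna(dna)
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    logs = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = _CODON_TO_AA[codon]
        if aa == _STOP_SYMBOL or len(_FAMILY[aa]) == 1:
            continue
        w = weights.get(codon, 0.0)
        if w <= 0.0:
            w = zero_floor
        logs.append(np.log(min(w, 1.0)))
    if not logs:
        raise ValueError("no informative codons; CAI undefined")
    return float(np.exp(np.mean(logs)))


def mrna_window(
    construct: str,
    atg_index: int,
    offset: int = -4,
    length: int = 42,
) -> tuple[int, int, str]:
    """Coordinates (0-based, half-open) and sequence of the folding window.

    The window starts ``offset`` nucleotides from the A of the annotated ATG
    (negative = upstream) and spans ``length`` nt.  The folding free energy
    itself is computed externally; only the window is extracted here.
    """
    seq = _check_dna(construct)
    start = atg_index + offset
    end = start + length
    if start < 0 or end > len(seq):
        raise CoordinateError(
            f"window [{start}, {end}) exceeds construct bounds [0, {len(seq)})"
        )
    return start, end, seq[start:end]


def tm_from_thermogram(
    thermogram: Thermogram,
    smooth_window: int = 1,
    flat_tol: float = 1e-12,
) -> float:
    """Apparent melting temperature: peak of the baseline-subtracted scan.

    The baseline is the straight line through the first and last grid points
    (linear-endpoints subtraction); an optional centered moving average of odd
    width ``smooth_window`` is applied before taking the global maximum.
    """
    t = thermogram.temperature
    s = thermogram.signal
    if t.size < 5:
        raise ValueError("need at least 5 grid points")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    baseline = s[0] + (s[-1] - s[0]) * (t - t[0]) / (t[-1] - t[0])
    y = s - baseline
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        y = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")
    if y.max() - y.min() < flat_tol:
        raise NoTransitionError("signal is flat after baseline subtraction")
    return float(t[int(np.argmax(y))])


def translate(dna: str) -> str:
    """Translate an ORF (standard code); trailing stop is dropped."""
    seq = _check_dna(dna)
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    aa = str(Seq(seq).translate())
    return aa[:-1] if aa.endswith("*") else aa
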