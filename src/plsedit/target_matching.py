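"""Juxtaposing a PPR array with an RNA window and scoring the fit.

The array is laid along the target with numbered repeat k opposite
nucleotide −(k+3) and the terminal triplet opposite −3..−1; position 0 is
the candidate editing cytidine.  Each repeat–nucleotide pair is classified
against the repeat's code expectation:

* ``MATCH`` — the nucleotide equals the expected one (for the unranked
  C/U rule, either pyrimidine);
* ``PYRIMIDINE_TRANSITION`` — a ranked pyrimidine rule (C > U or U > C)
  paired with the other pyrimidine;
* ``PURINE_TRANSITION`` — a purine expectation paired with the other
  purine (A↔G);
* ``MISMATCH`` — everything else with a non-empty expectation;
* ``NO_EXPECTATION`` — uncoded residue pair or an N in the window.

The score is a weighted sum over pairs.  Default weights reflect the
mutational evidence that purine positions dominate recognition (purine
transitions abolish editing, some pyrimidine swaps are tolerated): purine
matches at P/S repeats count double, purine transitions and mismatches are
penalised, L-type matches count at reduced weight, and the terminal
triplet is neutral (the −3..−1 environment is handled as an explicit
constraint in the scanner, not by the linear score).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ppr_model import (
    NucleotideExpectation,
    PPRArray,
    PPRRepeat,
    expected_nucleotides,
    repeat_position,
)

RNA_ALPHABET = set("ACGUN")
PURINES = ("A", "G")
PYRIMIDINES = ("C", "U")

_COMPLEMENT = str.maketrans("ACGTUN", "UGCAAN")


def reverse_complement_rna(seq: str) -> str:
    """Reverse complement, RNA alphabet out (T/U both accepted in)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


class MatchCategory(enum.Enum):
    MATCH = "MATCH"
    PYRIMIDINE_TRANSITION = "PYRIMIDINE_TRANSITION"
    PURINE_TRANSITION = "PURINE_TRANSITION"
    MISMATCH = "MISMATCH"
    NO_EXPECTATION = "NO_EXPECTATION"


@dataclass(frozen=True)
class TargetWindow:
    """RNA nucleotides covering positions −W..+D around a candidate site.

    ``sequence`` is 5′→3′ on the edited strand; index W of the string is
    position 0 (the candidate cytidine).  Windows truncated at sequence
    ends are padded with N.
    """

    sequence: str
    W: int = 33
    D: int = 5
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != self.W + 1 + self.D:
            raise ValueError(
                f"window length {len(self.sequence)} != W+1+D = "
                f"{self.W + 1 + self.D}"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters in window: {sorted(bad)}")

    @property
    def site_nt(self) -> str:
        return self.sequence[self.W]

    def at(self, position: int) -> str:
        """Nucleotide at a site-relative position; N outside the window."""
        i = position + self.W
        if 0 <= i < len(self.sequence):
            return self.sequence[i]
        return "N"

    def mutate(self, position: int, nt: str) -> "TargetWindow":
        """Copy of the window with one position substituted."""
        i = position + self.W
        seq = self.sequence[:i] + to_rna(nt) + self.sequence[i + 1:]
        return TargetWindow(seq, self.W, self.D, self.source)


def extract_window(
    sequence: str,
    site_index: int,
    W: int = 33,
    D: int = 5,
    strand: str = "+",
    source: str = "",
    require_c: bool = False,
) -> TargetWindow:
    """Cut a −W..+D window around a 0-based site in a nucleotide sequence.

    DNA input is transparently converted to RNA.  On strand '−' the window
    is taken from the reverse complement so that the returned sequence
    reads 5′→3′ on the edited strand.  Ends are N-padded.
    """
    if not 0 <= site_index < len(sequence):
        raise IndexError(f"site_index {site_index} outside sequence")
    seq = to_rna(sequence)
    if strand == "-":
        seq = reverse_complement_rna(seq)
        site_index = len(seq) - 1 - site_index
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    lo, hi = site_index - W, site_index + D + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    window = "N" * left_pad + seq[max(0, lo):min(len(seq), hi)] + "N" * right_pad
    tw = TargetWindow(window, W, D, source=source)
    if require_c and tw.site_nt != "C":
        raise ValueError(
            f"site nucleotide is {tw.site_nt}, not C ({source or 'window'})"
        )
    return tw


def classify_pair(expectation: NucleotideExpectation, nt: str) -> MatchCategory:
    """Classify one repeat–nucleotide pair against the code expectation."""
    if nt not in RNA_ALPHABET:
        raise ValueError(f"invalid nucleotide {nt!r}")
    if expectation.empty or nt == "N":
        return MatchCategory.NO_EXPECTATION
    if nt == expectation.primary:
        return MatchCategory.MATCH
    if expectation.unranked and nt == expectation.secondary:
        return MatchCategory.MATCH
    if expectation.secondary is not None and nt == expectation.secondary:
        return MatchCategory.PYRIMIDINE_TRANSITION
    if expectation.is_purine and nt in PURINES:
        return MatchCategory.PURINE_TRANSITION
    return MatchCategory.MISMATCH


@dataclass(frozen=True)
class MatchPair:
    repeat: PPRRepeat
    position: int
    nt: str
    category: MatchCategory


@dataclass(frozen=True)
class ScoringWeights:
    """Per-(repeat class, category) score contributions.

    ``match_purine_ps``/``match_pyrimidine_ps`` apply to numbered P/S
    repeats, ``match_l`` to numbered L repeats (``promote_l`` lifts L
    matches to full P/S weight); the triplet always contributes
    ``triplet`` (default 0).
    """

    match_purine_ps: float = 2.0
    match_pyrimidine_ps: float = 1.0
    match_l: float = 0.5
    pyrimidine_transition: float = 0.5
    purine_transition: float = -1.0
    mismatch: float = -1.0
    no_expectation: float = 0.0
    triplet: float = 0.0
    promote_l: bool = False

    def weight(self, repeat: PPRRepeat, expectation: NucleotideExpectation,
               category: MatchCategory) -> float:
        if repeat.is_triplet:
            return self.triplet
        if category is MatchCategory.NO_EXPECTATION:
            return self.no_expectation
        if category is MatchCategory.MATCH:
            if repeat.ptype == "L" and not self.promote_l:
                return self.match_l
            if expectation.is_purine:
                return self.match_purine_ps
            return self.match_pyrimidine_ps
        if category is MatchCategory.PYRIMIDINE_TRANSITION:
            return self.pyrimidine_transition
        if category is MatchCategory.PURINE_TRANSITION:
            return self.purine_transition
        return self.mismatch

    def max_repeat_weight(self, repeat: PPRRepeat) -> float:
        """Best attainable contribution of one repeat (its MATCH weight)."""
        exp = expected_nucleotides(repeat.res5, repeat.resL)
        if repeat.is_triplet or exp.empty:
            return self.triplet if repeat.is_triplet else 0.0
        return self.weight(repeat, exp, MatchCategory.MATCH)


DEFAULT_WEIGHTS = ScoringWeights()


@dataclass(frozen=True)
class MatchProfile:
    """The full repeat-by-repeat alignment of an array to one window."""

    array_name: str
    source: str
    pairs: tuple[MatchPair, ...]
    score: float

    def category_counts(self) -> dict[MatchCategory, int]:
        out = {c: 0 for c in MatchCategory}
        for p in self.pairs:
            out[p.category] += 1
        return out


def match_profile(
    array: PPRArray,
    window: TargetWindow,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    shift: int = 0,
) -> MatchProfile:
    """Pair every repeat with its window nucleotide and score the fit.

    ``shift`` displaces the whole register by one nucleotide (+1 toward the
    editing site, −1 upstream); positions outside the window raise unless
    the window can still cover every repeat.
    """
    upstream, _ = array.span
    if shift == 0 and upstream < -window.W:
        culprit = min(array, key=repeat_position)
        raise ValueError(
            f"window too short for repeat {culprit.label} "
            f"at position {upstream}"
        )
    # shifted registers may step one nucleotide past the window edge;
    # window.at returns N there, which scores 0
    pairs = []
    score = 0.0
    for repeat in array:
        pos = repeat_position(repeat) + shift
        nt = window.at(pos)
        exp = expected_nucleotides(repeat.res5, repeat.resL)
        cat = classify_pair(exp, nt)
        pairs.append(MatchPair(repeat, pos, nt, cat))
        score += weights.weight(repeat, exp, cat)
    return MatchProfile(
        array_name=array.name, source=window.source,
        pairs=tuple(pairs), score=score,
    )


def score_profile(profile: MatchProfile,
                  weights: ScoringWeights = DEFAULT_WEIGHTS) -> float:
    """Recompute the weighted sum over a profile's pairs."""
    total = 0.0
    for p in profile.pairs:
        exp = expected_nucleotides(p.repeat.res5, p.repeat.resL)
        total += weights.weight(p.repeat, exp, p.category)
    return total


def max_attainable_score(array: PPRArray,
                         weights: ScoringWeights = DEFAULT_WEIGHTS) -> float:
    """Score of a hypothetical all-MATCH window for this array."""
    return sum(weights.max_repeat_weight(r) for r in array)


def count_perfect_PS_matches(profile: MatchProfile) -> tuple[int, int]:
    """(perfect matches, coded repeats) over numbered P- and S-type repeats.

    The denominator counts P/S repeats whose residue pair carries a
    non-empty code expectation; the triplet and L repeats are excluded.
    """
    n_match = 0
    n_coded = 0
    for p in profile.pairs:
        if p.repeat.is_triplet or p.repeat.ptype not in ("P", "S"):
            continue
        exp = expected_nucleotides(p.repeat.res5, p.repeat.resL)
        if exp.empty:
            continue
        n_coded += 1
        if p.category is MatchCategory.MATCH:
            n_match += 1
    return n_match, n_coded


def profile_to_rows(profile: MatchProfile,
                    weights: ScoringWeights = DEFAULT_WEIGHTS) -> list[dict]:
    """Tabular form of a profile (repeat, position, nt, category, weight)."""
    rows = []
    for p in profile.pairs:
        exp = expected_nucleotides(p.repeat.res5, p.repeat.resL)
        rows.append({
            "repeat": p.repeat.label,
            "position": p.position,
            "nt": p.nt,
            "category": p.category.value,
            "weight": weights.weight(p.repeat, exp, p.category),
        })
    return rows
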