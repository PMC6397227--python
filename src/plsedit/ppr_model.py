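"""PLS-type PPR arrays and the amino-acid → nucleotide recognition code.

PLS-type pentatricopeptide-repeat (PPR) editing factors bind RNA one
nucleotide per repeat.  Repeats come in three flavours — canonical P
(35 aa), long L (35–36 aa) and short S (31–32 aa) — and the array ends in a
divergent C-terminal P2-L2-S2 triplet.  The two residues at repeat
positions 5 and L (the last position) jointly specify the preferred target
nucleotide:

    =====  =====  ==================
    res 5  res L  expected nucleotide
    =====  =====  ==================
    T or S   N     A
    T or S   D     G
      N      N     C or U (unranked)
      N      S     C > U
      N      D     U > C
    =====  =====  ==================

Any other residue pair carries no expectation and is neutral in scoring.

Repeats are numbered backwards: S-1 is the last numbered repeat before the
triplet and sits opposite target nucleotide −4 (the edited cytidine is
position 0), so numbered repeat k binds position −(k+3) and the triplet
P2/L2/S2 binds −3/−2/−1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
TRIPLET_LABELS = ("P2", "L2", "S2")
REPEAT_TYPES = ("P", "L", "S") + TRIPLET_LABELS


class ArraySpecError(ValueError):
    """Raised for malformed or inconsistent PPR array specifications."""


@dataclass(frozen=True)
class PPRRepeat:
    """One PPR repeat: type, backward index (or triplet label) and the
    two code-determining residues."""

    index: Union[int, str]  # 1, 2, ... or "P2"/"L2"/"S2"
    ptype: str              # P, L, S, P2, L2, S2
    res5: str               # one-letter residue at repeat position 5, or "-"
    resL: str               # one-letter residue at position L(last), or "-"

    def __post_init__(self) -> None:
        if self.ptype not in REPEAT_TYPES:
            raise ArraySpecError(f"unknown repeat type {self.ptype!r}")
        for res in (self.res5, self.resL):
            if res != GAP and res not in AA_LETTERS:
                raise ArraySpecError(f"invalid residue {res!r}")
        if self.ptype in TRIPLET_LABELS:
            if self.index != self.ptype:
                raise ArraySpecError(
                    f"triplet repeat {self.ptype} must use its label as index"
                )
        else:
            if not isinstance(self.index, int) or self.index < 1:
                raise ArraySpecError(
                    f"numbered repeat index must be a positive integer, "
                    f"got {self.index!r}"
                )

    @property
    def is_triplet(self) -> bool:
        return self.ptype in TRIPLET_LABELS

    @property
    def label(self) -> str:
        """Display label, e.g. ``P-6TD`` or ``S2``."""
        if self.is_triplet:
            return self.ptype
        return f"{self.ptype}-{self.index}{self.res5}{self.resL}"


@dataclass(frozen=True)
class NucleotideExpectation:
    """Nucleotide(s) a repeat's residue pair selects for.

    ``primary`` is the preferred nucleotide; ``secondary`` the tolerated
    alternative of a ranked pyrimidine rule (C > U, U > C).  ``unranked``
    marks the N+N rule where C and U are equally acceptable.
    """

    primary: Optional[str] = None
    secondary: Optional[str] = None
    unranked: bool = False

    def __post_init__(self) -> None:
        if self.primary is None and self.secondary is not None:
            raise ValueError("secondary expectation without primary")
        if self.primary is not None and self.primary == self.secondary:
            raise ValueError("primary and secondary must differ")

    @property
    def empty(self) -> bool:
        return self.primary is None

    @property
    def is_purine(self) -> bool:
        return self.primary in ("A", "G")


NO_EXPECTATION = NucleotideExpectation()

# The five coded residue combinations.  Keys: (res5, resL).
_CODE_TABLE: dict[tuple[str, str], NucleotideExpectation] = {}
for _r5 in ("T", "S"):
    _CODE_TABLE[(_r5, "N")] = NucleotideExpectation("A")
    _CODE_TABLE[(_r5, "D")] = NucleotideExpectation("G")
_CODE_TABLE[("N", "N")] = NucleotideExpectation("C", "U", unranked=True)
_CODE_TABLE[("N", "S")] = NucleotideExpectation("C", "U")
_CODE_TABLE[("N", "D")] = NucleotideExpectation("U", "C")


def expected_nucleotides(res5: str, resL: str) -> NucleotideExpectation:
    """Map a (position-5, position-L) residue pair to its target-nucleotide
    expectation.  Pairs outside the five-rule code table — including gap
    markers — yield the empty expectation."""
    return _CODE_TABLE.get((res5, resL), NO_EXPECTATION)


def repeat_position(repeat: PPRRepeat) -> int:
    """Target position a repeat is juxtaposed with (editing site = 0).

    Numbered repeat k → −(k+3); triplet P2 → −3, L2 → −2, S2 → −1.
    """
    if repeat.is_triplet:
        return {"P2": -3, "L2": -2, "S2": -1}[repeat.ptype]
    return -(repeat.index + 3)


@dataclass(frozen=True)
class PPRArray:
    """An ordered PLS-type PPR array, N- to C-terminus.

    Numbered repeats must descend consecutively to S-1 (or the innermost
    numbered repeat present) and any P2/L2/S2 triplet repeats must close the
    array in that order.
    """

    name: str
    repeats: tuple[PPRRepeat, ...]

    def __post_init__(self) -> None:
        if not self.repeats:
            raise ArraySpecError("no repeats")
        numbered = [r for r in self.repeats if not r.is_triplet]
        triplet = [r for r in self.repeats if r.is_triplet]
        if not numbered:
            raise ArraySpecError("array has no numbered repeats")
        # triplet strictly C-terminal, in P2 L2 S2 order, at most one each
        n_num = len(numbered)
        if any(not r.is_triplet for r in self.repeats[n_num:]):
            raise ArraySpecError("triplet must be C-terminal")
        labels = [r.ptype for r in triplet]
        if len(set(labels)) != len(labels):
            raise ArraySpecError("duplicate triplet repeat")
        order = [t for t in TRIPLET_LABELS if t in labels]
        if labels != order:
            raise ArraySpecError("triplet out of order (expected P2, L2, S2)")
        # backward numbering: N-terminal repeat carries the highest index,
        # descending by 1 down to the repeat adjacent to the triplet
        indices = [r.index for r in numbered]
        if len(set(indices)) != len(indices):
            raise ArraySpecError(f"duplicate index in {indices}")
        expected = list(range(indices[0], indices[0] - n_num, -1))
        if indices != expected:
            raise ArraySpecError(
                f"backward numbering not consecutive: {indices}"
            )
        if triplet and indices[-1] != 1:
            raise ArraySpecError(
                "repeat adjacent to the terminal triplet must be number 1"
            )

    def __iter__(self):
        return iter(self.repeats)

    def __len__(self) -> int:
        return len(self.repeats)

    @property
    def numbered_repeats(self) -> tuple[PPRRepeat, ...]:
        return tuple(r for r in self.repeats if not r.is_triplet)

    def positions(self) -> dict[PPRRepeat, int]:
        """Repeat → target-position register for the whole array."""
        return {r: repeat_position(r) for r in self.repeats}

    @property
    def span(self) -> tuple[int, int]:
        """(most upstream, most downstream) target position bound."""
        pos = [repeat_position(r) for r in self.repeats]
        return min(pos), max(pos)


def _parse_record(ptype: str, index: str, res5: str, resL: str) -> PPRRepeat:
    ptype = ptype.strip().upper()
    index = index.strip().upper()
    res5 = res5.strip().upper() or GAP
    resL = resL.strip().upper() or GAP
    if ptype not in REPEAT_TYPES:
        raise ArraySpecError(f"unknown repeat type {ptype!r}")
    if ptype in TRIPLET_LABELS or index in TRIPLET_LABELS:
        if ptype in ("P", "L", "S"):
            ptype = index  # rows like "P2,P2,..." or "P,P2,..."
        if index != ptype:
            raise ArraySpecError(
                f"triplet row index {index!r} disagrees with type {ptype!r}"
            )
        return PPRRepeat(index=ptype, ptype=ptype, res5=res5, resL=resL)
    try:
        idx = int(index)
    except ValueError as exc:
        raise ArraySpecError(f"bad repeat index {index!r}") from exc
    return PPRRepeat(index=idx, ptype=ptype, res5=res5, resL=resL)


def parse_array_spec(text: str, name: str = "array") -> PPRArray:
    """Parse a PPR array specification into a validated :class:`PPRArray`.

    Two equivalent forms are accepted:

    * a headered TSV/CSV with columns ``type, index, res5, resL`` (triplet
      rows use index values P2/L2/S2), one repeat per row, N→C;
    * a one-line compact string of semicolon-separated repeat labels,
      e.g. ``"P-3TD;L-2SP;S-1ND;P2--;L2--;S2--"``.
    """
    text = text.strip()
    if not text:
        raise ArraySpecError("no repeats")
    if "\n" not in text and ";" in text:
        repeats = [_parse_label(tok) for tok in text.split(";") if tok.strip()]
    else:
        repeats = _parse_table(text)
    if not repeats:
        raise ArraySpecError("no repeats")
    return PPRArray(name=name, repeats=tuple(repeats))


def _parse_table(text: str) -> list[PPRRepeat]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ArraySpecError("no repeats")
    sep = "\t" if "\t" in lines[0] else ","
    header = [c.strip().lower() for c in lines[0].split(sep)]
    body = lines
    if "type" in header:
        cols = {c: i for i, c in enumerate(header)}
        body = lines[1:]
    else:
        cols = {"type": 0, "index": 1, "res5": 2, "resl": 3}
    repeats = []
    for ln in body:
        fields = [f.strip() for f in ln.split(sep)]
        if len(fields) < 4:
            raise ArraySpecError(f"record needs 4 fields: {ln!r}")
        repeats.append(
            _parse_record(
                fields[cols["type"]], fields[cols["index"]],
                fields[cols["res5"]], fields[cols["resl"]],
            )
        )
    return repeats


def _parse_label(token: str) -> PPRRepeat:
    """Parse a compact repeat label like ``S-7ND``, ``P2--`` or ``S2``."""
    tok = token.strip().upper()
    for t in TRIPLET_LABELS:
        if tok.startswith(t):
            rest = tok[len(t):] or GAP * 2
            res5 = rest[0] if len(rest) >= 1 else GAP
            resL = rest[1] if len(rest) >= 2 else GAP
            return PPRRepeat(index=t, ptype=t, res5=res5, resL=resL)
    if "-" not in tok:
        raise ArraySpecError(f"cannot parse repeat label {token!r}")
    ptype, rest = tok.split("-", 1)
    digits = ""
    for ch in rest:
        if ch.isdigit():
            digits += ch
        else:
            break
    if not digits:
        raise ArraySpecError(f"cannot parse repeat label {token!r}")
    resid = rest[len(digits):] or GAP * 2
    res5 = resid[0] if len(resid) >= 1 else GAP
    resL = resid[1] if len(resid) >= 2 else GAP
    return _parse_record(ptype, digits, res5, resL)


def array_to_tsv(array: PPRArray) -> str:
    """Serialise an array back to the headered TSV form."""
    out = ["type\tindex\tres5\tresL"]
    for r in array:
        out.append(f"{r.ptype}\t{r.index}\t{r.res5}\t{r.resL}")
    return "\n".join(out) + "\n"
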