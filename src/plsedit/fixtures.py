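"""Synthetic PPR65 / ccmFC worked-example fixtures.

These fixtures emulate the moss editing factor PPR65 and its target
ccmFCeU103PS for tests and worked examples.  They are *synthetic
reconstructions*: the repeat residue table and the −33..+5 target window
are not copied from any deposited dataset but constructed to satisfy the
documented properties of the system —

* 15 numbered PLS repeats (P-15 .. S-1) plus the terminal P2-L2-S2 triplet;
* repeat identities S-13NN, L-8AE, S-7ND, P-6TD, L-5TD, S-4SN, P-3TD;
* native target nucleotides G(−16), A(−13), A(−12), G(−11), U(−10), A(−9),
  G(−8), A(−7), G(−6), U(−2), U(−1) and the edited C at 0 opening a CCA
  (proline) codon;
* six of the eight coded P/S repeats perfectly matching the code, with the
  native A(−9) a purine transition opposite P-6TD and G(−16) a mismatch
  opposite S-13NN, and L-5TD matching the G at −8;
* seven off-target windows that all carry a G at −9 and of which six are
  identical to the native target at positions −1..−3.

Residues and nucleotides not pinned down by those constraints were chosen
once, arbitrarily, and are not meaningful.
"""

from __future__ import annotations

from .ppr_model import PPRArray, parse_array_spec
from .target_matching import TargetWindow

#: Repeat table, N→C.  Repeats without a coded res5/resL combination carry
#: filler residues outside the five-rule code table (no expectation).
PPR65_ARRAY_TSV = """\
type	index	res5	resL
P	15	V	T
L	14	I	N
S	13	N	N
P	12	A	D
L	11	C	S
S	10	T	N
P	9	T	N
L	8	A	E
S	7	N	D
P	6	T	D
L	5	T	D
S	4	S	N
P	3	T	D
L	2	S	P
S	1	N	D
P2	P2	F	S
L2	L2	L	D
S2	S2	P	N
"""

#: Native ccmFC-like window, positions −33..+5; index 33 is the edited C.
PPR65_NATIVE_WINDOW = (
    "GAUUCGAAUGCUAAG"      # −33..−19 (unconstrained filler)
    "UAGCUAAGUAGAGAUAUU"   # −18..−1
    "C"                    # 0, edited cytidine (CCA → UCA, P→S)
    "CAGAU"                # +1..+5
)

# Seven synthetic off-target windows, expressed as substitutions applied to
# the native window.  All carry the G at −9 preferred by P-6TD; ot7 breaks
# the −1..−3 identity with the native target (6 of 7 identical there).
_OFFTARGET_MUTATIONS: dict[str, dict[int, str]] = {
    "ot1": {-9: "G", -16: "C", -22: "A", -30: "G"},
    "ot2": {-9: "G", -14: "A", -19: "C", -28: "U"},
    "ot3": {-9: "G", -10: "C", -21: "G", -33: "A"},
    "ot4": {-9: "G", -13: "G", -24: "C"},
    "ot5": {-9: "G", -7: "G", -18: "C", -26: "A"},
    "ot6": {-9: "G", -6: "A", -11: "C", -31: "U"},
    "ot7": {-9: "G", -2: "C", -12: "G", -27: "G"},
}

#: Per-off-target mean editing level and read coverage (synthetic values;
#: one site above 10%, the rest below, sorted decreasing).
PPR65_OFFTARGET_STATS: dict[str, tuple[float, int]] = {
    "ot1": (0.163, 1482),
    "ot2": (0.098, 903),
    "ot3": (0.074, 655),
    "ot4": (0.052, 1210),
    "ot5": (0.031, 489),
    "ot6": (0.024, 770),
    "ot7": (0.016, 512),
}


def ppr65_array() -> PPRArray:
    """The synthetic PPR65 array (15 PLS repeats + P2L2S2)."""
    return parse_array_spec(PPR65_ARRAY_TSV, name="PPR65")


def ppr65_native_window() -> TargetWindow:
    """The synthetic native ccmFCeU103PS target window (−33..+5)."""
    return TargetWindow(PPR65_NATIVE_WINDOW, W=33, D=5, source="ccmFCeU103PS")


def ppr65_offtarget_windows() -> list[TargetWindow]:
    """The seven synthetic PPR65 off-target windows, sorted by decreasing
    editing level."""
    native = PPR65_NATIVE_WINDOW
    out = []
    for name, muts in _OFFTARGET_MUTATIONS.items():
        seq = list(native)
        for pos, nt in muts.items():
            seq[pos + 33] = nt
        out.append(TargetWindow("".join(seq), W=33, D=5, source=name))
    return out
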