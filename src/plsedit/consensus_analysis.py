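"""Per-position consensus over aligned editing-site windows.

Off-target windows aligned on the edited cytidine are summarised as a
position-frequency matrix.  Conservation at each position is shaded by the
fraction of sequences carrying the majority nucleotide: black for ≥90%,
light green for ≥60%, yellow for ≥30%, unshaded below.  N observations
are excluded from denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .editing_caller import EditingCall
from .target_matching import TargetWindow

NUCS = ("A", "C", "G", "U")

SHADE_THRESHOLDS = (("black", 0.9), ("light_green", 0.6), ("yellow", 0.3))


def shade(fraction: float) -> str:
    """Conservation shading category for a majority fraction (thresholds
    inclusive: exactly 0.9 is black)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    for name, threshold in SHADE_THRESHOLDS:
        if fraction >= threshold:
            return name
    return "none"


@dataclass(frozen=True)
class ConsensusMatrix:
    """Counts, fractions and shading per window position −W..+D."""

    W: int
    D: int
    n: int
    counts: pd.DataFrame      # index: position; columns: A C G U
    fractions: pd.DataFrame   # same shape; rows sum to 1 over non-N obs

    @property
    def positions(self) -> list[int]:
        return list(self.counts.index)

    def majority(self, position: int) -> tuple[str, float]:
        """(majority nucleotide, its fraction); alphabetic tie-break."""
        row = self.fractions.loc[position]
        # argmax over alphabetical order keeps the first maximum: ties
        # break alphabetically for display, fractions are unaffected
        best = NUCS[int(np.argmax([row[nt] for nt in NUCS]))]
        return best, float(row[best])

    def shading(self) -> pd.Series:
        """Per-position shading category of the majority nucleotide."""
        return pd.Series(
            {p: shade(self.majority(p)[1]) for p in self.positions},
            name="shade",
        )

    def fraction(self, position: int, nt: str) -> float:
        return float(self.fractions.loc[position, nt])

    def to_pfm_tsv(self) -> str:
        """Position-frequency matrix as TSV (rows A/C/G/U, columns by
        position), consumable by standard sequence-logo tools."""
        mat = self.fractions[list(NUCS)].T
        mat.index.name = "nt"
        return mat.to_csv(sep="\t", float_format="%.6f")


def frequency_matrix(windows: Sequence[TargetWindow]) -> ConsensusMatrix:
    """Per-position nucleotide counts/fractions over same-shape windows."""
    if not windows:
        raise ValueError("need at least one window")
    W, D = windows[0].W, windows[0].D
    for w in windows:
        if (w.W, w.D) != (W, D):
            raise ValueError(
                f"inconsistent window widths: ({w.W},{w.D}) vs ({W},{D})"
            )
    positions = list(range(-W, D + 1))
    counts = pd.DataFrame(0, index=positions, columns=list(NUCS))
    for w in windows:
        for pos in positions:
            nt = w.at(pos)
            if nt != "N":
                counts.loc[pos, nt] += 1
    denom = counts.sum(axis=1)
    fractions = counts.div(denom.replace(0, np.nan), axis=0).fillna(0.0)
    return ConsensusMatrix(W=W, D=D, n=len(windows),
                           counts=counts, fractions=fractions)


def identity_count(windows: Sequence[TargetWindow],
                   positions: Sequence[int],
                   reference: TargetWindow) -> int:
    """Number of windows identical to the reference at all given positions
    (vacuously all of them for an empty position set)."""
    return sum(
        1 for w in windows
        if all(w.at(p) == reference.at(p) for p in positions)
    )


def consensus_report(calls: Sequence[EditingCall],
                     windows: Sequence[TargetWindow],
                     cap: Optional[int] = None,
                     ) -> tuple[pd.DataFrame, ConsensusMatrix]:
    """Off-target report: one row per call sorted by decreasing mean
    editing level, plus the consensus matrix over the (shift-aligned)
    windows.  ``cap`` keeps only the top hits.

    Windows are expected in the same order as ``calls`` and should already
    incorporate any +1/−1 register shift so the matrix aligns repeats, not
    raw coordinates.
    """
    if len(calls) != len(windows):
        raise ValueError("need exactly one window per call")
    order = sorted(range(len(calls)),
                   key=lambda i: (-calls[i].mean_level,
                                  calls[i].seq_id, calls[i].pos))
    if cap is not None:
        order = order[:cap]
    rows = []
    kept_windows = []
    for i in order:
        c, w = calls[i], windows[i]
        rows.append({
            "genome_pos": f"{c.seq_id}:{c.pos + 1}",
            "label": (c.label or "") + ("as" if c.antisense
                                        and not (c.label or "").endswith("as")
                                        else ""),
            "ed_pct": round(100.0 * c.mean_level, 1),
            "coverage": c.coverage,
            "window": w.sequence,
        })
        kept_windows.append(w)
    report = pd.DataFrame(
        rows, columns=["genome_pos", "label", "ed_pct", "coverage", "window"]
    )
    return report, frequency_matrix(kept_windows)


def render_shading(matrix: ConsensusMatrix) -> str:
    """Character-cell rendering of the consensus: majority nucleotide per
    position with a shading glyph (# black, + light green, . yellow,
    space none)."""
    glyph = {"black": "#", "light_green": "+", "yellow": ".", "none": " "}
    nts, marks = [], []
    for p in matrix.positions:
        nt, frac = matrix.majority(p)
        nts.append(nt if matrix.counts.loc[p].sum() else "N")
        marks.append(glyph[shade(frac)])
    return "".join(nts) + "\n" + "".join(marks)
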