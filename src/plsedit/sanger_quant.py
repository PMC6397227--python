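"""Editing-efficiency quantification from Sanger chromatogram peaks.

At an editing site the chromatogram of an RT-PCR product shows overlapping
T and C peaks; editing is quantified as T / (T + C) over the peak heights.
Replicate measurements (independent clones) are summarised as mean ±
sample standard deviation; quantified sites conventionally rest on at
least three biological replicates.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakPair:
    """T and C peak heights at one editing site in one trace."""

    T_height: float
    C_height: float
    site: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.T_height < 0 or self.C_height < 0:
            raise ValueError("peak heights must be non-negative")


def peak_editing_fraction(p: PeakPair) -> float:
    """T / (T + C): the edited fraction implied by the two peak heights.

    Scale-invariant — only the ratio of the heights matters.
    """
    total = p.T_height + p.C_height
    if total == 0:
        raise ValueError(
            f"site {p.site or '?'} has no T or C signal; not quantifiable"
        )
    return p.T_height / total


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sample s.d., n) over replicate editing fractions.

    n = 1 yields s.d. 0.0 with a warning; fewer than three replicates is
    flagged as below the conventional minimum for quantified sites.
    """
    if not values:
        raise ValueError("no replicate values to aggregate")
    n = len(values)
    if n < 3:
        logger.warning("only %d replicate(s); quantified sites "
                       "conventionally need ≥3", n)
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if n > 1 else 0.0
    return mean, sd, n


def read_peaks(path: Union[str, Path]) -> list[PeakPair]:
    """Load a peaks TSV (columns site, replicate, T_height, C_height)."""
    df = pd.read_csv(path, sep="\t")
    required = {"site", "replicate", "T_height", "C_height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peaks table missing columns {sorted(missing)}")
    return [
        PeakPair(T_height=float(r.T_height), C_height=float(r.C_height),
                 site=str(r.site), replicate=str(r.replicate))
        for r in df.itertuples()
    ]


def quantify_table(peaks: Sequence[PeakPair]) -> pd.DataFrame:
    """Per-site summary table (site, n, mean, sd) over peak pairs."""
    per_site: dict[str, list[float]] = {}
    for p in peaks:
        per_site.setdefault(p.site, []).append(peak_editing_fraction(p))
    rows = []
    for site in sorted(per_site):
        mean, sd, n = aggregate_replicates(per_site[site])
        rows.append({"site": site, "n": n,
                     "mean": round(mean, 4), "sd": round(sd, 4)})
    return pd.DataFrame(rows, columns=["site", "n", "mean", "sd"])
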