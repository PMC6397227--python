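"""C-to-U editing-site calling from per-site base-count tables.

The caller compares RNA read counts against DNA read counts at each site
and emits a call only when a strict filter cascade passes:

1. read coverage at least ``min_cov`` in every RNA replicate and in DNA;
2. purity — the DNA background is clean (C, or G for antisense calls,
   strictly above 98% of reads) and the RNA reads are consistent with pure
   C/U mixtures (U+C, or G+A antisense, strictly above 98%);
3. replicate concordance — the edited base is detected (count ≥
   ``min_alt``) in *every* RNA replicate;
4. control exclusion — control RNA samples (untransformed host, or a
   strain carrying a different factor) show at most ``max_alt`` edited
   reads at the site.

The editing level at a site is the fraction of altered RNA reads minus
the same fraction in DNA (nearly always zero); it is a difference, so
slightly negative values are possible and are reported unclipped.

Input is a long-format count table (TSV columns ``seq_id, pos, sample,
replicate, role, nA, nC, nG, nT`` with role one of RNA/DNA/CONTROL), a
text stand-in for pileups over mapped reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

NUCS = ("A", "C", "G", "U")

#: reference / altered base per orientation: sense calls are C→U on the
#: forward pileup, antisense calls appear as G→A
ORIENTATIONS = {
    "sense": {"ref": "C", "alt": "U", "pure_rna": ("U", "C"),
              "strand": "+"},
    "antisense": {"ref": "G", "alt": "A", "pure_rna": ("G", "A"),
                  "strand": "-"},
}


@dataclass(frozen=True)
class SiteCounts:
    """Raw base counts for one site in one sample/replicate."""

    seq_id: str
    pos: int
    counts: Mapping[str, int]      # keys A, C, G, U
    sample: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        for nt in NUCS:
            c = self.counts.get(nt, 0)
            if c < 0 or c != int(c):
                raise ValueError(f"count for {nt} must be a non-negative "
                                 f"integer, got {c!r}")

    @property
    def total(self) -> int:
        return sum(int(self.counts.get(nt, 0)) for nt in NUCS)

    def count(self, nt: str) -> int:
        nt = "U" if nt == "T" else nt
        return int(self.counts.get(nt, 0))

    def fraction(self, *nts: str) -> float:
        return sum(self.count(nt) for nt in nts) / self.total


def site_ratio(counts: SiteCounts, alt: str) -> float:
    """Fraction of reads carrying the altered base."""
    if counts.total == 0:
        raise ZeroDivisionError(
            f"no reads at {counts.seq_id}:{counts.pos} ({counts.sample})"
        )
    return counts.count(alt) / counts.total


def editing_level(rna: SiteCounts, dna: SiteCounts, alt: str) -> float:
    """RNA alt-ratio minus DNA alt-ratio; may be slightly negative."""
    return site_ratio(rna, alt) - site_ratio(dna, alt)


def passes_purity(rna: SiteCounts, dna: SiteCounts,
                  orientation: str = "sense",
                  threshold: float = 0.98) -> bool:
    """Strict >98% purity of the DNA background and of the RNA C/U (or
    G/A) composition."""
    spec = ORIENTATIONS[orientation]
    if dna.total == 0 or rna.total == 0:
        return False
    return (dna.fraction(spec["ref"]) > threshold
            and rna.fraction(*spec["pure_rna"]) > threshold)


def replicate_concordant(replicates: Sequence[SiteCounts], alt: str,
                         min_alt: int = 1,
                         allow_single: bool = False) -> bool:
    """Edited base detected (≥ ``min_alt`` reads) in every RNA replicate."""
    if len(replicates) < 2 and not allow_single:
        raise ValueError(
            "replicate concordance needs ≥2 replicates "
            "(enable single-replicate mode explicitly to override)"
        )
    return all(r.count(alt) >= min_alt for r in replicates)


def control_clean(controls: Sequence[SiteCounts], alt: str,
                  max_alt: int = 0) -> bool:
    """No (or at most ``max_alt``) edited reads in any covered control."""
    if not controls:
        logger.warning("no control samples supplied; control filter is "
                       "vacuously true")
        return True
    return all(c.count(alt) <= max_alt
               for c in controls if c.total > 0)


@dataclass(frozen=True)
class CallerConfig:
    min_cov: int = 10          # minimum reads per RNA replicate and DNA
    purity: float = 0.98       # strict lower bound, per the filter cascade
    min_alt: int = 1           # "detected" in a replicate
    max_alt: int = 0           # "not present" in a control
    allow_single_replicate: bool = False


@dataclass(frozen=True)
class EditingCall:
    seq_id: str
    pos: int
    strand: str                       # '+' sense (C→U), '-' antisense (G→A)
    levels: tuple[float, ...]         # per RNA replicate
    mean_level: float
    coverage: int                     # total RNA reads over replicates
    antisense: bool
    label: Optional[str] = None


def _row_counts(row: pd.Series) -> SiteCounts:
    return SiteCounts(
        seq_id=row["seq_id"], pos=int(row["pos"]),
        counts={"A": int(row["nA"]), "C": int(row["nC"]),
                "G": int(row["nG"]), "U": int(row["nT"])},
        sample=str(row["sample"]), replicate=str(row["replicate"]),
    )


def read_count_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"seq_id", "pos", "sample", "replicate", "role",
                "nA", "nC", "nG", "nT"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    return df


def call_sites(counts: pd.DataFrame,
               config: CallerConfig = CallerConfig()) -> list[EditingCall]:
    """Run the full filter cascade over a count table.

    Returns calls sorted by mean editing level descending (ties by site).
    Raises if the table has no DNA rows — DNA subtraction is part of the
    editing-level definition, not an optional refinement.
    """
    roles = counts["role"].str.upper()
    if not (roles == "DNA").any():
        raise ValueError("count table contains no DNA sample; DNA "
                         "subtraction is required")
    calls: list[EditingCall] = []
    for (seq_id, pos), site_df in counts.groupby(["seq_id", "pos"],
                                                 sort=True):
        role = site_df["role"].str.upper()
        rna = [_row_counts(r) for _, r in site_df[role == "RNA"].iterrows()]
        dna_rows = site_df[role == "DNA"]
        ctrl = [_row_counts(r)
                for _, r in site_df[role == "CONTROL"].iterrows()]
        if dna_rows.empty or not rna:
            continue
        dna = _row_counts(dna_rows.iloc[0])
        for orientation, spec in ORIENTATIONS.items():
            call = _call_one(seq_id, int(pos), rna, dna, ctrl,
                             orientation, config)
            if call is not None:
                calls.append(call)
    calls.sort(key=lambda c: (-c.mean_level, c.seq_id, c.pos, c.strand))
    return calls


def _call_one(seq_id: str, pos: int, rna: list[SiteCounts],
              dna: SiteCounts, controls: list[SiteCounts],
              orientation: str, config: CallerConfig,
              ) -> Optional[EditingCall]:
    spec = ORIENTATIONS[orientation]
    alt = spec["alt"]
    # 1. coverage
    if dna.total < config.min_cov or any(r.total < config.min_cov
                                         for r in rna):
        return None
    # 2. purity on every replicate and the DNA sample
    if not all(passes_purity(r, dna, orientation, config.purity)
               for r in rna):
        return None
    # 3. concordant detection across replicates
    if not replicate_concordant(rna, alt, config.min_alt,
                                config.allow_single_replicate):
        return None
    # 4. clean controls
    if not control_clean(controls, alt, config.max_alt):
        return None
    levels = tuple(editing_level(r, dna, alt) for r in rna)
    return EditingCall(
        seq_id=seq_id, pos=pos, strand=spec["strand"],
        levels=levels, mean_level=sum(levels) / len(levels),
        coverage=sum(r.total for r in rna),
        antisense=(orientation == "antisense"),
    )


def calls_to_frame(calls: Sequence[EditingCall]) -> pd.DataFrame:
    """Calls as a report table (position, label, mean Ed%, coverage,
    per-replicate levels, antisense flag)."""
    rows = []
    for c in calls:
        rows.append({
            "seq_id": c.seq_id,
            "pos": c.pos,
            "strand": c.strand,
            "label": c.label or "",
            "ed_pct": round(100.0 * c.mean_level, 2),
            "coverage": c.coverage,
            "levels": ";".join(f"{x:.4f}" for x in c.levels),
            "antisense": c.antisense,
        })
    return pd.DataFrame(
        rows, columns=["seq_id", "pos", "strand", "label", "ed_pct",
                       "coverage", "levels", "antisense"],
    )
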