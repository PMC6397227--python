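"""Transcriptome-wide scan for editable cytidines and editing-site labels.

Every C on both strands of the input sequences is profiled against the
array register, scored, optionally checked against −3..−1 nucleotide
constraints, and ranked.  One-nucleotide register shifts (+1/−1) are
annotated where they improve the fit, mirroring how weakly matching
off-targets can be rescued by sliding the array by one position.

Editing sites are named ``<gene>eU<position><aa_change>`` — the target
gene, "eU" for the C-to-U conversion, the 1-based transcript position
counted from the A of the start codon (negative upstream of it, no zero),
and the amino-acid change for non-synonymous CDS edits (e.g.
``ccmFCeU103PS``: proline → serine at codon 35).  Sites antisense to the
annotated gene get the suffix ``as``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio import SeqIO

from .ppr_model import PPRArray
from .target_matching import (
    DEFAULT_WEIGHTS,
    MatchProfile,
    ScoringWeights,
    TargetWindow,
    extract_window,
    match_profile,
    max_attainable_score,
    to_rna,
)

logger = logging.getLogger(__name__)

Constraints = Mapping[int, frozenset | set | Sequence[str]]


@dataclass(frozen=True)
class CandidateSite:
    """One scored candidate editing cytidine."""

    seq_id: str
    coord: int            # 0-based, forward-strand coordinate of the site
    strand: str           # '+' or '-': strand carrying the C
    score: float          # unshifted profile score (re-validatable)
    profile: MatchProfile
    shift: int = 0        # −1/0/+1; non-zero only if it improves the score
    shifted_score: Optional[float] = None
    label: Optional[str] = None


def annotate_shift(
    array: PPRArray,
    window: TargetWindow,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
) -> tuple[int, float]:
    """Best register shift in {−1, 0, +1} and its score (ties prefer 0).

    A shift of −1 slides the array one nucleotide upstream (each repeat
    reads the position 5′ of its usual one); +1 slides downstream.
    """
    best_shift, best_score = 0, match_profile(array, window, weights).score
    for s in (1, -1):
        score = match_profile(array, window, weights, shift=s).score
        if score > best_score:
            best_shift, best_score = s, score
    return best_shift, best_score


def _passes_constraints(window: TargetWindow, constraints: Constraints) -> bool:
    return all(window.at(pos) in set(allowed)
               for pos, allowed in constraints.items())


def constraints_from_window(window: TargetWindow,
                            positions: Sequence[int] = (-3, -2, -1)) -> dict:
    """Constraint set requiring the given positions to equal a reference
    window's nucleotides (e.g. a native target's −3..−1 environment)."""
    return {p: frozenset({window.at(p)}) for p in positions}


def load_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA file into an id → sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def scan_transcriptome(
    sequences: Union[Mapping[str, str], str, Path],
    array: PPRArray,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    min_score: Optional[float] = None,
    constraints: Optional[Constraints] = None,
    W: int = 33,
    D: int = 5,
    annotate_shifts: bool = True,
) -> list[CandidateSite]:
    """Profile every C on both strands and return ranked candidates.

    ``min_score`` defaults to 60% of the array's maximum attainable score.
    Ranking is by unshifted score descending, ties broken by
    (seq id, coordinate, strand).  Window-extraction failures are logged
    and skipped.
    """
    if isinstance(sequences, (str, Path)):
        sequences = load_fasta(sequences)
    if not sequences:
        raise ValueError("no sequences to scan")
    if min_score is None:
        min_score = 0.6 * max_attainable_score(array, weights)
    hits: list[CandidateSite] = []
    for seq_id in sequences:
        seq = to_rna(sequences[seq_id])
        for strand in ("+", "-"):
            target_nt = "C" if strand == "+" else "G"
            for i, nt in enumerate(seq):
                if nt != target_nt:
                    continue
                try:
                    window = extract_window(
                        seq, i, W=W, D=D, strand=strand,
                        source=f"{seq_id}:{i}:{strand}",
                    )
                    profile = match_profile(array, window, weights)
                except (ValueError, IndexError) as exc:
                    logger.warning("skipping %s:%d:%s: %s",
                                   seq_id, i, strand, exc)
                    continue
                if constraints and not _passes_constraints(window, constraints):
                    continue
                if profile.score < min_score:
                    continue
                shift, shifted = 0, None
                if annotate_shifts:
                    shift, best = annotate_shift(array, window, weights)
                    shifted = best if shift != 0 else None
                hits.append(CandidateSite(
                    seq_id=seq_id, coord=i, strand=strand,
                    score=profile.score, profile=profile,
                    shift=shift, shifted_score=shifted,
                ))
    hits.sort(key=lambda h: (-h.score, h.seq_id, h.coord, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Editing-site nomenclature


@dataclass(frozen=True)
class GeneAnnotation:
    """Minimal gene model: a CDS span plus UTR allowances.

    ``cds_start`` is the 0-based coordinate of the A of the start codon in
    forward-strand coordinates; ``cds_end`` the exclusive forward-strand
    end.  For minus-strand genes ``cds_start > cds_end`` is not used:
    ``cds_start`` still marks the start-codon A (the highest CDS
    coordinate) and ``cds_end`` the exclusive coordinate past the stop on
    the forward strand (i.e. the lowest CDS coordinate).
    """

    name: str
    seq_id: str
    cds_start: int
    cds_end: int
    strand: str = "+"
    utr5: int = 300   # nt upstream of the start codon still "in transcript"
    utr3: int = 300   # nt downstream of the stop codon

    @property
    def cds_length(self) -> int:
        return abs(self.cds_end - self.cds_start)

    def transcript_offset(self, coord: int) -> int:
        """0-based offset of a coordinate from the start-codon A, in
        transcript orientation (negative upstream)."""
        if self.strand == "+":
            return coord - self.cds_start
        return self.cds_start - coord

    def contains(self, coord: int) -> bool:
        off = self.transcript_offset(coord)
        return -self.utr5 <= off < self.cds_length + self.utr3


@dataclass(frozen=True)
class EditLabel:
    gene: str
    position: int               # 1-based in transcript; negative upstream
    aa_change: str = ""         # e.g. "PS"; empty if synonymous or non-CDS
    antisense: bool = False
    synonymous: bool = False

    def __post_init__(self) -> None:
        if self.position == 0:
            raise ValueError("transcript position 0 does not exist")

    def __str__(self) -> str:
        return (f"{self.gene}eU{self.position}{self.aa_change}"
                f"{'as' if self.antisense else ''}")


_LABEL_RE = re.compile(
    r"^(?P<gene>.+?)eU(?P<pos>-?\d+)(?P<aa>[A-Z\*]{2})?(?P<as>as)?$"
)


def parse_edit_label(text: str) -> EditLabel:
    """Inverse of ``str(EditLabel)`` (the ``syn`` tag is not part of the
    label string and is lost in the round trip)."""
    m = _LABEL_RE.match(text)
    if not m:
        raise ValueError(f"unparseable edit label {text!r}")
    return EditLabel(
        gene=m.group("gene"),
        position=int(m.group("pos")),
        aa_change=m.group("aa") or "",
        antisense=m.group("as") is not None,
    )


def edit_label(
    gene: GeneAnnotation,
    sequence: str,
    site_coord: int,
    site_strand: str = "+",
    code_table: int = 11,
) -> EditLabel:
    """Build the nomenclature label for a C→U edit at a genomic coordinate.

    ``code_table`` is an NCBI genetic-code table id (default 11, the
    bacterial/plant-organellar code; it agrees with the standard code for
    the worked examples).
    """
    if not 0 <= site_coord < len(sequence):
        raise ValueError(f"site {site_coord} outside sequence")
    if not gene.contains(site_coord):
        raise ValueError(
            f"site {site_coord} not within the annotated transcript of "
            f"{gene.name}"
        )
    offset = gene.transcript_offset(site_coord)
    position = offset + 1 if offset >= 0 else offset
    antisense = site_strand != gene.strand

    aa_change = ""
    synonymous = False
    if not antisense and 0 <= offset < gene.cds_length:
        codon_i = offset // 3
        within = offset % 3
        if gene.strand == "+":
            start = gene.cds_start + 3 * codon_i
            codon = to_rna(sequence[start:start + 3])
        else:
            end = gene.cds_start - 3 * codon_i + 1
            codon = to_rna(
                str(Seq(sequence[end - 3:end]).reverse_complement())
            )
        if len(codon) == 3:
            if codon[within] != "C":
                raise ValueError(
                    f"reference base at CDS position {position} of "
                    f"{gene.name} is {codon[within]}, not C"
                )
            edited = codon[:within] + "U" + codon[within + 1:]
            table = CodonTable.unambiguous_rna_by_id[code_table]
            aa_before = _translate_codon(codon, table)
            aa_after = _translate_codon(edited, table)
            if aa_before == aa_after:
                synonymous = True
            else:
                aa_change = aa_before + aa_after
    return EditLabel(gene=gene.name, position=position, aa_change=aa_change,
                     antisense=antisense, synonymous=synonymous)


def _translate_codon(codon: str, table: CodonTable.CodonTable) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def sites_to_rows(sites: Sequence[CandidateSite],
                  windows: Optional[Sequence[TargetWindow]] = None) -> list[dict]:
    """Scanner output as TSV-ready rows."""
    rows = []
    for i, s in enumerate(sites):
        rows.append({
            "seq_id": s.seq_id,
            "coord": s.coord,
            "strand": s.strand,
            "score": s.score,
            "shift": s.shift,
            "label": s.label or "",
            "window": windows[i].sequence if windows else "",
        })
    return rows
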