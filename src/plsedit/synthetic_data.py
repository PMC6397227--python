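"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the experimental design of a bacterial editing
assay read out by sequencing: a background transcriptome with planted
target windows of controlled similarity to a given PPR array, per-site
base counts for RNA replicates / genomic DNA / control RNA under a
binomial editing + uniform sequencing-error model, and noisy chromatogram
peak pairs.  Everything is a pure function of its parameters and a single
integer seed.

Planted site kinds:

* ``edited`` — true C-to-U editing at a stated level; absent from DNA and
  control;
* ``dna_variant`` — a heterozygous-like C/T genomic variant (≈50% alt in
  DNA and RNA) that must be rejected by the DNA-purity filter;
* ``control_shared`` — apparent editing present at the same level in the
  control RNA, rejected by the control filter;
* ``clean`` — background only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .editing_caller import CallerConfig
from .ppr_model import PPRArray, expected_nucleotides
from .sanger_quant import PeakPair
from .target_matching import (
    MatchCategory,
    PURINES,
    PYRIMIDINES,
    TargetWindow,
    repeat_position,
)

RNA = ("A", "C", "G", "U")
DNA = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PlantedSite:
    seq_id: str
    pos: int          # 0-based coordinate of the C (forward strand)
    strand: str
    kind: str         # edited | dna_variant | control_shared | clean
    level: float = 0.0


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulation: planted sites and the parameters that
    produced them."""

    sites: tuple[PlantedSite, ...]
    seed: int
    params: dict = field(default_factory=dict)

    def of_kind(self, kind: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"seq_id": s.seq_id, "pos": s.pos, "strand": s.strand,
              "kind": s.kind, "level": s.level} for s in self.sites],
            columns=["seq_id", "pos", "strand", "kind", "level"],
        )


class InfeasibleSimilarity(ValueError):
    """Requested per-category match counts cannot be realised."""


def _random_nt(rng: np.random.Generator, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return str(rng.choice(np.array(RNA), p=p))


def _window_for_categories(
    array: PPRArray,
    similarity: Optional[Mapping[str, int]],
    rng: np.random.Generator,
    gc: float,
    W: int,
    D: int,
    fixed_positions: Optional[Mapping[int, str]] = None,
) -> str:
    """Build one RNA window whose profile has the requested category
    counts over the array's coded numbered repeats.

    ``similarity`` maps category names (MATCH, PYRIMIDINE_TRANSITION,
    PURINE_TRANSITION, MISMATCH) to counts; coded repeats not covered by a
    request are made MATCH.  None means all-MATCH.
    """
    coded = [r for r in array.numbered_repeats
             if not expected_nucleotides(r.res5, r.resL).empty]
    requested = dict(similarity or {})
    requested.setdefault("MATCH", 0)
    unknown = set(requested) - {c.value for c in MatchCategory}
    if unknown:
        raise InfeasibleSimilarity(f"unknown categories {sorted(unknown)}")
    total = sum(requested.values())
    if total > len(coded):
        raise InfeasibleSimilarity(
            f"requested {total} categorised repeats but the array has only "
            f"{len(coded)} coded numbered repeats"
        )
    requested["MATCH"] += len(coded) - total

    # assign non-MATCH categories to feasible repeats first
    assignment: dict = {}
    pool = list(coded)
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    for category in ("PURINE_TRANSITION", "PYRIMIDINE_TRANSITION",
                     "MISMATCH"):
        for _ in range(requested.get(category, 0)):
            feasible = [r for r in pool if _feasible(r, category)]
            if not feasible:
                raise InfeasibleSimilarity(
                    f"no remaining repeat can realise {category} "
                    f"(needs a {'purine' if category == 'PURINE_TRANSITION' else 'ranked-pyrimidine' if category == 'PYRIMIDINE_TRANSITION' else 'coded'} expectation)"
                )
            chosen = feasible[0]
            pool.remove(chosen)
            assignment[chosen] = category
    for r in pool:
        assignment[r] = "MATCH"

    seq = [_random_nt(rng, gc) for _ in range(W + 1 + D)]
    seq[W] = "C"
    for repeat, category in assignment.items():
        pos = repeat_position(repeat)
        exp = expected_nucleotides(repeat.res5, repeat.resL)
        seq[pos + W] = _nt_for_category(exp, category, rng)
    for pos, nt in (fixed_positions or {}).items():
        seq[pos + W] = nt
    return "".join(seq)


def _feasible(repeat, category: str) -> bool:
    exp = expected_nucleotides(repeat.res5, repeat.resL)
    if category == "PURINE_TRANSITION":
        return exp.is_purine
    if category == "PYRIMIDINE_TRANSITION":
        return exp.secondary is not None and not exp.unranked
    return True  # MISMATCH is realisable for every coded expectation


def _nt_for_category(exp, category: str, rng: np.random.Generator) -> str:
    if category == "MATCH":
        return exp.primary
    if category == "PURINE_TRANSITION":
        return "G" if exp.primary == "A" else "A"
    if category == "PYRIMIDINE_TRANSITION":
        return exp.secondary
    # MISMATCH: cross the purine/pyrimidine divide
    if exp.is_purine:
        return str(rng.choice(np.array(PYRIMIDINES)))
    return str(rng.choice(np.array(PURINES)))


def simulate_transcriptome(
    array: PPRArray,
    n_offtargets: int,
    similarity: Union[Mapping[str, int], Sequence[Mapping[str, int]],
                      None] = None,
    length: int = 10_000,
    gc: float = 0.5,
    seed: int = 0,
    levels: Optional[Sequence[float]] = None,
    n_dna_variants: int = 0,
    n_control_shared: int = 0,
    n_clean: int = 0,
    W: int = 33,
    D: int = 5,
    seq_id: str = "synth1",
    fixed_positions: Optional[Sequence[Optional[Mapping[int, str]]]] = None,
) -> tuple[dict[str, str], TruthTable]:
    """Random background sequence with planted, non-overlapping windows.

    Returns (id → DNA sequence dict, truth table).  ``similarity`` may be
    one mapping for all plants or one per plant; ``levels`` are the true
    editing levels of the edited plants (default: evenly spaced on
    [0.05, 1.0]).  Decoy sites carry only a planted C.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if levels is None:
        levels = list(np.linspace(0.05, 1.0, n_offtargets))
    if len(levels) != n_offtargets:
        raise ValueError("need one level per edited plant")
    if isinstance(similarity, Mapping) or similarity is None:
        similarity = [similarity] * n_offtargets
    if len(similarity) != n_offtargets:
        raise ValueError("need one similarity spec per edited plant")
    if fixed_positions is None:
        fixed_positions = [None] * n_offtargets

    n_total = n_offtargets + n_dna_variants + n_control_shared + n_clean
    slot = W + D + 2
    n_slots = (length - 2) // slot
    if n_slots < n_total:
        raise InfeasibleSimilarity(
            f"length {length} fits only {n_slots} windows, "
            f"{n_total} requested"
        )
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(np.array(DNA), size=length, p=p))
    slots = rng.permutation(n_slots)[:n_total]
    positions = sorted(int(s) * slot + 1 + W for s in slots)

    sites: list[PlantedSite] = []
    kinds = (["edited"] * n_offtargets
             + ["dna_variant"] * n_dna_variants
             + ["control_shared"] * n_control_shared
             + ["clean"] * n_clean)
    edited_i = 0
    for pos, kind in zip(positions, kinds):
        if kind == "edited":
            window = _window_for_categories(
                array, similarity[edited_i], rng, gc, W, D,
                fixed_positions[edited_i],
            )
            seq[pos - W:pos + D + 1] = list(window.replace("U", "T"))
            level = float(levels[edited_i])
            edited_i += 1
        else:
            seq[pos] = "C"
            level = 0.5 if kind in ("dna_variant", "control_shared") else 0.0
        sites.append(PlantedSite(seq_id=seq_id, pos=pos, strand="+",
                                 kind=kind, level=level))
    truth = TruthTable(
        sites=tuple(sites), seed=seed,
        params={"length": length, "gc": gc, "W": W, "D": D,
                "n_offtargets": n_offtargets},
    )
    return {seq_id: "".join(seq)}, truth


def _noisy_counts(rng: np.random.Generator, n: int,
                  composition: Mapping[str, float],
                  error: float) -> dict[str, int]:
    """Multinomial counts for a true base composition, each read then
    miscalled with probability ``error`` uniformly to the other bases."""
    bases = list(RNA)
    p = np.array([composition.get(b, 0.0) for b in bases], dtype=float)
    p = p / p.sum()
    true = rng.multinomial(n, p)
    out = dict.fromkeys(bases, 0)
    for b, k in zip(bases, true):
        if k == 0:
            continue
        n_err = rng.binomial(k, error)
        out[b] += int(k - n_err)
        if n_err:
            others = [x for x in bases if x != b]
            spread = rng.multinomial(n_err, [1 / 3] * 3)
            for o, e in zip(others, spread):
                out[o] += int(e)
    return out


def simulate_counts(
    truth: TruthTable,
    coverage: int = 200,
    error: float = 0.005,
    n_replicates: int = 2,
    seed: int = 0,
    sample: str = "ppr",
) -> pd.DataFrame:
    """Count table (long TSV layout) for every planted site.

    RNA U counts at edited sites follow Binomial(coverage, level); DNA is
    pure C; a uniform per-base miscall rate ``error`` is layered on every
    sample.  ``dna_variant`` sites carry the ≈50% alternative base in DNA
    (and hence RNA); ``control_shared`` sites show their level in the
    control RNA too.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error < 0.02:
        raise ValueError("error rate outside the sane range [0, 0.02)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC2]))
    rows = []

    def emit(site, smp, rep, role, comp):
        counts = _noisy_counts(rng, coverage, comp, error)
        rows.append({
            "seq_id": site.seq_id, "pos": site.pos, "sample": smp,
            "replicate": rep, "role": role,
            "nA": counts["A"], "nC": counts["C"],
            "nG": counts["G"], "nT": counts["U"],
        })

    pure_c = {"C": 1.0}
    for site in truth.sites:
        if site.kind == "edited":
            rna = {"U": site.level, "C": 1.0 - site.level}
            dna, ctrl = pure_c, pure_c
        elif site.kind == "dna_variant":
            rna = {"U": site.level, "C": 1.0 - site.level}
            dna = {"U": site.level, "C": 1.0 - site.level}
            ctrl = rna
        elif site.kind == "control_shared":
            rna = {"U": site.level, "C": 1.0 - site.level}
            dna, ctrl = pure_c, rna
        else:
            rna, dna, ctrl = pure_c, pure_c, pure_c
        for rep in range(1, n_replicates + 1):
            emit(site, sample, str(rep), "RNA", rna)
        emit(site, "dna", "1", "DNA", dna)
        emit(site, "control", "1", "CONTROL", ctrl)
    return pd.DataFrame(
        rows, columns=["seq_id", "pos", "sample", "replicate", "role",
                       "nA", "nC", "nG", "nT"],
    )


def simulate_chromatogram(
    level: float,
    noise: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
    height: float = 1000.0,
    site: str = "",
    replicate: str = "",
) -> PeakPair:
    """Noisy T/C peak pair for a site edited at ``level``.

    Heights are ``level·H·(1+ε)`` and ``(1−level)·H·(1+ε′)`` with
    independent multiplicative Gaussian noise terms (s.d. ``noise``,
    truncated so heights stay non-negative).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(np.random.SeedSequence([seed, 0x5A])))
    eps_t, eps_c = rng.normal(0.0, noise, size=2) if noise else (0.0, 0.0)
    t = level * height * max(0.0, 1.0 + eps_t)
    c = (1.0 - level) * height * max(0.0, 1.0 + eps_c)
    return PeakPair(T_height=t, C_height=c, site=site, replicate=replicate)


# ---------------------------------------------------------------------------
# Presets

#: Conditions of the planted-site recovery experiment: ten edited sites
#: spanning levels 0.05–1.0 at coverage 200 with two RNA replicates and a
#: 0.5% per-base error, plus three DNA-variant and two control-shared
#: decoys.  Detection thresholds are calibrated to the error model at 3
#: sigma: control U miscalls follow Binomial(200, error/3) (mean 0.33,
#: s.d. 0.58), so "absent from control" tolerates up to
#: ceil(mean + 3 s.d.) = 3 alt reads, and "detected" in a replicate means
#: ≥2 alt reads (the lowest planted level, 0.05, yields ~10).
RECOVERY_PRESET = {
    "n_offtargets": 10,
    "levels": tuple(np.linspace(0.05, 1.0, 10)),
    "coverage": 200,
    "n_replicates": 2,
    "error": 0.005,
    "n_dna_variants": 3,
    "n_control_shared": 2,
    "length": 6000,
    "seed": 17,
}


def recovery_preset(array: PPRArray, seed: Optional[int] = None):
    """Generate the full recovery experiment: (fasta, truth, counts,
    caller config)."""
    p = dict(RECOVERY_PRESET)
    if seed is not None:
        p["seed"] = seed
    fasta, truth = simulate_transcriptome(
        array,
        n_offtargets=p["n_offtargets"],
        levels=list(p["levels"]),
        length=p["length"],
        n_dna_variants=p["n_dna_variants"],
        n_control_shared=p["n_control_shared"],
        seed=p["seed"],
    )
    counts = simulate_counts(
        truth, coverage=p["coverage"], error=p["error"],
        n_replicates=p["n_replicates"], seed=p["seed"],
    )
    config = CallerConfig(min_cov=100, min_alt=2, max_alt=3)
    return fasta, truth, counts, config
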