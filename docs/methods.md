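# Methods

## Recognition model

PLS-type PPR editing factors are modelled as ordered repeat arrays
(P/L/S repeats plus an optional C-terminal P2-L2-S2 triplet) with a rigid
register: numbered repeat *k* (backward numbering, 1 adjacent to the
triplet) is juxtaposed with target position −(k+3), the triplet with
−3..−1, and the edited cytidine is position 0. The nucleotide preference
of a repeat is read off the residues at repeat positions 5 and L(last)
through the five-rule code (T/S+N → A, T/S+D → G, N+N → C/U unranked,
N+S → C>U, N+D → U>C). Every other residue pair — including gap markers
for unresolved repeats — carries no expectation and is neutral
throughout; only the seven coded residue-letter pairs score.

Each repeat–nucleotide pair is classified as MATCH, pyrimidine
transition (the tolerated other pyrimidine of a ranked C>U / U>C rule),
purine transition (A↔G against a purine expectation), mismatch, or
no-expectation (uncoded repeat or N in the window).

## Match score

The score is a weighted sum over pairs. Defaults:

| repeat class | category | weight |
|---|---|---|
| P/S | MATCH (purine expectation) | +2.0 |
| P/S | MATCH (pyrimidine expectation) | +1.0 |
| L | MATCH | +0.5 (`promote_l` lifts to P/S weight) |
| any numbered | pyrimidine transition | +0.5 |
| any numbered | purine transition | −1.0 |
| any numbered | mismatch | −1.0 |
| P2/L2/S2 | any | 0 |

Rationale: in the mutational data the model summarises, purine-position
changes abolish editing while several pyrimidine changes only reduce it,
so purine matches carry double weight and purine transitions a penalty;
L-type repeats demonstrably contribute (L-5TD in PPR65) but less
reliably, hence half weight by default. The triplet's −3..−1 environment
shows strong conservation but no residue code, so it is excluded from
the linear score and handled as an explicit nucleotide-constraint filter
in the scanner. The linear model cannot represent the observed
phenomenon that *improving* a match can reduce editing; no attempt is
made to capture such cooperative effects.

## Scanner

Every C on both strands is profiled (windows −W..+D, default W=33, D=5,
N-padded at sequence ends; minus-strand windows are reported 5′→3′ on
the edited strand). Sites below `min_score` — default 60% of the array's
maximum attainable score, a pragmatic cut to keep candidate lists short
— or failing the optional −3..−1 constraints are dropped; survivors are
ranked by unshifted score with deterministic tie-breaking (sequence id,
coordinate, strand). Register shifts of ±1 are evaluated per site and
annotated when they beat the unshifted score (ties prefer 0); the stored
score remains the unshifted one so every hit re-validates by
re-profiling its window.

## Editing caller

Input is a long-format per-site base-count table (RNA replicates, one
DNA sample, any number of control RNAs) — a text stand-in for pileups.
The cascade, in order: coverage ≥ `min_cov` (default 10) in every RNA
replicate and in DNA; purity, strict — DNA C (sense) or G (antisense)
> 98% and RNA U+C (or G+A) > 98%; detection of the edited base in
*every* replicate (`min_alt`, default 1 — the conventional "detected in
both replicates" has no published numeric threshold, so the floor is
configurable); and control exclusion (`max_alt`, default 0). The editing
level is `alt/total(RNA) − alt/total(DNA)`, reported per replicate and
as the mean, unclipped (slightly negative values are legitimate for a
difference). Calls are sorted by mean level descending. A missing DNA
sample is an error, not a warning: the subtraction is part of the
definition. Mapping, per-read filters of external variant callers, and
indels are out of scope; the purity thresholds take their place.

## Consensus

Windows aligned on the edited C (post shift-annotation, so a +1/−1 site
contributes its shifted window) are tallied into a position-frequency
matrix; N observations are excluded from denominators. Conservation
shading of the per-position majority nucleotide uses inclusive
thresholds — ≥90% black, ≥60% light green, ≥30% yellow — read as "in at
least that share of sequences"; majority ties break alphabetically for
display only. The matrix exports as a plain PFM TSV for logo tools.

## Sanger quantification

Editing at a site is T/(T+C) over chromatogram peak heights
(scale-invariant). Replicates aggregate to mean ± sample (n−1) standard
deviation — sample rather than population s.d. because replicates are
few; fewer than three replicates triggers a warning, matching the usual
reporting convention for quantified sites.

## Synthetic data

The generators emulate the bacterial editing assay: a uniform-composition
(optionally GC-biased) background sequence with non-overlapping planted
windows whose profiles realise requested per-category counts over the
coded repeats; per-site counts with binomial editing
(U ~ Binomial(coverage, level)) and a uniform per-base miscall rate
applied to RNA, DNA and control alike; and chromatogram peak pairs with
multiplicative Gaussian noise. All generators are pure functions of
their parameters and one integer seed.

The recovery preset fixes the conditions used in the end-to-end test:
ten edited sites at levels evenly spaced over 0.05–1.0, coverage 200,
two RNA replicates, error 0.005, three DNA-variant decoys (≈50% alt in
DNA) and two control-shared decoys, seed 17. Its caller configuration is
calibrated to that error model at three sigma: control U miscalls follow
Binomial(200, ε/3) (mean 0.33, s.d. 0.58), so the control tolerance is
ceil(mean+3σ) = 3 reads and "detected" means ≥2 alt reads per replicate
(the weakest planted site yields ~10). The recovery check compares each
estimated level against the error-model expectation p(1 − 4ε/3) — the
known attenuation from miscalls out of and into the U channel — within
three binomial standard errors of the pooled estimate.

What the simulations do **not** model: mapping artefacts, strand bias,
position-dependent error profiles, overdispersion between replicates,
transcript-abundance variation and RNA structure. Passing recovery tests
therefore demonstrates the correctness of the filter logic and level
arithmetic, not robustness to alignment pathologies of real RNA-seq.

## Fixtures

The PPR65 array and its native/off-target windows in `plsedit.fixtures`
are synthetic reconstructions: repeat identities, the key native
nucleotides, the 6-of-8 P/S match structure, the all-G −9 column and the
6-of-7 identity at −1..−3 are fixed by the documented behaviour of the
system; all residues and nucleotides not pinned down by those
constraints were invented once and carry no information. Quantities
computed on these fixtures (match counts, consensus fractions) test the
implementation against the documented structure, not the exact deposited
sequences.

## Numerical and degenerate-input choices

Window positions outside the sequence read as N and score 0. A window
too short to cover the most N-terminal repeat is an error naming that
repeat (shifted registers may overhang by one nucleotide, reading N).
Zero-coverage sites are skipped with a warning rather than propagating
NaNs. Purity thresholds are strict inequalities (98.0% exactly fails).
Empty control sets pass the control filter vacuously, with a warning.
Problem sizes in the test suite and acceptance script — 2 kb scan
sequences, 6 kb recovery transcriptomes, coverage 200–1000 — are chosen
so every stage exercises its full logic while the whole suite runs in
seconds.
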