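# plsedit

Analysis toolkit for **PLS-type pentatricopeptide-repeat (PPR) C-to-U RNA
editing factors** expressed in a bacterial host. Plant organellar editing
factors of the PLS class recognise an RNA target one nucleotide per repeat
and deaminate a specific cytidine; expressing single moss factors such as
PPR65 or PPR56 in *E. coli* turns editing into a sequencing-readable assay,
complete with transcriptome-wide off-targets. This package implements the
computational layer of that kind of study, for people who design targets,
hunt off-targets, or quantify editing:

* the **PPR–RNA recognition code** for P/L/S repeats and the repeat→target
  register (repeat *k* binds nucleotide −(k+3); the terminal P2-L2-S2
  triplet binds −3..−1; the edited C is position 0),
* repeat-by-repeat **match profiling and scoring** of candidate windows,
* a **transcriptome scanner** for editable cytidines on both strands, with
  ±1 register-shift annotation and editing-site nomenclature
  (`ccmFCeU103PS` = gene, "eU", CDS position, amino-acid change),
* a strict **RNA-vs-DNA editing-site caller** on base-count tables
  (coverage → >98% purity → replicate concordance → control exclusion),
  with the editing level defined as
  `level = alt/total (RNA) − alt/total (DNA)`,
* **consensus/conservation analysis** of off-target windows (90/60/30%
  shading, position-frequency export for logo tools),
* **Sanger peak quantification** `T / (T + C)` with replicate aggregation,
* a **synthetic-data generator** (planted targets, binomial counts, noisy
  chromatograms) so the whole pipeline is testable with known ground truth.

The recognition code maps the residues at repeat positions 5 and L(last)
to a nucleotide preference: T/S+N → A, T/S+D → G, N+N → C/U, N+S → C>U,
N+D → U>C. Match scoring weights purine positions double (purine
transitions are fatal in the wet assay, pyrimidine swaps are often
tolerated) and L-type repeats at half weight.

## Worked example

Profile the bundled PPR65 reconstruction against its native ccmFC target
window:

```python
from plsedit.fixtures import ppr65_array, ppr65_native_window
from plsedit.target_matching import match_profile, count_perfect_PS_matches

profile = match_profile(ppr65_array(), ppr65_native_window())
print(count_perfect_PS_matches(profile))   # (6, 8)
print(profile.score)                       # 8.5
```

Six of the eight coded P/S repeats match the code perfectly; the native
mismatches are an A at −9 opposite P-6TD (a purine transition) and a G at
−16 opposite S-13NN. The default-weight score of 8.5 compares with a
maximum attainable 13.5 for this array.

The same from the shell, plus an off-target consensus:

```sh
plsedit match --array ppr65.tsv --fasta target.fa --site tgt:33:+
plsedit simulate --preset recovery --seed 17 --out sim/
plsedit call --counts sim/counts.tsv --min-cov 100 --min-alt 2 --max-alt 3
```

The `simulate`/`call` pair plants ten edited sites (true levels
0.05–1.0, coverage 200, two RNA replicates, 0.5% sequencing error) plus
five decoys, and the caller reports exactly the ten planted sites with
their estimated levels — the decoys fall to the DNA-purity and control
filters.

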