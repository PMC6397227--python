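"""Transcriptome scanning, register shifts and editing-site nomenclature."""

import numpy as np
import pytest

from plsedit.offtarget_scan import (
    GeneAnnotation,
    annotate_shift,
    constraints_from_window,
    edit_label,
    parse_edit_label,
    scan_transcriptome,
)
from plsedit.target_matching import (
    MatchCategory,
    TargetWindow,
    extract_window,
    match_profile,
    reverse_complement_rna,
)


def _random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScanner:
    def test_planted_perfect_window_ranks_first(self, ppr65, native_window):
        # plant a fully code-matching variant of the native window
        perfect = native_window.mutate(-9, "G").mutate(-16, "C")
        background = _random_dna(3000, seed=5)
        seq = (background[:1200]
               + perfect.sequence.replace("U", "T")
               + background[1200:])
        hits = scan_transcriptome({"chr": seq}, ppr65,
                                  annotate_shifts=False)
        assert hits, "planted site not found"
        top = hits[0]
        assert (top.coord, top.strand) == (1200 + 33, "+")

    def test_reverse_complement_swaps_strands(self, ppr65):
        seq = _random_dna(800, seed=11)
        fwd = scan_transcriptome({"s": seq}, ppr65, min_score=-100,
                                 annotate_shifts=False)
        rev = scan_transcriptome(
            {"s": reverse_complement_rna(seq).replace("U", "T")},
            ppr65, min_score=-100, annotate_shifts=False)
        flipped = sorted(
            (len(seq) - 1 - h.coord, {"+": "-", "-": "+"}[h.strand],
             h.score) for h in rev
        )
        assert flipped == sorted((h.coord, h.strand, h.score) for h in fwd)

    def test_scanner_matches_bruteforce_oracle(self, ppr65):
        """Independent re-profiling of every C on both strands yields the
        identical ranked list (2-kb random sequence, fixed seed)."""
        seq = _random_dna(2000, seed=7)
        hits = scan_transcriptome({"chr1": seq}, ppr65, min_score=4.0,
                                  annotate_shifts=False)
        oracle = []
        rna = seq.replace("T", "U")
        for strand in "+-":
            watch = "C" if strand == "+" else "G"
            for i, nt in enumerate(rna):
                if nt != watch:
                    continue
                w = extract_window(rna, i, strand=strand)
                score = match_profile(ppr65, w).score
                if score >= 4.0:
                    oracle.append((i, strand, score))
        oracle.sort(key=lambda t: (-t[2], "chr1", t[0], t[1]))
        assert [(h.coord, h.strand, h.score) for h in hits] == oracle

    def test_constraints_drop_nonconforming_sites(self, ppr65,
                                                  native_window):
        seq = _random_dna(1500, seed=3)
        cons = constraints_from_window(native_window)  # requires A,U,U
        hits = scan_transcriptome({"s": seq}, ppr65, min_score=-100,
                                  constraints=cons, annotate_shifts=False)
        for h in hits:
            w = extract_window(seq, h.coord, strand=h.strand)
            assert (w.at(-3), w.at(-2), w.at(-1)) == ("A", "U", "U")

    def test_empty_fasta_rejected(self, ppr65):
        with pytest.raises(ValueError, match="no sequences"):
            scan_transcriptome({}, ppr65)

    def test_reported_sites_revalidate(self, ppr65):
        seq = _random_dna(1000, seed=9)
        for h in scan_transcriptome({"s": seq}, ppr65, min_score=2.0,
                                    annotate_shifts=False):
            w = extract_window(seq, h.coord, strand=h.strand)
            assert match_profile(ppr65, w).score == h.score


class TestShift:
    def test_native_window_prefers_no_shift(self, ppr65, native_window):
        shift, score = annotate_shift(ppr65, native_window)
        assert shift == 0
        assert score == match_profile(ppr65, native_window).score

    def test_all_n_window_prefers_no_shift(self, ppr65):
        shift, score = annotate_shift(ppr65, TargetWindow("N" * 39))
        assert (shift, score) == (0, 0.0)

    def test_upstream_insertion_recovered_by_minus_one(self, ppr65,
                                                       native_window):
        """Inserting one nucleotide just upstream of the site (at −5)
        pushes all upstream register positions out of frame; a −1 shift
        realigns them and must win."""
        s = native_window.sequence
        i = -5 + 33
        inserted = s[1:i] + "G" + s[i:]  # drop leftmost nt to keep length
        window = TargetWindow(inserted, W=33, D=5)
        scores = {
            shift: match_profile(ppr65, window, shift=shift).score
            for shift in (-1, 0, 1)
        }
        best_shift, best = annotate_shift(ppr65, window)
        assert best_shift == -1
        assert best == scores[-1] > scores[0]
        # the upstream matches are indeed recovered in the shifted frame
        shifted = match_profile(ppr65, window, shift=-1)
        for label in ("P-9TN", "S-10TN", "S-7ND"):
            (pair,) = [p for p in shifted.pairs if p.repeat.label == label]
            assert pair.category is MatchCategory.MATCH


class TestEditLabel:
    def _gene_with_codon(self, codon, cds_pos):
        """Synthetic gene whose CDS carries `codon` covering 1-based CDS
        position cds_pos at the codon slot that makes it the C."""
        within = (cds_pos - 1) % 3
        codon_i = (cds_pos - 1) // 3
        cds = "ATG" + "GCT" * (codon_i - 1) + codon + "TAA"
        seq = "T" * 50 + cds + "T" * 20
        gene = GeneAnnotation("g", "chr", cds_start=50,
                              cds_end=50 + len(cds))
        site = 50 + 3 * codon_i + within
        return gene, seq, site

    def test_ccmfc_style_proline_to_serine(self):
        # CDS position 103: first base of a CCA (Pro) codon; C→U gives UCA (Ser)
        gene, seq, site = self._gene_with_codon("CCA", 103)
        label = edit_label(GeneAnnotation("ccmFC", gene.seq_id,
                                          gene.cds_start, gene.cds_end),
                          seq, site)
        assert str(label) == "ccmFCeU103PS"

    def test_nad4_style_serine_to_leucine(self):
        # CDS position 272: middle base of TCA (Ser); C→U gives TTA (Leu)
        gene, seq, site = self._gene_with_codon("TCA", 272)
        label = edit_label(GeneAnnotation("nad4", gene.seq_id,
                                          gene.cds_start, gene.cds_end),
                          seq, site)
        assert str(label) == "nad4eU272SL"

    def test_upstream_site_gets_negative_position(self):
        seq = "A" * 45 + "C" + "A" * 4 + "ATGGCTTAA" + "A" * 20
        gene = GeneAnnotation("AJH09430", "chr", cds_start=50, cds_end=59)
        label = edit_label(gene, seq, 45)
        assert str(label) == "AJH09430eU-5"
        assert label.aa_change == ""

    def test_synonymous_edit_is_tagged_not_labelled(self):
        # CTC (Leu) → TTC? no: first base C→T gives TTC (Phe). Use CTG→TTG?
        # Leu→Leu needs CTG with C→T at position 1: TTG is still Leu.
        gene, seq, site = self._gene_with_codon("CTG", 4)
        label = edit_label(GeneAnnotation("syngene", gene.seq_id,
                                          gene.cds_start, gene.cds_end),
                          seq, site)
        assert label.synonymous and label.aa_change == ""
        assert str(label) == "syngeneeU4"

    def test_antisense_site_suffixed_as(self):
        seq = "T" * 50 + "ATGGCTCATTAA" + "T" * 20
        gene = GeneAnnotation("yfjL", "chr", cds_start=50, cds_end=62)
        label = edit_label(gene, seq, 52, site_strand="-")
        assert label.antisense and str(label).endswith("as")
        assert label.aa_change == ""

    def test_site_outside_transcript_rejected(self):
        seq = "A" * 400 + "ATGTAA" + "A" * 400
        gene = GeneAnnotation("far", "chr", cds_start=400, cds_end=406,
                              utr5=50, utr3=50)
        with pytest.raises(ValueError, match="not within"):
            edit_label(gene, seq, 10)

    def test_non_c_reference_base_rejected(self):
        gene, seq, site = self._gene_with_codon("GGA", 103)
        with pytest.raises(ValueError, match="not C"):
            edit_label(GeneAnnotation("g", gene.seq_id, gene.cds_start,
                                      gene.cds_end), seq, site)

    @pytest.mark.parametrize("text", [
        "ccmFCeU103PS", "nad4eU272SL", "AJH09430eU-5", "yfjLeU88as",
    ])
    def test_label_roundtrip(self, text):
        assert str(parse_edit_label(text)) == text
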