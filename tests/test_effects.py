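"""Consequence prediction, residue-class labels, panel exclusion, ranking."""

import numpy as np
import pytest

from introbsa import effects as ef
from introbsa.synthetic_data import VariantSite

# frozen standard nuclear codon table: the independent oracle for translation
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def test_all_64_codons_translate_per_standard_table():
    from Bio.Seq import Seq

    for codon, aa in CODON_TABLE.items():
        assert str(Seq(codon).translate()) == aa


class TestMapToCds:
    def test_forward_gene_offset_and_codon(self):
        gene = ef.GeneModel("g", "c", "+", [(101, 112)])
        hit = ef.map_to_cds(VariantSite("c", 105, "G", "A"), gene)
        assert (hit.offset, hit.codon_index) == (5, 2)

    def test_intron_gap_is_non_coding(self):
        gene = ef.GeneModel("g", "c", "+", [(101, 106), (120, 125)])
        assert ef.map_to_cds(VariantSite("c", 110, "G", "A"), gene) is None

    def test_other_chromosome_is_non_coding(self):
        gene = ef.GeneModel("g", "c", "+", [(101, 112)])
        assert ef.map_to_cds(VariantSite("d", 105, "G", "A"), gene) is None

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ef.GeneModel("g", "c", "+", [(101, 112), (110, 120)])


class TestPredictConsequence:
    def _setup(self, cds_seq, strand="+"):
        ref = {"c": "NN" + cds_seq + "NN"}
        gene = ef.GeneModel("g", "c", strand, [(3, 2 + len(cds_seq))])
        return ref, gene

    def test_missense_gly_to_glu(self):
        ref, gene = self._setup("ATGGGACTGTAA")  # codon 2 = GGA
        call = ef.predict_consequence(VariantSite("c", 7, "G", "A"), gene, ref)
        assert call.consequence == "missense"
        assert call.codon_change == "GGA>GAA"
        assert call.residue_change == "G2E"

    def test_nonsense_gln_to_stop(self):
        ref, gene = self._setup("ATGCAACTGTAA")  # codon 2 = CAA
        call = ef.predict_consequence(VariantSite("c", 6, "C", "T"), gene, ref)
        assert call.consequence == "nonsense"
        assert call.residue_change == "Q2stop"

    def test_synonymous_leu(self):
        ref, gene = self._setup("ATGCTGAAATAA")  # codon 2 = CTG
        call = ef.predict_consequence(VariantSite("c", 8, "G", "A"), gene, ref)
        assert call.consequence == "synonymous"
        assert call.codon_change == "CTG>CTA"

    def test_frameshift_indel(self):
        ref, gene = self._setup("ATGCTGAAATAA")
        call = ef.predict_consequence(VariantSite("c", 7, "T", "TAG"), gene, ref)
        assert call.consequence == "frameshift"

    def test_inframe_indel(self):
        ref, gene = self._setup("ATGCTGAAATAA")
        call = ef.predict_consequence(VariantSite("c", 7, "T", "TGGG"), gene, ref)
        assert call.consequence == "inframe_indel"

    def test_non_coding_variant(self):
        ref = {"c": "AA" + "ATGCTGAAATAA" + "AA"}
        gene = ef.GeneModel("g", "c", "+", [(3, 14)])
        call = ef.predict_consequence(VariantSite("c", 1, "A", "G"), gene, ref)
        assert call.consequence == "non_coding"

    def test_reference_mismatch_names_position(self):
        ref, gene = self._setup("ATGCTGAAATAA")
        with pytest.raises(ef.ReferenceMismatchError, match="c:6"):
            ef.predict_consequence(VariantSite("c", 6, "G", "A"), gene, ref)


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_RC)[::-1]


def test_minus_strand_equals_mirrored_plus_strand():
    """Strand-mirror oracle: a minus-strand call must equal the plus-strand
    call computed on the reverse-complemented genome at mirrored coordinates."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    n_checked = 0
    for _ in range(100):
        glen = 60
        seq = "".join(bases[rng.integers(0, 4, size=glen)])
        cds_len = 12
        start = int(rng.integers(5, glen - cds_len - 5))
        gene_minus = ef.GeneModel("gm", "c", "-", [(start, start + cds_len - 1)])
        pos = int(rng.integers(start, start + cds_len))
        ref_base = seq[pos - 1]
        alt = str(bases[(list("ACGT").index(ref_base) + int(rng.integers(1, 4))) % 4])
        v = VariantSite("c", pos, ref_base, alt)
        call_minus = ef.predict_consequence(v, gene_minus, {"c": seq})

        mseq = _revcomp(seq)
        mpos = glen - pos + 1
        mstart = glen - (start + cds_len - 1) + 1
        gene_plus = ef.GeneModel("gp", "c", "+", [(mstart, mstart + cds_len - 1)])
        mv = VariantSite("c", mpos, ref_base.translate(_RC), alt.translate(_RC))
        call_plus = ef.predict_consequence(mv, gene_plus, {"c": mseq})

        assert call_minus.consequence == call_plus.consequence
        assert call_minus.codon_change == call_plus.codon_change
        assert call_minus.residue_change == call_plus.residue_change
        n_checked += 1
    assert n_checked == 100


class TestResidueClasses:
    @pytest.mark.parametrize(
        "pair,label",
        [
            (("A", "V"), "hydrophobic → hydrophobic"),
            (("E", "K"), "negative → positive"),
            (("S", "N"), "polar → polar"),
            (("V", "I"), "nonpolar → nonpolar"),
            (("G", "E"), "nonpolar → negative"),
        ],
    )
    def test_published_transitions(self, pair, label):
        assert ef.classify_residue_change(*pair) == label

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            ef.classify_residue_change("X", "A")

    def test_custom_map_overrides_default(self):
        custom = {"G": ("tiny",), "E": ("charged",)}
        assert ef.classify_residue_change("G", "E", custom) == "tiny → charged"


class TestPanelExclude:
    def test_in_panel_removed_absent_retained(self):
        panel = {("chr1", 100, "A")}
        hit = VariantSite("chr1", 100, "G", "A")
        miss = VariantSite("chr1", 200, "G", "A")
        assert ef.panel_exclude([hit, miss], panel) == [miss]

    def test_five_decoys_one_novel(self):
        decoys = [VariantSite("chr1", p, "G", "A") for p in range(10, 60, 10)]
        novel = VariantSite("chr1", 999, "C", "T")
        panel = {(v.chrom, v.pos, v.alt) for v in decoys}
        assert ef.panel_exclude(decoys + [novel], panel) == [novel]


class TestRankCandidates:
    def _consequence(self, v, kind, residue="G2E"):
        return ef.ConsequenceCall(v, "g", kind, residue_change=residue,
                                  residue_position=2)

    def test_variant_present_in_normal_bulk_excluded(self):
        # a candidate seen at index 1/9 in the normal bulk is background
        # polymorphism among the recurrent parents, not the cause
        v = VariantSite("chr1", 100, "C", "A")
        report = ef.rank_candidates(
            [v], {v.key: (1.0, 1 / 9)},
            {v.key: self._consequence(v, "missense", "S2Y")},
        )
        assert report.ranked == []
        assert report.filtered_out["index"] == [v]

    def test_synonymous_only_region_is_empty_with_report(self):
        v = VariantSite("chr1", 100, "G", "A")
        report = ef.rank_candidates(
            [v], {v.key: (1.0, 0.0)}, {v.key: self._consequence(v, "synonymous")}
        )
        assert report.ranked == []
        assert report.filtered_out["consequence"] == [v]

    def test_severity_ordering(self):
        vs = [VariantSite("chr1", p, "G", "A") for p in (10, 20, 30)]
        kinds = [("missense", "V2I"), ("nonsense", "Q2stop"), ("missense", "G2E")]
        indices = {v.key: (1.0, 0.0) for v in vs}
        cons = {v.key: self._consequence(v, k, r) for v, (k, r) in zip(vs, kinds)}
        report = ef.rank_candidates(vs, indices, cons)
        got = [r.consequence.consequence for r in report.ranked]
        # truncating first, then the class-changing missense, then V2I
        assert got == ["nonsense", "missense", "missense"]
        assert report.ranked[1].class_transition == "nonpolar → negative"
        assert report.ranked[2].class_transition == "nonpolar → nonpolar"
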