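"""Gene feature arithmetic, mass/pI, intron typing and exon comparison."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from famevol.catalog import (
    AVERAGE_RESIDUE_MASS,
    CANONICAL_INTERNAL_EXONS,
    WATER_MASS,
    ExonModel,
    GeneRecord,
    InvalidCDSError,
    StructureComparisonError,
    UnknownResidueError,
    classify_intron_type,
    compare_exon_structure,
    isoelectric_point,
    net_charge,
    protein_mass,
    read_exon_models_gff3,
    read_exon_models_tsv,
    translate_length,
)

AA = "".join(sorted(AVERAGE_RESIDUE_MASS))
aa_seq = st.text(alphabet=AA, min_size=1, max_size=60)


class TestTranslateLength:
    @pytest.mark.parametrize(
        "cds,aa", [(1368, 455), (1086, 361), (6, 1), (1095, 364), (1029, 342)]
    )
    def test_known_values(self, cds, aa):
        assert translate_length(cds) == aa

    @pytest.mark.parametrize("cds", [0, 3, 7, 100, -9])
    def test_rejects_invalid_cds(self, cds):
        with pytest.raises(InvalidCDSError):
            translate_length(cds)

    def test_whole_feature_table_is_self_consistent(self, gene_records):
        """Every cloned gene's printed protein length equals CDS/3 - 1 and
        all other record invariants hold."""
        assert len(gene_records) == 13
        for rec in gene_records:
            rec.validate()
            assert rec.protein_len_aa == translate_length(rec.cds_len_bp)


class TestProteinMass:
    def test_dipeptide_hand_sum(self):
        # Met 131.1926 + Gly 57.0519 + water 18.0152 = 206.2597 Da
        assert protein_mass("MG") == pytest.approx(0.20626, abs=5e-5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(UnknownResidueError):
            protein_mass("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(UnknownResidueError):
            protein_mass("MGX")

    @settings(derandomize=True, max_examples=50)
    @given(a=aa_seq, b=aa_seq)
    def test_additive_up_to_one_water(self, a, b):
        whole = protein_mass(a + b)
        parts = protein_mass(a) + protein_mass(b) - WATER_MASS / 1000.0
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_matches_biopython_average_mass(self):
        from Bio.SeqUtils import molecular_weight

        seq = "MDKVLNREESNGSAWWDAFKPQSTR"
        ours = protein_mass(seq) * 1000.0
        theirs = molecular_weight(seq, seq_type="protein", monoisotopic=False)
        assert ours == pytest.approx(theirs, rel=1e-3)


class TestIsoelectricPoint:
    def test_acidic_and_basic_extremes(self):
        assert isoelectric_point("EE") < 4.5
        assert isoelectric_point("KK") > 9.0

    def test_bisection_root_property(self):
        """The returned pH really is a root of the charge function."""
        import numpy as np

        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = "".join(rng.choice(list(AA), size=100))
            ph = isoelectric_point(seq)
            assert abs(net_charge(seq, ph)) < 1e-4

    @settings(derandomize=True, max_examples=50)
    @given(seq=aa_seq)
    def test_adding_lysine_never_decreases_pi(self, seq):
        assert isoelectric_point(seq + "K") >= isoelectric_point(seq) - 1e-6

    def test_close_to_biopython_with_bjellqvist_pk(self):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        import numpy as np

        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(25):
            seq = "".join(rng.choice(list(AA), size=80))
            diffs.append(
                abs(isoelectric_point(seq, pk_set="bjellqvist") - IsoelectricPoint(seq).pi())
            )
        assert max(diffs) < 0.8  # pK-set dependence, same charge model


class TestIntronTyping:
    @pytest.mark.parametrize(
        "count,label",
        [(7, "I"), (8, "I"), (9, "I"), (5, "II"), (6, "II"), (3, "UNCLASSIFIED"),
         (0, "UNCLASSIFIED"), (12, "UNCLASSIFIED")],
    )
    def test_ranges(self, count, label):
        assert classify_intron_type(count) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_intron_type(-1)


class TestExonComparison:
    def make(self, internal):
        return ExonModel("g", (200, *internal, 300))

    def test_canonical_model_all_match(self):
        events = compare_exon_structure(self.make(CANONICAL_INTERNAL_EXONS))
        assert [e.kind for e in events] == ["MATCH"] * 7

    def test_fusion_of_first_two_internal_exons(self):
        # 177 = 75 + 102: one observed exon spans canonical exons 1-2
        events = compare_exon_structure(self.make((177, 54, 93, 93, 105, 99)))
        assert events[0].kind == "FUSION"
        assert (events[0].canon_start, events[0].canon_end) == (1, 2)
        assert [e.kind for e in events[1:]] == ["MATCH"] * 5

    def test_perturbed_length_is_mismatch(self):
        events = compare_exon_structure(self.make((75, 100, 54, 93, 93, 105, 99)))
        kinds = [e.kind for e in events]
        assert kinds[0] == "MATCH"
        assert kinds[1] == "MISMATCH"
        assert kinds[2:] == ["MATCH"] * 5

    def test_too_few_exons_rejected(self):
        with pytest.raises(StructureComparisonError):
            compare_exon_structure(ExonModel("g", (100, 200)))

    def test_leftover_exons_reported(self):
        events = compare_exon_structure(self.make((75, 102)))
        assert sum(e.kind == "MISMATCH" for e in events) == 5  # unmatched canon


class TestRecordValidation:
    def test_bad_protein_length_rejected(self):
        rec = GeneRecord("g", "X1", 2000, 1368, 9, 400, 45.0, 5.5, "Nuclear")
        with pytest.raises(ValueError, match="protein length"):
            rec.validate()

    def test_gene_shorter_than_cds_rejected(self):
        rec = GeneRecord("g", "X1", 1000, 1368, 9, 455, 51.9, 5.5, "Nuclear")
        with pytest.raises(ValueError, match="shorter"):
            rec.validate()

    def test_implausible_mass_rejected(self):
        rec = GeneRecord("g", "X1", 2000, 1368, 9, 455, 95.0, 5.5, "Nuclear")
        with pytest.raises(ValueError, match="mass"):
            rec.validate()


class TestExonModelIO:
    def test_tsv_reader(self, tmp_path):
        path = tmp_path / "models.tsv"
        path.write_text("gene_id\texons\tphases\ng1\t200,75,102,300\t0,1,2\n")
        (model,) = read_exon_models_tsv(path)
        assert model.exon_lengths_bp == (200, 75, 102, 300)
        assert model.intron_phases == (0, 1, 2)

    def test_gff3_reader(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=gene1\n"
            "chr1\tsrc\tmRNA\t1\t1000\t.\t+\t.\tID=t1;Parent=gene1\n"
            "chr1\tsrc\texon\t1\t200\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\texon\t301\t375\t.\t+\t.\tParent=t1\n"
            "chr1\tsrc\texon\t501\t602\t.\t+\t.\tParent=t1\n"
        )
        (model,) = read_exon_models_gff3(gff)
        assert model.exon_lengths_bp == (200, 75, 102)
        assert model.internal_exons == (75,)
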