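"""Structural annotation, anticodon classification, G3:U70, scoring."""

import pytest

from trnavarseq.allele_calling import Edit
from trnavarseq.reference_model import TRNALocus, build_canonical_gene
from trnavarseq.structure_function import (
    FoldScores,
    ScoringModel,
    ScoringWindowError,
    annotate_variant,
    classify_anticodon_variant,
    classify_delta,
    detect_g3u70,
    region_of_label,
)


def _locus(anticodon="GCC", overrides=None, missing=(), intron_seq="", n_e=0,
           high_confidence=True, locus_id="L"):
    gene, labels, structure = build_canonical_gene(
        anticodon, overrides=overrides or {}, missing=missing,
        intron_seq=intron_seq, n_e=n_e,
    )
    intron_intervals = ()
    if intron_seq:
        s = labels.index("intron")
        intron_intervals = ((s, s + len(intron_seq)),)
    return TRNALocus(
        locus_id=locus_id, chrom="chr1", start=0, end=len(gene), strand="+",
        gene_seq=gene, flank5="T" * 20, flank3="GGGGG",
        intron_intervals=intron_intervals, isotype="Gly", anticodon=anticodon,
        high_confidence=high_confidence, structure=structure,
        sprinzl_map=labels,
    )


class TestRegions:
    @pytest.mark.parametrize(
        "label,region",
        [
            ("3", "acceptor stem"), ("70", "acceptor stem"),
            ("35", "anticodon"), ("33", "anticodon loop"),
            ("29", "anticodon stem"), ("17a", "D-arm"),
            ("e4", "variable arm"), ("47", "variable arm"),
            ("58", "T-arm"), ("58+", "T-arm"),
            ("73", "discriminator"), ("intron", "intron"),
            ("8", "other"), ("26", "other"),  # linker/hinge positions
        ],
    )
    def test_label_regions(self, label, region):
        assert region_of_label(label) == region

    def test_annotate_snv_at_35(self):
        locus = _locus("GCC")
        pos = locus.position_of("35")
        edits = [Edit("snv", pos, "C", "T")]
        ann = annotate_variant(edits, locus)
        assert ann.labels == ("35",)
        assert ann.regions == ("anticodon",)
        assert ann.anticodon_changed

    def test_annotate_intron_edit(self):
        locus = _locus("GTA", intron_seq="ACGTACGTA")
        pos = locus.sprinzl_map.index("intron")
        ref = locus.gene_seq[pos]
        alt = "A" if ref != "A" else "C"
        ann = annotate_variant([Edit("snv", pos, ref, alt)], locus)
        assert ann.regions == ("intron",)
        assert not ann.anticodon_changed

    def test_insertion_label_carries_marker(self):
        locus = _locus("GCC")
        pos = locus.position_of("58") + 1
        ann = annotate_variant([Edit("ins", pos, "", "C")], locus)
        assert ann.labels == ("58+",)
        assert ann.regions == ("T-arm",)


class TestAnticodonClassification:
    @pytest.mark.parametrize(
        "ref_ac,var_ac,synonymous,wt,var",
        [
            ("GTT", "ATT", True, "Asn", "Asn"),
            ("AGA", "AAA", False, "Ser", "Phe"),
            ("TCC", "TCA", False, "Gly", "STOP"),
            ("GTC", "GAC", False, "Asp", "Val"),
        ],
    )
    def test_examples(self, ref_ac, var_ac, synonymous, wt, var):
        cls = classify_anticodon_variant(ref_ac, var_ac)
        assert cls.synonymous is synonymous
        assert (cls.wt_identity, cls.var_identity) == (wt, var)


class TestG3U70:
    def test_creation_from_a3_u70(self):
        locus = _locus(overrides={"3": "A"})  # A3:U70 pair
        pos3 = locus.position_of("3")
        assert detect_g3u70(locus, [Edit("snv", pos3, "A", "G")]) is True

    def test_creation_from_c3_u70_mismatch(self):
        locus = _locus(overrides={"3": "C", "70": "T"})
        pos3 = locus.position_of("3")
        assert detect_g3u70(locus, [Edit("snv", pos3, "C", "G")]) is True

    def test_already_present_not_creation(self):
        locus = _locus(overrides={"3": "G", "70": "T"})
        pos = locus.position_of("35")
        assert detect_g3u70(locus, [Edit("snv", pos, "C", "A")]) is False

    def test_unrelated_variant_false(self):
        locus = _locus(overrides={"3": "A"})
        pos = locus.position_of("20")
        ref = locus.gene_seq[pos]
        alt = "A" if ref != "A" else "C"
        assert detect_g3u70(locus, [Edit("snv", pos, ref, alt)]) is False

    def test_missing_position70_not_evaluable(self):
        locus = _locus(missing=("70",))
        pos3 = locus.position_of("3")
        assert detect_g3u70(locus, [Edit("snv", pos3, "G", "A")]) is None


@pytest.fixture(scope="module")
def model(small_reference):
    return ScoringModel.from_reference(small_reference.loci)


class TestPromoterScore:
    def test_reference_vs_itself_delta_zero(self, small_reference, model):
        for locus in small_reference.loci:
            report = model.delta_scores([], locus)
            assert report.delta_box_total == 0.0
            assert report.delta_fold_total == 0.0

    def test_consensus_sequence_maximises_box_scores(self, small_reference, model):
        """A gene matching the PSSM argmax everywhere scores the maximum."""
        locus = next(iter(small_reference.loci))
        consensus_edits = []
        best_total = 0.0
        from trnavarseq.structure_function import A_BOX_LABELS, B_BOX_LABELS

        for lab in A_BOX_LABELS + B_BOX_LABELS:
            pos = locus.position_of(lab)
            if pos is None:
                continue
            col = model.logodds[lab]
            best_base = max(col, key=col.get)
            best_total += col[best_base]
            if locus.gene_seq[pos] != best_base:
                consensus_edits.append(
                    Edit("snv", pos, locus.gene_seq[pos], best_base)
                )
        box = model.score_ab_box(locus, consensus_edits)
        assert box.total == pytest.approx(best_total)
        assert box.total >= model.score_ab_box(locus).total

    def test_mutating_most_conserved_bbox_column_lowers_score(
        self, small_reference, model
    ):
        """Oracle: enumerate all single B-box substitutions; the largest drop
        is at the most conserved column, and all consensus-base mutations
        strictly lower the total."""
        from trnavarseq.structure_function import B_BOX_LABELS

        locus = next(iter(small_reference.loci))
        base_total = model.score_ab_box(locus).total
        drops = {}
        for lab in B_BOX_LABELS:
            pos = locus.position_of(lab)
            if pos is None:
                continue
            ref = locus.gene_seq[pos]
            col = model.logodds[lab]
            if ref != max(col, key=col.get):
                continue  # locus is off-consensus here; a change could help
            for alt in "ACGT":
                if alt == ref:
                    continue
                total = model.score_ab_box(
                    locus, [Edit("snv", pos, ref, alt)]
                ).total
                assert total < base_total
                drops[(lab, alt)] = base_total - total
        # the maximal drop happens at the column with the highest log-odds gap
        (worst_lab, _), worst_drop = max(drops.items(), key=lambda kv: kv[1])
        gaps = {
            lab: model.logodds[lab][locus.gene_seq[locus.position_of(lab)]]
            - min(model.logodds[lab].values())
            for (lab, _) in drops
        }
        assert gaps[worst_lab] == pytest.approx(max(gaps.values()))

    def test_window_off_gene_raises(self, model):
        locus = _locus(missing=tuple(str(i) for i in range(52, 63)))
        with pytest.raises(ScoringWindowError, match="B box"):
            model.score_ab_box(locus)


class TestFoldScore:
    def test_watson_crick_reference_maximises_secondary(self, model):
        """All-WC stems score 2 bits per annotated pair."""
        locus = _locus("GCC")
        fold = model.score_fold(locus)
        n_pairs = sum(1 for j in locus.pairing if j != -1) // 2
        assert fold.secondary == pytest.approx(2.0 * n_pairs)

    def test_breaking_stem_pair_lowers_secondary(self, model):
        locus = _locus("GCC")
        pos = locus.position_of("49")  # T-stem 5' side
        ref = locus.gene_seq[pos]
        alt = "A" if ref != "A" else "C"
        before = model.score_fold(locus).secondary
        after = model.score_fold(locus, [Edit("snv", pos, ref, alt)]).secondary
        assert after < before

    def test_pseudo_rule(self):
        assert FoldScores(primary=9.5, secondary=6.0).pseudo is True
        assert FoldScores(primary=10.0, secondary=5.0).pseudo is False
        assert FoldScores(primary=30.0, secondary=4.9).pseudo is True

    def test_high_confidence_references_not_pseudo(self, small_reference, model):
        """Packaged-matrix calibration: high-confidence loci score functional."""
        for locus in small_reference.loci:
            if locus.high_confidence:
                assert model.score_fold(locus).pseudo is False


class TestDeltaClassification:
    @pytest.mark.parametrize(
        "delta,expected",
        [(2.3, "increase"), (-0.4, "neutral"), (-5.0, "decrease"),
         (1.0, "neutral"), (-1.0, "neutral")],
    )
    def test_neutral_band(self, delta, expected):
        assert classify_delta(delta) == expected

    def test_report_classification_and_pseudo_transition(
        self, small_reference, model
    ):
        locus = next(iter(small_reference.loci))
        # deleting many paired bases should wreck the fold
        pairing = locus.pairing
        paired = [i for i, j in enumerate(pairing) if j > i][:12]
        edits = [Edit("snv", p, locus.gene_seq[p],
                      "A" if locus.gene_seq[p] != "A" else "C") for p in paired]
        report = model.delta_scores(edits, locus)
        assert report.classification == "decrease"
        if locus.high_confidence and report.var_fold.pseudo:
            assert report.pseudo_transition == "functional_to_pseudo"
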