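"""btop parsing/emission, flank trimming, genomic descriptors, allele frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import edlib

from trnavarseq.allele_calling import (
    BtopError,
    Edit,
    Genotype,
    GenotypeAllele,
    apply_btop,
    apply_edits,
    btop_from_alignment,
    cohort_allele_frequencies,
    emit_btop,
    parse_btop,
    to_genomic,
    trim_to_gene,
)
from trnavarseq.reference_model import ReferenceSet, TRNALocus, build_canonical_gene


def _nw_btop(ref: str, read: str) -> str:
    """Independent btop via edlib global alignment."""
    res = edlib.align(ref, read, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, ref, read)
    return btop_from_alignment(nice["query_aligned"], nice["target_aligned"])


class TestBtop:
    def test_identical_sequences(self):
        seq = "A" * 72
        assert _nw_btop(seq, seq) == "72"
        assert apply_btop("72", seq) == seq

    def test_substitution_pair_order(self):
        """Pairs are (reference base, read base), the BLAST query-first order."""
        ref, read = "ACGTACGT", "ACGAACGT"
        btop = _nw_btop(ref, read)
        assert btop == "3TA4"
        assert apply_btop(btop, ref) == read

    def test_read_deletion(self):
        ref, read = "ACGT", "AGT"
        btop = _nw_btop(ref, read)
        assert btop == "1C-2"
        assert apply_btop(btop, ref) == read

    def test_read_insertion(self):
        ref, read = "ACGT", "ACGGT"
        btop = _nw_btop(ref, read)
        assert apply_btop(btop, ref) == read
        assert "-G" in btop

    def test_parse_emit_identity(self):
        for btop in ("97", "3TA4", "1C-2", "10-A5CT2", "AC"):
            assert emit_btop(parse_btop(btop)) == btop

    def test_malformed_reports_offset(self):
        with pytest.raises(BtopError) as err:
            parse_btop("12AX3")
        assert err.value.offset == 2
        with pytest.raises(BtopError):
            parse_btop("3A")  # dangling edit character

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_random_edits(self, seed):
        """apply(parse(btop)) reconstructs reads with random SNVs and indels."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 90))
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        read = list(ref)
        for _ in range(int(rng.integers(0, 5))):
            p = int(rng.integers(0, len(read)))
            op = rng.integers(0, 3)
            if op == 0:
                read[p] = "ACGT"[rng.integers(0, 4)]
            elif op == 1 and len(read) > 10:
                del read[p]
            else:
                read.insert(p, "ACGT"[rng.integers(0, 4)])
        read = "".join(read)
        btop = _nw_btop(ref, read)
        assert apply_btop(btop, ref) == read
        assert emit_btop(parse_btop(btop)) == btop


def _bare_locus(strand: str, start: int = 100, length: int = 10) -> TRNALocus:
    """Minimal unvalidated locus carcass for coordinate arithmetic."""
    return TRNALocus(
        locus_id="L", chrom="chrN", start=start, end=start + length,
        strand=strand, gene_seq="ACGTACGTAC"[:length], flank5="A" * 20,
        flank3="A" * 5, intron_intervals=(), isotype="Gly", anticodon="GCC",
        high_confidence=True, structure="." * length,
        sprinzl_map=tuple(str(i + 1) for i in range(length)),
    )


class TestToGenomic:
    def test_plus_strand_snv(self):
        locus = _bare_locus("+", start=100)
        assert to_genomic(Edit("snv", 2, "G", "C"), locus) == "chrN:103 G/C"

    def test_minus_strand_mirrors_and_complements(self):
        locus = _bare_locus("-", start=100, length=10)
        # gene-strand A>G at gene_pos 3 -> plus-strand T/C at end - 3
        assert to_genomic(Edit("snv", 3, "A", "G"), locus) == "chrN:107 T/C"

    def test_insertion_renders_dash_alt(self):
        locus = _bare_locus("+", start=100)
        assert to_genomic(Edit("ins", 4, "", "C"), locus) == "chrN:104 -/C"

    def test_deletion_renders_dash_ref(self):
        locus = _bare_locus("+", start=100)
        assert to_genomic(Edit("del", 4, "A", ""), locus) == "chrN:105 A/-"


class TestTrimToGene:
    @pytest.fixture(scope="class")
    def locus(self):
        gene, labels, structure = build_canonical_gene("GCC")
        return TRNALocus(
            locus_id="L", chrom="chr1", start=0, end=len(gene), strand="+",
            gene_seq=gene, flank5="TGACTGACTGACTGACTGAC", flank3="TTGCA",
            intron_intervals=(), isotype="Gly", anticodon="GCC",
            high_confidence=True, structure=structure, sprinzl_map=labels,
        )

    def test_flank_mismatch_dropped(self, locus):
        # substitution at query position 5, inside the 5' flank
        btop = f"5{locus.flank5[5]}A{14 + len(locus.gene_seq) + 5}"
        assert trim_to_gene(btop, locus) == []

    def test_gene_boundary_position_zero(self, locus):
        ref0 = locus.gene_seq[0]
        alt = "A" if ref0 != "A" else "C"
        btop = f"20{ref0}{alt}{len(locus.gene_seq) - 1 + 5}"
        edits = trim_to_gene(btop, locus)
        assert edits == [Edit("snv", 0, ref0, alt)]

    def test_boundary_insertion_dropped(self, locus):
        # insertion between flank5 and gene start is not a gene edit
        btop = f"20-A{len(locus.gene_seq) + 5}"
        assert trim_to_gene(btop, locus) == []

    def test_inner_insertion_kept(self, locus):
        btop = f"30-A{len(locus.gene_seq) - 10 + 5}"
        edits = trim_to_gene(btop, locus)
        assert len(edits) == 1 and edits[0].kind == "ins"

    def test_indels_left_aligned(self):
        gene, labels, structure = build_canonical_gene("GCC")
        # template has CC at Sprinzl 74-75; deleting the second C must
        # normalise onto the first
        locus = TRNALocus(
            locus_id="L", chrom="chr1", start=0, end=len(gene), strand="+",
            gene_seq=gene, flank5="T" * 20, flank3="GGGGG",
            intron_intervals=(), isotype="Gly", anticodon="GCC",
            high_confidence=True, structure=structure, sprinzl_map=labels,
        )
        i = gene.index("CC")
        btop = f"{20 + i + 1}C-{len(gene) - i - 2 + 5}"
        edits = trim_to_gene(btop, locus)
        assert edits == [Edit("del", i, "C", "")]

    def test_apply_edits_reconstructs_gene_allele(self, locus):
        alt = "T" if locus.gene_seq[10] != "T" else "G"
        edits = [Edit("snv", 10, locus.gene_seq[10], alt)]
        var = apply_edits(locus.gene_seq, edits)
        assert var[10] == alt and len(var) == len(locus.gene_seq)


def _genotypes_with_singleton(n_individuals: int, ref: str, var: str):
    gts = {}
    key = ("L1",)
    for i in range(n_individuals):
        ind = f"i{i}"
        if i == 0:
            alleles = (
                GenotypeAllele(ref, (), 1, 30),
                GenotypeAllele(var, (Edit("snv", 0, ref[0], var[0]),), 1, 28),
            )
        else:
            alleles = (GenotypeAllele(ref, (), 2, 60),)
        gts[ind] = {key: Genotype(ind, key, alleles)}
    return gts


class TestCohortAlleleFrequencies:
    @pytest.fixture(scope="class")
    def reference(self):
        gene, labels, structure = build_canonical_gene("GCC")
        return ReferenceSet([
            TRNALocus(
                locus_id="L1", chrom="chr1", start=1000, end=1000 + len(gene),
                strand="+", gene_seq=gene, flank5="T" * 20, flank3="GGGGG",
                intron_intervals=(), isotype="Gly", anticodon="GCC",
                high_confidence=True, structure=structure, sprinzl_map=labels,
            )
        ])

    def test_singleton_in_84_individuals(self, reference):
        """One heterozygote among 84 covered individuals -> AF 1/168 ~ 0.006."""
        ref_seq = reference["L1"].gene_seq
        var_seq = ("A" if ref_seq[0] != "A" else "C") + ref_seq[1:]
        gts = _genotypes_with_singleton(84, ref_seq, var_seq)
        (record,) = cohort_allele_frequencies(gts, reference)
        assert record.carrier_allele_count == 1
        assert record.allele_frequency == pytest.approx(1 / 168)
        assert round(record.allele_frequency, 3) == 0.006

    def test_covered_only_denominator(self, reference):
        """Locus covered in 50 of 84 individuals, 5 carrier alleles -> AF 0.05."""
        ref_seq = reference["L1"].gene_seq
        var_seq = ("A" if ref_seq[0] != "A" else "C") + ref_seq[1:]
        key = ("L1",)
        gts = {}
        for i in range(84):
            ind = f"i{i}"
            if i >= 50:
                gts[ind] = {}  # uncovered
            elif i < 5:
                gts[ind] = {key: Genotype(ind, key, (
                    GenotypeAllele(ref_seq, (), 1, 30),
                    GenotypeAllele(
                        var_seq, (Edit("snv", 0, ref_seq[0], var_seq[0]),), 1, 30
                    ),
                ))}
            else:
                gts[ind] = {key: Genotype(ind, key, (
                    GenotypeAllele(ref_seq, (), 2, 60),
                ))}
        (record,) = cohort_allele_frequencies(gts, reference)
        assert record.n_covered_individuals == 50
        assert record.allele_frequency == pytest.approx(5 / 100)

    def test_af_sums_to_one_with_reference(self, reference):
        """Carrier + reference allele counts exhaust 2 x covered individuals."""
        ref_seq = reference["L1"].gene_seq
        var_a = ("A" if ref_seq[0] != "A" else "C") + ref_seq[1:]
        var_b = ref_seq[:5] + ("G" if ref_seq[5] != "G" else "T") + ref_seq[6:]
        key = ("L1",)
        gts = {}
        for i in range(10):
            ind = f"i{i}"
            if i < 3:
                alleles = (
                    GenotypeAllele(var_a, (Edit("snv", 0, ref_seq[0], var_a[0]),), 2, 60),
                )
            elif i < 5:
                alleles = (
                    GenotypeAllele(ref_seq, (), 1, 30),
                    GenotypeAllele(var_b, (Edit("snv", 5, ref_seq[5], var_b[5]),), 1, 30),
                )
            else:
                alleles = (GenotypeAllele(ref_seq, (), 2, 60),)
            gts[ind] = {key: Genotype(ind, key, alleles)}
        records = cohort_allele_frequencies(gts, reference)
        total_carriers = sum(r.carrier_allele_count for r in records)
        assert sum(r.allele_frequency for r in records) + (20 - total_carriers) / 20 == 1

    def test_multi_edit_allele_is_one_record(self, reference):
        """An allele with two SNVs is one variant, not two records."""
        ref_seq = reference["L1"].gene_seq
        e1 = Edit("snv", 0, ref_seq[0], "A" if ref_seq[0] != "A" else "C")
        e2 = Edit("snv", 9, ref_seq[9], "A" if ref_seq[9] != "A" else "C")
        var = apply_edits(ref_seq, (e1, e2))
        key = ("L1",)
        gts = {"i0": {key: Genotype("i0", key, (
            GenotypeAllele(ref_seq, (), 1, 30),
            GenotypeAllele(var, (e1, e2), 1, 30),
        ))}}
        records = cohort_allele_frequencies(gts, reference)
        assert len(records) == 1
        assert records[0].n_edits == 2
        assert len(records[0].descriptors) == 2
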