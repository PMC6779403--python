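"""Worked-example catalogs of published human tRNA gene variants.

Two small curated sets of variants reported from capture sequencing of
human tRNA genes in an 84-individual cohort:

* 18 anticodon-substitution variants (6 synonymous, 12 changing the
  decoded identity, including two turned toward stop codons);
* 6 variants creating the G3:U70 alanyl-tRNA synthetase identity element
  in glycine tRNAs (three as single mutations, three alongside a second
  edit or an insertion).

The genomic descriptors, allele frequencies, Sprinzl positions, anticodon
identities and confidence flags are the published values (GRCh37/hg19
coordinates).  The gene models returned by :func:`g3u70_gene_models` and
:func:`anticodon_gene_models` are *synthetic stand-ins*: canonical-template
cloverleaf sequences whose strand, coordinates, anticodon and the bases
touched by each variant are made consistent with the published
descriptors, so the annotation/classification stack can be exercised
end-to-end without the licensed genome sequence.  Published coordinate
arithmetic fixes the Sprinzl maps of the glycine models (they lack
positions 17 and 47).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allele_calling import Edit
from .reference_model import (
    FLANK3_LEN,
    FLANK5_LEN,
    ReferenceSet,
    TRNALocus,
    build_canonical_gene,
)


@dataclass(frozen=True)
class AnticodonVariantEntry:
    """One published anticodon-substitution variant."""

    loci: tuple[str, ...]
    descriptors: tuple[str, ...]
    allele_frequency: float
    positions: tuple[str, ...]  # Sprinzl labels of all edits on the allele
    wt_anticodon: str
    wt_identity: str
    var_anticodon: str
    var_identity: str
    synonymous: bool
    high_confidence: bool


ANTICODON_VARIANTS: tuple[AnticodonVariantEntry, ...] = (
    # synonymous
    AnticodonVariantEntry(("tRNA-Asn-GTT-2-3",), ("chr10:22518477 C/T",),
                          0.006, ("34",), "GTT", "Asn", "ATT", "Asn", True, True),
    AnticodonVariantEntry(("tRNA-Asn-GTT-2-6",), ("chr19:1383596 G/A",),
                          0.012, ("34",), "GTT", "Asn", "ATT", "Asn", True, True),
    AnticodonVariantEntry(("tRNA-Asn-GTT-15-1",), ("chr1:149284542 C/T",),
                          0.006, ("34",), "GTT", "Asn", "ATT", "Asn", True, False),
    AnticodonVariantEntry(("tRNA-Gly-GCC-2-2",), ("chr2:157257697 C/T",),
                          0.006, ("34",), "GCC", "Gly", "ACC", "Gly", True, True),
    AnticodonVariantEntry(("tRNA-Lys-TTT-7-1",),
                          ("chr6:28715537 T/C", "chr6:28715554 T/C",
                           "chr6:28715564 C/G"),
                          0.006, ("17", "34", "44"), "TTT", "Lys", "CTT", "Lys",
                          True, True),
    AnticodonVariantEntry(("tRNA-Arg-CCT-5-1",),
                          ("chr16:3243922 C/A", "chr16:3243942 T/C",
                           "chr16:3243951 C/T"),
                          0.307, ("5", "25", "34"), "CCT", "Arg", "TCT", "Arg",
                          True, True),
    # non-synonymous
    AnticodonVariantEntry(("tRNA-Thr-AGT-5-1",), ("chr17:8042808 C/T",),
                          0.006, ("35",), "AGT", "Thr", "AAT", "Ile", False, True),
    AnticodonVariantEntry(("tRNA-Ser-AGA-2-3",), ("chr6:27463627 G/A",),
                          0.030, ("35",), "AGA", "Ser", "AAA", "Phe", False, True),
    AnticodonVariantEntry(("tRNA-Asp-GTC-3-1",), ("chr6:27551273 A/T",),
                          0.006, ("35",), "GTC", "Asp", "GAC", "Val", False, True),
    AnticodonVariantEntry(("tRNA-Val-AAC-6-1",), ("chr6:28703244 T/C",),
                          0.536, ("35",), "AAC", "Val", "AGC", "Ala", False, True),
    AnticodonVariantEntry(("tRNA-Ala-AGC-6-1",), ("chr6:28779887 C/G",),
                          0.085, ("35",), "AGC", "Ala", "ACC", "Gly", False, True),
    AnticodonVariantEntry(("tRNA-Cys-GCA-10-1",), ("chr7:149074639 G/A",),
                          0.006, ("35",), "GCA", "Cys", "GTA", "Tyr", False, True),
    AnticodonVariantEntry(("tRNA-Arg-TCG-6-1",), ("chr9:112960837 C/T",),
                          0.006, ("35",), "TCG", "Arg", "TTG", "Gln", False, True),
    AnticodonVariantEntry(("tRNA-Gly-TCC-2-6",), ("chr1:161500938 C/A",),
                          0.006, ("36",), "TCC", "Gly", "TCA", "STOP", False, True),
    AnticodonVariantEntry(("tRNA-Gly-TCC-2-6",), ("chr1:161500938 C/G",),
                          0.006, ("36",), "TCC", "Gly", "TCG", "Arg", False, True),
    AnticodonVariantEntry(("tRNA-Ala-AGC-18-1", "tRNA-Ala-AGC-18-2"),
                          ("chr6:26728291 C/T",),
                          0.003, ("36",), "AGC", "Ala", "AGT", "Thr", False, False),
    AnticodonVariantEntry(("tRNA-Cys-GCA-chr8-6",), ("chr8:111946808 A/G",),
                          0.015, ("36",), "GCA", "Cys", "GCG", "Arg", False, False),
    AnticodonVariantEntry(("tRNA-Ser-ACT-1-1",),
                          ("chr6:27261700 C/G", "chr6:27261706 C/T"),
                          0.024, ("29", "35"), "ACT", "Ser", "ATT", "Asn",
                          False, False),
)


@dataclass(frozen=True)
class G3U70VariantEntry:
    """One published variant creating a G3:U70 pair in a glycine tRNA."""

    locus: str
    descriptors: tuple[str, ...]
    allele_frequency: float
    positions: tuple[str, ...]
    high_confidence: bool


G3U70_VARIANTS: tuple[G3U70VariantEntry, ...] = (
    G3U70VariantEntry("tRNA-Gly-CCC-1-1", ("chr1:16872502 T/C",),
                      0.052, ("3",), True),
    G3U70VariantEntry("tRNA-Gly-CCC-5-1", ("chr1:17053782 C/G",),
                      0.215, ("3",), False),
    G3U70VariantEntry("tRNA-Gly-GCC-1-5", ("chr21:18827175 T/C",),
                      0.012, ("3",), True),
    G3U70VariantEntry("tRNA-Gly-CCC-1-1",
                      ("chr1:16872502 T/C", "chr1:16872448 A/G"),
                      0.046, ("3", "59"), True),
    G3U70VariantEntry("tRNA-Gly-CCC-5-1",
                      ("chr1:17053782 C/G", "chr1:17053826 C/T"),
                      0.058, ("3", "49"), False),
    G3U70VariantEntry("tRNA-Gly-CCC-5-1",
                      ("chr1:17053782 C/G", "chr1:17053835 -/C"),
                      0.012, ("3", "58"), False),
)


def _synthetic_flanks(seed: int) -> tuple[str, str]:
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    f5 = "".join(bases[i] for i in rng.integers(0, 4, FLANK5_LEN))
    f3 = "".join(bases[i] for i in rng.integers(0, 4, FLANK3_LEN))
    return f5, f3


def _make_locus(
    locus_id: str,
    chrom: str,
    strand: str,
    anchor_1based: int,
    anchor_label: str,
    anticodon: str,
    isotype: str,
    high_confidence: bool,
    overrides: dict[str, str] | None = None,
    missing: tuple[str, ...] = (),
    n_e: int = 0,
    flank_seed: int = 0,
) -> TRNALocus:
    """Synthetic stand-in gene model anchored on one published coordinate.

    ``anchor_1based`` is the published plus-strand position of the base at
    Sprinzl ``anchor_label``; start/end are back-computed from it so every
    edit at a mapped Sprinzl position reproduces its published descriptor.
    """
    gene, labels, structure = build_canonical_gene(
        anticodon, missing=missing, n_e=n_e, overrides=overrides or {}
    )
    idx = {lab: i for i, lab in enumerate(labels)}
    gene_pos = idx[anchor_label]
    if strand == "+":
        start = anchor_1based - 1 - gene_pos
        end = start + len(gene)
    else:
        end = anchor_1based + gene_pos
        start = end - len(gene)
    f5, f3 = _synthetic_flanks(flank_seed)
    return TRNALocus(
        locus_id=locus_id, chrom=chrom, start=start, end=end, strand=strand,
        gene_seq=gene, flank5=f5, flank3=f3, intron_intervals=(),
        isotype=isotype, anticodon=anticodon,
        high_confidence=high_confidence, structure=structure,
        sprinzl_map=labels,
    )


def g3u70_gene_models() -> ReferenceSet:
    """Synthetic stand-in models for the three glycine loci.

    Acceptor-stem composition follows the published variants: A3:U70 for
    tRNA-Gly-CCC-1-1 / tRNA-Gly-GCC-1-5 and a C3:U70 mismatch for
    tRNA-Gly-CCC-5-1; the published coordinate spacing implies Sprinzl
    positions 17 and 47 are absent from these genes.
    """
    missing = ("17", "47")
    return ReferenceSet(
        [
            _make_locus(
                "tRNA-Gly-CCC-1-1", "chr1", "-", 16872502, "3", "CCC", "Gly",
                True, overrides={"3": "A"}, missing=missing, flank_seed=11,
            ),
            _make_locus(
                "tRNA-Gly-CCC-5-1", "chr1", "+", 17053782, "3", "CCC", "Gly",
                False, overrides={"3": "C", "70": "T"}, missing=missing,
                flank_seed=12,
            ),
            _make_locus(
                "tRNA-Gly-GCC-1-5", "chr21", "-", 18827175, "3", "GCC", "Gly",
                True, overrides={"3": "A"}, missing=missing, flank_seed=13,
            ),
        ]
    )


def g3u70_variant_edits(
    models: ReferenceSet | None = None,
) -> list[tuple[G3U70VariantEntry, TRNALocus, tuple[Edit, ...]]]:
    """Gene-coordinate edits for every published G3:U70 variant."""
    models = models or g3u70_gene_models()
    out = []
    for entry in G3U70_VARIANTS:
        locus = models[entry.locus]
        idx = locus.label_index
        edits = []
        for label in entry.positions:
            if label == "3":
                pos = idx["3"]
                edits.append(Edit("snv", pos, locus.gene_seq[pos], "G"))
            elif label == "58" and entry.descriptors[-1].endswith("-/C"):
                # insertion immediately 3' of Sprinzl 58
                pos = idx["58"] + 1
                edits.append(Edit("ins", pos, "", "C"))
            else:
                pos = idx[label]
                ref = locus.gene_seq[pos]
                # published plus-strand alt, mapped to the gene strand
                alt = {"59": "C", "49": "T"}[label]
                edits.append(Edit("snv", pos, ref, alt))
        out.append((entry, locus, tuple(edits)))
    return out


_ALT_CYCLE = {"A": "G", "C": "T", "G": "A", "T": "C"}


def anticodon_gene_models() -> ReferenceSet:
    """Synthetic stand-in models for the anticodon-variant loci.

    One model per distinct first locus id; serine loci carry the long
    variable arm.  Coordinates are placeholders (the anticodon catalog is
    exercised for classification and annotation, not descriptor output).
    """
    loci = []
    seen = set()
    cursor = 10_000
    for i, entry in enumerate(ANTICODON_VARIANTS):
        locus_id = entry.loci[0]
        if locus_id in seen:
            continue
        seen.add(locus_id)
        isotype = locus_id.split("-")[1]
        n_e = 8 if isotype in ("Ser", "Leu", "SeC") else 0
        gene, labels, structure = build_canonical_gene(
            entry.wt_anticodon, n_e=n_e
        )
        f5, f3 = _synthetic_flanks(100 + i)
        chrom = entry.descriptors[0].split(":")[0]
        loci.append(
            TRNALocus(
                locus_id=locus_id, chrom=chrom, start=cursor,
                end=cursor + len(gene), strand="+", gene_seq=gene,
                flank5=f5, flank3=f3, intron_intervals=(),
                isotype=isotype, anticodon=entry.wt_anticodon,
                high_confidence=entry.high_confidence,
                structure=structure, sprinzl_map=labels,
            )
        )
        cursor += 10_000
    return ReferenceSet(loci)


def anticodon_variant_edits(
    models: ReferenceSet | None = None,
) -> list[tuple[AnticodonVariantEntry, TRNALocus, tuple[Edit, ...]]]:
    """Gene-coordinate edits for every published anticodon variant.

    The anticodon edit substitutes the differing base between the wild-type
    and variant anticodons; additional edits on multi-edit alleles are
    placed at their published Sprinzl positions (stand-in alt bases).
    """
    models = models or anticodon_gene_models()
    out = []
    for entry in ANTICODON_VARIANTS:
        locus = models[entry.loci[0]]
        idx = locus.label_index
        edits = []
        for label in entry.positions:
            pos = idx[label]
            ref = locus.gene_seq[pos]
            if label in ("34", "35", "36"):
                offset = int(label) - 34
                alt = entry.var_anticodon[offset]
                assert entry.wt_anticodon[offset] == ref
            else:
                alt = _ALT_CYCLE[ref]
            edits.append(Edit("snv", pos, ref, alt))
        out.append((entry, locus, tuple(edits)))
    return out
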