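"""Variant calling from full-length allele alignments.

Converts retained per-individual alleles into cohort-level variant records:
parses and emits BLAST trace-back operation (btop) edit strings, trims
flank-extended alignments to the gene body, expresses edits in gene and
genomic coordinates, and computes cohort allele frequencies.

btop convention (BLAST+, with the *reference query* as the BLAST query and
the read as the subject): integers are match-run lengths; a two-character
pair is ``(reference base, read base)``; a dash marks the gapped side, so a
base deleted from the read is ``"C-"`` and a base inserted in the read is
``"-C"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference_model import (
    FLANK5_LEN,
    ReferenceSet,
    TRNALocus,
    reverse_complement,
)

_BTOP_BASES = frozenset("ACGTN-")

MATCH = "="  # op tag for match runs


class BtopError(ValueError):
    """Malformed btop string; carries the character offset of the defect."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


# one alignment column: (ref_char, read_char), '-' on the gapped side
Column = tuple[str, str]


def parse_btop(btop: str) -> list[Column]:
    """Tokenise a btop string into (ref, read) operations.

    Match runs stay run-length encoded as ``("=", "<n>")`` entries; edit
    columns are explicit ``(ref_char, read_char)`` pairs with ``"-"`` on the
    gapped side.
    """
    ops: list[Column] = []
    i = 0
    n = len(btop)
    while i < n:
        ch = btop[i]
        if ch.isdigit():
            j = i
            while j < n and btop[j].isdigit():
                j += 1
            ops.append((MATCH, btop[i:j]))
            i = j
        else:
            if i + 1 >= n:
                raise BtopError("dangling edit character", i)
            ref_c, read_c = btop[i], btop[i + 1]
            if ref_c not in _BTOP_BASES or read_c not in _BTOP_BASES:
                raise BtopError(f"bad edit pair {btop[i:i + 2]!r}", i)
            if ref_c == "-" and read_c == "-":
                raise BtopError("edit pair cannot be gap on both sides", i)
            ops.append((ref_c, read_c))
            i += 2
    return ops


def emit_btop(ops: Iterable[Column]) -> str:
    """Inverse of :func:`parse_btop`; merges adjacent match runs."""
    parts: list[str] = []
    pending = 0
    for ref_c, read_c in ops:
        if ref_c == MATCH:
            pending += int(read_c)
            continue
        if pending:
            parts.append(str(pending))
            pending = 0
        parts.append(ref_c + read_c)
    if pending:
        parts.append(str(pending))
    return "".join(parts)


def btop_from_alignment(ref_aligned: str, read_aligned: str) -> str:
    """btop for a pair of gapped, equal-length alignment rows."""
    if len(ref_aligned) != len(read_aligned):
        raise ValueError("alignment rows differ in length")
    ops: list[Column] = []
    run = 0
    for r, q in zip(ref_aligned, read_aligned):
        if r == q and r != "-":
            run += 1
            continue
        if run:
            ops.append((MATCH, str(run)))
            run = 0
        ops.append((r, q))
    if run:
        ops.append((MATCH, str(run)))
    return emit_btop(ops)


def apply_btop(ops: list[Column] | str, ref: str) -> str:
    """Replay a btop against the reference, reconstructing the read."""
    if isinstance(ops, str):
        ops = parse_btop(ops)
    out: list[str] = []
    pos = 0
    for ref_c, read_c in ops:
        if ref_c == MATCH:
            n = int(read_c)
            out.append(ref[pos:pos + n])
            pos += n
        elif ref_c == "-":          # insertion in read
            out.append(read_c)
        elif read_c == "-":         # deletion from read
            pos += 1
        else:                       # substitution
            out.append(read_c)
            pos += 1
    if pos > len(ref):
        raise BtopError("btop overruns the reference", len(ref))
    return "".join(out)


def btop_ref_span(ops: list[Column] | str) -> int:
    """Number of reference positions consumed by a btop."""
    if isinstance(ops, str):
        ops = parse_btop(ops)
    span = 0
    for ref_c, read_c in ops:
        if ref_c == MATCH:
            span += int(read_c)
        elif ref_c != "-":
            span += 1
    return span


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edit:
    """One difference from the reference gene, in gene coordinates.

    ``gene_pos`` is 0-based on the reference gene.  For insertions it is the
    gene position *before which* the bases are inserted and ``ref_bases`` is
    empty; for deletions ``alt_bases`` is empty.
    """

    kind: str  # "snv" | "ins" | "del"
    gene_pos: int
    ref_bases: str
    alt_bases: str
    sprinzl: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "snv":
            if len(self.ref_bases) != 1 or len(self.alt_bases) != 1:
                raise ValueError("snv must have single ref and alt base")
        elif self.kind == "ins":
            if self.ref_bases or not self.alt_bases:
                raise ValueError("ins must have empty ref and non-empty alt")
        elif self.kind == "del":
            if self.alt_bases or not self.ref_bases:
                raise ValueError("del must have empty alt and non-empty ref")
        else:
            raise ValueError(f"unknown edit kind {self.kind!r}")


def apply_edits(gene_seq: str, edits: Sequence[Edit]) -> str:
    """Apply gene-coordinate edits to a reference gene sequence."""
    seq = gene_seq
    for e in sorted(edits, key=lambda e: e.gene_pos, reverse=True):
        if e.kind == "snv":
            if seq[e.gene_pos] != e.ref_bases:
                raise ValueError(
                    f"edit ref base {e.ref_bases} != sequence base "
                    f"{seq[e.gene_pos]} at {e.gene_pos}"
                )
            seq = seq[:e.gene_pos] + e.alt_bases + seq[e.gene_pos + 1:]
        elif e.kind == "ins":
            seq = seq[:e.gene_pos] + e.alt_bases + seq[e.gene_pos:]
        else:
            end = e.gene_pos + len(e.ref_bases)
            if seq[e.gene_pos:end] != e.ref_bases:
                raise ValueError("deletion ref bases do not match sequence")
            seq = seq[:e.gene_pos] + seq[end:]
    return seq


def variant_position_map(gene_len: int, edits: Sequence[Edit]) -> list[int | None]:
    """Reference gene position -> variant sequence position (None = deleted)."""
    mapping: list[int | None] = [None] * gene_len
    shift = 0
    deleted: set[int] = set()
    ins_at: dict[int, int] = {}
    for e in edits:
        if e.kind == "del":
            deleted.update(range(e.gene_pos, e.gene_pos + len(e.ref_bases)))
        elif e.kind == "ins":
            ins_at[e.gene_pos] = ins_at.get(e.gene_pos, 0) + len(e.alt_bases)
    var_pos = 0
    for p in range(gene_len):
        var_pos += ins_at.get(p, 0)
        if p in deleted:
            mapping[p] = None
        else:
            mapping[p] = var_pos
            var_pos += 1
    return mapping


def _left_align(edit: Edit, gene_seq: str) -> Edit:
    """Shift an indel left while the flanking base equals its last base."""
    if edit.kind == "snv":
        return edit
    pos, bases = edit.gene_pos, (edit.alt_bases or edit.ref_bases)
    while pos > 0 and gene_seq[pos - 1] == bases[-1]:
        bases = gene_seq[pos - 1] + bases[:-1]
        pos -= 1
    if edit.kind == "ins":
        return replace(edit, gene_pos=pos, alt_bases=bases)
    return replace(edit, gene_pos=pos, ref_bases=bases)


def trim_to_gene(
    btop: str | list[Column],
    locus: TRNALocus,
    flank5_len: int = FLANK5_LEN,
) -> list[Edit]:
    """Edits within the gene body from a full-query btop.

    Walks the btop over the flank-extended query; differences falling in the
    flanks are dropped.  Insertions at a flank/gene boundary are kept only
    when flanked by gene bases on both sides.  Runs of adjacent same-kind
    columns merge into one edit; indels are left-aligned within the gene.
    """
    if isinstance(btop, str):
        btop = parse_btop(btop)
    gene_len = len(locus.gene_seq)
    edits: list[Edit] = []
    qpos = 0  # query (flank-extended reference) coordinate

    def gene_pos(q: int) -> int | None:
        g = q - flank5_len
        return g if 0 <= g < gene_len else None

    for ref_c, read_c in btop:
        if ref_c == MATCH:
            qpos += int(read_c)
        elif ref_c == "-":  # insertion in read, before query position qpos
            left, right = gene_pos(qpos - 1), gene_pos(qpos)
            if left is not None and right is not None:
                g = right
                if edits and edits[-1].kind == "ins" and edits[-1].gene_pos == g:
                    edits[-1] = replace(
                        edits[-1], alt_bases=edits[-1].alt_bases + read_c
                    )
                else:
                    edits.append(Edit("ins", g, "", read_c))
        elif read_c == "-":  # deletion from read
            g = gene_pos(qpos)
            if g is not None:
                if (
                    edits
                    and edits[-1].kind == "del"
                    and edits[-1].gene_pos + len(edits[-1].ref_bases) == g
                ):
                    edits[-1] = replace(
                        edits[-1], ref_bases=edits[-1].ref_bases + ref_c
                    )
                else:
                    edits.append(Edit("del", g, ref_c, ""))
            qpos += 1
        else:  # substitution
            g = gene_pos(qpos)
            if g is not None:
                edits.append(Edit("snv", g, ref_c, read_c))
            qpos += 1

    edits = [_left_align(e, locus.gene_seq) for e in edits]
    return sorted(edits, key=lambda e: (e.gene_pos, e.kind))


def to_genomic(edit: Edit, locus: TRNALocus) -> str:
    """Printed-style genomic descriptor, 1-based plus strand.

    Substitutions and deletions report the 1-based plus-strand coordinate of
    the (first) affected base; insertions report the plus-strand base
    immediately 5' (in gene orientation) of the insertion point and render
    as ``-/X``.  Minus-strand loci have ref/alt reverse-complemented.
    """
    if locus.strand == "+":
        if edit.kind == "ins":
            pos1 = locus.start + edit.gene_pos  # base before the insertion
        else:
            pos1 = locus.start + edit.gene_pos + 1
        ref, alt = edit.ref_bases, edit.alt_bases
    else:
        if edit.kind == "ins":
            pos1 = locus.end - edit.gene_pos + 1
        elif edit.kind == "del":
            pos1 = locus.end - (edit.gene_pos + len(edit.ref_bases) - 1)
        else:
            pos1 = locus.end - edit.gene_pos
        ref = reverse_complement(edit.ref_bases) if edit.ref_bases else ""
        alt = reverse_complement(edit.alt_bases) if edit.alt_bases else ""
    return f"{locus.chrom}:{pos1} {ref or '-'}/{alt or '-'}"


# ---------------------------------------------------------------------------
# Cohort variant records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeAllele:
    """One retained allele of one individual at one locus (or group)."""

    gene_seq: str
    edits: tuple[Edit, ...]
    allele_count: int  # 2 if homozygous, else 1
    depth: int

    @property
    def is_reference(self) -> bool:
        return not self.edits


@dataclass
class Genotype:
    """Depth-filtered diploid genotype of one individual at one locus key."""

    individual: str
    locus_key: tuple[str, ...]
    alleles: tuple[GenotypeAllele, ...]
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class VariantRecord:
    """A cohort-level unique variant allele.

    Identity is the whole variant gene sequence: alleles sharing one SNV but
    differing at a second position are distinct records.
    """

    locus_key: tuple[str, ...]
    edits: tuple[Edit, ...]
    descriptors: tuple[str, ...]
    allele_frequency: float
    carrier_allele_count: int
    n_covered_individuals: int
    gene_seq: str

    @property
    def n_edits(self) -> int:
        return len(self.edits)


CohortGenotypes = Mapping[str, Mapping[tuple[str, ...], Genotype]]


def cohort_allele_frequencies(
    genotypes: CohortGenotypes,
    reference: ReferenceSet,
) -> list[VariantRecord]:
    """Aggregate per-individual genotypes into cohort variant records.

    For each locus (or ambiguity group, treated as one compound locus) the
    denominator is the total number of alleles observed there: 2 x the
    number of individuals with a retained genotype.  AF = carrier allele
    count / total alleles, so one heterozygote among 84 covered individuals
    gives 1/168 ~ 0.006.
    """
    per_key: dict[tuple[str, ...], dict[str, list[GenotypeAllele]]] = {}
    for ind, by_key in genotypes.items():
        for key, gt in by_key.items():
            per_key.setdefault(key, {})[ind] = list(gt.alleles)

    records: list[VariantRecord] = []
    for key in sorted(per_key):
        by_ind = per_key[key]
        n_cov = len(by_ind)
        carriers: dict[str, tuple[tuple[Edit, ...], int]] = {}
        for alleles in by_ind.values():
            for al in alleles:
                if al.is_reference:
                    continue
                prev = carriers.get(al.gene_seq)
                count = al.allele_count + (prev[1] if prev else 0)
                carriers[al.gene_seq] = (al.edits, count)
        anchor = reference[key[0]]
        for seq in sorted(carriers):
            edits, count = carriers[seq]
            records.append(
                VariantRecord(
                    locus_key=key,
                    edits=edits,
                    descriptors=tuple(to_genomic(e, anchor) for e in edits),
                    allele_frequency=count / (2 * n_cov),
                    carrier_allele_count=count,
                    n_covered_individuals=n_cov,
                    gene_seq=seq,
                )
            )
    return records


def variants_to_table(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Variant records as a tidy table (one row per unique variant allele)."""
    rows = []
    for r in records:
        rows.append(
            {
                "locus": "|".join(r.locus_key),
                "descriptors": "; ".join(r.descriptors),
                "n_edits": r.n_edits,
                "edits": ";".join(
                    f"{e.kind}@{e.gene_pos}:{e.ref_bases or '-'}>{e.alt_bases or '-'}"
                    for e in r.edits
                ),
                "allele_frequency": r.allele_frequency,
                "carrier_allele_count": r.carrier_allele_count,
                "n_covered_individuals": r.n_covered_individuals,
                "gene_seq": r.gene_seq,
            }
        )
    return pd.DataFrame(rows)
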