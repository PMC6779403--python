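"""End-to-end pipeline: read pairs -> merged reads -> locus assignment ->
depth-filtered alleles -> diploid genotypes -> cohort variant records.

This is the programmatic equivalent of running merge / map / call in
sequence, holding everything in memory; the CLI wraps these functions for
file-based use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .allele_calling import (
    CohortGenotypes,
    Genotype,
    GenotypeAllele,
    VariantRecord,
    apply_edits,
    cohort_allele_frequencies,
    trim_to_gene,
)
from .locus_assignment import (
    DEFAULT_MIN_DEPTH,
    DEFAULT_MIN_IDENTITY,
    DiploidCall,
    LocusAssignment,
    QueryIndex,
    collapse_alleles,
    genotype_locus,
)
from .read_processing import (
    DEFAULT_MAX_MISMATCH_FRAC,
    DEFAULT_MIN_OVERLAP,
    MergedRead,
    ReadPair,
    merge_pairs,
)
from .reference_model import FLANK3_LEN, FLANK5_LEN, ReferenceSet


@dataclass
class PipelineConfig:
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_depth: int = DEFAULT_MIN_DEPTH
    flank5_len: int = FLANK5_LEN
    flank3_len: int = FLANK3_LEN


@dataclass
class CohortResult:
    """Everything the pipeline produced for one cohort."""

    genotypes: dict[str, dict[tuple[str, ...], Genotype]]
    variants: list[VariantRecord]
    assignments: dict[str, list[LocusAssignment]]
    warnings: list[str] = field(default_factory=list)

    def assignment_counts(self) -> dict[str, int]:
        counts = {"unique": 0, "ambiguous": 0, "unmapped": 0}
        for per_ind in self.assignments.values():
            for a in per_ind:
                counts[a.status] += 1
        return counts


def _diploid_to_genotype(
    call: DiploidCall,
    individual: str,
    reference: ReferenceSet,
    flank5_len: int,
) -> Genotype:
    """Trim alleles to the gene body and aggregate per gene sequence.

    Two full-span alleles that differ only in flank bases collapse to the
    same gene-level allele; their allele counts add (an individual whose
    two haplotypes agree over the gene body is homozygous there).
    """
    anchor = reference[call.locus_key[0]]
    by_seq: dict[str, GenotypeAllele] = {}
    for allele, count in zip(call.alleles, call.counts):
        edits = tuple(trim_to_gene(allele.btop, anchor, flank5_len))
        gene_seq = apply_edits(anchor.gene_seq, edits)
        prev = by_seq.get(gene_seq)
        if prev is None:
            by_seq[gene_seq] = GenotypeAllele(
                gene_seq=gene_seq, edits=edits,
                allele_count=count, depth=allele.depth,
            )
        else:
            by_seq[gene_seq] = GenotypeAllele(
                gene_seq=gene_seq, edits=prev.edits,
                allele_count=prev.allele_count + count,
                depth=prev.depth + allele.depth,
            )
    alleles = tuple(
        sorted(by_seq.values(), key=lambda a: (-a.allele_count, a.gene_seq))
    )
    warnings = (call.warning,) if call.warning else ()
    return Genotype(
        individual=individual, locus_key=call.locus_key,
        alleles=alleles, warnings=warnings,
    )


def genotype_individual(
    merged: Sequence[MergedRead],
    index: QueryIndex,
    individual: str,
    reference: ReferenceSet,
    config: PipelineConfig,
) -> tuple[dict[tuple[str, ...], Genotype], list[LocusAssignment], list[str]]:
    """Assign one individual's merged reads and genotype every covered locus."""
    assignments = index.assign_all(merged)
    alleles = collapse_alleles(assignments, individual, min_depth=config.min_depth)
    genotypes: dict[tuple[str, ...], Genotype] = {}
    warnings: list[str] = []
    for key, calls in alleles.items():
        diploid = genotype_locus(calls)
        if diploid is None:
            continue
        gt = _diploid_to_genotype(diploid, individual, reference, config.flank5_len)
        genotypes[key] = gt
        warnings.extend(gt.warnings)
    return genotypes, assignments, warnings


def run_cohort(
    reads_by_individual: Mapping[str, Sequence[ReadPair]],
    reference: ReferenceSet,
    config: PipelineConfig | None = None,
) -> CohortResult:
    """Run the full pipeline over a cohort of paired-end read sets."""
    config = config or PipelineConfig()
    queries = reference.queries(config.flank5_len, config.flank3_len)
    index = QueryIndex(queries, min_identity=config.min_identity)

    all_genotypes: dict[str, dict[tuple[str, ...], Genotype]] = {}
    all_assignments: dict[str, list[LocusAssignment]] = {}
    warnings: list[str] = []
    for individual, pairs in reads_by_individual.items():
        merged = merge_pairs(
            pairs,
            min_overlap=config.min_overlap,
            max_mismatch_frac=config.max_mismatch_frac,
        )
        genotypes, assignments, warns = genotype_individual(
            merged, index, individual, reference, config
        )
        all_genotypes[individual] = genotypes
        all_assignments[individual] = assignments
        warnings.extend(warns)

    variants = cohort_allele_frequencies(all_genotypes, reference)
    return CohortResult(
        genotypes=all_genotypes,
        variants=variants,
        assignments=all_assignments,
        warnings=warnings,
    )
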