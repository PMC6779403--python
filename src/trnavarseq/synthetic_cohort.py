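"""Synthetic reference sets, diploid cohorts and paired-end reads.

Generates everything the downstream pipeline consumes, so the whole stack
is testable without any external download:

* a reference locus set organised into isodecoder families, including
  gene-body-identical locus pairs distinguishable only by their 5' flanks;
* a diploid cohort with variant alleles planted at a stated allele-
  frequency spectrum, some alleles carrying 2-4 edits (multi-SNP alleles);
* overlapping paired-end reads at a target coverage with a small iid
  per-base substitution error rate.

Defaults emulate the capture-sequencing study conditions at desk scale:
isodecoder families with ~20% of loci in gene-body-identical pairs, an AF
spectrum with 76% uncommon (<5%), 20% intermediate (5-50%) and 4% common
(>50%) variants, 87/10/2.5/0.5% of variants carrying 1/2/3/4 edits, ~3%
indel edits, 60x coverage and 0.2% per-base error.  Carriers arise by
Hardy-Weinberg sampling of two alleles per individual, so homozygotes
appear naturally.  Sequencing errors are substitutions only; planted
indels are the only source of gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allele_calling import Edit, apply_edits
from .read_processing import ReadPair
from .reference_model import (
    FLANK3_LEN,
    FLANK5_LEN,
    ReferenceSet,
    TRNALocus,
    build_canonical_gene,
    dot_bracket_pairing,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

# isotype/anticodon inventory cycled over when building families; feature
# flags give structural variety (long variable arm, D-loop 17a, intron)
_FAMILY_TYPES: tuple[tuple[str, str, dict], ...] = (
    ("Gly", "GCC", {"has_17a": True}),
    ("Ala", "AGC", {}),
    ("Ser", "AGA", {"n_e": 8}),
    ("Asn", "GTT", {}),
    ("Val", "AAC", {}),
    ("Arg", "TCG", {}),
    ("Thr", "AGT", {}),
    ("Gly", "CCC", {}),
    ("Leu", "CAA", {"n_e": 8}),
    ("Asp", "GTC", {}),
    ("Tyr", "GTA", {"intron": True}),
    ("Lys", "TTT", {}),
    ("Cys", "GCA", {}),
    ("Phe", "GAA", {}),
    ("iMet", "CAT", {}),
    ("SeC", "TCA", {"n_e": 8}),
)

# isotypes for which decode_anticodon(anticodon) need not equal the isotype
ISOTYPE_EXEMPT = frozenset({"Und", "SeC", "iMet"})


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults are the study conditions at desk scale."""

    n_individuals: int = 30
    n_loci: int = 20
    identical_pair_fraction: float = 0.2
    max_family_size: int = 3
    archetype_divergence: int = 4   # substitutions from template per family
    member_divergence: tuple[int, int] = (1, 3)  # per non-identical member
    af_bin_probs: tuple[float, float, float] = (0.76, 0.20, 0.04)
    af_bin_ranges: tuple[tuple[float, float], ...] = (
        (0.008, 0.05), (0.05, 0.5), (0.5, 0.9),
    )
    edit_count_probs: tuple[float, ...] = (0.87, 0.10, 0.025, 0.005)
    indel_fraction: float = 0.03
    variants_per_locus_probs: tuple[float, ...] = (0.45, 0.35, 0.20)
    coverage_mean: float = 60.0
    read_length: int = 100
    fragment_length: int = 150
    error_rate: float = 0.002
    context_len: int = 60
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (
            ("af_bin_probs", self.af_bin_probs),
            ("edit_count_probs", self.edit_count_probs),
            ("variants_per_locus_probs", self.variants_per_locus_probs),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in probs):
                raise ValueError(f"{name} must be non-negative")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("n_individuals and n_loci must be >= 1")
        if not 0 <= self.identical_pair_fraction <= 1:
            raise ValueError("identical_pair_fraction must be in [0, 1]")
        if self.identical_pair_fraction > 0 and self.n_loci < 2:
            raise ValueError(
                "gene-body-identical pairs require at least 2 loci"
            )
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        if self.fragment_length >= 2 * self.read_length:
            raise ValueError(
                "read pairs must overlap: fragment_length < 2 * read_length"
            )
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, params.seed])


@dataclass(frozen=True)
class SyntheticReference:
    """Reference loci plus the flanking genomic context reads are drawn from."""

    loci: ReferenceSet
    contexts: dict[str, tuple[str, str]]  # locus_id -> (ctx5, ctx3), gene strand


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASE_STR[i] for i in rng.integers(0, 4, size=n))


def _mutate_positions(
    seq: list[str],
    positions: Sequence[int],
    pairing: Sequence[int],
    rng: np.random.Generator,
) -> None:
    """Substitute at ``positions``; paired partners are repaired to WC."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for p in positions:
        old = seq[p]
        choices = [b for b in _BASE_STR if b != old]
        new = choices[rng.integers(0, 3)]
        seq[p] = new
        j = pairing[p]
        if j != -1:
            seq[j] = comp[new]


def make_reference(params: SimParams) -> SyntheticReference:
    """Deterministically generate a validated reference locus set."""
    params.validate()
    rng = _rng(params, 1)

    n_pairs = int(round(params.identical_pair_fraction * params.n_loci / 2))
    if 2 * n_pairs > params.n_loci:
        raise ValueError("identical_pair_fraction infeasible for n_loci")

    # family plan: identical pairs first, then ordinary families
    plans: list[tuple[int, bool]] = [(2, True)] * n_pairs
    remaining = params.n_loci - 2 * n_pairs
    while remaining > 0:
        size = int(rng.integers(1, params.max_family_size + 1))
        size = min(size, remaining)
        plans.append((size, False))
        remaining -= size

    loci: list[TRNALocus] = []
    contexts: dict[str, tuple[str, str]] = {}
    family_counter: dict[tuple[str, str], int] = {}
    seen_gene_seqs: set[str] = set()
    seen_flank5: set[str] = set()
    genome_cursor = 500

    for fam_i, (size, identical) in enumerate(plans):
        isotype, anticodon, feats = _FAMILY_TYPES[fam_i % len(_FAMILY_TYPES)]
        fam_no = family_counter[(isotype, anticodon)] = (
            family_counter.get((isotype, anticodon), 0) + 1
        )
        intron_seq = _random_seq(rng, 9) if feats.get("intron") else ""
        gene, labels, structure = build_canonical_gene(
            anticodon,
            has_17a=feats.get("has_17a", False),
            n_e=feats.get("n_e", 0),
            intron_seq=intron_seq,
        )
        pairing = dot_bracket_pairing(structure)
        anticodon_pos = {
            i for i, lab in enumerate(labels) if lab in ("34", "35", "36")
        }
        intron_pos = {i for i, lab in enumerate(labels) if lab == "intron"}
        eligible = [
            i for i in range(len(gene))
            if i not in anticodon_pos and i not in intron_pos
        ]

        archetype = list(gene)
        arch_sites = rng.choice(
            eligible, size=min(params.archetype_divergence, len(eligible)),
            replace=False,
        )
        _mutate_positions(archetype, list(arch_sites), pairing, rng)

        for member in range(size):
            for _attempt in range(50):
                member_seq = list(archetype)
                if not identical and member > 0:
                    lo, hi = params.member_divergence
                    k = int(rng.integers(lo, hi + 1))
                    sites = rng.choice(eligible, size=k, replace=False)
                    _mutate_positions(member_seq, list(sites), pairing, rng)
                seq_str = "".join(member_seq)
                if identical or seq_str not in seen_gene_seqs or member == 0:
                    break
            if identical:
                seq_str = "".join(archetype)
            seen_gene_seqs.add(seq_str)

            while True:
                flank5 = _random_seq(rng, FLANK5_LEN)
                if flank5 not in seen_flank5:
                    seen_flank5.add(flank5)
                    break
            flank3 = _random_seq(rng, FLANK3_LEN)
            ctx5 = _random_seq(rng, params.context_len)
            ctx3 = _random_seq(rng, params.context_len)

            locus_id = f"tRNA-{isotype}-{anticodon}-{fam_no}-{member + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            start = genome_cursor
            end = start + len(seq_str)
            genome_cursor = end + 2000
            intron_intervals = ()
            if intron_pos:
                s = min(intron_pos)
                intron_intervals = ((s, s + len(intron_pos)),)
            loci.append(
                TRNALocus(
                    locus_id=locus_id,
                    chrom="chrS",
                    start=start,
                    end=end,
                    strand=strand,
                    gene_seq=seq_str,
                    flank5=flank5,
                    flank3=flank3,
                    intron_intervals=intron_intervals,
                    isotype=isotype,
                    anticodon=anticodon,
                    high_confidence=bool(rng.random() < 0.8),
                    structure=structure,
                    sprinzl_map=labels,
                )
            )
            contexts[locus_id] = (ctx5, ctx3)

    return SyntheticReference(loci=ReferenceSet(loci), contexts=contexts)


# ---------------------------------------------------------------------------
# Cohort planting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedVariant:
    """Truth descriptor for one planted variant allele."""

    locus_id: str
    edits: tuple[Edit, ...]
    target_af: float
    gene_seq: str
    realized_count: int = 0


@dataclass
class CohortTruth:
    """Ground truth for a simulated diploid cohort."""

    params: SimParams
    reference: SyntheticReference
    variants: list[PlantedVariant]
    # locus_id -> allele gene sequences; index 0 is the reference allele
    locus_alleles: dict[str, list[str]]
    # individual -> locus_id -> (allele index, allele index)
    genotypes: dict[str, dict[str, tuple[int, int]]]

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes)

    def realized_variants(self) -> list[PlantedVariant]:
        """Planted variants actually carried by at least one individual."""
        return [v for v in self.variants if v.realized_count > 0]


def _plant_edits(
    locus: TRNALocus, n_edits: int, indel_fraction: float,
    rng: np.random.Generator,
) -> tuple[Edit, ...]:
    n = len(locus.gene_seq)
    positions = sorted(rng.choice(np.arange(1, n - 1), size=n_edits, replace=False))
    edits = []
    for p in positions:
        p = int(p)
        ref_base = locus.gene_seq[p]
        if rng.random() < indel_fraction:
            if rng.random() < 0.5:
                edits.append(Edit("ins", p, "", _BASE_STR[rng.integers(0, 4)]))
            else:
                edits.append(Edit("del", p, ref_base, ""))
        else:
            alt = [b for b in _BASE_STR if b != ref_base][rng.integers(0, 3)]
            edits.append(Edit("snv", p, ref_base, alt))
    return tuple(edits)


def plant_cohort(reference: SyntheticReference, params: SimParams) -> CohortTruth:
    """Plant variant alleles and sample diploid genotypes for the cohort."""
    params.validate()
    rng = _rng(params, 2)
    n_var_choices = np.arange(len(params.variants_per_locus_probs))
    edit_choices = np.arange(1, len(params.edit_count_probs) + 1)

    variants: list[PlantedVariant] = []
    locus_alleles: dict[str, list[str]] = {}
    locus_afs: dict[str, list[float]] = {}

    for locus in reference.loci:
        alleles = [locus.gene_seq]
        afs: list[float] = []
        n_var = int(rng.choice(n_var_choices, p=params.variants_per_locus_probs))
        for _ in range(n_var):
            for _attempt in range(50):
                bin_i = int(rng.choice(3, p=params.af_bin_probs))
                lo, hi = params.af_bin_ranges[bin_i]
                af = float(rng.uniform(lo, hi))
                if sum(afs) + af <= 0.95:
                    break
            else:
                continue
            for _attempt in range(50):
                n_edits = int(rng.choice(edit_choices, p=params.edit_count_probs))
                edits = _plant_edits(locus, n_edits, params.indel_fraction, rng)
                seq = apply_edits(locus.gene_seq, edits)
                if seq not in alleles:
                    break
            else:
                continue
            alleles.append(seq)
            afs.append(af)
            variants.append(
                PlantedVariant(
                    locus_id=locus.locus_id, edits=edits,
                    target_af=af, gene_seq=seq,
                )
            )
        locus_alleles[locus.locus_id] = alleles
        locus_afs[locus.locus_id] = afs

    genotypes: dict[str, dict[str, tuple[int, int]]] = {}
    realized: dict[tuple[str, str], int] = {}
    width = len(str(params.n_individuals))
    for i in range(params.n_individuals):
        ind = f"ind{i + 1:0{width}d}"
        by_locus: dict[str, tuple[int, int]] = {}
        for locus in reference.loci:
            afs = locus_afs[locus.locus_id]
            probs = np.array([1.0 - sum(afs)] + afs)
            draw = rng.choice(len(probs), size=2, p=probs)
            pair = (int(draw[0]), int(draw[1]))
            by_locus[locus.locus_id] = pair
            for a in pair:
                if a > 0:
                    seq = locus_alleles[locus.locus_id][a]
                    realized[(locus.locus_id, seq)] = (
                        realized.get((locus.locus_id, seq), 0) + 1
                    )
        genotypes[ind] = by_locus

    variants = [
        replace(v, realized_count=realized.get((v.locus_id, v.gene_seq), 0))
        for v in variants
    ]
    return CohortTruth(
        params=params, reference=reference, variants=variants,
        locus_alleles=locus_alleles, genotypes=genotypes,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for p in hits:
        old = chr(arr[p])
        choices = [b for b in _BASE_STR if b != old]
        arr[p] = ord(choices[rng.integers(0, 3)])
    return arr.tobytes().decode("ascii")


def simulate_reads(
    truth: CohortTruth,
    params: SimParams | None = None,
    with_provenance: bool = False,
):
    """Simulate overlapping paired-end reads per individual.

    Fragments are drawn uniformly over start positions that keep the full
    flank-extended query span inside the fragment; each haplotype receives
    Poisson(coverage/2) fragments.  Fragment orientation is random; base
    call errors are iid substitutions on each mate.  Deterministic under
    the simulation seed.

    Returns ``{individual: [ReadPair, ...]}``; with ``with_provenance`` a
    second mapping ``{pair_id: (locus_id, allele_index)}`` records which
    haplotype each fragment was sheared from.
    """
    params = params or truth.params
    provenance: dict[str, tuple[str, int]] = {}
    rng = _rng(params, 3)
    q_const = "F" * params.read_length  # Q37
    out: dict[str, list[ReadPair]] = {}
    warned_short = False

    for ind in truth.individuals:
        pairs: list[ReadPair] = []
        counter = 0
        for locus in truth.reference.loci:
            ctx5, ctx3 = truth.reference.contexts[locus.locus_id]
            hap = truth.genotypes[ind][locus.locus_id]
            for allele_idx in hap:
                gene = truth.locus_alleles[locus.locus_id][allele_idx]
                region = ctx5 + locus.flank5 + gene + locus.flank3 + ctx3
                q_start = len(ctx5)
                q_len = len(locus.flank5) + len(gene) + len(locus.flank3)
                L = params.fragment_length
                if L < q_len and not warned_short:
                    warnings.warn(
                        "fragment_length shorter than the flank-extended "
                        "query; reads cannot be full length",
                        stacklevel=2,
                    )
                    warned_short = True
                lo = max(0, q_start + q_len - L)
                hi = min(len(region) - L, q_start)
                if hi < lo:
                    lo = max(0, min(lo, len(region) - L))
                    hi = lo
                n_frag = int(rng.poisson(params.coverage_mean / 2.0))
                for _ in range(n_frag):
                    start = int(rng.integers(lo, hi + 1))
                    frag = region[start:start + L]
                    if rng.random() < 0.5:
                        frag = reverse_complement(frag)
                    r1 = frag[: params.read_length]
                    r2 = reverse_complement(frag)[: params.read_length]
                    r1 = _add_errors(r1, params.error_rate, rng)
                    r2 = _add_errors(r2, params.error_rate, rng)
                    counter += 1
                    pair_id = f"{ind}.{counter}"
                    provenance[pair_id] = (locus.locus_id, allele_idx)
                    pairs.append(
                        ReadPair(
                            pair_id=pair_id,
                            seq1=r1, qual1=q_const,
                            seq2=r2, qual2=q_const,
                        )
                    )
        out[ind] = pairs
    if with_provenance:
        return out, provenance
    return out


def write_fastq_pairs(
    pairs: Sequence[ReadPair], fastq1: str | Path, fastq2: str | Path
) -> None:
    """Write mate pairs as two parallel Phred+33 FASTQ files."""
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def truth_table(truth: CohortTruth) -> pd.DataFrame:
    """Planted-variant truth as a tidy table."""
    rows = [
        {
            "locus_id": v.locus_id,
            "n_edits": len(v.edits),
            "edits": ";".join(
                f"{e.kind}@{e.gene_pos}:{e.ref_bases or '-'}>{e.alt_bases or '-'}"
                for e in v.edits
            ),
            "target_af": v.target_af,
            "realized_count": v.realized_count,
            "gene_seq": v.gene_seq,
        }
        for v in truth.variants
    ]
    return pd.DataFrame(rows)
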