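"""Reference model for tRNA gene loci.

Loads, validates and indexes a reference set of tRNA genes; builds the
flank-extended query sequences used for full-length read matching; and
provides Sprinzl-numbering and genetic-code services.

Conventions
-----------
* Genomic intervals are 0-based half-open internally.  All *reported*
  genomic positions are 1-based on the plus strand (``chr1:16872502 T/C``
  style).
* ``gene_seq``, ``flank5`` and ``flank3`` are stored on the gene (tRNA
  coding) strand.  For a minus-strand locus they are the reverse
  complement of the plus-strand genomic window.
* Sprinzl numbering: canonical labels ``"1"``..``"76"`` plus the optional
  D-loop insertions ``"17a"``, ``"20a"``, ``"20b"``; positions of the long
  variable arm of serine/leucine-type tRNAs are labelled ``"e1"``,
  ``"e2"``, ... ; intronic positions are labelled ``"intron"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLANK5_LEN = 20
FLANK3_LEN = 5

_DNA = frozenset("ACGT")
_DNA_N = frozenset("ACGTN")

ANTICODON_LABELS = ("34", "35", "36")
INTRON_LABEL = "intron"


class ReferenceValidationError(ValueError):
    """A locus violates the reference-model invariants."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

STOP = "STOP"


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid mapping (three-letter names, ``"STOP"`` for stops)."""

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map 64 codons, got {len(self.table)}")
        n_stop = sum(1 for aa in self.table.values() if aa == STOP)
        if n_stop != 3:
            raise ValueError(f"standard genetic code has 3 stop codons, got {n_stop}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """Build the standard nuclear code from Biopython's codon tables."""
        bio = CodonTable.unambiguous_dna_by_id[1]
        one_to_three = IUPACData.protein_letters_1to3
        table = {codon: one_to_three[aa] for codon, aa in bio.forward_table.items()}
        for codon in bio.stop_codons:
            table[codon] = STOP
        return cls(table=dict(table))

    def decode(self, codon: str) -> str:
        codon = codon.upper()
        if len(codon) != 3 or not set(codon) <= _DNA:
            raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
        return self.table[codon]


def decode_anticodon(anticodon: str, code: GeneticCode | None = None) -> str:
    """Amino-acid (or STOP) identity read by a tRNA anticodon.

    The anticodon pairs with the mRNA codon in antiparallel orientation, so
    the decoded codon is the reverse complement of the anticodon (both given
    as DNA).  E.g. anticodon ``"AAA"`` reads codon ``TTT`` -> Phe, and
    ``"TCA"`` reads codon ``TGA`` -> STOP.
    """
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or not set(anticodon) <= _DNA:
        raise ValueError(f"not an unambiguous DNA anticodon: {anticodon!r}")
    code = code or GeneticCode.standard()
    return code.decode(reverse_complement(anticodon))


# ---------------------------------------------------------------------------
# Locus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TRNALocus:
    """One reference tRNA gene with flanks, structure and Sprinzl map.

    ``structure`` is a dot-bracket string over the gene sequence (introns
    unpaired); ``sprinzl_map`` gives one canonical label per gene position.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_seq: str
    flank5: str
    flank3: str
    intron_intervals: tuple[tuple[int, int], ...]
    isotype: str
    anticodon: str
    high_confidence: bool
    structure: str
    sprinzl_map: tuple[str, ...]

    # -- derived -----------------------------------------------------------

    @property
    def pairing(self) -> tuple[int, ...]:
        """Partner index per gene position (-1 = unpaired)."""
        return dot_bracket_pairing(self.structure)

    @property
    def label_index(self) -> dict[str, int]:
        """Sprinzl label -> gene position (intron positions excluded)."""
        return {
            lab: i for i, lab in enumerate(self.sprinzl_map) if lab != INTRON_LABEL
        }

    def position_of(self, label: str) -> int | None:
        return self.label_index.get(label)

    def base_at(self, label: str) -> str | None:
        pos = self.position_of(label)
        return None if pos is None else self.gene_seq[pos]

    def plus_strand_region_seq(self) -> str:
        """Plus-strand genomic sequence of the flank5+gene+flank3 window."""
        gene_strand = self.flank5 + self.gene_seq + self.flank3
        return gene_strand if self.strand == "+" else reverse_complement(gene_strand)


def dot_bracket_pairing(structure: str) -> tuple[int, ...]:
    pairing = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ReferenceValidationError("unbalanced dot-bracket structure")
            j = stack.pop()
            pairing[i], pairing[j] = j, i
        elif ch != ".":
            raise ReferenceValidationError(f"bad structure character {ch!r}")
    if stack:
        raise ReferenceValidationError("unbalanced dot-bracket structure")
    return tuple(pairing)


def validate_locus(locus: TRNALocus) -> None:
    """Check all TRNALocus invariants; raise ReferenceValidationError."""
    lid = locus.locus_id
    if len(locus.flank5) != FLANK5_LEN:
        raise ReferenceValidationError(
            f"{lid}: flank5 must be {FLANK5_LEN} nt, got {len(locus.flank5)}"
        )
    if len(locus.flank3) != FLANK3_LEN:
        raise ReferenceValidationError(
            f"{lid}: flank3 must be {FLANK3_LEN} nt, got {len(locus.flank3)}"
        )
    for name, seq in (("gene_seq", locus.gene_seq), ("flank5", locus.flank5),
                      ("flank3", locus.flank3)):
        if not set(seq) <= _DNA:
            raise ReferenceValidationError(f"{lid}: {name} contains non-ACGT symbols")
    if locus.strand not in "+-":
        raise ReferenceValidationError(f"{lid}: strand must be '+' or '-'")
    if locus.end - locus.start != len(locus.gene_seq):
        raise ReferenceValidationError(
            f"{lid}: genomic interval length {locus.end - locus.start} != "
            f"gene length {len(locus.gene_seq)}"
        )
    n = len(locus.gene_seq)
    if len(locus.structure) != n:
        raise ReferenceValidationError(f"{lid}: structure/sequence length mismatch")
    if len(locus.sprinzl_map) != n:
        raise ReferenceValidationError(f"{lid}: Sprinzl map must cover every gene position")
    non_intron = [lab for lab in locus.sprinzl_map if lab != INTRON_LABEL]
    if len(set(non_intron)) != len(non_intron):
        raise ReferenceValidationError(f"{lid}: duplicate Sprinzl labels")
    pairing = locus.pairing  # raises on malformed structure
    for i, j in enumerate(pairing):
        if j != -1 and pairing[j] != i:
            raise ReferenceValidationError(f"{lid}: pairing is not an involution")
    idx = locus.label_index
    for lab in ANTICODON_LABELS:
        if lab not in idx:
            raise ReferenceValidationError(f"{lid}: missing Sprinzl position {lab}")
    observed = "".join(locus.gene_seq[idx[lab]] for lab in ANTICODON_LABELS)
    if observed != locus.anticodon:
        raise ReferenceValidationError(
            f"{lid}: anticodon field {locus.anticodon} does not match gene "
            f"sequence at Sprinzl 34-36 ({observed})"
        )
    for s, e in locus.intron_intervals:
        if not (0 <= s < e <= n):
            raise ReferenceValidationError(f"{lid}: intron interval out of range")
        for p in range(s, e):
            if locus.sprinzl_map[p] != INTRON_LABEL:
                raise ReferenceValidationError(
                    f"{lid}: intron interval position {p} not labelled 'intron'"
                )
    intron_positions = {p for s, e in locus.intron_intervals for p in range(s, e)}
    for p, lab in enumerate(locus.sprinzl_map):
        if lab == INTRON_LABEL and p not in intron_positions:
            raise ReferenceValidationError(
                f"{lid}: position {p} labelled 'intron' outside intron intervals"
            )


def sprinzl_label(locus: TRNALocus, gene_pos: int) -> str:
    """Canonical Sprinzl label for a 0-based gene position."""
    if not 0 <= gene_pos < len(locus.gene_seq):
        raise IndexError(
            f"{locus.locus_id}: gene position {gene_pos} out of range "
            f"[0, {len(locus.gene_seq)})"
        )
    return locus.sprinzl_map[gene_pos]


# ---------------------------------------------------------------------------
# Flank-extended queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QueryRecord:
    """Flank-extended query sequence for full-length read matching."""

    locus_id: str
    query_seq: str
    flank5_len: int = FLANK5_LEN
    flank3_len: int = FLANK3_LEN

    @property
    def gene_len(self) -> int:
        return len(self.query_seq) - self.flank5_len - self.flank3_len


def build_query(
    locus: TRNALocus,
    flank5_len: int = FLANK5_LEN,
    flank3_len: int = FLANK3_LEN,
) -> QueryRecord:
    """Concatenate 5' flank + gene + 3' flank in gene-strand orientation.

    ``flank5_len``/``flank3_len`` may be reduced (down to 0) to study the
    effect of flank length on mapping uniqueness.
    """
    if not 0 <= flank5_len <= len(locus.flank5):
        raise ValueError(f"flank5_len must be in [0, {len(locus.flank5)}]")
    if not 0 <= flank3_len <= len(locus.flank3):
        raise ValueError(f"flank3_len must be in [0, {len(locus.flank3)}]")
    f5 = locus.flank5[len(locus.flank5) - flank5_len:]
    f3 = locus.flank3[:flank3_len]
    return QueryRecord(
        locus_id=locus.locus_id,
        query_seq=f5 + locus.gene_seq + f3,
        flank5_len=flank5_len,
        flank3_len=flank3_len,
    )


# ---------------------------------------------------------------------------
# Reference set
# ---------------------------------------------------------------------------


class ReferenceSet:
    """Validated, indexed collection of tRNA loci."""

    def __init__(self, loci: Iterable[TRNALocus]):
        self._loci: dict[str, TRNALocus] = {}
        for locus in loci:
            validate_locus(locus)
            if locus.locus_id in self._loci:
                raise ReferenceValidationError(f"duplicate locus id {locus.locus_id}")
            self._loci[locus.locus_id] = locus

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[TRNALocus]:
        return iter(self._loci.values())

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._loci

    def __getitem__(self, locus_id: str) -> TRNALocus:
        return self._loci[locus_id]

    @property
    def locus_ids(self) -> list[str]:
        return list(self._loci)

    def loci_overlapping(self, chrom: str, start: int, end: int) -> list[TRNALocus]:
        """Loci whose genomic interval overlaps [start, end) on ``chrom``."""
        return [
            loc for loc in self
            if loc.chrom == chrom and loc.start < end and loc.end > start
        ]

    def identity_groups(self) -> list[tuple[str, ...]]:
        """Groups (size >= 2) of loci with byte-identical gene bodies.

        These are the isodecoder loci that can only be told apart by their
        flanking sequence.
        """
        by_seq: dict[str, list[str]] = {}
        for loc in self:
            by_seq.setdefault(loc.gene_seq, []).append(loc.locus_id)
        return sorted(
            tuple(sorted(ids)) for ids in by_seq.values() if len(ids) >= 2
        )

    def queries(
        self, flank5_len: int = FLANK5_LEN, flank3_len: int = FLANK3_LEN
    ) -> dict[str, QueryRecord]:
        return {
            loc.locus_id: build_query(loc, flank5_len, flank3_len) for loc in self
        }


# ---------------------------------------------------------------------------
# File IO (reference FASTA + metadata TSV + structure file)
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = [
    "locus_id", "chrom", "start", "end", "strand", "isotype", "anticodon",
    "high_confidence", "introns", "flank5", "flank3",
]


def _format_introns(intervals: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def _parse_introns(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text in (".", "nan"):
        return ()
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_reference(ref: ReferenceSet, out_dir: str | Path) -> dict[str, Path]:
    """Emit the three reference files; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "trna_genes.fa"
    metadata_path = out_dir / "trna_metadata.tsv"
    structure_path = out_dir / "trna_structures.txt"

    records = [
        SeqRecord(Seq(loc.gene_seq), id=loc.locus_id, description="")
        for loc in ref
    ]
    SeqIO.write(records, fasta_path, "fasta")

    rows = [
        {
            "locus_id": loc.locus_id, "chrom": loc.chrom, "start": loc.start,
            "end": loc.end, "strand": loc.strand, "isotype": loc.isotype,
            "anticodon": loc.anticodon,
            "high_confidence": int(loc.high_confidence),
            "introns": _format_introns(loc.intron_intervals) or ".",
            "flank5": loc.flank5, "flank3": loc.flank3,
        }
        for loc in ref
    ]
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False
    )

    with open(structure_path, "w") as fh:
        for loc in ref:
            fh.write(f">{loc.locus_id}\n{loc.structure}\n")
            fh.write(",".join(loc.sprinzl_map) + "\n")
    return {"fasta": fasta_path, "metadata": metadata_path, "structure": structure_path}


def _read_structure_file(path: str | Path) -> dict[str, tuple[str, tuple[str, ...]]]:
    out: dict[str, tuple[str, tuple[str, ...]]] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        header = lines[i].strip()
        if not header:
            i += 1
            continue
        if not header.startswith(">"):
            raise ReferenceValidationError(
                f"structure file: expected '>' header at line {i + 1}"
            )
        if i + 2 >= len(lines):
            raise ReferenceValidationError(
                f"structure file: truncated entry for {header[1:]}"
            )
        structure = lines[i + 1].strip()
        labels = tuple(lines[i + 2].strip().split(","))
        out[header[1:]] = (structure, labels)
        i += 3
    return out


def load_reference(
    fasta_path: str | Path,
    metadata_path: str | Path,
    structure_path: str | Path,
) -> ReferenceSet:
    """Load and validate a reference locus set from its three files."""
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    structures = _read_structure_file(structure_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ReferenceValidationError(f"metadata missing columns: {missing}")

    loci = []
    for row in meta.itertuples(index=False):
        lid = row.locus_id
        if lid not in seqs:
            raise ReferenceValidationError(f"metadata row {lid} has no FASTA sequence")
        if lid not in structures:
            raise ReferenceValidationError(f"missing structure annotation for {lid}")
        structure, labels = structures[lid]
        loci.append(
            TRNALocus(
                locus_id=lid,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                gene_seq=seqs[lid],
                flank5=row.flank5.upper(),
                flank3=row.flank3.upper(),
                intron_intervals=_parse_introns(row.introns),
                isotype=row.isotype,
                anticodon=row.anticodon.upper(),
                high_confidence=row.high_confidence in ("1", "True", "true", "yes"),
                structure=structure,
                sprinzl_map=labels,
            )
        )
    return ReferenceSet(loci)


# ---------------------------------------------------------------------------
# Canonical cloverleaf template
# ---------------------------------------------------------------------------
#
# A canonical 76-position tRNA with the standard four-stem cloverleaf.  The
# template is the scaffold from which synthetic loci and worked-example
# stand-in gene models are built: stems are Watson-Crick paired, the
# conserved loop bases (U8, G18G19, U33, T54T55C56, discriminator 73 and the
# 3'-CCA) are fixed, and the anticodon is substituted per locus.

_CANONICAL_NUMBERS = [str(i) for i in range(1, 77)]

# (5' label, 3' label) stem pairs of the cloverleaf
CLOVERLEAF_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (str(a), str(b))
    for a, b in (
        [(i, 73 - i) for i in range(1, 8)]          # acceptor stem 1-7 : 66-72
        + [(10, 25), (11, 24), (12, 23), (13, 22)]  # D stem
        + [(27, 43), (28, 42), (29, 41), (30, 40), (31, 39)]  # anticodon stem
        + [(49, 65), (50, 64), (51, 63), (52, 62), (53, 61)]  # T stem
    )
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# 5' stem sides and loop/linker bases; 3' stem sides are derived by pairing.
_TEMPLATE_BASES: dict[str, str] = {
    "1": "G", "2": "G", "3": "G", "4": "C", "5": "G", "6": "T", "7": "G",
    "8": "T", "9": "A",
    "10": "G", "11": "C", "12": "T", "13": "C",
    "14": "A", "15": "G", "16": "C", "17": "T", "17a": "C",
    "18": "G", "19": "G", "20": "T", "20a": "C", "20b": "T", "21": "A",
    "26": "A",
    "27": "G", "28": "C", "29": "C", "30": "G", "31": "G",
    "32": "C", "33": "T", "34": "G", "35": "C", "36": "C", "37": "A", "38": "A",
    "44": "A", "45": "G", "46": "G", "47": "T", "48": "C",
    "49": "C", "50": "G", "51": "G", "52": "G", "53": "G",
    "54": "T", "55": "T", "56": "C", "57": "G", "58": "A", "59": "T", "60": "C",
    "73": "A", "74": "C", "75": "C", "76": "A",
}

_E_ARM_FILL = "GAGGCTAGCT"  # unpaired filler for variable-arm positions


def canonical_labels(
    has_17a: bool = False,
    has_20ab: bool = False,
    n_e: int = 0,
    missing: Sequence[str] = (),
    intron_len: int = 0,
) -> list[str]:
    """Ordered Sprinzl labels for a locus with the given structural features.

    ``n_e`` variable-arm positions (``e1``..) are inserted after position 47;
    an intron of ``intron_len`` positions is inserted after position 37 (the
    canonical intron location).
    """
    missing_set = set(missing)
    labels: list[str] = []
    for num in _CANONICAL_NUMBERS:
        if num in missing_set:
            continue
        labels.append(num)
        if num == "17" and has_17a:
            labels.append("17a")
        if num == "20" and has_20ab:
            labels.extend(["20a", "20b"])
        if num == "37" and intron_len:
            labels.extend([INTRON_LABEL] * intron_len)
        if num == "47" and n_e:
            labels.extend(f"e{k}" for k in range(1, n_e + 1))
    return labels


def cloverleaf_structure(labels: Sequence[str]) -> str:
    """Dot-bracket string for the canonical pairs present in ``labels``."""
    index = {lab: i for i, lab in enumerate(labels) if lab != INTRON_LABEL}
    chars = ["."] * len(labels)
    for five, three in CLOVERLEAF_PAIRS:
        if five in index and three in index:
            chars[index[five]] = "("
            chars[index[three]] = ")"
    return "".join(chars)


def build_canonical_gene(
    anticodon: str,
    has_17a: bool = False,
    has_20ab: bool = False,
    n_e: int = 0,
    missing: Sequence[str] = (),
    intron_seq: str = "",
    overrides: Mapping[str, str] | None = None,
) -> tuple[str, tuple[str, ...], str]:
    """Build (gene_seq, sprinzl_map, structure) from the canonical template.

    ``overrides`` maps Sprinzl labels to bases.  When only one side of a stem
    pair is overridden the partner is set to its Watson-Crick complement;
    overriding both sides permits non-canonical (e.g. mismatched) pairs.
    """
    overrides = dict(overrides or {})
    for i, base in enumerate(anticodon.upper()):
        overrides.setdefault(str(34 + i), base)

    labels = canonical_labels(
        has_17a=has_17a, has_20ab=has_20ab, n_e=n_e,
        missing=missing, intron_len=len(intron_seq),
    )
    partner = {}
    for five, three in CLOVERLEAF_PAIRS:
        partner[five] = three
        partner[three] = five

    e_iter = 0
    intron_iter = iter(intron_seq.upper())
    seq_chars: list[str] = []
    for lab in labels:
        if lab == INTRON_LABEL:
            seq_chars.append(next(intron_iter))
            continue
        if lab in overrides:
            base = overrides[lab].upper()
        elif lab in _TEMPLATE_BASES:
            base = _TEMPLATE_BASES[lab]
        elif lab.startswith("e"):
            base = _E_ARM_FILL[e_iter % len(_E_ARM_FILL)]
            e_iter += 1
        else:  # 3' stem side: complement of the (possibly overridden) 5' base
            mate = partner[lab]
            mate_base = overrides.get(mate, _TEMPLATE_BASES[mate]).upper()
            base = _COMPLEMENT[mate_base]
        seq_chars.append(base)

    structure = cloverleaf_structure(labels)
    return "".join(seq_chars), tuple(labels), structure
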