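"""Assignment of merged reads to tRNA loci by full-length identity matching.

Every merged read is aligned against every flank-extended query with a
glocal alignment: global in the query (the alignment must cover the query
end-to-end) and local in the read (the read may extend beyond the query on
either side).  Identity is matches / aligned query columns, with gap
columns counting as mismatches.  The best identity wins; exact ties of any
size make the read ambiguous and it is annotated with all tied loci.

Reads from gene-body-identical isodecoder loci are only separable through
their flanking sequence; with flanks stripped from the queries those loci
collapse into ambiguity groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import edlib

from .allele_calling import btop_from_alignment
from .read_processing import MergedRead
from .reference_model import QueryRecord, reverse_complement

DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_DEPTH = 10

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class FullLengthHit:
    """A full-query-coverage alignment of a read against one locus query."""

    locus_id: str
    identity: Fraction
    read_start: int
    read_end: int  # exclusive
    btop: str
    n_matches: int
    n_columns: int


def _hit_from_path(
    query: QueryRecord, read_seq: str, result: dict
) -> FullLengthHit:
    start, end = result["locations"][0]
    nice = edlib.getNiceAlignment(result, query.query_seq, read_seq)
    q_aln = nice["query_aligned"]
    t_aln = nice["target_aligned"]
    n_cols = len(q_aln)
    n_match = sum(1 for a, b in zip(q_aln, t_aln) if a == b and a != "-")
    return FullLengthHit(
        locus_id=query.locus_id,
        identity=Fraction(n_match, n_cols),
        read_start=start,
        read_end=end + 1,
        btop=btop_from_alignment(q_aln, t_aln),
        n_matches=n_match,
        n_columns=n_cols,
    )


def align_full_length(
    query: QueryRecord,
    read: MergedRead | str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> FullLengthHit | None:
    """Glocal alignment of a read to one query; ``None`` below threshold.

    The minimum-edit-distance alignment is used.  Because identity counts
    gap columns as mismatches over the aligned query span, an edit distance
    ``d`` can reach identity ``t`` only if ``d <= len(query) * (1-t)/t``,
    which bounds the banded search.
    """
    read_seq = read.sequence if isinstance(read, MergedRead) else read
    qseq = query.query_seq
    k = int(len(qseq) * (1.0 - min_identity) / min_identity)
    result = edlib.align(qseq, read_seq, mode="HW", task="path", k=k)
    if result["editDistance"] < 0:
        return None
    hit = _hit_from_path(query, read_seq, result)
    if hit.identity < Fraction(min_identity).limit_denominator(10**6):
        return None
    return hit


@dataclass(frozen=True)
class LocusAssignment:
    """Mapping outcome for one merged read."""

    read_id: str
    status: str  # unique | ambiguous | unmapped
    loci: tuple[str, ...]
    identity: Fraction | None
    allele_seq: str | None  # read segment spanning the query
    btop: str | None
    reverse: bool = False


class QueryIndex:
    """Queries indexed for repeated read assignment.

    Exact full-query substring hits (identity 1, the overwhelmingly common
    case) are found without alignment; everything else goes through the
    banded glocal alignment.  Results are memoised per distinct read
    sequence, so collapsing identical merged fragments costs nothing.
    """

    def __init__(
        self,
        queries: Mapping[str, QueryRecord] | Iterable[QueryRecord],
        min_identity: float = DEFAULT_MIN_IDENTITY,
    ):
        if isinstance(queries, Mapping):
            records = list(queries.values())
        else:
            records = list(queries)
        self.queries: list[QueryRecord] = sorted(records, key=lambda q: q.locus_id)
        self.min_identity = float(min_identity)
        self._by_seq: dict[str, list[QueryRecord]] = {}
        for q in self.queries:
            self._by_seq.setdefault(q.query_seq, []).append(q)
        self._cache: dict[str, LocusAssignment] = {}

    # -- internals ---------------------------------------------------------

    def _exact_hits(self, read_seq: str) -> list[FullLengthHit]:
        hits = []
        for qseq, records in self._by_seq.items():
            start = read_seq.find(qseq)
            if start < 0:
                continue
            n = len(qseq)
            for q in records:
                hits.append(
                    FullLengthHit(
                        locus_id=q.locus_id,
                        identity=Fraction(1),
                        read_start=start,
                        read_end=start + n,
                        btop=str(n),
                        n_matches=n,
                        n_columns=n,
                    )
                )
        return hits

    def _all_hits(self, read_seq: str) -> list[FullLengthHit]:
        hits = self._exact_hits(read_seq)
        if hits:  # identity 1 is maximal; only identity-1 ties matter
            return hits
        for q in self.queries:
            hit = align_full_length(q, read_seq, self.min_identity)
            if hit is not None:
                hits.append(hit)
        return hits

    # -- public ------------------------------------------------------------

    def assign(self, read: MergedRead | str, read_id: str = "") -> LocusAssignment:
        """Assign one read; tries both orientations, best identity wins."""
        read_seq = read.sequence if isinstance(read, MergedRead) else read
        if isinstance(read, MergedRead) and not read_id:
            read_id = read.pair_id
        cached = self._cache.get(read_seq)
        if cached is not None:
            return (
                cached
                if cached.read_id == read_id
                else LocusAssignment(
                    read_id, cached.status, cached.loci, cached.identity,
                    cached.allele_seq, cached.btop, cached.reverse,
                )
            )

        fwd = self._all_hits(read_seq)
        rc = reverse_complement(read_seq)
        rev = self._all_hits(rc) if rc != read_seq else []
        candidates = [(h, False) for h in fwd] + [(h, True) for h in rev]
        if not candidates:
            out = LocusAssignment(read_id, UNMAPPED, (), None, None, None)
        else:
            best_identity = max(h.identity for h, _ in candidates)
            tied = [(h, r) for h, r in candidates if h.identity == best_identity]
            tied.sort(key=lambda hr: (hr[0].locus_id, hr[1]))
            loci = tuple(dict.fromkeys(h.locus_id for h, _ in tied))
            hit, is_rev = tied[0]
            source = rc if is_rev else read_seq
            out = LocusAssignment(
                read_id=read_id,
                status=UNIQUE if len(loci) == 1 else AMBIGUOUS,
                loci=loci,
                identity=best_identity,
                allele_seq=source[hit.read_start:hit.read_end],
                btop=hit.btop,
                reverse=is_rev,
            )
        self._cache[read_seq] = out
        return out

    def assign_all(self, reads: Iterable[MergedRead]) -> list[LocusAssignment]:
        return [self.assign(r) for r in reads]


def assign_read(
    read: MergedRead | str,
    queries: Mapping[str, QueryRecord] | QueryIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> LocusAssignment:
    """One-shot read assignment (builds a throwaway index if needed)."""
    index = (
        queries
        if isinstance(queries, QueryIndex)
        else QueryIndex(queries, min_identity)
    )
    return index.assign(read)


# ---------------------------------------------------------------------------
# Allele collapsing and genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleCall:
    """One distinct full-length sequence observed at one locus key."""

    individual: str
    locus_key: tuple[str, ...]
    seq: str  # read sequence over the query span
    depth: int
    btop: str


def collapse_alleles(
    assignments: Iterable[LocusAssignment],
    individual: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> dict[tuple[str, ...], list[AlleleCall]]:
    """Collapse one individual's assigned reads into depth-filtered alleles.

    Identical read sequences over the query span collapse to one allele
    with summed depth; alleles below ``min_depth`` are discarded as likely
    sequencing-error survivors.  Retained alleles sort by depth (deepest
    first), ties by sequence.
    """
    buckets: dict[tuple[tuple[str, ...], str], tuple[int, str]] = {}
    for a in assignments:
        if a.status == UNMAPPED or a.allele_seq is None:
            continue
        key = (a.loci, a.allele_seq)
        depth, btop = buckets.get(key, (0, a.btop or ""))
        buckets[key] = (depth + 1, btop)

    out: dict[tuple[str, ...], list[AlleleCall]] = {}
    for (loci, seq), (depth, btop) in buckets.items():
        if depth < min_depth:
            continue
        out.setdefault(loci, []).append(
            AlleleCall(
                individual=individual, locus_key=loci, seq=seq,
                depth=depth, btop=btop,
            )
        )
    for loci in out:
        out[loci].sort(key=lambda c: (-c.depth, c.seq))
    return out


@dataclass(frozen=True)
class DiploidCall:
    """Diploid genotype at one locus key: alleles with counts (sum = 2)."""

    locus_key: tuple[str, ...]
    alleles: tuple[AlleleCall, ...]
    counts: tuple[int, ...]
    warning: str | None = None


def genotype_locus(alleles: Sequence[AlleleCall]) -> DiploidCall | None:
    """Diploid genotype from depth-filtered alleles at one locus.

    One allele means the individual is assumed homozygous (allele count 2);
    two alleles are a heterozygote (1 + 1); more than two retained alleles
    keep the two deepest with a warning.  No alleles -> locus uncovered
    (``None``).
    """
    if not alleles:
        return None
    key = alleles[0].locus_key
    ranked = sorted(alleles, key=lambda c: (-c.depth, c.seq))
    if len(ranked) == 1:
        return DiploidCall(key, (ranked[0],), (2,))
    warning = None
    if len(ranked) > 2:
        warning = (
            f"{ranked[0].individual} @ {'|'.join(key)}: {len(ranked)} alleles "
            f"passed the depth filter; keeping the two deepest"
        )
    return DiploidCall(key, tuple(ranked[:2]), (1, 1), warning)
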