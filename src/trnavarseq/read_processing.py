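"""Merging of overlapping paired-end reads into full-fragment consensi.

Each read pair is assumed to come from a fragment shorter than the summed
read lengths, so the 3' ends of the two reads overlap.  The mate is reverse
complemented and the best suffix/prefix overlap is taken; disagreements in
the overlap resolve toward the higher-quality base and the consensus quality
is the maximum of the two.

Best overlap = lowest mismatch fraction among overlaps of length >=
``min_overlap`` with mismatch fraction <= ``max_mismatch_frac``; ties break
toward the longer overlap, then toward higher aggregate overlap quality.
``N`` bases are uninformative: they never count as mismatches and never win
a consensus column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .reference_model import reverse_complement

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MAX_MISMATCH_FRAC = 0.1

PHRED_OFFSET = 33

_VALID = frozenset("ACGTN")
_N = ord("N")


@dataclass(frozen=True)
class MergedRead:
    """Consensus fragment reconstructed from one overlapping read pair."""

    sequence: str
    qualities: tuple[int, ...]
    pair_id: str
    overlap: int

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")

    @property
    def quality_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.qualities)


def _to_arrays(seq: str, qual: Sequence[int] | str) -> tuple[np.ndarray, np.ndarray]:
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if isinstance(qual, str):
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
        q -= PHRED_OFFSET
    else:
        q = np.asarray(qual, dtype=np.int16)
    if len(a) != len(q):
        raise ValueError("sequence/quality length mismatch")
    return a, q


def merge_pair(
    seq1: str,
    qual1: Sequence[int] | str,
    seq2: str,
    qual2: Sequence[int] | str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    pair_id: str = "",
) -> MergedRead | None:
    """Merge one read pair; ``None`` when no qualifying overlap exists.

    ``seq2``/``qual2`` are the raw mate as sequenced (they are reverse
    complemented here before the overlap search).  Qualities may be Phred+33
    strings or integer sequences.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    for s in (seq1, seq2):
        if not set(s) <= _VALID:
            raise ValueError("reads may only contain A, C, G, T or N")

    a1, q1 = _to_arrays(seq1.upper(), qual1)
    rc2 = reverse_complement(seq2.upper())
    a2, q2 = _to_arrays(rc2, qual2)
    q2 = q2[::-1].copy()  # qualities follow the reverse complement
    l1, l2 = len(a1), len(a2)

    best: tuple[int, int, int] | None = None  # (mismatches, length, agg_qual)
    for olen in range(min(l1, l2), min_overlap - 1, -1):
        s1 = a1[l1 - olen:]
        s2 = a2[:olen]
        informative = (s1 != _N) & (s2 != _N)
        mism = int(np.count_nonzero((s1 != s2) & informative))
        if mism > max_mismatch_frac * olen:
            continue
        agg = int(q1[l1 - olen:].sum() + q2[:olen].sum())
        if best is None:
            best = (mism, olen, agg)
            continue
        b_mism, b_olen, b_agg = best
        # lower mismatch fraction wins; then longer; then higher quality
        if (
            mism * b_olen < b_mism * olen
            or (mism * b_olen == b_mism * olen and olen > b_olen)
            or (mism * b_olen == b_mism * olen and olen == b_olen and agg > b_agg)
        ):
            best = (mism, olen, agg)
    if best is None:
        return None
    _, olen, _ = best

    s1, s2 = a1[l1 - olen:], a2[:olen]
    o_q1, o_q2 = q1[l1 - olen:], q2[:olen]
    take2 = o_q2 > o_q1            # higher quality wins disagreements
    take2 |= (s1 == _N) & (s2 != _N)   # N never wins
    take2 &= ~((s2 == _N) & (s1 != _N))
    cons = np.where(take2, s2, s1)
    cons_q = np.maximum(o_q1, o_q2)

    seq = (
        a1[: l1 - olen].tobytes() + cons.tobytes() + a2[olen:].tobytes()
    ).decode("ascii")
    quals = tuple(
        int(x) for x in np.concatenate([q1[: l1 - olen], cons_q, q2[olen:]])
    )
    return MergedRead(sequence=seq, qualities=quals, pair_id=pair_id, overlap=olen)


@dataclass(frozen=True)
class ReadPair:
    """A raw paired-end read as it comes off the sequencer."""

    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def merge_pairs(
    pairs: Iterable[ReadPair],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> list[MergedRead]:
    """Merge a stream of read pairs, dropping pairs with no valid overlap."""
    merged = []
    for p in pairs:
        m = merge_pair(
            p.seq1, p.qual1, p.seq2, p.qual2,
            min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac,
            pair_id=p.pair_id,
        )
        if m is not None:
            merged.append(m)
    return merged


# ---------------------------------------------------------------------------
# FASTQ IO
# ---------------------------------------------------------------------------


def read_fastq_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    """Iterate mate pairs from two parallel FASTQ files (Phred+33)."""
    it1 = SeqIO.parse(str(fastq1), "fastq")
    it2 = SeqIO.parse(str(fastq2), "fastq")
    for r1, r2 in zip(it1, it2, strict=True):
        yield ReadPair(
            pair_id=r1.id,
            seq1=str(r1.seq).upper(),
            qual1="".join(
                chr(q + PHRED_OFFSET)
                for q in r1.letter_annotations["phred_quality"]
            ),
            seq2=str(r2.seq).upper(),
            qual2="".join(
                chr(q + PHRED_OFFSET)
                for q in r2.letter_annotations["phred_quality"]
            ),
        )


def write_merged_fastq(merged: Iterable[MergedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in merged:
            fh.write(f"@{m.pair_id}\n{m.sequence}\n+\n{m.quality_string}\n")
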