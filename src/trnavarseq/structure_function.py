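"""Structural and functional annotation of tRNA variants.

Maps variant edits onto the cloverleaf (Sprinzl positions and structural
regions), classifies anticodon variants (synonymous vs identity-changing,
with decoded amino-acid identities) and G3:U70 gain (the major alanyl-tRNA
synthetase identity element, whose transplantation onto a non-Ala tRNA
predicts mischarging with alanine), and scores variants against their
reference with:

* an internal-promoter score: log-odds PSSM sums over the A-box (Sprinzl
  8-19) and B-box (Sprinzl 52-62) windows, in the spirit of EufindtRNA's
  consensus scoring;
* an "Infernal-like" fold score decomposed into a primary-sequence
  component (per-position PSSM over Sprinzl-aligned columns) and a
  secondary-structure component (a pair-scoring table over the annotated
  stem pairs: Watson-Crick > G:U wobble > mismatch), with the pseudo-tRNA
  rule applied to the decomposition: a gene is flagged pseudo when the
  primary component is below 10 bits or the secondary component below
  5 bits.

The covariance-model machinery of the original Infernal scoring is *not*
re-implemented; these simplified scores are meant to be used ordinally
(increase / neutral / decrease vs the reference), not to reproduce
covariance-model bit scores.  PSSMs are estimated from the packaged
reference set itself with add-one smoothing against a uniform background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .allele_calling import Edit, VariantRecord, apply_edits, variant_position_map
from .reference_model import (
    GeneticCode,
    INTRON_LABEL,
    ReferenceSet,
    TRNALocus,
    decode_anticodon,
)

PSEUDO_PRIMARY_BITS = 10.0
PSEUDO_SECONDARY_BITS = 5.0
NEUTRAL_BAND_BITS = 1.0

A_BOX_LABELS = tuple(str(i) for i in range(8, 20))    # Sprinzl 8-19
B_BOX_LABELS = tuple(str(i) for i in range(52, 63))   # Sprinzl 52-62

# pair-scoring table (bits): Watson-Crick > G:U wobble > anything else
PAIR_SCORES: dict[frozenset[str], float] = {
    frozenset({"A", "T"}): 2.0,
    frozenset({"G", "C"}): 2.0,
    frozenset({"G", "T"}): 1.0,
}
MISMATCH_PAIR_SCORE = -4.0

ANTICODON_LABELS = ("34", "35", "36")

REGIONS = (
    "acceptor stem", "D-arm", "anticodon stem", "anticodon loop",
    "anticodon", "variable arm", "T-arm", "discriminator", "intron", "other",
)

_REGION_BY_NUMBER: dict[int, str] = {}
for _n in range(1, 8):
    _REGION_BY_NUMBER[_n] = "acceptor stem"
for _n in range(66, 73):
    _REGION_BY_NUMBER[_n] = "acceptor stem"
for _n in range(10, 26):
    _REGION_BY_NUMBER[_n] = "D-arm"
for _n in (27, 28, 29, 30, 31, 39, 40, 41, 42, 43):
    _REGION_BY_NUMBER[_n] = "anticodon stem"
for _n in (32, 33, 37, 38):
    _REGION_BY_NUMBER[_n] = "anticodon loop"
for _n in (34, 35, 36):
    _REGION_BY_NUMBER[_n] = "anticodon"
for _n in range(44, 49):
    _REGION_BY_NUMBER[_n] = "variable arm"
for _n in range(49, 66):
    _REGION_BY_NUMBER[_n] = "T-arm"
_REGION_BY_NUMBER[73] = "discriminator"


def region_of_label(label: str) -> str:
    """Structural region of a Sprinzl label ("58+" insertion markers allowed)."""
    label = label.rstrip("+")
    if label == INTRON_LABEL:
        return "intron"
    if label.startswith("e"):
        return "variable arm"
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        return "other"
    return _REGION_BY_NUMBER.get(int(digits), "other")


# ---------------------------------------------------------------------------
# Per-variant structural annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralAnnotation:
    """Sprinzl labels, regions and functional flags for one variant."""

    labels: tuple[str, ...]           # one per edit; insertions carry a "+"
    regions: tuple[str, ...]
    anticodon_changed: bool
    ref_anticodon: str
    var_anticodon: str | None         # None if an anticodon base was deleted
    synonymous: bool | None           # None unless the anticodon changed
    wt_identity: str
    var_identity: str | None
    g3u70_created: bool | None        # None when position 3 or 70 is absent


def edit_sprinzl_label(edit: Edit, locus: TRNALocus) -> str:
    """Sprinzl label for one edit.

    Substitutions and deletions take the label of the (first) affected
    reference base; insertions take the label of the preceding reference
    position with a ``+`` marker.
    """
    if edit.kind == "ins":
        anchor = edit.gene_pos - 1
        if anchor < 0:
            return locus.sprinzl_map[0] + "+"
        return locus.sprinzl_map[anchor] + "+"
    return locus.sprinzl_map[edit.gene_pos]


def _variant_base_at(
    locus: TRNALocus,
    var_seq: str,
    pos_map: Sequence[int | None],
    label: str,
) -> str | None:
    ref_pos = locus.position_of(label)
    if ref_pos is None:
        return None
    var_pos = pos_map[ref_pos]
    return None if var_pos is None else var_seq[var_pos]


def variant_anticodon(locus: TRNALocus, edits: Sequence[Edit]) -> str | None:
    """Anticodon of the variant allele (bases at Sprinzl 34-36)."""
    var_seq = apply_edits(locus.gene_seq, edits)
    pos_map = variant_position_map(len(locus.gene_seq), edits)
    bases = [
        _variant_base_at(locus, var_seq, pos_map, lab) for lab in ANTICODON_LABELS
    ]
    if any(b is None for b in bases):
        return None
    return "".join(bases)  # type: ignore[arg-type]


@dataclass(frozen=True)
class AnticodonClassification:
    synonymous: bool
    wt_identity: str
    var_identity: str


def classify_anticodon_variant(
    ref_anticodon: str,
    var_anticodon: str,
    code: GeneticCode | None = None,
) -> AnticodonClassification:
    """Synonymous vs non-synonymous anticodon change, with identities.

    Synonymous means both anticodons decode the same amino acid (e.g. a
    G34A wobble change); STOP is a legal variant identity (an anticodon
    turned towards a stop codon).
    """
    code = code or GeneticCode.standard()
    wt = decode_anticodon(ref_anticodon, code)
    var = decode_anticodon(var_anticodon, code)
    return AnticodonClassification(
        synonymous=(wt == var), wt_identity=wt, var_identity=var
    )


def detect_g3u70(
    locus: TRNALocus, edits: Sequence[Edit]
) -> bool | None:
    """Does this variant *create* a G3:U70 acceptor-stem pair?

    True iff the variant allele has G at Sprinzl 3 and T (U) at Sprinzl 70
    while the reference 3:70 pair is not already G:T.  The reference pair
    need not be a Watson-Crick pair (a C3:U70 mismatch converted to G3:U70
    counts as creation).  Returns None when the locus lacks position 3 or
    70, where the flag is not evaluable.
    """
    pos3, pos70 = locus.position_of("3"), locus.position_of("70")
    if pos3 is None or pos70 is None:
        return None
    ref3, ref70 = locus.gene_seq[pos3], locus.gene_seq[pos70]
    var_seq = apply_edits(locus.gene_seq, edits)
    pos_map = variant_position_map(len(locus.gene_seq), edits)
    var3 = _variant_base_at(locus, var_seq, pos_map, "3")
    var70 = _variant_base_at(locus, var_seq, pos_map, "70")
    if var3 != "G" or var70 != "T":
        return False
    return not (ref3 == "G" and ref70 == "T")


def annotate_variant(
    record: VariantRecord | Sequence[Edit],
    locus: TRNALocus,
    code: GeneticCode | None = None,
) -> StructuralAnnotation:
    """Annotate a variant's edits onto the cloverleaf."""
    edits = tuple(record.edits) if isinstance(record, VariantRecord) else tuple(record)
    code = code or GeneticCode.standard()
    labels = tuple(edit_sprinzl_label(e, locus) for e in edits)
    regions = tuple(region_of_label(lab) for lab in labels)
    var_ac = variant_anticodon(locus, edits)
    changed = var_ac != locus.anticodon
    wt_identity = decode_anticodon(locus.anticodon, code)
    var_identity = decode_anticodon(var_ac, code) if var_ac else None
    synonymous: bool | None = None
    if changed and var_ac is not None:
        synonymous = var_identity == wt_identity
    return StructuralAnnotation(
        labels=labels,
        regions=regions,
        anticodon_changed=changed,
        ref_anticodon=locus.anticodon,
        var_anticodon=var_ac,
        synonymous=synonymous,
        wt_identity=wt_identity,
        var_identity=var_identity,
        g3u70_created=detect_g3u70(locus, edits),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


class ScoringWindowError(ValueError):
    """A promoter box window has no scoreable positions on this gene."""


@dataclass(frozen=True)
class BoxScores:
    abox: float
    bbox: float

    @property
    def total(self) -> float:
        return self.abox + self.bbox


@dataclass(frozen=True)
class FoldScores:
    primary: float
    secondary: float

    @property
    def total(self) -> float:
        return self.primary + self.secondary

    @property
    def pseudo(self) -> bool:
        return (
            self.primary < PSEUDO_PRIMARY_BITS
            or self.secondary < PSEUDO_SECONDARY_BITS
        )


@dataclass(frozen=True)
class ScoreReport:
    """Promoter and fold scores of a variant allele vs its reference."""

    ref_box: BoxScores
    var_box: BoxScores
    ref_fold: FoldScores
    var_fold: FoldScores

    @property
    def delta_box_total(self) -> float:
        return self.var_box.total - self.ref_box.total

    @property
    def delta_fold_total(self) -> float:
        return self.var_fold.total - self.ref_fold.total

    @property
    def classification(self) -> str:
        return classify_delta(self.delta_fold_total)

    @property
    def pseudo_transition(self) -> str:
        ref_p, var_p = self.ref_fold.pseudo, self.var_fold.pseudo
        if ref_p == var_p:
            return "none"
        return "functional_to_pseudo" if var_p else "pseudo_to_functional"


def classify_delta(delta: float, band: float = NEUTRAL_BAND_BITS) -> str:
    """Classify a score change: neutral when it does not exceed 1 bit."""
    if delta > band:
        return "increase"
    if delta < -band:
        return "decrease"
    return "neutral"


def pair_score(base_i: str | None, base_j: str | None) -> float:
    if base_i is None or base_j is None:
        return MISMATCH_PAIR_SCORE
    if base_i == base_j:  # A:A etc. cannot pair
        return MISMATCH_PAIR_SCORE
    return PAIR_SCORES.get(frozenset({base_i, base_j}), MISMATCH_PAIR_SCORE)


class ScoringModel:
    """Sprinzl-aligned log-odds profiles estimated from a reference set.

    Per-column base probabilities use add-one smoothing over the loci that
    possess the column; log-odds are log2(p / 0.25).  A deleted column
    contributes its minimum log-odds (a deletion can never look like
    consensus).
    """

    def __init__(self, logodds: Mapping[str, Mapping[str, float]]):
        self.logodds = {lab: dict(scores) for lab, scores in logodds.items()}
        self._col_min = {
            lab: min(scores.values()) for lab, scores in self.logodds.items()
        }

    @classmethod
    def from_reference(cls, ref: ReferenceSet) -> "ScoringModel":
        counts: dict[str, dict[str, int]] = {}
        for locus in ref:
            for pos, lab in enumerate(locus.sprinzl_map):
                if lab == INTRON_LABEL:
                    continue
                col = counts.setdefault(lab, {b: 0 for b in "ACGT"})
                col[locus.gene_seq[pos]] += 1
        logodds: dict[str, dict[str, float]] = {}
        for lab, col in counts.items():
            n = sum(col.values())
            logodds[lab] = {
                b: math.log2(((col[b] + 1) / (n + 4)) / 0.25) for b in "ACGT"
            }
        return cls(logodds)

    # -- helpers -----------------------------------------------------------

    def _column_score(self, label: str, base: str | None) -> float:
        col = self.logodds.get(label)
        if col is None:
            return 0.0
        if base is None:
            return self._col_min[label]
        return col.get(base, self._col_min[label])

    def _variant_bases(
        self, locus: TRNALocus, edits: Sequence[Edit]
    ) -> dict[str, str | None]:
        """Sprinzl label -> variant base (None = deleted) for this allele."""
        if not edits:
            return {
                lab: locus.gene_seq[pos]
                for pos, lab in enumerate(locus.sprinzl_map)
                if lab != INTRON_LABEL
            }
        var_seq = apply_edits(locus.gene_seq, edits)
        pos_map = variant_position_map(len(locus.gene_seq), edits)
        out: dict[str, str | None] = {}
        for pos, lab in enumerate(locus.sprinzl_map):
            if lab == INTRON_LABEL:
                continue
            vp = pos_map[pos]
            out[lab] = None if vp is None else var_seq[vp]
        return out

    # -- public ------------------------------------------------------------

    def score_ab_box(
        self, locus: TRNALocus, edits: Sequence[Edit] = ()
    ) -> BoxScores:
        """A-box/B-box log-odds sums for the (possibly edited) gene."""
        bases = self._variant_bases(locus, edits)
        scores = []
        for name, window in (("A box", A_BOX_LABELS), ("B box", B_BOX_LABELS)):
            present = [lab for lab in window if lab in bases]
            if not present:
                raise ScoringWindowError(
                    f"{locus.locus_id}: no {name} positions on this gene"
                )
            scores.append(sum(self._column_score(lab, bases[lab]) for lab in present))
        return BoxScores(abox=scores[0], bbox=scores[1])

    def score_fold(
        self, locus: TRNALocus, edits: Sequence[Edit] = ()
    ) -> FoldScores:
        """Primary (PSSM) + secondary (pair table) fold score in bits."""
        bases = self._variant_bases(locus, edits)
        primary = sum(
            self._column_score(lab, base) for lab, base in bases.items()
        )
        pairing = locus.pairing
        secondary = 0.0
        for i, j in enumerate(pairing):
            if j <= i:
                continue
            lab_i, lab_j = locus.sprinzl_map[i], locus.sprinzl_map[j]
            secondary += pair_score(bases.get(lab_i), bases.get(lab_j))
        return FoldScores(primary=primary, secondary=secondary)

    def delta_scores(
        self, record: VariantRecord | Sequence[Edit], locus: TRNALocus
    ) -> ScoreReport:
        """Score a variant allele against its reference locus."""
        edits = (
            tuple(record.edits)
            if isinstance(record, VariantRecord)
            else tuple(record)
        )
        return ScoreReport(
            ref_box=self.score_ab_box(locus),
            var_box=self.score_ab_box(locus, edits),
            ref_fold=self.score_fold(locus),
            var_fold=self.score_fold(locus, edits),
        )


# module-level conveniences mirroring the operation names ------------------


def score_ab_box(
    locus: TRNALocus, model: ScoringModel, edits: Sequence[Edit] = ()
) -> BoxScores:
    return model.score_ab_box(locus, edits)


def score_fold(
    locus: TRNALocus, model: ScoringModel, edits: Sequence[Edit] = ()
) -> FoldScores:
    return model.score_fold(locus, edits)


def delta_scores(
    record: VariantRecord | Sequence[Edit], locus: TRNALocus, model: ScoringModel
) -> ScoreReport:
    return model.delta_scores(record, locus)
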