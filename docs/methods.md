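# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `trnavarseq`.

## Reference model

A locus is a tRNA gene on its coding strand with 20 nt of 5′ and 5 nt of
3′ flanking sequence, genomic coordinates (0-based half-open internally;
every *reported* position is 1-based plus-strand), a dot-bracket secondary
structure and a Sprinzl map assigning each gene position a canonical label.
Sprinzl labels are `"1"`–`"76"` plus the D-loop insertions `"17a"`,
`"20a"`, `"20b"`; positions of the long variable arm of serine/leucine-type
tRNAs are labelled `"e1"`, `"e2"`, … in 5′→3′ order (a deliberately
simplified scheme — the full e11–e27 sub-numbering distinguishes paired
and unpaired variable-arm positions, a distinction nothing downstream
consumes); intronic positions are labelled `"intron"`. Sprinzl maps are
supplied as data with each locus, not inferred by folding: the annotation
task is to transfer curated numbering, not to predict structure.
Validation enforces flank lengths, pairing involution, label uniqueness
and agreement between the anticodon field and the bases at labels 34–36.

Anticodon decoding uses the standard nuclear genetic code; the decoded
codon is the reverse complement of the anticodon. Selenocysteine (TCA
anticodon), iMet and undetermined loci are exempt from the
isotype-consistency check, but decoding itself always follows the code
table (a SeC tRNA's anticodon still reads as STOP); biological recoding is
metadata, not a code change.

Structural regions used in annotation: acceptor stem 1–7/66–72, D-arm
10–25, anticodon stem 27–31/39–43, anticodon loop 32–33/37–38, anticodon
34–36, variable arm 44–48 and `e*`, T-arm 49–65, discriminator 73; linker
positions (8, 9, 26, 74–76) report `"other"`.

## Read merging

The mate is reverse-complemented and all suffix/prefix overlaps of length
≥ `min_overlap` (default 20) with mismatch fraction ≤ `max_mismatch_frac`
(default 0.1) are enumerated; the lowest mismatch fraction wins, ties
break toward the longer overlap, then toward higher aggregate overlap
quality. These defaults are this package's own choices — merging tools
differ here and nothing downstream is sensitive to them at the simulated
error rates. Overlap disagreements resolve to the higher-quality base
(first read on quality ties), the consensus quality is the maximum of the
two, and `N` is treated as uninformative: it never counts as a mismatch
and never wins a consensus column.

## Locus assignment

Each merged fragment is aligned to every flank-extended query with a
glocal alignment (global in the query, local in the read), computed as the
minimum-edit-distance alignment via edlib; both read orientations are
tried. Identity = matches / aligned query columns, *gap columns count as
mismatches*; this denominator convention is a documented local choice
(BLAST-like tools do not pin it down). Identity is kept as an exact
rational so tie detection is exact: a read is `unique` only when strictly
best, any exact tie yields `ambiguous` with the full tied locus set, and
assignment is invariant to query input order. An identity threshold of
0.95 over a ~100 nt query admits alleles with up to four edits while
rejecting cross-family matches. A full-query exact-substring fast path
handles the dominant case without alignment; a banded search (edit
distance ≤ len(query)·(1−t)/t, the largest distance compatible with
identity t) bounds the rest.

Per individual, identical read sequences over the query span collapse into
alleles with summed depth; alleles under 10× are discarded as likely
error survivors. One retained allele ⇒ assumed homozygous (count 2); two ⇒
heterozygous (1+1); more than two ⇒ the two deepest are kept and a warning
is recorded (the tail case is not specified by the underlying protocol;
this is a local rule).

## Variant calling

Alignments are serialised as BLAST trace-back operations (btop): integer
match runs, two-character edit pairs in (query, subject) = (reference,
read) order, `-` on the gapped side. The pair order was frozen against
BLAST+ output. Flank-extended alignments are trimmed to the gene body:
flank-only differences are dropped, and an insertion at a flank/gene
boundary is kept only when flanked by gene bases on both sides. Indels are
left-aligned within the gene for deterministic normalisation. Two
full-span alleles differing only in flank bases therefore collapse to the
same gene-level allele.

Variant identity is the whole variant gene sequence: an allele carrying
two SNVs is one record, distinct from either single-SNV allele. AF =
carrier allele count / (2 × individuals with a retained genotype at the
locus or ambiguity group); an ambiguity group is one compound locus, and
individuals without coverage at a locus are excluded from its denominator
(whether uncovered individuals belonged in the denominator is not
documented for the original protocol; covered-only is this package's
choice). One heterozygote among 84 covered individuals gives
1/168 ≈ 0.006. Genomic descriptors complement ref/alt and mirror
coordinates for minus-strand loci; insertions render `-/X` anchored on the
base 5′ of the insertion point in gene orientation, deletions `X/-`.

## Scoring

Both scores are position-specific log-odds profiles over Sprinzl-aligned
columns, estimated from the packaged reference set itself with add-one
smoothing against a uniform 0.25 background (log2, bits). Shipping
matrices derived from the reference keeps the package self-contained and
reproducible; the published promoter-scoring matrices are not available in
print.

* **Promoter (EufindtRNA-like):** sums over the A-box window (Sprinzl
  8–19) and B-box window (52–62), standard internal RNA polymerase III
  promoter positions. Missing individual positions (e.g. genes lacking
  17) are skipped; a window with *no* scoreable positions raises an error
  naming the box.
* **Fold (Infernal-like):** primary component = PSSM sum over non-intron
  columns; secondary component = sum over annotated stem pairs of a pair
  table (Watson–Crick +2.0, G:U wobble +1.0, anything else −4.0 bits). A
  deleted column contributes its column minimum; a pair with a deleted
  side scores as a mismatch. The pseudo-tRNA rule is applied to this
  decomposition: primary < 10 bits or secondary < 5 bits ⇒ pseudo.

The covariance-model machinery behind the real Infernal bit score is
deliberately **not** re-implemented; these scores reproduce ordinal
behaviour (increase / neutral within ±1 bit / decrease, and pseudo
transitions), not covariance-model score magnitudes. Score deltas of
variants against their own reference are classified with the ±1-bit
neutral band.

## Synthetic cohorts

The generator's defaults are the desk-scale study conditions used
throughout the tests: 20 loci in isodecoder families with ~20% of loci in
gene-body-identical pairs (identical gene bodies, distinct 5′ flanks), 30
diploid individuals, 60× mean coverage, 2×100 nt reads from 150 nt
fragments (so pairs overlap by ~50 nt), 0.2% iid per-base substitution
error, an AF spectrum of 76% / 20% / 4% across the <5%, 5–50% and >50%
bins, edit counts of 1–4 per allele with fractions 87/10/2.5/0.5%, and a
3% indel fraction among edits. Loci are built from a canonical cloverleaf
template (Watson–Crick stems, conserved loop bases) with family-level and
member-level substitutions whose stem partners are repaired to maintain
pairing — this conservation is what makes reference-derived PSSMs
informative, mirroring real tRNA conservation. Variants are planted
independently per locus; carriers arise by Hardy–Weinberg sampling of two
alleles per individual, so homozygotes occur naturally and realized
carrier counts are Binomial(2N, AF).

What the generator does **not** emulate: empirical error profiles and
quality-score structure (qualities are constant Q37, errors are
substitutions only — planted indels are the only gaps), PCR duplicates,
capture-efficiency bias, linkage between loci, and population structure.
Passing tests on this generator therefore demonstrate the pipeline's
logic (flank-driven disambiguation, depth filtering, whole-allele
calling, census AF), not robustness to instrument-specific artefacts.

## Worked-example catalogs

Two curated sets of published variants (18 anticodon substitutions; 6
G3:U70 creations in glycine tRNAs) are packaged as data, with synthetic
stand-in gene models built from the canonical template. For the glycine
models, strand and coordinates are back-computed from the published
genomic descriptors; the published coordinate spacing between positions 3
and 59/49/58 fixes their Sprinzl maps (positions 17 and 47 absent). The
stand-ins reproduce every published descriptor byte-for-byte and the
published synonymous / non-synonymous / G3:U70 partitions, but their
sequences away from the constrained positions are template-derived, not
genomic.

## Statistics

Welch's t-test uses the Welch–Satterthwaite df (two-sided); the
two-sample proportion test follows R's `prop.test` convention (2×2
chi-squared with Yates continuity correction capped at the absolute
observed−expected difference, df = 1); both were verified against the R
implementations to <1e-9 on fixed fixtures. Bonferroni multiplies by the
number of tests and caps at 1. AF thresholds "<25%" and "<5%" are strict
inequalities. Hierarchical clustering is complete linkage on Euclidean
row distances with leaf order fixed by (merge height, then
lexicographically smallest label) for reproducibility; K-means on
individuals uses a fixed seed with 25 restarts. Accumulation curves draw
100 subsets per size without replacement (mean ± sd); the closed-form
expectation Σ_l (1 − C(N−c_l, k)/C(N, k)) serves as the independent
oracle. The per-cohort carriage matrix stores allele *counts* (0–2 per
variant) with a binary toggle; whether the original analysis used counts
or presence/absence is not documented.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline on the
default 20-locus × 30-individual × 60× cohort (~36,000 read pairs,
~15 s), 10,000 btop round-trips, and 100-replicate planting checks; these
sizes give stable statistics while keeping the whole suite under a minute
of compute.

## Known limitations

* Alignment is minimum-edit-distance; among co-optimal alignments edlib's
  canonical traceback is used, so btop strings for ambiguous indel
  placements are deterministic but not guaranteed to match another
  aligner's traceback (left-alignment normalises the gene-level edits).
* Identity ties are exact rational ties; near-ties (one mismatch apart)
  always resolve to the better hit, with no margin parameter.
* The fold score is ordinal; absolute bit values are not comparable to
  covariance-model scores.
* Ambiguity-group descriptors are anchored on the alphabetically first
  member locus.
* No genotype-likelihood model: calling is a census over depth-filtered
  alleles, as in the underlying protocol.
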