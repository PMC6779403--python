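"""Cohort-level summaries of tRNA gene variation.

Per-individual variant counts at allele-frequency thresholds, the AF
spectrum, the loci x individuals variation matrix with hierarchical and
K-means clustering, variation accumulation (rarefaction) curves, and the
study's significance tests (Welch's t, two-sample proportion test with
continuity correction matching R's ``prop.test``, Bonferroni correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .allele_calling import CohortGenotypes, VariantRecord

DEFAULT_THRESHOLDS = (1.0, 0.25, 0.05)


def _locus_label(key: tuple[str, ...]) -> str:
    return "|".join(key)


# ---------------------------------------------------------------------------
# Carriage matrix
# ---------------------------------------------------------------------------


def carriage_matrix(
    genotypes: CohortGenotypes,
    variants: Sequence[VariantRecord] | None = None,
    max_af: float | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """Loci x individuals matrix of variant-allele carriage counts.

    Cells count the variant alleles an individual carries at a locus (or
    ambiguity group): 0-2 per variant, summed over variants.  Only loci
    with at least one variant appear as rows.  ``max_af`` restricts to
    variants with cohort AF strictly below the threshold (requires
    ``variants``); ``binary`` reduces cells to presence/absence.
    """
    allowed: set[tuple[tuple[str, ...], str]] | None = None
    if max_af is not None:
        if variants is None:
            raise ValueError("max_af filtering requires variant records")
        allowed = {
            (v.locus_key, v.gene_seq)
            for v in variants
            if v.allele_frequency < max_af
        }

    individuals = list(genotypes)
    cells: dict[tuple[str, ...], dict[str, int]] = {}
    for ind, by_key in genotypes.items():
        for key, gt in by_key.items():
            count = 0
            for al in gt.alleles:
                if al.is_reference:
                    continue
                if allowed is not None and (key, al.gene_seq) not in allowed:
                    continue
                count += al.allele_count
            if count:
                cells.setdefault(key, {})[ind] = count

    rows = sorted(cells)
    mat = pd.DataFrame(
        0, index=[_locus_label(k) for k in rows], columns=individuals, dtype=int
    )
    for key in rows:
        for ind, count in cells[key].items():
            mat.loc[_locus_label(key), ind] = count
    if binary:
        mat = (mat > 0).astype(int)
    return mat


def per_individual_counts(
    genotypes: CohortGenotypes,
    variants: Sequence[VariantRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Number of variant-carrying loci per individual, per AF threshold.

    A locus counts toward threshold ``t`` when the individual carries at
    least one variant allele there with cohort AF strictly below ``t``
    (``t = 1.0`` approximates "all variants"; thresholds are strict
    because the study reports "less than" 25% / 5%).
    """
    af_by_variant = {(v.locus_key, v.gene_seq): v.allele_frequency for v in variants}
    data = {}
    for ind, by_key in genotypes.items():
        counts = {t: 0 for t in thresholds}
        for key, gt in by_key.items():
            best_af = None
            for al in gt.alleles:
                if al.is_reference:
                    continue
                af = af_by_variant.get((key, al.gene_seq))
                if af is None:
                    continue
                best_af = af if best_af is None else min(best_af, af)
            if best_af is None:
                continue
            for t in thresholds:
                if best_af < t:
                    counts[t] += 1
        data[ind] = counts
    out = pd.DataFrame(data).T
    out.columns = [f"af_lt_{t:g}" for t in thresholds]
    return out


def af_spectrum(
    afs: Sequence[float],
    bins: Sequence[tuple[float, float]] = ((0.0, 0.05), (0.05, 0.5), (0.5, 1.0)),
) -> list[float]:
    """Fraction of variants per AF bin: [0, 0.05), [0.05, 0.5], (0.5, 1]."""
    afs = list(afs)
    if not afs:
        raise ValueError("no variants: the AF spectrum is undefined")
    fractions = []
    for i, (lo, hi) in enumerate(bins):
        if i == 0:
            n = sum(1 for a in afs if lo <= a < hi)
        elif i == len(bins) - 1:
            n = sum(1 for a in afs if lo < a <= hi)
        else:
            n = sum(1 for a in afs if lo <= a <= hi)
        fractions.append(n / len(afs))
    return fractions


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    matrix: pd.DataFrame
    linkage: np.ndarray
    row_order: list[str]
    column_clusters: dict[str, int]


def _deterministic_leaf_order(
    Z: np.ndarray, labels: Sequence[str]
) -> list[str]:
    """Leaf order fixed by (merge height, then lexicographic smallest label)."""
    n = len(labels)
    # cluster id -> (ordered leaf list, sort key)
    clusters: dict[int, tuple[list[int], tuple]] = {
        i: ([i], (0.0, labels[i])) for i in range(n)
    }
    for m, (a, b, height, _size) in enumerate(Z):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        first, second = sorted((ca, cb), key=lambda c: c[1])
        leaves = first[0] + second[0]
        key = (float(height), min(first[1][1], second[1][1]))
        clusters[n + m] = (leaves, key)
    (leaves, _), = clusters.values()
    return [labels[i] for i in leaves]


def build_matrix_and_cluster(
    genotypes: CohortGenotypes,
    variants: Sequence[VariantRecord] | None = None,
    k: int = 2,
    seed: int = 0,
    n_init: int = 25,
    binary: bool = False,
) -> ClusterResult:
    """Variation matrix with complete-linkage rows and K-means columns.

    Rows (loci) are hierarchically clustered with complete linkage on
    Euclidean distances; individuals (columns) are grouped by K-means with
    ``n_init`` seeded restarts.
    """
    mat = carriage_matrix(genotypes, variants, binary=binary)
    if mat.shape[0] < 1 or mat.shape[1] < 2:
        raise ValueError("clustering needs >=1 variant locus and >=2 individuals")
    if not mat.to_numpy().any():
        raise ValueError("variation matrix is all zero")
    if mat.shape[0] == 1:  # a single variant row clusters trivially
        Z = np.empty((0, 4))
        row_order = list(mat.index)
    else:
        Z = hierarchy.linkage(
            pdist(mat.to_numpy(), metric="euclidean"), method="complete"
        )
        row_order = _deterministic_leaf_order(Z, list(mat.index))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    col_labels = km.fit_predict(mat.to_numpy().T)
    return ClusterResult(
        matrix=mat,
        linkage=Z,
        row_order=row_order,
        column_clusters={ind: int(c) for ind, c in zip(mat.columns, col_labels)},
    )


# ---------------------------------------------------------------------------
# Accumulation curve
# ---------------------------------------------------------------------------


def accumulation_curve(
    carriage: pd.DataFrame,
    n_subsamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Variation accumulation by subsampling individuals without replacement.

    For each subset size k = 1..N, draws ``n_subsamples`` subsets of
    individuals and counts distinct loci with at least one variant carrier
    in the subset; reports mean and standard deviation per k.
    """
    rng = np.random.default_rng(seed)
    mat = carriage.to_numpy() > 0  # loci x individuals, carrier flags
    n_ind = mat.shape[1]
    if n_ind < 1:
        raise ValueError("need at least one individual")
    rows = []
    for k in range(1, n_ind + 1):
        counts = np.empty(n_subsamples, dtype=int)
        for s in range(n_subsamples):
            cols = rng.choice(n_ind, size=k, replace=False)
            counts[s] = int(mat[:, cols].any(axis=1).sum())
        rows.append(
            {"k": k, "mean": float(counts.mean()), "sd": float(counts.std())}
        )
    return pd.DataFrame(rows)


def expected_accumulation(carriage: pd.DataFrame) -> list[float]:
    """Closed-form expected accumulation curve.

    E[distinct variant loci among k of N individuals] =
    sum over loci of 1 - C(N - c, k) / C(N, k), where c is the number of
    individuals carrying a variant at that locus.
    """
    mat = carriage.to_numpy() > 0
    n_ind = mat.shape[1]
    carriers = mat.sum(axis=1)
    out = []
    for k in range(1, n_ind + 1):
        expected = 0.0
        for c in carriers:
            expected += 1.0 - math.comb(n_ind - int(c), k) / math.comb(n_ind, k)
        out.append(expected)
    return out


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided unpaired Welch's t-test (Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t-test needs n >= 2 per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return WelchResult(t=0.0, df=float(len(x) + len(y) - 2), p=1.0)
        raise ValueError("zero variance in both groups: p undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass(frozen=True)
class ProportionResult:
    statistic: float
    p: float


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> ProportionResult:
    """Two-sample test of equal proportions, R ``prop.test`` convention.

    Chi-squared test on the 2x2 success/failure table with Yates continuity
    correction (df = 1, two-sided).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if min(n1, n2) == 0:
        raise ValueError("group sizes must be positive")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if k1 / n1 == k2 / n2:
        return ProportionResult(statistic=0.0, p=1.0)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    expected = np.outer(row, col) / obs.sum()
    yates = min(0.5, float(np.abs(obs - expected).min())) if correction else 0.0
    chi2 = float((((np.abs(obs - expected) - yates) ** 2) / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return ProportionResult(statistic=chi2, p=p)


def bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[bool]]:
    """Bonferroni-adjusted p-values (capped at 1) and reject decisions."""
    reject, adjusted, _, _ = multipletests(
        list(p_values), alpha=alpha, method="bonferroni"
    )
    return [float(p) for p in adjusted], [bool(r) for r in reject]
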