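"""Pairwise distance and similarity kernels.

* Bruvo distance for dosage-ambiguous polyploid microsatellite phenotypes,
  combining the stepwise-mutation allele kernel ``1 - 2**(-|dx|)`` with
  minimum-cost allele matching and genome-addition / genome-loss handling of
  unequal apparent ploidy.
* Goldstein (delta-mu squared) distance for haploid cpSSR haplotypes.
* The geometric similarity index on STRUCTURE membership vectors
  (dot product, optionally cosine-normalized), with distance 1 - r.
* Nei's standard genetic distance on band-presence frequency profiles.
* Binary squared-Euclidean (mismatch count) for AMOVA on presence/absence
  data.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import AllelePhenotype, DistanceMatrix, GenotypeMatrix, Haplotype, QMatrix

__all__ = [
    "SimilarityResult",
    "bruvo_allele_distance",
    "bruvo_genotype_distance",
    "bruvo_sample_distance",
    "bruvo_distance_matrix",
    "goldstein_distance",
    "goldstein_distance_matrix",
    "geometric_similarity",
    "q_distance_matrix",
    "nei_band_distance",
    "binary_squared_euclidean",
]


# ---------------------------------------------------------------------------
# Bruvo distance
# ---------------------------------------------------------------------------

def bruvo_allele_distance(x: int, y: int) -> float:
    """Stepwise-mutation kernel between two alleles: ``1 - 2**(-|x - y|)``.

    Zero for identical alleles; approaches 1 as the repeat-count difference
    grows, reflecting the geometrically decaying probability of large
    stepwise jumps.
    """
    return 1.0 - 2.0 ** (-abs(int(x) - int(y)))


def _allele_cost(a: Sequence[int], b: Sequence[int]) -> np.ndarray:
    av = np.asarray(a, dtype=float)[:, None]
    bv = np.asarray(b, dtype=float)[None, :]
    return 1.0 - 2.0 ** (-np.abs(av - bv))


@functools.lru_cache(maxsize=1_000_000)
def _bruvo_sets(small: tuple[int, ...], large: tuple[int, ...]) -> float:
    """Core Bruvo computation on sorted allele tuples, small first (cached —
    phenotype pairs recur heavily across sample pairs and bootstrap loci)."""
    if small == large:
        return 0.0
    k2 = len(large)
    cost = _allele_cost(large, small)  # rows: large alleles, cols: small alleles
    if len(small) == k2:
        rows, cols = linear_sum_assignment(cost)
        return float(cost[rows, cols].sum() / k2)
    m = k2 - len(small)
    # genome addition: wildcard columns, each matchable to any small allele
    wildcard = cost.min(axis=1, keepdims=True)
    add_cost = np.hstack([cost, np.repeat(wildcard, m, axis=1)])
    rows, cols = linear_sum_assignment(add_cost)
    addition = add_cost[rows, cols].sum() / k2
    # genome loss: rectangular assignment; unmatched large alleles pair with
    # their own virtual copies at zero cost
    rows, cols = linear_sum_assignment(cost)
    loss = cost[rows, cols].sum() / k2
    return float(0.5 * (addition + loss))


def bruvo_genotype_distance(a: AllelePhenotype, b: AllelePhenotype) -> float:
    """Bruvo distance between two allele phenotypes at one locus.

    Equal set sizes: minimum over bijections of the mean allele distance.
    Unequal sizes (apparent ploidy differs because dosage is hidden): the
    smaller set is padded with virtual alleles under two models —

    * genome addition: virtual alleles are copies of the smaller set's own
      alleles (minimized over copies and bijections);
    * genome loss: virtual alleles are copies of the larger set's alleles.

    The reported value is the mean of the two models.  Both minimizations are
    solved as linear assignment problems: padding with a free copy of the
    smaller set is equivalent to a wildcard column whose cost to each large
    allele is that allele's nearest small allele, and padding from the larger
    set lets every unmatched large allele pair with its own copy at zero cost.
    """
    if a.is_missing or b.is_missing:
        raise ValueError("Bruvo distance undefined for missing phenotypes")
    x = tuple(sorted(a.alleles))
    y = tuple(sorted(b.alleles))
    if len(x) > len(y):
        x, y = y, x
    elif len(x) == len(y) and x > y:
        x, y = y, x
    return _bruvo_sets(x, y)


def bruvo_sample_distance(
    genotypes: GenotypeMatrix, sample_a: str, sample_b: str,
    loci: Sequence[str] | None = None,
) -> float:
    """Mean per-locus Bruvo distance over loci non-missing in both samples.

    ``loci`` restricts (with repetition allowed — used by the locus
    bootstrap) the loci considered; default is every locus of the matrix.
    """
    loci = list(loci) if loci is not None else genotypes.loci
    total = 0.0
    used = 0
    for locus in loci:
        pa = genotypes.phenotype(sample_a, locus)
        pb = genotypes.phenotype(sample_b, locus)
        if pa.is_missing or pb.is_missing:
            continue
        total += bruvo_genotype_distance(pa, pb)
        used += 1
    if used == 0:
        raise ValueError(
            f"no shared non-missing locus between {sample_a!r} and {sample_b!r}"
        )
    return total / used


def _bruvo_locus_matrix(genotypes: GenotypeMatrix, locus: str) -> np.ndarray:
    """Pairwise Bruvo distances at one locus (NaN where either sample is
    missing), cached on the genotype matrix so locus bootstraps only pay
    for each locus once."""
    cache = genotypes.__dict__.setdefault("_bruvo_locus_cache", {})
    if locus in cache:
        return cache[locus]
    ids = genotypes.samples
    n = len(ids)
    sets = [tuple(sorted(genotypes.alleles(s, locus))) for s in ids]
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        if not sets[i]:
            d[i, i] = np.nan
            continue
        for j in range(i + 1, n):
            if not sets[j]:
                continue
            x, y = sets[i], sets[j]
            if len(x) > len(y) or (len(x) == len(y) and x > y):
                x, y = y, x
            d[i, j] = d[j, i] = _bruvo_sets(x, y)
    cache[locus] = d
    return d


def bruvo_distance_matrix(
    genotypes: GenotypeMatrix,
    loci: Sequence[str] | None = None,
    missing_pair: str = "raise",
) -> DistanceMatrix:
    """Pairwise multilocus Bruvo distances over all samples.

    ``loci`` may repeat entries (locus bootstrap).  Pairs sharing no scored
    locus either raise (default) or, with ``missing_pair="max"``, get the
    maximal distance 1.0 — used when stringent rank thresholds empty whole
    profiles.
    """
    ids = genotypes.samples
    loci = list(loci) if loci is not None else genotypes.loci
    stack = np.stack([_bruvo_locus_matrix(genotypes, l) for l in loci])
    with np.errstate(invalid="ignore"):
        d = np.nanmean(stack, axis=0)
    bad = np.isnan(d)
    if bad.any():
        if missing_pair == "max":
            d[bad] = 1.0
            np.fill_diagonal(d, 0.0)
        else:
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"no shared non-missing locus between {ids[i]!r} and {ids[j]!r}"
            )
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Goldstein distance
# ---------------------------------------------------------------------------

def goldstein_distance(h1: Haplotype, h2: Haplotype, mode: str = "mean") -> float:
    """Goldstein (delta-mu)^2 distance between two haplotypes.

    Squared repeat-count differences per locus, averaged (``mode="mean"``,
    the default) or summed (``mode="sum"``) over loci.
    """
    if len(h1.repeats) != len(h2.repeats):
        raise ValueError(
            f"haplotype length mismatch: {len(h1.repeats)} vs {len(h2.repeats)}"
        )
    sq = [(x - y) ** 2 for x, y in zip(h1.repeats, h2.repeats)]
    return float(sum(sq) / len(sq)) if mode == "mean" else float(sum(sq))


def goldstein_distance_matrix(
    haplotypes: Sequence[Haplotype], mode: str = "mean"
) -> DistanceMatrix:
    ids = [h.sample_id for h in haplotypes]
    n = len(ids)
    arr = np.array([h.repeats for h in haplotypes], dtype=float)
    diff = arr[:, None, :] - arr[None, :, :]
    d = (diff ** 2).mean(axis=2) if mode == "mean" else (diff ** 2).sum(axis=2)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# geometric similarity on Q-matrix rows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityResult:
    """Similarity r in [0, 1]; the associated distance is 1 - r."""

    r: float
    normalized: bool

    @property
    def distance(self) -> float:
        return 1.0 - self.r


def geometric_similarity(
    p_i: Sequence[float], p_j: Sequence[float], normalized: bool = True
) -> SimilarityResult:
    """Geometric similarity index between two membership vectors.

    Raw mode is the plain dot product ``r = sum_k p_ik p_jk``.  Because the
    dot product of a non-degenerate membership vector with itself is < 1,
    the identity property (identical vectors score exactly 1) only holds
    after cosine normalization — dividing by the product of the Euclidean
    norms — which is therefore the default.
    """
    a = np.asarray(p_i, dtype=float)
    b = np.asarray(p_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("membership vectors must have equal K")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero membership vector")
    r = float(a @ b)
    if normalized:
        if np.array_equal(a, b):
            r = 1.0  # exact identity, immune to sqrt round-off
        else:
            r = min(r / (na * nb), 1.0)
    return SimilarityResult(r, normalized)


def q_distance_matrix(q: QMatrix, normalized: bool = True) -> DistanceMatrix:
    """Pairwise 1 - r distances over the rows of a Q-matrix."""
    p = q.p
    if normalized:
        norms = np.linalg.norm(p, axis=1)
        r = (p @ p.T) / np.outer(norms, norms)
        r = np.minimum(r, 1.0)
    else:
        r = p @ p.T
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return DistanceMatrix(q.sample_ids, d)


# ---------------------------------------------------------------------------
# Nei distance on band frequencies, binary kernel
# ---------------------------------------------------------------------------

def nei_band_distance(freq_a: Sequence[float], freq_b: Sequence[float]) -> float:
    """Nei's standard genetic distance on band-presence frequency profiles.

    ``-ln(J_AB / sqrt(J_A * J_B))`` with ``J_AB = sum f_A f_B`` and the
    within-population identities ``J_A``, ``J_B``.  Orthogonal profiles have
    ``J_AB = 0`` and an infinite distance, reported as an error.
    """
    fa = np.asarray(freq_a, dtype=float)
    fb = np.asarray(freq_b, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("band lists differ in length")
    j_a = float(fa @ fa)
    j_b = float(fb @ fb)
    if j_a == 0.0 or j_b == 0.0:
        raise ValueError("all-zero band frequency vector")
    j_ab = float(fa @ fb)
    if j_ab == 0.0:
        raise ValueError("orthogonal band profiles: Nei distance is infinite")
    return float(-np.log(j_ab / np.sqrt(j_a * j_b)))


def binary_squared_euclidean(a: Sequence[int], b: Sequence[int]) -> int:
    """Squared Euclidean distance between presence/absence vectors (= number
    of mismatching positions)."""
    av = np.asarray(a)
    bv = np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("vectors differ in length")
    for v in (av, bv):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")
    return int(np.sum(av != bv))
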