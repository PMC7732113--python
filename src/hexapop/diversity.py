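"""Diversity and differentiation statistics for dosage-ambiguous polyploids.

Because allele copy number is unobservable in a hexaploid phenotype, allele
frequencies are estimated under an equal-dosage assumption: each individual
contributes uniformly over its observed alleles.  Diversity within a
population is summarized as the Shannon index over distinct multilocus
genotypes (clonal diversity: it equals ln N exactly when all N genotypes are
unique), allele counts and private alleles.  Differentiation between
populations is measured with Jost's D and Nei's G_ST on the estimated
frequencies, with bootstrap significance, and with a binary AMOVA (Phi_PT,
permutation test) on the presence/absence expansion of the genotypes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GenotypeMatrix

logger = logging.getLogger("hexapop")

__all__ = [
    "DiversitySummary",
    "DifferentiationResult",
    "AmovaResult",
    "estimate_allele_frequencies",
    "shannon_genotype_diversity",
    "count_alleles_and_private",
    "pairwise_differentiation",
    "to_presence_absence",
    "band_frequencies",
    "amova_binary",
]


@dataclass(frozen=True)
class DiversitySummary:
    population: str
    n_samples: int
    total_alleles: int
    shannon_h: float
    private_alleles: int


@dataclass(frozen=True)
class DifferentiationResult:
    population_a: str
    population_b: str
    jost_d: float
    g_st: float
    p_jost_d: float | None
    p_g_st: float | None
    n_boot: int


@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float  # may be negative (method-of-moments estimator)
    sigma2_within: float
    pct_among: float  # display percentage, Phi truncated at 0
    pct_within: float
    phi_pt: float
    p_value: float | None
    n_perm: int


# ---------------------------------------------------------------------------
# allele frequencies and diversity
# ---------------------------------------------------------------------------

def estimate_allele_frequencies(
    genotypes: GenotypeMatrix, population: str
) -> dict[str, dict[int, float]]:
    """Dosage-agnostic allele frequencies per locus for one population.

    Each individual's contribution at a locus is uniform over its observed
    alleles; the population frequency is the mean contribution over
    individuals non-missing at that locus.  Loci missing in every individual
    are skipped with a warning.
    """
    samples = genotypes.samples_of(population)
    if not samples:
        raise ValueError(f"population {population!r} is empty")
    freqs: dict[str, dict[int, float]] = {}
    for locus in genotypes.loci:
        contrib: dict[int, float] = {}
        n_used = 0
        for s in samples:
            alleles = genotypes.alleles(s, locus)
            if not alleles:
                continue
            w = 1.0 / len(alleles)
            for a in alleles:
                contrib[a] = contrib.get(a, 0.0) + w
            n_used += 1
        if n_used == 0:
            logger.warning(
                "population %s: locus %s missing in all individuals; skipped",
                population, locus,
            )
            continue
        freqs[locus] = {a: v / n_used for a, v in sorted(contrib.items())}
    return freqs


def shannon_genotype_diversity(genotypes: GenotypeMatrix, population: str) -> float:
    """Shannon index over distinct multilocus genotypes: H = -sum f ln f.

    Equals ln N when all N genotypes in the population are distinct, and is
    depressed by clonal repetition.
    """
    samples = genotypes.samples_of(population)
    if not samples:
        raise ValueError(f"population {population!r} is empty")
    keys = [
        tuple(genotypes.alleles(s, l) for l in genotypes.loci) for s in samples
    ]
    counts = pd.Series(keys).value_counts().to_numpy(dtype=float)
    f = counts / counts.sum()
    return float(-(f * np.log(f)).sum())


def count_alleles_and_private(genotypes: GenotypeMatrix) -> list[DiversitySummary]:
    """Per-population totals of observed alleles, Shannon genotype diversity,
    and private alleles (alleles seen in exactly one population)."""
    pops = genotypes.populations
    observed: dict[str, dict[str, set[int]]] = {
        p: {l: set() for l in genotypes.loci} for p in pops
    }
    for s in genotypes.samples:
        p = genotypes.population_of[s]
        for l in genotypes.loci:
            observed[p][l] |= genotypes.alleles(s, l)
    out = []
    for p in pops:
        total = sum(len(v) for v in observed[p].values())
        private = 0
        for l in genotypes.loci:
            for a in observed[p][l]:
                if all(a not in observed[q][l] for q in pops if q != p):
                    private += 1
        out.append(
            DiversitySummary(
                p,
                len(genotypes.samples_of(p)),
                total,
                shannon_genotype_diversity(genotypes, p),
                private,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Jost's D and G_ST
# ---------------------------------------------------------------------------

def _freq_d_gst(va: np.ndarray, vb: np.ndarray) -> tuple[float, float] | None:
    """Per-locus Jost's D and G_ST from two allele-frequency vectors; None
    for monomorphic loci (H_T = 0, no differentiation signal)."""
    h_s = 0.5 * ((1.0 - va @ va) + (1.0 - vb @ vb))
    mean = 0.5 * (va + vb)
    h_t = 1.0 - float(mean @ mean)
    if h_t <= 0.0:
        return None
    d = (h_t - h_s) / (1.0 - h_s) * 2.0 if h_s < 1.0 else 0.0
    g = (h_t - h_s) / h_t
    return float(d), float(g)


def _contribution_matrix(
    genotypes: GenotypeMatrix, samples: Sequence[str], locus: str,
    allele_index: Mapping[int, int],
) -> np.ndarray:
    """Individual-level frequency contributions (uniform over observed
    alleles); rows of missing individuals are NaN."""
    out = np.full((len(samples), len(allele_index)), np.nan)
    for i, s in enumerate(samples):
        alleles = genotypes.alleles(s, locus)
        if not alleles:
            continue
        out[i] = 0.0
        w = 1.0 / len(alleles)
        for a in alleles:
            out[i, allele_index[a]] = w
    return out


def _global_d_gst(
    genotypes: GenotypeMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
) -> tuple[float, float]:
    """Across-locus mean Jost's D and G_ST between two sample groups."""
    ds, gs = [], []
    for locus in genotypes.loci:
        alleles = sorted(
            set().union(
                *(genotypes.alleles(s, locus) for s in [*samples_a, *samples_b])
            )
        )
        if not alleles:
            continue
        index = {a: k for k, a in enumerate(alleles)}
        a = _contribution_matrix(genotypes, samples_a, locus, index)
        b = _contribution_matrix(genotypes, samples_b, locus, index)
        if np.isnan(a).all() or np.isnan(b).all():
            continue
        res = _freq_d_gst(np.nanmean(a, axis=0), np.nanmean(b, axis=0))
        if res is None:
            continue
        ds.append(res[0])
        gs.append(res[1])
    if not ds:
        return 0.0, 0.0
    return float(np.mean(ds)), float(np.mean(gs))


def pairwise_differentiation(
    genotypes: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DifferentiationResult:
    """Pairwise Jost's D and G_ST between two populations.

    Per locus, with dosage-agnostic frequencies: H_S is the mean gene
    diversity of the two populations, H_T the gene diversity of their mean
    frequency vector; Jost's D = (H_T - H_S)/(1 - H_S) * n/(n-1) with n = 2
    populations, G_ST = (H_T - H_S)/H_T.  Global values are across-locus
    means (monomorphic loci skipped).  Significance: individuals are
    bootstrapped within populations ``n_boot`` times and the p-value is the
    proportion of replicates in which the statistic falls to or below zero.
    """
    sa = genotypes.samples_of(pop_a)
    sb = genotypes.samples_of(pop_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both populations need >= 2 samples")
    # per-locus contribution matrices shared by the observed statistic and
    # every bootstrap replicate
    mats: list[tuple[np.ndarray, np.ndarray]] = []
    for locus in genotypes.loci:
        alleles = sorted(
            set().union(*(genotypes.alleles(s, locus) for s in [*sa, *sb]))
        )
        if not alleles:
            continue
        index = {a: k for k, a in enumerate(alleles)}
        mats.append(
            (
                _contribution_matrix(genotypes, sa, locus, index),
                _contribution_matrix(genotypes, sb, locus, index),
            )
        )

    def global_stats(idx_a: np.ndarray, idx_b: np.ndarray) -> tuple[float, float]:
        ds, gs = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            for a, b in mats:
                fa = np.nanmean(a[idx_a], axis=0)
                fb = np.nanmean(b[idx_b], axis=0)
                if np.isnan(fa).any() or np.isnan(fb).any():
                    continue
                res = _freq_d_gst(fa, fb)
                if res is None:
                    continue
                ds.append(res[0])
                gs.append(res[1])
        if not ds:
            return 0.0, 0.0
        return float(np.mean(ds)), float(np.mean(gs))

    full_a = np.arange(len(sa))
    full_b = np.arange(len(sb))
    d_obs, g_obs = global_stats(full_a, full_b)
    p_d = p_g = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        hits_d = hits_g = 0
        for _ in range(n_boot):
            d_b, g_b = global_stats(
                rng.integers(0, len(sa), len(sa)),
                rng.integers(0, len(sb), len(sb)),
            )
            hits_d += d_b <= 0.0
            hits_g += g_b <= 0.0
        p_d = hits_d / n_boot
        p_g = hits_g / n_boot
    return DifferentiationResult(pop_a, pop_b, d_obs, g_obs, p_d, p_g, n_boot)


# ---------------------------------------------------------------------------
# presence/absence expansion and binary AMOVA
# ---------------------------------------------------------------------------

def to_presence_absence(
    genotypes: GenotypeMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand genotypes into a samples x (locus, allele) 0/1 matrix.

    Returns the binary matrix (columns named ``locus:allele``) and a boolean
    samples x loci mask flagging missing cells (their columns are 0-filled).
    """
    columns: list[tuple[str, int]] = []
    for l in genotypes.loci:
        alleles = sorted(
            set().union(*(genotypes.alleles(s, l) for s in genotypes.samples))
        )
        columns.extend((l, a) for a in alleles)
    data = np.zeros((len(genotypes.samples), len(columns)), dtype=int)
    col_index = {c: k for k, c in enumerate(columns)}
    missing = np.zeros((len(genotypes.samples), len(genotypes.loci)), dtype=bool)
    for i, s in enumerate(genotypes.samples):
        for j, l in enumerate(genotypes.loci):
            alleles = genotypes.alleles(s, l)
            if not alleles:
                missing[i, j] = True
                continue
            for a in alleles:
                data[i, col_index[(l, a)]] = 1
    binary = pd.DataFrame(
        data, index=genotypes.samples, columns=[f"{l}:{a}" for l, a in columns]
    )
    mask = pd.DataFrame(missing, index=genotypes.samples, columns=genotypes.loci)
    return binary, mask


def band_frequencies(genotypes: GenotypeMatrix, population: str) -> pd.Series:
    """Presence proportion of each (locus, allele) band within a population,
    computed over individuals non-missing at the band's locus."""
    binary, mask = to_presence_absence(genotypes)
    samples = genotypes.samples_of(population)
    sub = binary.loc[samples]
    msub = mask.loc[samples]
    freqs = {}
    for col in binary.columns:
        locus = col.rsplit(":", 1)[0]
        ok = ~msub[locus]
        freqs[col] = float(sub.loc[ok, col].mean()) if ok.any() else 0.0
    return pd.Series(freqs)


def _amova_components(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Sums of squares and variance components from a squared-distance matrix."""
    n = d2.shape[0]
    pops, counts = np.unique(labels, return_counts=True)
    p = len(pops)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for pop, n_p in zip(pops, counts):
        idx = np.flatnonzero(labels == pop)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(n_p, 1)].sum() / n_p
    ss_among = ss_total - ss_within
    df_among = p - 1
    df_within = n - p
    sigma_w = ss_within / df_within
    n0 = (n - (counts ** 2).sum() / n) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n0
    return ss_among, ss_within, sigma_a, sigma_w, df_among


def amova_binary(
    binary: pd.DataFrame | np.ndarray,
    populations: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Binary AMOVA: partition squared-Euclidean (mismatch-count) distance
    variation among vs within populations; Phi_PT with a permutation test.

    The permutation p-value is ``(1 + #{permuted Phi >= observed}) /
    (n_perm + 1)`` under random reassignment of samples to populations.
    """
    x = np.asarray(binary, dtype=int)
    labels = np.asarray(populations)
    if x.shape[0] != labels.shape[0]:
        raise ValueError("row count does not match population labels")
    pops, counts = np.unique(labels, return_counts=True)
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    if counts.min() < 2:
        raise ValueError("every population needs >= 2 samples")
    diff = x[:, None, :] != x[None, :, :]
    d2 = diff.sum(axis=2).astype(float)  # binary: squared Euclidean = mismatches

    n = x.shape[0]
    p = len(pops)
    ss_a, ss_w, sig_a, sig_w, _ = _amova_components(d2, labels)
    denom = sig_a + sig_w
    phi = sig_a / denom if denom > 0 else 0.0
    phi_disp = max(phi, 0.0)
    pct_among = 100.0 * phi_disp
    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = labels[rng.permutation(n)]
            _, _, sa, sw, _ = _amova_components(d2, perm)
            dn = sa + sw
            phi_p = sa / dn if dn > 0 else 0.0
            hits += phi_p >= phi - 1e-12
        p_value = (1 + hits) / (n_perm + 1)
    return AmovaResult(
        df_among=p - 1,
        df_within=n - p,
        ss_among=ss_a,
        ss_within=ss_w,
        sigma2_among=sig_a,
        sigma2_within=sig_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_pt=phi,
        p_value=p_value,
        n_perm=n_perm,
    )
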