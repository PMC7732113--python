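"""Bayesian population assignment from haploid cpSSR haplotypes.

Queries are scored against reference populations with the Rannala-Mountain
posterior-predictive likelihood: at each locus the probability of the
query's allele is ``(n_a + 1/k) / (n + 1)`` where ``n_a`` is the allele's
count in the reference, ``n`` the reference gene count at the locus, and
``k`` the number of distinct alleles at the locus in the full data set (the
1/k Dirichlet prior keeps alleles unseen in a reference from zeroing the
likelihood).  Normalized scores, Monte-Carlo exclusion (Paetkau
simulation), a leave-one-out self-assignment quality index, reference
merging, and Evanno's delta-K support for the number of STRUCTURE clusters
complete the module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import Haplotype

logger = logging.getLogger("hexapop")

__all__ = [
    "ReferenceSet",
    "AssignmentResult",
    "merge_reference_populations",
    "rannala_mountain_loglik",
    "assign",
    "paetkau_exclusion",
    "self_assignment_quality",
    "evanno_delta_k",
]


class ReferenceSet:
    """Reference populations of haploid multilocus haplotypes.

    ``extra`` haplotypes (e.g. the queries) widen the per-locus distinct
    allele counts ``k_l`` without contributing to any reference frequency.
    """

    def __init__(
        self,
        populations: Mapping[str, Sequence[Haplotype]],
        extra: Sequence[Haplotype] = (),
    ) -> None:
        if not populations:
            raise ValueError("empty reference set")
        lengths = {len(h.repeats) for hs in populations.values() for h in hs}
        lengths |= {len(h.repeats) for h in extra}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent haplotype lengths: {sorted(lengths)}")
        self.n_loci = lengths.pop()
        self.populations = {p: list(hs) for p, hs in populations.items()}
        for p, hs in self.populations.items():
            if not hs:
                raise ValueError(f"reference population {p!r} is empty")
        # per-population, per-locus allele counts
        self.counts: dict[str, list[dict[int, int]]] = {}
        for p, hs in self.populations.items():
            per_locus: list[dict[int, int]] = [dict() for _ in range(self.n_loci)]
            for h in hs:
                for l, a in enumerate(h.repeats):
                    per_locus[l][a] = per_locus[l].get(a, 0) + 1
            self.counts[p] = per_locus
        self.k = [
            len(
                {h.repeats[l] for hs in self.populations.values() for h in hs}
                | {h.repeats[l] for h in extra}
            )
            for l in range(self.n_loci)
        ]

    @property
    def labels(self) -> list[str]:
        return sorted(self.populations)

    def size(self, population: str) -> int:
        return len(self.populations[population])


def merge_reference_populations(
    populations: Mapping[str, Sequence[Haplotype]],
    merge_map: Mapping[str, str],
) -> dict[str, list[Haplotype]]:
    """Relabel and pool reference populations according to ``merge_map``.

    A merge target that collides with an existing label not itself included
    in the merge raises an error; so does a merge producing an empty
    population.
    """
    for old in merge_map:
        if old not in populations:
            raise ValueError(f"merge source {old!r} is not a reference population")
    targets = set(merge_map.values())
    for target in targets:
        sources = {old for old, new in merge_map.items() if new == target}
        if target in populations and target not in sources:
            raise ValueError(
                f"merge target {target!r} collides with an unmerged population"
            )
    merged: dict[str, list[Haplotype]] = {}
    for old, hs in populations.items():
        merged.setdefault(merge_map.get(old, old), []).extend(hs)
    for p, hs in merged.items():
        if not hs:
            raise ValueError(f"merged population {p!r} is empty")
    return merged


def rannala_mountain_loglik(
    query: Haplotype,
    population: str,
    refs: ReferenceSet,
    leave_one_out: bool = False,
) -> float:
    """Rannala-Mountain log-likelihood of a haploid query in one reference.

    ``sum_l ln[(n_a + 1/k_l) / (n_l + 1)]``; with ``leave_one_out`` the
    query's own record is removed from the reference counts first (used for
    self-assignment).
    """
    if len(query.repeats) != refs.n_loci:
        raise ValueError("query length does not match reference loci")
    counts = refs.counts[population]
    n_total = refs.size(population)
    remove = leave_one_out and any(
        h.sample_id == query.sample_id for h in refs.populations[population]
    )
    total = 0.0
    for l, allele in enumerate(query.repeats):
        n_a = counts[l].get(allele, 0)
        n_l = n_total
        if remove:
            own = next(
                h for h in refs.populations[population]
                if h.sample_id == query.sample_id
            )
            n_a -= own.repeats[l] == allele
            n_l -= 1
        total += math.log((n_a + 1.0 / refs.k[l]) / (n_l + 1.0))
    return total


@dataclass
class AssignmentResult:
    sample_id: str
    loglik: dict[str, float]
    scores: dict[str, float]  # normalized likelihood, percent; sums to 100
    best: str
    exclusion_p: dict[str, float] = field(default_factory=dict)


def assign(
    query: Haplotype, refs: ReferenceSet, leave_one_out: bool = False
) -> AssignmentResult:
    """Assign a query to the reference with the highest normalized score.

    Scores are likelihoods normalized over references (x100); ties are
    broken by label order for determinism.
    """
    if len(refs.labels) < 2:
        raise ValueError("assignment needs >= 2 reference populations")
    logliks = {
        p: rannala_mountain_loglik(query, p, refs, leave_one_out)
        for p in refs.labels
    }
    vals = np.array([logliks[p] for p in refs.labels])
    norm = logsumexp(vals)
    scores = {p: float(np.exp(l - norm) * 100.0) for p, l in logliks.items()}
    best = refs.labels[int(np.argmax([logliks[p] for p in refs.labels]))]
    return AssignmentResult(query.sample_id, logliks, scores, best)


def _locus_loglik_tables(
    refs: ReferenceSet, population: str
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per locus: (alleles, sampling probabilities, RM log-lik per allele)."""
    out = []
    n = refs.size(population)
    for l in range(refs.n_loci):
        counts = refs.counts[population][l]
        alleles = np.array(sorted(counts))
        c = np.array([counts[a] for a in alleles], dtype=float)
        probs = c / c.sum()
        loglik = np.log((c + 1.0 / refs.k[l]) / (n + 1.0))
        out.append((alleles, probs, loglik))
    return out


def paetkau_exclusion(
    query: Haplotype,
    population: str,
    refs: ReferenceSet,
    n_sim: int = 10_000,
    alpha: float = 0.01,
    seed: int | None = None,
) -> tuple[float, bool]:
    """Monte-Carlo exclusion test of a query from one reference population.

    ``n_sim`` haplotypes are simulated by drawing each locus independently
    from the reference allele frequencies; the p-value is the rank of the
    observed Rannala-Mountain log-likelihood in the simulated null,
    ``(1 + #{sim <= obs}) / (n_sim + 1)``; the query is excluded when
    p < alpha.
    """
    if n_sim < 100:
        logger.warning("paetkau_exclusion with n_sim=%d (< 100) is unreliable", n_sim)
    rng = np.random.default_rng(seed)
    obs = rannala_mountain_loglik(query, population, refs)
    sim_loglik = np.zeros(n_sim)
    for alleles, probs, loglik in _locus_loglik_tables(refs, population):
        idx = rng.choice(len(alleles), size=n_sim, p=probs)
        sim_loglik += loglik[idx]
    p = (1 + int(np.sum(sim_loglik <= obs + 1e-12))) / (n_sim + 1)
    return float(p), p < alpha


def self_assignment_quality(refs: ReferenceSet, seed: int | None = None) -> float:
    """Quality index QI: mean leave-one-out self-assignment score (percent).

    Every reference individual is assigned with its own record removed; QI
    is the mean normalized score granted to the individual's true
    population.  Deterministic; ``seed`` is accepted for interface symmetry.
    """
    for p in refs.labels:
        if refs.size(p) < 2:
            raise ValueError(f"reference {p!r} needs >= 2 samples for QI")
    scores = []
    for p in refs.labels:
        for h in refs.populations[p]:
            res = assign(h, refs, leave_one_out=True)
            scores.append(res.scores[p])
    return float(np.mean(scores))


def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno delta-K from a table of STRUCTURE runs (columns K, run, log_prob).

    ``deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K)``,
    defined only for interior K; K values with zero across-run sd get NaN.
    """
    required = {"K", "log_prob"}
    if not required <= set(runs.columns):
        raise ValueError(f"runs table needs columns {sorted(required)}")
    grouped = runs.groupby("K")["log_prob"].agg(["mean", "std", "count"])
    ks = sorted(grouped.index)
    if len(ks) < 3:
        raise ValueError("delta-K needs >= 3 consecutive K values")
    if (grouped["count"] < 2).any():
        raise ValueError("delta-K needs >= 2 runs per K")
    delta = {}
    for i, k in enumerate(ks):
        if i == 0 or i == len(ks) - 1:
            delta[k] = np.nan
            continue
        sd = grouped.loc[k, "std"]
        if sd == 0 or np.isnan(sd):
            delta[k] = np.nan
            logger.warning("delta-K undefined at K=%s (zero sd)", k)
            continue
        num = abs(
            grouped.loc[ks[i + 1], "mean"]
            - 2 * grouped.loc[k, "mean"]
            + grouped.loc[ks[i - 1], "mean"]
        )
        delta[k] = num / sd
    out = grouped.rename(columns={"mean": "mean_log_prob", "std": "sd_log_prob"})
    out["delta_k"] = pd.Series(delta)
    return out.drop(columns="count").reset_index()
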