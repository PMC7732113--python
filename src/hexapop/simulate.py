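"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the sampling design of a range-wide survey of a
hexaploid clonal conifer: two weakly differentiated regional clusters
(north/south), several populations per cluster, hexaploid nuclear SSR
genotypes with hidden allele dosage, clonally propagated individuals
(2-3 ramets per clone) with rare somatic mutation, rank-annotated
fluorescent peaks with stutter artifacts whose rank distribution overlaps
the true-peak distribution more for less reliable markers, stepwise-mutated
chloroplast haplotype pools, and Dirichlet-distributed STRUCTURE membership
matrices.  Every stage records its ground truth so downstream estimators
can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AllelePhenotype,
    Genome,
    GenotypeMatrix,
    Group,
    Haplotype,
    MarkerClass,
    MarkerDef,
    PeakRecord,
    QMatrix,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_allele_frequencies",
    "simulate_individuals",
    "simulate_peak_table",
    "simulate_cp_haplotypes",
    "simulate_q_matrix",
    "simulate_dataset",
    "recovery_rate",
]

CLUSTERS = ("NORTH", "SOUTH")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 2 clusters x 4 populations x 40
    samples (~320 trees), 12 nuclear and 6 chloroplast loci, hexaploidy,
    weak differentiation, ~10% of samples in clones of 2-3 ramets.
    """

    seed: int = 0
    n_populations: int = 4          # per cluster
    n_samples: int = 40             # per population
    n_loci: int = 12                # nuclear SSRs
    n_cp_loci: int = 6              # chloroplast SSRs
    n_alleles: int = 20             # per nuclear locus (range-wide surveys of
                                    # outcrossing conifers run ~20 SSR alleles)
    ploidy: int = 6
    divergence_F: float = 0.1       # Dirichlet divergence of pops from cluster
    clone_fraction: float = 0.1     # fraction of samples sitting in multi-ramet clones
    ramets_per_clone: tuple[int, int] = (2, 3)
    somatic_mutation_rate: float = 0.01   # per locus per ramet, +-1 repeat shift
    stutter_prob: float = 0.15      # per true allele, artifact at allele - 1
    rank_reliability: float | tuple[float, ...] = 0.98  # per marker
    rank_thresholds: tuple[int, ...] | None = None      # default cycles 7..10
    motif_length: int = 3
    cp_base_repeats: int = 15
    cp_pool_size: int = 6           # haplotype pool per population
    cp_step_p: float = 0.5          # geometric(p) - 1 mutation steps per locus
    cp_inter_cluster_steps: int | None = None  # default max(1, round(10 F))

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence_F < 1.0:
            raise ValueError(f"divergence_F must be in (0, 1), got {self.divergence_F}")
        for name in ("clone_fraction", "somatic_mutation_rate", "stutter_prob",
                     "cp_step_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def marker_ids(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]

    @property
    def thresholds(self) -> list[int]:
        if self.rank_thresholds is not None:
            if len(self.rank_thresholds) != self.n_loci:
                raise ValueError("rank_thresholds length must equal n_loci")
            return list(self.rank_thresholds)
        return [(7, 8, 9, 10)[i % 4] for i in range(self.n_loci)]

    @property
    def reliabilities(self) -> list[float]:
        r = self.rank_reliability
        if isinstance(r, (int, float)):
            return [float(r)] * self.n_loci
        if len(r) != self.n_loci:
            raise ValueError("rank_reliability length must equal n_loci")
        return [float(v) for v in r]

    def markers(self) -> list[MarkerDef]:
        return [
            MarkerDef(m, Genome.NUCLEAR, MarkerClass.NSSR, self.motif_length, t)
            for m, t in zip(self.marker_ids, self.thresholds)
        ]

    def child_rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator derived deterministically from the master
        seed, so each stage is individually reproducible."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**32)
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic artifact."""

    clone_of: dict[str, str]
    cluster_of: dict[str, str]
    population_of: dict[str, str]
    true_alleles: dict[tuple[str, str], frozenset[int]]
    true_haplotype: dict[str, tuple[int, ...]] = field(default_factory=dict)


@dataclass
class SimDataset:
    config: SimConfig
    genotypes: GenotypeMatrix
    peaks: list[PeakRecord]
    markers: list[MarkerDef]
    haplotypes: list[Haplotype]
    truth: SimTruth


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def simulate_allele_frequencies(
    cfg: SimConfig,
) -> dict[str, dict[str, list[np.ndarray]]]:
    """Per-cluster, per-population, per-locus allele frequency vectors.

    Cluster baselines are symmetric-Dirichlet draws; population vectors are
    Dirichlet draws centred on their cluster baseline with concentration
    ``(1 - F)/F * baseline``, so the expected divergence of populations from
    the baseline rises with ``divergence_F`` (the F-model of drift).
    """
    rng = cfg.child_rng("frequencies")
    conc = (1.0 - cfg.divergence_F) / cfg.divergence_F
    out: dict[str, dict[str, list[np.ndarray]]] = {}
    for ci, cluster in enumerate(CLUSTERS):
        baselines = [rng.dirichlet(np.ones(cfg.n_alleles)) for _ in range(cfg.n_loci)]
        out[cluster] = {}
        for p in range(cfg.n_populations):
            pop = f"{cluster[0]}{p + 1}"
            out[cluster][pop] = [
                rng.dirichlet(np.maximum(conc * b, 1e-9)) for b in baselines
            ]
    return out


# ---------------------------------------------------------------------------
# individuals, clones, ramets
# ---------------------------------------------------------------------------

def _draw_phenotype(
    rng: np.random.Generator, freq: np.ndarray, ploidy: int
) -> frozenset[int]:
    copies = rng.choice(len(freq), size=ploidy, p=freq)
    return frozenset(int(c) for c in copies)


def simulate_individuals(
    freqs: Mapping[str, Mapping[str, Sequence[np.ndarray]]], cfg: SimConfig
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw hexaploid individuals, then expand designated clones into ramets.

    Each individual draws ``ploidy`` allele copies per locus i.i.d. from its
    population's frequencies; the phenotype keeps the distinct-allele set
    (dosage hidden).  Roughly ``clone_fraction`` of each population's samples
    belong to clones of 2-3 ramets; each ramet is independently perturbed:
    with ``somatic_mutation_rate`` per locus, one of its alleles shifts by
    one repeat unit (stepwise somatic mutation).
    """
    rng = cfg.child_rng("individuals")
    loci = cfg.marker_ids
    samples: list[str] = []
    cells: dict[tuple[str, str], AllelePhenotype] = {}
    population_of: dict[str, str] = {}
    clone_of: dict[str, str] = {}
    cluster_of: dict[str, str] = {}
    true_alleles: dict[tuple[str, str], frozenset[int]] = {}
    lo, hi = cfg.ramets_per_clone

    def add_sample(sid: str, pop: str, cluster: str, clone: str,
                   genotype: dict[str, frozenset[int]]) -> None:
        samples.append(sid)
        population_of[sid] = pop
        cluster_of[sid] = cluster
        clone_of[sid] = clone
        for l in loci:
            cells[(sid, l)] = AllelePhenotype(sid, l, genotype[l], cfg.ploidy)
            true_alleles[(sid, l)] = frozenset(genotype[l])

    for cluster in CLUSTERS:
        for pop, pop_freqs in freqs[cluster].items():
            clone_budget = int(round(cfg.clone_fraction * cfg.n_samples))
            placed = 0
            idx = 0
            clone_idx = 0
            while placed < cfg.n_samples:
                remaining = cfg.n_samples - placed
                founder = {
                    l: _draw_phenotype(rng, pop_freqs[k], cfg.ploidy)
                    for k, l in enumerate(loci)
                }
                if placed < clone_budget and remaining >= lo:
                    clone_idx += 1
                    clone = f"{pop}_clone{clone_idx}"
                    n_ramets = min(int(rng.integers(lo, hi + 1)), remaining)
                    for r in range(n_ramets):
                        idx += 1
                        sid = f"{pop}_s{idx:03d}"
                        genotype = dict(founder)
                        for l in loci:
                            if rng.random() < cfg.somatic_mutation_rate:
                                alleles = sorted(genotype[l])
                                a = alleles[rng.integers(len(alleles))]
                                shift = int(rng.choice((-1, 1)))
                                genotype[l] = frozenset(
                                    (set(alleles) - {a}) | {a + shift}
                                )
                        add_sample(sid, pop, cluster, clone, genotype)
                        placed += 1
                else:
                    idx += 1
                    sid = f"{pop}_s{idx:03d}"
                    add_sample(sid, pop, cluster, f"{sid}_self", founder)
                    placed += 1

    group_of = {}
    for pop in {population_of[s] for s in samples}:
        group_of[pop] = Group.NORTH if pop.startswith("N") else Group.SOUTH
    genotypes = GenotypeMatrix(samples, loci, cells, population_of, group_of)
    truth = SimTruth(clone_of, cluster_of, dict(population_of), true_alleles)
    return genotypes, truth


# ---------------------------------------------------------------------------
# rank-annotated peaks with stutter
# ---------------------------------------------------------------------------

def _triangular_ranks(
    rng: np.random.Generator, low: int, high: int, ascending: bool, size: int
) -> np.ndarray:
    support = np.arange(low, high + 1)
    w = np.arange(1, len(support) + 1, dtype=float)
    if not ascending:
        w = w[::-1]
    return rng.choice(support, size=size, p=w / w.sum())


def simulate_peak_table(
    genotypes: GenotypeMatrix, cfg: SimConfig
) -> list[PeakRecord]:
    """Emit one rank-annotated peak per true allele plus stutter artifacts.

    True peaks draw their rank, with probability ``rank_reliability``, from
    a discrete triangular distribution rising over [threshold, 10] (so the
    marker's true threshold passes them) and otherwise uniformly over
    [7, 10].  With ``stutter_prob`` each allele also emits an artifact one
    repeat unit shorter whose rank falls, with probability
    ``rank_reliability``, on a descending triangular over [3, threshold-1]
    and otherwise uniformly over [3, 8] — so artifact and true ranks overlap
    more for low-reliability markers and the choice of threshold matters.
    """
    rng = cfg.child_rng("peaks")
    peaks: list[PeakRecord] = []
    thresholds = cfg.thresholds
    reliabilities = cfg.reliabilities
    for k, locus in enumerate(genotypes.loci):
        t = thresholds[k]
        rel = reliabilities[k]
        for s in genotypes.samples:
            for allele in sorted(genotypes.alleles(s, locus)):
                size = 100.0 + allele * cfg.motif_length
                if rng.random() < rel:
                    rank = int(_triangular_ranks(rng, t, 10, True, 1)[0])
                else:
                    rank = int(rng.integers(7, 11))
                peaks.append(PeakRecord(s, locus, size, rank))
                if rng.random() < cfg.stutter_prob:
                    if rng.random() < rel:
                        s_hi = max(t - 1, 3)
                        s_rank = int(_triangular_ranks(rng, 3, s_hi, False, 1)[0])
                    else:
                        s_rank = int(rng.integers(3, 9))
                    peaks.append(
                        PeakRecord(s, locus, size - cfg.motif_length, s_rank)
                    )
    return peaks


# ---------------------------------------------------------------------------
# chloroplast haplotypes
# ---------------------------------------------------------------------------

def simulate_cp_haplotypes(
    cfg: SimConfig, truth: SimTruth | None = None
) -> tuple[list[Haplotype], SimTruth]:
    """Stepwise-mutated cpSSR haplotypes drawn from population pools.

    Each cluster has a founder haplotype; the two founders are separated by
    ``cp_inter_cluster_steps`` repeat units per locus (random sign), default
    ``max(1, round(10 * divergence_F))``.  Each population carries a pool of
    ``cp_pool_size`` haplotypes mutated from the founder with
    ``geometric(cp_step_p) - 1`` stepwise +-1 mutations per locus.
    Individuals draw a pool member; ramets of a clone share their founder's
    haplotype (chloroplasts are clonally inherited).
    """
    rng = cfg.child_rng("chloroplast")
    sep = cfg.cp_inter_cluster_steps
    if sep is None:
        sep = max(1, int(round(10 * cfg.divergence_F)))
    founders: dict[str, np.ndarray] = {}
    base = np.full(cfg.n_cp_loci, cfg.cp_base_repeats)
    for ci, cluster in enumerate(CLUSTERS):
        if ci == 0:
            founders[cluster] = base.copy()
        else:
            signs = rng.choice((-1, 1), size=cfg.n_cp_loci)
            founders[cluster] = base + signs * sep

    def mutate(vec: np.ndarray) -> tuple[int, ...]:
        out = vec.copy()
        for l in range(cfg.n_cp_loci):
            steps = int(rng.geometric(cfg.cp_step_p)) - 1
            if steps:
                out[l] += int(rng.choice((-1, 1), size=steps).sum())
        return tuple(int(v) for v in out)

    if truth is None:
        # standalone mode: fabricate the population structure from cfg
        population_of: dict[str, str] = {}
        cluster_of: dict[str, str] = {}
        clone_of: dict[str, str] = {}
        for cluster in CLUSTERS:
            for p in range(cfg.n_populations):
                pop = f"{cluster[0]}{p + 1}"
                for i in range(cfg.n_samples):
                    sid = f"{pop}_s{i + 1:03d}"
                    population_of[sid] = pop
                    cluster_of[sid] = cluster
                    clone_of[sid] = f"{sid}_self"
        truth = SimTruth(clone_of, cluster_of, population_of, {})

    pools: dict[str, list[tuple[int, ...]]] = {}
    for sid in truth.population_of:
        pop = truth.population_of[sid]
        if pop not in pools:
            cluster = truth.cluster_of[sid]
            pools[pop] = [
                mutate(founders[cluster]) for _ in range(cfg.cp_pool_size)
            ]

    clone_hap: dict[str, tuple[int, ...]] = {}
    haplotypes: list[Haplotype] = []
    for sid in truth.population_of:
        clone = truth.clone_of.get(sid, sid)
        if clone not in clone_hap:
            pool = pools[truth.population_of[sid]]
            clone_hap[clone] = pool[int(rng.integers(len(pool)))]
        truth.true_haplotype[sid] = clone_hap[clone]
        haplotypes.append(Haplotype(sid, clone_hap[clone]))
    return haplotypes, truth


# ---------------------------------------------------------------------------
# Q-matrices
# ---------------------------------------------------------------------------

def simulate_q_matrix(
    n: int, K: int, alpha: float = 1.0, seed: int | None = None
) -> QMatrix:
    """Membership matrix with rows i.i.d. Dirichlet(alpha), renormalized so
    every row sums to exactly 1 at machine precision."""
    if n < 1 or K < 1:
        raise ValueError("n and K must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(K, alpha), size=n)
    p = p / p.sum(axis=1, keepdims=True)
    return QMatrix([f"ind{i + 1}" for i in range(n)], p)


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Run every generator stage under the master seed and bundle the result."""
    freqs = simulate_allele_frequencies(cfg)
    genotypes, truth = simulate_individuals(freqs, cfg)
    peaks = simulate_peak_table(genotypes, cfg)
    haplotypes, truth = simulate_cp_haplotypes(cfg, truth)
    return SimDataset(cfg, genotypes, peaks, cfg.markers(), haplotypes, truth)


def recovery_rate(
    scored: GenotypeMatrix, truth: SimTruth, offsets: Sequence[int] = range(-3, 4)
) -> float:
    """Fraction of (sample, locus) cells whose scored allele set matches the
    true set, allowing one constant per-locus repeat offset.

    The repeat-unit anchoring is offset-free (alleles are anchored at the
    marker's minimum observed fragment size), so truth comparison must align
    each locus by the best constant shift.
    """
    total = 0
    correct = 0
    for l in scored.loci:
        best = -1
        for off in offsets:
            hits = 0
            for s in scored.samples:
                obs = frozenset(a + off for a in scored.alleles(s, l))
                if obs == truth.true_alleles[(s, l)]:
                    hits += 1
            best = max(best, hits)
        correct += best
        total += len(scored.samples)
    return correct / total
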