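"""Domain types shared by every stage of the pipeline.

The central objects mirror how polyploid microsatellite data actually
arrive: fluorescent peaks with subjective quality ranks (:class:`PeakRecord`),
dosage-ambiguous allele sets (:class:`AllelePhenotype`) — in a hexaploid an
individual shows between 1 and 6 distinct alleles per locus and the copy
number of each is unobservable from peak data — haploid chloroplast
haplotypes (:class:`Haplotype`), and STRUCTURE-style membership matrices
(:class:`QMatrix`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Genome",
    "MarkerClass",
    "Group",
    "MarkerDef",
    "PeakRecord",
    "AllelePhenotype",
    "GenotypeMatrix",
    "Haplotype",
    "QMatrix",
    "DistanceMatrix",
]


class Genome(str, enum.Enum):
    NUCLEAR = "nuclear"
    CHLOROPLAST = "chloroplast"


class MarkerClass(str, enum.Enum):
    NSSR = "nSSR"
    EST_SSR = "EST-SSR"
    CPSSR = "cpSSR"


class Group(str, enum.Enum):
    """Regional grouping: above / below San Francisco Bay, or introduced."""

    NORTH = "NORTH"
    SOUTH = "SOUTH"
    GER = "GER"


@dataclass(frozen=True)
class MarkerDef:
    """Definition of one SSR marker.

    Parameters
    ----------
    marker_id : str
        Short marker name, e.g. ``"RW56"``.
    genome : Genome
        Nuclear or chloroplast.
    marker_class : MarkerClass
        nSSR (anonymous genomic), EST-SSR (expressed sequence) or cpSSR.
    motif_length : int
        Base pairs per repeat unit (e.g. 4 for a tetranucleotide).
    rank_threshold : int or None
        Peak-rank acceptance threshold in [1, 10] for nuclear markers.
        Chloroplast markers are haploid and unambiguous and never carry one.
    """

    marker_id: str
    genome: Genome = Genome.NUCLEAR
    marker_class: MarkerClass = MarkerClass.NSSR
    motif_length: int = 2
    rank_threshold: int | None = None

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        if self.genome is Genome.CHLOROPLAST and self.rank_threshold is not None:
            raise ValueError(
                f"cpSSR marker {self.marker_id!r} must not carry a rank_threshold"
            )
        if self.rank_threshold is not None and not 1 <= self.rank_threshold <= 10:
            raise ValueError(
                f"rank_threshold must be in [1, 10], got {self.rank_threshold}"
            )


@dataclass(frozen=True)
class PeakRecord:
    """One called fluorescent peak: sample, marker, fragment size, rank 1-10."""

    sample_id: str
    marker_id: str
    size_bp: float
    rank: int

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= 10:
            raise ValueError(f"rank must be in [1, 10], got {self.rank}")
        if self.size_bp <= 0:
            raise ValueError(f"size_bp must be positive, got {self.size_bp}")


@dataclass(frozen=True)
class AllelePhenotype:
    """Distinct alleles (repeat units) seen in one sample at one locus.

    Dosage is unknown; ploidy bounds the set size. The empty set denotes
    missing data.
    """

    sample_id: str
    locus_id: str
    alleles: frozenset[int] = frozenset()
    max_ploidy: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", frozenset(int(a) for a in self.alleles))
        if len(self.alleles) > self.max_ploidy:
            raise ValueError(
                f"{self.sample_id}/{self.locus_id}: {len(self.alleles)} alleles "
                f"exceed max_ploidy={self.max_ploidy}"
            )

    @property
    def is_missing(self) -> bool:
        return len(self.alleles) == 0


class GenotypeMatrix:
    """Samples x loci grid of :class:`AllelePhenotype` with population labels.

    Every cell is present (possibly as an empty, i.e. missing, phenotype).
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[str],
        cells: Mapping[tuple[str, str], AllelePhenotype],
        population_of: Mapping[str, str],
        group_of: Mapping[str, Group] | None = None,
    ) -> None:
        self.samples = list(samples)
        self.loci = list(loci)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.cells: dict[tuple[str, str], AllelePhenotype] = {}
        for s in self.samples:
            for l in self.loci:
                ph = cells.get((s, l))
                if ph is None:
                    ph = AllelePhenotype(s, l, frozenset())
                self.cells[(s, l)] = ph
        self.population_of = dict(population_of)
        for s in self.samples:
            if not self.population_of.get(s):
                raise ValueError(f"sample {s!r} has no population label")
        self.group_of = dict(group_of or {})

    def phenotype(self, sample: str, locus: str) -> AllelePhenotype:
        return self.cells[(sample, locus)]

    def alleles(self, sample: str, locus: str) -> frozenset[int]:
        return self.cells[(sample, locus)].alleles

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population_of[s], None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s in self.samples if self.population_of[s] == population]

    def subset(self, samples: Sequence[str]) -> "GenotypeMatrix":
        keep = set(samples)
        return GenotypeMatrix(
            [s for s in samples],
            self.loci,
            {k: v for k, v in self.cells.items() if k[0] in keep},
            {s: self.population_of[s] for s in samples},
            self.group_of,
        )

    def relabel_populations(self, mapping: Mapping[str, str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples,
            self.loci,
            self.cells,
            {s: mapping.get(p, p) for s, p in self.population_of.items()},
            self.group_of,
        )


@dataclass(frozen=True)
class Haplotype:
    """Ordered repeat counts over the cpSSR loci of one sample."""

    sample_id: str
    repeats: tuple[int, ...]
    haplotype_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "repeats", tuple(int(r) for r in self.repeats))


class QMatrix:
    """STRUCTURE membership coefficients: n samples x K clusters, rows sum to 1."""

    def __init__(self, sample_ids: Sequence[str], p: np.ndarray) -> None:
        p = np.asarray(p, dtype=float)
        if p.ndim != 2:
            raise ValueError("p must be 2-D")
        if len(sample_ids) != p.shape[0]:
            raise ValueError("sample_ids length does not match row count")
        sums = p.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
        if bad.size:
            raise ValueError(
                f"rows do not sum to 1 within 1e-9: first offender "
                f"{sample_ids[bad[0]]!r} (sum={sums[bad[0]]:.6g})"
            )
        self.sample_ids = list(sample_ids)
        self.p = p

    @property
    def n(self) -> int:
        return self.p.shape[0]

    @property
    def K(self) -> int:
        return self.p.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        return self.p[self.sample_ids.index(sample_id)]


class DistanceMatrix:
    """Symmetric zero-diagonal pairwise distances with ordered ids."""

    def __init__(self, ids: Sequence[str], d: np.ndarray) -> None:
        d = np.asarray(d, dtype=float)
        n = len(ids)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} ids")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        self.ids = list(ids)
        self.d = 0.5 * (d + d.T)
        np.fill_diagonal(self.d, 0.0)
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.d[self._index[i], self._index[j]])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])
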