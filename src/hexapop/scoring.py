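"""Rank-threshold allele scoring and ranking-combination selection.

Polyploid SSR peak tables carry artifact peaks (stutter, split peaks) whose
shape/intensity ranks sit mostly below those of true alleles, but the
discriminative rank differs between markers.  A ranking combination assigns
each nuclear marker a threshold in [7, 10]; peaks at or above their marker's
threshold are scored as alleles.  The best combination is chosen on a
clone/ramet validation panel: the combination under which Bruvo-distance
clone assignment regroups the ramets of each known clone, with the highest
bootstrap support for those groupings, wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .distances import bruvo_distance_matrix
from .io import peaks_to_repeat_units
from .model import (
    AllelePhenotype,
    DistanceMatrix,
    GenotypeMatrix,
    MarkerDef,
    PeakRecord,
)
from .trees import assign_clones, bootstrap_support

__all__ = [
    "RankingCombination",
    "CombinationScore",
    "filter_peaks",
    "enumerate_combinations",
    "score_combination",
    "select_best_combination",
]

THRESHOLD_RANGE = (7, 8, 9, 10)


@dataclass(frozen=True)
class RankingCombination:
    """Per-marker rank thresholds, each in [7, 10]."""

    thresholds: tuple[tuple[str, int], ...]  # (marker_id, threshold), marker order

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "RankingCombination":
        for m, t in mapping.items():
            if t not in THRESHOLD_RANGE:
                raise ValueError(f"threshold for {m!r} must be in [7, 10], got {t}")
        return cls(tuple(sorted(mapping.items())))

    def threshold(self, marker_id: str) -> int:
        for m, t in self.thresholds:
            if m == marker_id:
                return t
        raise KeyError(f"marker {marker_id!r} has no threshold in this combination")

    def as_dict(self) -> dict[str, int]:
        return dict(self.thresholds)


@dataclass(frozen=True)
class CombinationScore:
    combination: RankingCombination
    clones_correct: int
    mean_support: float  # 0-100
    n_bootstrap: int


def filter_peaks(
    peaks: Sequence[PeakRecord],
    combination: RankingCombination,
    markers: Sequence[MarkerDef],
    population_of: Mapping[str, str] | None = None,
    max_ploidy: int = 6,
) -> GenotypeMatrix:
    """Score peaks into allele phenotypes under a ranking combination.

    A peak survives iff its rank >= its marker's threshold.  Repeat units
    are anchored at the marker's minimum fragment size over *all* peaks
    (pre-filter), so raising a threshold can only remove alleles, never
    shift them.  Cells with more than ``max_ploidy`` surviving alleles are
    capped by keeping the 6 highest-ranked peaks (ties: largest fragment
    first).
    """
    marker_by_id = {m.marker_id: m for m in markers}
    combo = combination.as_dict()
    for m in marker_by_id:
        if m not in combo:
            raise ValueError(f"marker {m!r} has no threshold in the combination")
    by_marker: dict[str, list[PeakRecord]] = {m: [] for m in marker_by_id}
    samples_seen: dict[str, None] = {}
    for p in peaks:
        if p.marker_id not in marker_by_id:
            raise ValueError(f"unknown marker {p.marker_id!r} in peak table")
        by_marker[p.marker_id].append(p)
        samples_seen.setdefault(p.sample_id, None)
    samples = list(samples_seen)
    loci = [m.marker_id for m in markers]
    cells: dict[tuple[str, str], AllelePhenotype] = {}
    for marker_id, marker_peaks in by_marker.items():
        if not marker_peaks:
            continue
        units = peaks_to_repeat_units(marker_peaks, marker_by_id[marker_id])
        # map each peak to its repeat unit using the same anchor
        min_size = min(p.size_bp for p in marker_peaks)
        motif = marker_by_id[marker_id].motif_length
        threshold = combo[marker_id]
        per_sample: dict[str, list[tuple[int, float, int]]] = {}
        for p in marker_peaks:
            if p.rank < threshold:
                continue
            unit = round((p.size_bp - min_size) / motif)
            per_sample.setdefault(p.sample_id, []).append((p.rank, p.size_bp, unit))
        for sid, entries in per_sample.items():
            entries.sort(key=lambda e: (-e[0], -e[1]))
            kept: list[int] = []
            for rank, size, unit in entries:
                if unit not in kept:
                    kept.append(unit)
                if len(kept) == max_ploidy:
                    break
            cells[(sid, marker_id)] = AllelePhenotype(
                sid, marker_id, frozenset(kept), max_ploidy
            )
    pop_of = dict(population_of) if population_of else {s: "ALL" for s in samples}
    return GenotypeMatrix(samples, loci, cells, pop_of)


def enumerate_combinations(
    markers: Sequence[MarkerDef],
    mode: str = "per_marker_sweep",
    base_level: int = 7,
    explicit: Sequence[Mapping[str, int]] | None = None,
) -> list[RankingCombination]:
    """Candidate ranking combinations.

    ``uniform``: every marker at the same threshold, one combination per
    level 7-10.  ``per_marker_sweep``: the uniform set plus, for each
    marker, deviations of that marker alone across 7-10 while the others
    hold ``base_level`` (deduplicated; 4 + n_markers x 3 candidates).
    ``explicit``: the given list, validated and passed through.
    """
    if not markers:
        raise ValueError("empty marker list")
    ids = [m.marker_id for m in markers]
    if mode == "explicit":
        if not explicit:
            raise ValueError("explicit mode needs a combination list")
        return [RankingCombination.from_mapping(c) for c in explicit]
    uniform = [RankingCombination.from_mapping({m: t for m in ids}) for t in THRESHOLD_RANGE]
    if mode == "uniform":
        return uniform
    if mode != "per_marker_sweep":
        raise ValueError(f"unknown mode {mode!r}")
    out = list(uniform)
    seen = {c.thresholds for c in out}
    for m in ids:
        for t in THRESHOLD_RANGE:
            mapping = {k: base_level for k in ids}
            mapping[m] = t
            combo = RankingCombination.from_mapping(mapping)
            if combo.thresholds not in seen:
                seen.add(combo.thresholds)
                out.append(combo)
    return out


def _clones_correct(
    group_of: Mapping[str, str], clone_map: Mapping[str, str]
) -> int:
    """Clones whose ramets form exactly one inferred group with no foreign
    member (exact recovery, stricter than co-membership)."""
    members: dict[str, list[str]] = {}
    for s, c in clone_map.items():
        members.setdefault(c, []).append(s)
    inferred: dict[str, list[str]] = {}
    for s, g in group_of.items():
        inferred.setdefault(g, []).append(s)
    correct = 0
    for clone, ramets in members.items():
        groups = {group_of[s] for s in ramets}
        if len(groups) != 1:
            continue
        if sorted(inferred[groups.pop()]) == sorted(ramets):
            correct += 1
    return correct


def score_combination(
    peaks: Sequence[PeakRecord],
    combination: RankingCombination,
    clone_map: Mapping[str, str],
    markers: Sequence[MarkerDef],
    n_bootstrap: int = 100,
    seed: int | None = None,
    clone_threshold: float = 0.2,
) -> CombinationScore:
    """Score a ranking combination on a clone/ramet validation panel.

    Peaks are filtered, Bruvo distances computed, clones assigned at the
    mismatch threshold, and exact clone recovery counted; an NJ tree with
    locus bootstrap yields the mean support over the smallest clades
    containing each multi-ramet clone.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    genotypes = filter_peaks(peaks, combination, markers)
    missing_from_table = set(clone_map) - set(genotypes.samples)
    if missing_from_table:
        raise ValueError(f"clone_map samples missing from peaks: {sorted(missing_from_table)}")
    genotypes = genotypes.subset(sorted(clone_map))

    def metric(g: GenotypeMatrix, loci):
        # stringent thresholds can empty whole profiles; score such pairs
        # as maximally distant instead of failing
        return bruvo_distance_matrix(g, loci, missing_pair="max")

    dm = metric(genotypes, None)
    clones = assign_clones(dm, clone_threshold)
    correct = _clones_correct(clones.group_of, clone_map)

    tree = bootstrap_support(genotypes, metric, n_bootstrap, seed)
    supports = []
    for clone, ramets in itertools.groupby(
        sorted(clone_map, key=clone_map.get), key=clone_map.get
    ):
        ramets = list(ramets)
        if len(ramets) < 2:
            continue
        lca = tree.lca(ramets)
        supports.append(float(getattr(lca, "support", 0.0) or 0.0))
    mean_support = float(np.mean(supports)) if supports else 0.0
    return CombinationScore(combination, correct, mean_support, n_bootstrap)


def select_best_combination(scores: Sequence[CombinationScore]) -> RankingCombination:
    """Lexicographic winner: most clones exactly recovered, then highest mean
    bootstrap support; ties go to the lowest (most inclusive) thresholds,
    compared in marker-id order."""
    if not scores:
        raise ValueError("no scores to select from")
    def key(s: CombinationScore):
        return (
            -s.clones_correct,
            -s.mean_support,
            tuple(t for _, t in s.combination.thresholds),
        )
    return min(scores, key=key).combination
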