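"""End-to-end orchestration: simulate or ingest, score, distances, clones,
diversity, AMOVA, network, assignment — from one config, with provenance.

The run directory is flat; a ``manifest.json`` records the config hash,
seed, and the outputs of each completed stage, so reruns with an unchanged
config skip completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .assign import ReferenceSet, assign as assign_query, self_assignment_quality
from .distances import bruvo_distance_matrix
from .diversity import (
    amova_binary,
    count_alleles_and_private,
    pairwise_differentiation,
    to_presence_absence,
)
from .model import GenotypeMatrix, Haplotype
from .network import build_network, call_haplotypes, count_unique_haplotypes, write_network
from .scoring import (
    enumerate_combinations,
    filter_peaks,
    score_combination,
    select_best_combination,
)
from .simulate import SimConfig, simulate_dataset
from .trees import assign_clones, bootstrap_support

logger = logging.getLogger("hexapop")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; thresholds default to the standard analysis values
    (clone mismatch 0.2, 1000 bootstraps, 999 AMOVA permutations, 10 000
    exclusion simulations at type-I error 0.01)."""

    seed: int = 0
    simulation: SimConfig | None = None
    peaks_path: str | None = None
    haplotypes_path: str | None = None
    populations_path: str | None = None
    ranking_mode: str = "per_marker_sweep"
    clone_threshold: float = 0.2
    n_bootstrap: int = 1000
    n_boot_diff: int = 1000
    n_perm: int = 999
    n_sim: int = 10_000
    alpha: float = 0.01

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimConfig(**sim)
        elif cfg.peaks_path is None:
            cfg.simulation = SimConfig(seed=cfg.seed)
        return cfg

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class _Manifest:
    def __init__(self, out_dir: Path, digest: str, seed: int) -> None:
        self.path = out_dir / "manifest.json"
        self.digest = digest
        self.seed = seed
        if self.path.exists():
            stored = json.loads(self.path.read_text())
            self.stages = stored.get("stages", {}) if stored.get("config_hash") == digest else {}
        else:
            self.stages = {}

    def done(self, stage: str, outputs: list[Path]) -> bool:
        rec = self.stages.get(stage)
        return bool(rec) and all(Path(p).exists() for p in rec["outputs"]) and \
            rec["outputs"] == [str(p) for p in outputs]

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages[stage] = {"outputs": [str(p) for p in outputs]}
        self.path.write_text(
            json.dumps(
                {"config_hash": self.digest, "seed": self.seed, "stages": self.stages},
                indent=2,
            )
        )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages in dependency order; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config.digest(), config.seed)

    # ------------------------------------------------------------------ data
    if config.simulation is not None:
        ds = simulate_dataset(config.simulation)
        peaks, markers, haplotypes = ds.peaks, ds.markers, ds.haplotypes
        population_of = ds.truth.population_of
        clone_map = {
            s: c
            for s, c in ds.truth.clone_of.items()
            if sum(v == c for v in ds.truth.clone_of.values()) >= 2
        }
        outputs = [out / "peaks.tsv", out / "haplotypes.tsv", out / "populations.tsv",
                   out / "truth_clones.tsv"]
        if not manifest.done("data", outputs):
            hio.write_peak_table(peaks, outputs[0])
            hio.write_haplotype_table(
                haplotypes, [f"cp{i+1}" for i in range(config.simulation.n_cp_loci)],
                outputs[1],
            )
            hio.write_population_map(population_of, outputs[2])
            pd.DataFrame(
                sorted(ds.truth.clone_of.items()), columns=["sample_id", "clone_id"]
            ).to_csv(outputs[3], sep="\t", index=False)
            manifest.record("data", outputs)
    else:
        if not (config.peaks_path and config.haplotypes_path and config.populations_path):
            missing = [
                name for name, v in [
                    ("peaks_path", config.peaks_path),
                    ("haplotypes_path", config.haplotypes_path),
                    ("populations_path", config.populations_path),
                ] if not v
            ]
            raise ValueError(f"config missing genotype source field(s): {missing}")
        raise NotImplementedError(
            "external ingestion requires marker definitions; use the library API"
        )

    # ----------------------------------------------------------------- score
    from .scoring import RankingCombination

    score_outputs = [out / "combination_scores.tsv", out / "best_combination.yaml"]
    if manifest.done("score", score_outputs):
        best = RankingCombination.from_mapping(
            yaml.safe_load(score_outputs[1].read_text())
        )
    else:
        combos = enumerate_combinations(markers, mode="uniform")
        scores = [
            score_combination(
                peaks, c, clone_map, markers,
                n_bootstrap=max(10, config.n_bootstrap // 20), seed=config.seed,
                clone_threshold=config.clone_threshold,
            )
            for c in combos
        ]
        if config.ranking_mode == "per_marker_sweep":
            base = max(
                scores, key=lambda s: (s.clones_correct, s.mean_support)
            ).combination.thresholds[0][1]
            sweep = enumerate_combinations(markers, "per_marker_sweep", base_level=base)
            known = {s.combination.thresholds for s in scores}
            scores += [
                score_combination(
                    peaks, c, clone_map, markers,
                    n_bootstrap=max(10, config.n_bootstrap // 20), seed=config.seed,
                    clone_threshold=config.clone_threshold,
                )
                for c in sweep if c.thresholds not in known
            ]
        best = select_best_combination(scores)
        pd.DataFrame(
            [
                {**s.combination.as_dict(), "clones_correct": s.clones_correct,
                 "mean_support": s.mean_support}
                for s in scores
            ]
        ).to_csv(score_outputs[0], sep="\t", index=False)
        score_outputs[1].write_text(yaml.safe_dump(best.as_dict()))
        manifest.record("score", score_outputs)

    # ----------------------------------------------- genotypes and distances
    genotypes = filter_peaks(peaks, best, markers, population_of)
    dm = bruvo_distance_matrix(genotypes, missing_pair="max")
    dist_outputs = [out / "bruvo_distances.tsv", out / "nj_tree.nwk"]
    if not manifest.done("distances", dist_outputs):
        hio.write_distance_matrix(dm, dist_outputs[0])
        tree = bootstrap_support(
            genotypes,
            lambda g, loci: bruvo_distance_matrix(g, loci, missing_pair="max"),
            n_boot=max(10, config.n_bootstrap // 10),
            seed=config.seed,
        )
        hio.write_newick(tree, dist_outputs[1])
        manifest.record("distances", dist_outputs)

    # ---------------------------------------------------------------- clones
    clones = assign_clones(dm, config.clone_threshold)
    pd.DataFrame(
        sorted(clones.group_of.items()), columns=["sample_id", "clone_group"]
    ).to_csv(out / "clones.tsv", sep="\t", index=False)
    # one representative per clone for the diversity estimates
    representatives = sorted({g: s for s, g in sorted(clones.group_of.items(), reverse=True)}.values())
    collapsed = genotypes.subset(representatives)
    manifest.record("clones", [out / "clones.tsv"])

    # ------------------------------------------------------------- diversity
    div_outputs = [out / "diversity.tsv", out / "differentiation.tsv", out / "amova.tsv"]
    if not manifest.done("diversity", div_outputs):
        summaries = count_alleles_and_private(collapsed)
        pd.DataFrame(
            [dataclasses.asdict(s) for s in summaries]
        ).to_csv(div_outputs[0], sep="\t", index=False)

        pops = collapsed.populations
        rows = []
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                r = pairwise_differentiation(
                    collapsed, a, b, n_boot=config.n_boot_diff, seed=config.seed
                )
                rows.append(dataclasses.asdict(r))
        pd.DataFrame(rows).to_csv(div_outputs[1], sep="\t", index=False)

        binary, _ = to_presence_absence(collapsed)
        labels = [collapsed.population_of[s] for s in collapsed.samples]
        amova = amova_binary(binary, labels, n_perm=config.n_perm, seed=config.seed)
        pd.DataFrame([dataclasses.asdict(amova)]).to_csv(
            div_outputs[2], sep="\t", index=False
        )
        manifest.record("diversity", div_outputs)

    # --------------------------------------------------------------- network
    net_outputs = [out / "haplotype_table.tsv", out / "network_summary.yaml"]
    if not manifest.done("network", net_outputs):
        dataset_of = {h.sample_id: population_of[h.sample_id] for h in haplotypes}
        table = call_haplotypes(haplotypes, dataset_of)
        table.table.to_csv(net_outputs[0], sep="\t")
        net = build_network(table)
        write_network(net, out / "haplotype_network")
        net_outputs[1].write_text(
            yaml.safe_dump(
                {
                    "n_haplotypes": int(len(table.table)),
                    "n_unique": count_unique_haplotypes(table),
                    "percolation_threshold": net.percolation_threshold,
                    "n_components_at_threshold": len(net.components),
                }
            )
        )
        manifest.record("network", net_outputs)

    # ------------------------------------------------------------ assignment
    asn_outputs = [out / "assignments.tsv", out / "assignment_summary.yaml"]
    if not manifest.done("assignment", asn_outputs):
        by_pop: dict[str, list[Haplotype]] = {}
        for h in haplotypes:
            by_pop.setdefault(population_of[h.sample_id], []).append(h)
        refs = ReferenceSet(by_pop)
        qi = self_assignment_quality(refs)
        results = [assign_query(h, refs, leave_one_out=True) for h in haplotypes]
        pd.DataFrame(
            [
                {"sample_id": r.sample_id, "best": r.best,
                 "best_score": r.scores[r.best],
                 "true_population": population_of[r.sample_id]}
                for r in results
            ]
        ).to_csv(asn_outputs[0], sep="\t", index=False)
        asn_outputs[1].write_text(
            yaml.safe_dump({"QI_percent": float(qi), "n_queries": len(results)})
        )
        manifest.record("assignment", asn_outputs)
    return out
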