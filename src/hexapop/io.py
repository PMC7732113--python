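"""Readers and writers for the delimited-text and tree formats the pipeline touches.

All text I/O is UTF-8. Peak and haplotype tables may be comma- or
tab-delimited; the delimiter is sniffed from the header line.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
import yaml

from .model import (
    DistanceMatrix,
    Haplotype,
    MarkerDef,
    PeakRecord,
    QMatrix,
)

logger = logging.getLogger("hexapop")

#: alleles whose fragment size deviates from an integer multiple of the motif
#: by more than this many repeat units trigger a binning warning
BINNING_TOLERANCE = 0.35


def configure_logging(verbose: bool = False) -> None:
    """Log to standard error; ``verbose`` switches from WARNING to INFO."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)


def _sniff_sep(path: Path) -> str:
    header = Path(path).open(encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ("sample_id", "marker_id", "size_bp", "rank")


def read_peak_table(path: str | Path, markers: Sequence[MarkerDef]) -> list[PeakRecord]:
    """Read a peak table (columns sample_id, marker_id, size_bp, rank).

    Markers absent from ``markers`` and ranks outside [1, 10] raise
    ``ValueError`` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    known = {m.marker_id for m in markers}
    records: list[PeakRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        marker = row["marker_id"]
        if marker not in known:
            raise ValueError(
                f"{path}:{line}: unknown marker {marker!r}; known markers: "
                f"{sorted(known)}"
            )
        try:
            size = float(row["size_bp"])
            rank = int(row["rank"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: unparseable number ({exc})") from exc
        if not 1 <= rank <= 10:
            raise ValueError(f"{path}:{line}: rank {rank} outside [1, 10]")
        records.append(PeakRecord(str(row["sample_id"]), marker, size, rank))
    return records


def write_peak_table(peaks: Iterable[PeakRecord], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [(p.sample_id, p.marker_id, p.size_bp, p.rank) for p in peaks],
        columns=list(PEAK_COLUMNS),
    )
    df.to_csv(path, sep=sep, index=False)


def peaks_to_repeat_units(
    peaks: Sequence[PeakRecord], marker: MarkerDef
) -> dict[str, set[int]]:
    """Convert fragment sizes at one marker into repeat-unit allele integers.

    Alleles are anchored at the dataset-minimum fragment size for the marker:
    ``allele = round((size_bp - min_size) / motif_length)``.  The anchoring is
    offset-free — all downstream distances use repeat-count differences only,
    so the choice of origin is immaterial.  Sizes that are not within
    :data:`BINNING_TOLERANCE` repeat units of an integer multiple trigger a
    binning warning and are rounded to the nearest integer.
    """
    for p in peaks:
        if p.marker_id != marker.marker_id:
            raise ValueError(
                f"peak at marker {p.marker_id!r} passed to {marker.marker_id!r}"
            )
    if not peaks:
        return {}
    min_size = min(p.size_bp for p in peaks)
    out: dict[str, set[int]] = {}
    seen_sizes: dict[tuple[str, int], set[float]] = {}
    for p in peaks:
        units = (p.size_bp - min_size) / marker.motif_length
        nearest = int(round(units))
        if abs(units - nearest) > BINNING_TOLERANCE:
            logger.warning(
                "marker %s sample %s: size %.2f bp is %.2f repeat units from "
                "the nearest bin; rounded to %d",
                marker.marker_id, p.sample_id, p.size_bp, abs(units - nearest), nearest,
            )
        sizes = seen_sizes.setdefault((p.sample_id, nearest), set())
        if sizes and p.size_bp not in sizes:
            logger.warning(
                "marker %s sample %s: sizes %s collapse into one repeat-unit bin %d",
                marker.marker_id, p.sample_id,
                sorted(sizes | {p.size_bp}), nearest,
            )
        sizes.add(p.size_bp)
        out.setdefault(p.sample_id, set()).add(nearest)
    return out


# ---------------------------------------------------------------------------
# Q-matrices
# ---------------------------------------------------------------------------

def read_q_matrix(path: str | Path) -> QMatrix:
    """Read a whitespace-delimited Q-matrix: sample_id then K membership values.

    Rows whose sum falls within [0.99, 1.01] are renormalized to exactly 1;
    anything further off is a format error naming the row.
    """
    ids: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        ids.append(parts[0])
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: unparseable membership value") from exc
        s = sum(vals)
        if not 0.99 <= s <= 1.01:
            raise ValueError(
                f"{path}:{ln}: row {parts[0]!r} sums to {s:.4g}, outside [0.99, 1.01]"
            )
        rows.append([v / s for v in vals])
    if not rows:
        raise ValueError(f"{path}: empty Q-matrix")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: inconsistent K across rows: {sorted(widths)}")
    return QMatrix(ids, np.array(rows))


def write_q_matrix(q: QMatrix, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for sid, row in zip(q.sample_ids, q.p):
            fh.write(sid + " " + " ".join(f"{v:.10f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# distance matrices (square PHYLIP style)
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(dm)}\n")
        for sid, row in zip(dm.ids, dm.d):
            fh.write(sid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split("\t") if "\t" in line else line.split()
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(ids, np.array(rows))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths; internal node names carry
    bootstrap support percentages when present."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# haplotype tables and population maps
# ---------------------------------------------------------------------------

def write_haplotype_table(
    haplotypes: Sequence[Haplotype], loci: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(h.sample_id, *h.repeats) for h in haplotypes],
        columns=["sample_id", *loci],
    )
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_table(path: str | Path) -> tuple[list[Haplotype], list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    loci = [c for c in df.columns if c != "sample_id"]
    haps = [
        Haplotype(str(r["sample_id"]), tuple(int(r[l]) for l in loci))
        for _, r in df.iterrows()
    ]
    return haps, loci


def write_population_map(population_of: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(population_of.items()), columns=["sample_id", "population"]
    ).to_csv(path, sep="\t", index=False)


def read_population_map(path: str | Path) -> dict[str, str]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    return dict(zip(df["sample_id"], df["population"]))


def load_config(path: str | Path) -> dict:
    """Load a nested key-value config file (YAML)."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
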