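"""Clone dispersion and lineage-resolved distance analyses.

Covers: projection of myocyte clones onto anatomical (AP/DV) axes and the
spread fraction d/D; homotypic vs heterotypic distances among daughters and
granddaughters at three canonical timepoints (T0 shortly after the first
division, T1 just before the daughters' next division, T2 the last frame
with all granddaughters present before migration ends); midpoint distance
between the two half-families; pairwise dispersion of same-family myocytes
at the end of migration and after heart-tube formation; and progenitor
potency classification from leaf fates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (MYOCYTE_FATES, CellLife, FateLabel, LineageForest, euclidean)

logger = logging.getLogger(__name__)

MIN_CYCLE_AGE_MIN = 4 * 60.0  # cells must be >= 4 h into their cycle
T0_OFFSET_MIN = 20.0          # T0 = this many minutes after the first division


class EmptyCloneError(ValueError):
    pass


@dataclass
class AxisSpec:
    """Anatomical axis defined by two landmark points (μm)."""

    name: str            # "AP" or "DV"
    p0: np.ndarray
    p1: np.ndarray

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if np.allclose(self.p0, self.p1):
            raise ValueError("axis endpoints must differ")

    @property
    def length(self) -> float:
        return euclidean(self.p0, self.p1)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Scalar coordinates of points along the axis, 0 at p0 (μm)."""
        u = (self.p1 - self.p0) / self.length
        return (np.atleast_2d(points) - self.p0) @ u


@dataclass
class SpreadResult:
    clone_id: str
    axis_name: str
    d_um: float          # range of raw projections
    axis_length_um: float
    fraction: float      # clamped-range / axis length, in [0, 1]
    n_cells: int


@dataclass
class DistanceSample:
    family_id: str
    cell_a: str
    cell_b: str
    timepoint_tag: str   # T0 | T1 | T2 | END_MIGRATION | HEART_TUBE
    kind: str            # homotypic | heterotypic
    distance_um: float


def clone_axis_spread(
    clone_positions: np.ndarray,
    axis: AxisSpec,
    clone_id: str = "",
) -> SpreadResult:
    """Spread fraction d/D of a clone's cells along an anatomical axis.

    ``clone_positions`` are the (already filtered) eligible cell positions.
    The reported fraction uses projections clamped to the axis segment so it
    stays within [0, 1]; the raw (pre-clamp) range is reported as ``d_um``.
    """
    pts = np.atleast_2d(np.asarray(clone_positions, dtype=float))
    if pts.size == 0:
        raise EmptyCloneError(f"clone {clone_id}: no eligible cells")
    proj = axis.project(pts)
    d_raw = float(proj.max() - proj.min())
    clamped = np.clip(proj, 0.0, axis.length)
    frac = float((clamped.max() - clamped.min()) / axis.length)
    return SpreadResult(clone_id, axis.name, d_raw, axis.length, frac, len(pts))


def eligible_clone_positions(
    forest: LineageForest,
    root: CellLife,
    at_time: float,
    gfp_positive: Optional[set[str]] = None,
    min_cycle_age_min: float = MIN_CYCLE_AGE_MIN,
) -> np.ndarray:
    """Positions at ``at_time`` of clone cells >= 4 h into their cycle.

    ``gfp_positive``, if given, restricts to reporter-positive cell ids.
    """
    out = []
    for cell in forest.subtree(root):
        if gfp_positive is not None and cell.cell_id not in gfp_positive:
            continue
        if at_time - cell.birth_time < min_cycle_age_min:
            continue
        p = cell.position_at(at_time)
        if p is not None:
            out.append(p)
    return np.array(out) if out else np.empty((0, 3))


def _pair_kind(a: CellLife, b: CellLife) -> str:
    return "homotypic" if a.fate is b.fate else "heterotypic"


def family_distance_samples(
    forest: LineageForest,
    root: CellLife,
    end_of_migration: Optional[float] = None,
    t0_offset_min: float = T0_OFFSET_MIN,
    min_branch_min: float = MIN_CYCLE_AGE_MIN,
) -> list[DistanceSample]:
    """Homotypic/heterotypic distances at T0, T1 and T2 for one family.

    T0: daughters ``t0_offset_min`` after the mother's division. T1: last
    frame before the first daughter re-divides. T2: last frame at which all
    granddaughters coexist, clipped to the end of migration. Only branches
    tracked at least ``min_branch_min`` into their cycle are considered;
    pairs missing a position at a timepoint are skipped with a log entry.
    """
    if len(root.children) != 2:
        return []
    daughters = forest.children_of(root)
    eligible_d = [d for d in daughters if d.cycle_length_min >= min_branch_min]
    samples: list[DistanceSample] = []

    t0 = daughters[0].birth_time + t0_offset_min
    t1 = min((d.end_time for d in daughters))
    for tag, t in (("T0", t0), ("T1", t1)):
        samples.extend(_pairwise_at(forest, root.cell_id, eligible_d, tag, t))

    grandchildren = [g for d in daughters for g in forest.children_of(d)]
    if grandchildren:
        t2 = min(g.end_time for g in grandchildren)
        if end_of_migration is not None:
            t2 = min(t2, end_of_migration)
        eligible_g = [g for g in grandchildren
                      if g.cycle_length_min >= min_branch_min or
                      (t2 - g.birth_time) >= min_branch_min]
        samples.extend(_pairwise_at(forest, root.cell_id, eligible_g, "T2", t2))
    return samples


def _pairwise_at(forest, family_id, cells, tag, t) -> list[DistanceSample]:
    out = []
    for a, b in itertools.combinations(cells, 2):
        pa, pb = a.position_at(t), b.position_at(t)
        if pa is None or pb is None:
            logger.info("family %s: pair (%s, %s) missing position at %s=%.1f min",
                        family_id, a.cell_id, b.cell_id, tag, t)
            continue
        out.append(DistanceSample(family_id, a.cell_id, b.cell_id, tag,
                                  _pair_kind(a, b), euclidean(pa, pb)))
    return out


def midpoint_distance(side1: np.ndarray, side2: np.ndarray) -> float:
    """Distance between the centroids of D1's and D2's daughter positions."""
    s1 = np.atleast_2d(np.asarray(side1, dtype=float))
    s2 = np.atleast_2d(np.asarray(side2, dtype=float))
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both sides need at least one position")
    return euclidean(s1.mean(axis=0), s2.mean(axis=0))


def sister_myocyte_dispersion(
    forest: LineageForest,
    stage: str,
    end_of_migration: Optional[float] = None,
    gfp_positive: Optional[set[str]] = None,
    min_branch_min: float = MIN_CYCLE_AGE_MIN,
) -> tuple[list[DistanceSample], dict]:
    """Pairwise distances among same-family reporter-positive myocytes.

    ``stage`` is "END_MIGRATION" (sampled at the movie's end-of-migration
    time) or "HEART_TUBE" (sampled at each pair's last co-tracked frame).
    Returns the samples and a summary dict (mean, sd, n); empty with a
    warning when no pair is eligible.
    """
    if stage not in ("END_MIGRATION", "HEART_TUBE"):
        raise ValueError(f"unknown stage {stage!r}")
    samples: list[DistanceSample] = []
    for root in forest.roots:
        myocytes = [c for c in forest.subtree(root)
                    if c.fate in MYOCYTE_FATES
                    and c.cycle_length_min >= min_branch_min
                    and (gfp_positive is None or c.cell_id in gfp_positive)]
        for a, b in itertools.combinations(myocytes, 2):
            if stage == "END_MIGRATION":
                if end_of_migration is None:
                    raise ValueError("END_MIGRATION stage needs end_of_migration")
                t = end_of_migration
            else:
                t = min(a.end_time, b.end_time)
            pa, pb = a.position_at(t), b.position_at(t)
            if pa is None or pb is None:
                continue
            samples.append(DistanceSample(root.cell_id, a.cell_id, b.cell_id,
                                          stage, _pair_kind(a, b),
                                          euclidean(pa, pb)))
    dists = np.array([s.distance_um for s in samples])
    if dists.size == 0:
        logger.warning("no eligible myocyte pair at stage %s", stage)
        summary = {"mean": float("nan"), "sd": float("nan"), "n": 0}
    else:
        summary = {"mean": float(dists.mean()),
                   "sd": float(dists.std(ddof=1)) if dists.size > 1 else 0.0,
                   "n": int(dists.size)}
    return samples, summary


def classify_potency(forest: LineageForest, root: CellLife) -> tuple[str, Optional[int]]:
    """Potency of a mother from its leaf fates, plus the restriction generation.

    Returns one of "uni-fated", "bipotent", "tripotent", "multipotent" or
    "undetermined" (any leaf without a determined fate), and the earliest
    generation at which every subtree is fate-homogeneous (None when
    undetermined).
    """
    leaves = forest.leaves(root)
    fates = {leaf.fate for leaf in leaves}
    if FateLabel.UNDETERMINED in fates:
        return "undetermined", None
    n = len(fates)
    name = {1: "uni-fated", 2: "bipotent", 3: "tripotent"}.get(n, "multipotent")

    def homogeneous(cell: CellLife) -> bool:
        return len({l.fate for l in forest.leaves(cell)}) == 1

    def restriction(cell: CellLife, gen: int) -> int:
        if homogeneous(cell):
            return gen
        return max(restriction(forest.cells[c], gen + 1) for c in cell.children)

    return name, restriction(root, 0)
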