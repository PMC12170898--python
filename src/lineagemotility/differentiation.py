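"""GFP-based differentiation calling and temporal alignment of movies.

A knock-in reporter marks cardiomyocyte differentiation: a cell is called
differentiated at the first time its raw GFP exceeds a movie-specific
threshold. The threshold is a multiple ``m`` of the time-varying background,
where ``m`` is the lowest multiplier that keeps every endocardial-annotated
spot (a lineage that never activates the reporter) below threshold.

Movies are placed on a common clock by matching the mean differentiation
times of the myocyte classes to a reference movie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import CellLife, FateLabel, LineageForest, MovieMeta

EPS_STRICT = 1e-6  # makes "lowest multiplier" strict on continuous intensities


class DataError(ValueError):
    pass


@dataclass
class BackgroundModel:
    """Piecewise-linear background interpolant, constant beyond the samples."""

    samples: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.samples:
            raise DataError("background model needs at least one sample")
        self.samples = sorted(self.samples)
        self._t = np.array([s[0] for s in self.samples])
        self._v = np.array([s[1] for s in self.samples])

    def eval(self, t_min: float | np.ndarray) -> float | np.ndarray:
        out = np.interp(t_min, self._t, self._v)
        return float(out) if np.isscalar(t_min) else out

    __call__ = eval


@dataclass
class ThresholdModel:
    """GFP-positivity threshold: raw intensity > m × background(t)."""

    multiplier: float
    background: BackgroundModel

    def is_positive(self, gfp_raw: float, t_min: float) -> bool:
        return gfp_raw > self.multiplier * self.background.eval(t_min)


@dataclass
class DifferentiationCall:
    cell_id: str
    t_diff_min: Optional[float]  # None = never crossed threshold


def normalize_gfp(forest: LineageForest, meta: MovieMeta) -> LineageForest:
    """Set ``gfp_norm`` on every spot, scaling by the movie-wide GFP maximum."""
    gfp_max = meta.gfp_max
    if gfp_max is None:
        gfp_max = max((s.gfp_raw for c in forest.cells.values() for s in c.spots), default=0.0)
        meta.gfp_max = gfp_max
    if gfp_max <= 0:
        raise DataError(f"movie {meta.movie_id}: gfp_max must be positive, got {gfp_max}")
    for cell in forest.cells.values():
        for s in cell.spots:
            s.gfp_norm = s.gfp_raw / gfp_max
    return forest


def fit_background(samples: Iterable[tuple[float, float]]) -> BackgroundModel:
    return BackgroundModel(samples=list(samples))


def find_threshold(
    endocardial_cells: Sequence[CellLife],
    background: BackgroundModel,
) -> ThresholdModel:
    """Lowest multiplier keeping every endocardial spot strictly sub-threshold.

    ``m = (1 + eps) * max_spots gfp_raw / background(t)``; with eps = 1e-6 the
    supremum is attained strictly, so all endocardial spots classify negative.
    """
    if not endocardial_cells:
        raise DataError("need at least one endocardial cell to fit the threshold")
    worst = 0.0
    for cell in endocardial_cells:
        for s in cell.spots:
            bg = background.eval(s.t_min)
            if bg <= 0:
                raise DataError(f"background is {bg} at t={s.t_min} (spot {s.spot_id})")
            worst = max(worst, s.gfp_raw / bg)
    return ThresholdModel(multiplier=(1.0 + EPS_STRICT) * worst, background=background)


def call_differentiation(
    cell: CellLife,
    threshold: ThresholdModel,
    persistence_frames: int = 1,
    require_prior_negative: bool = False,
) -> DifferentiationCall:
    """First time GFP exceeds threshold for ``persistence_frames`` consecutive spots.

    With ``require_prior_negative`` the crossing must be observed within the
    cell's own track (at least one earlier sub-threshold spot); a cell that
    is already positive at its first spot inherited positivity from its
    mother and gets no call. Class-mean estimates use this stricter rule so
    late-born descendants of an already-differentiated lineage do not drag
    the mean towards their birth times.
    """
    run_start: Optional[float] = None
    run = 0
    seen_negative = False
    for s in cell.spots:
        if threshold.is_positive(s.gfp_raw, s.t_min):
            if run == 0:
                run_start = s.t_min
            run += 1
            if run >= persistence_frames:
                if require_prior_negative and not seen_negative:
                    continue  # inherited positivity; wait for an observed crossing
                return DifferentiationCall(cell.cell_id, run_start)
        else:
            seen_negative = True
            run, run_start = 0, None
    return DifferentiationCall(cell.cell_id, None)


def mean_differentiation_time(
    forest: LineageForest,
    fate_class: FateLabel,
    threshold: ThresholdModel,
    persistence_frames: int = 1,
) -> float:
    """Mean t_diff (minutes) over cells of ``fate_class`` with an observed crossing.

    Only cells whose own track shows the sub- to supra-threshold transition
    contribute; cells born already positive are inherited-positive, not
    newly differentiated.
    """
    calls = [
        call_differentiation(c, threshold, persistence_frames,
                             require_prior_negative=True).t_diff_min
        for c in forest.cells.values() if c.fate is fate_class
    ]
    called = [t for t in calls if t is not None]
    if not called:
        raise DataError(f"no {fate_class.value} cell crossed the threshold")
    return float(np.mean(called))


def align_movies(
    class_means: dict[str, dict[FateLabel, float]],
    reference_movie: str,
    frame_interval_min: float = 2.0,
) -> dict[str, float]:
    """Per-movie clock offsets (minutes) matching myocyte differentiation timing.

    For each movie the offset is the mean, over fate classes shared with the
    reference, of (reference class mean − movie class mean), rounded to the
    frame grid. Aligned time = movie time + offset; the reference offset is 0.
    """
    if reference_movie not in class_means:
        raise DataError(f"reference movie {reference_movie} absent from class means")
    ref = class_means[reference_movie]
    offsets: dict[str, float] = {}
    for movie, means in class_means.items():
        shared = sorted(set(ref) & set(means), key=lambda f: f.value)
        if not shared:
            raise DataError(f"movie {movie} shares no fate class with the reference")
        raw = float(np.mean([ref[f] - means[f] for f in shared]))
        offsets[movie] = round(raw / frame_interval_min) * frame_interval_min
    offsets[reference_movie] = 0.0
    return offsets


def migration_end(
    forest: LineageForest,
    threshold: ThresholdModel,
    fate_class: FateLabel = FateLabel.LV_AVC,
    persistence_frames: int = 1,
) -> float:
    """End of the migration period on the movie clock (minutes).

    Defined as the mean differentiation time of the relevant myocyte class:
    LV/AVC for crescent-lineage analyses, ATRIAL for atrial analyses.
    """
    return mean_differentiation_time(forest, fate_class, threshold, persistence_frames)
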