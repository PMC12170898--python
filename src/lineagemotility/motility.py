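"""Cell motility metrics: interval speeds, windowed tortuosity, sister contact.

Speeds are mean track speeds (total path length / duration, μm/min) within
5-hour bins of the aligned clock; cells contributing less than 40 min to a
bin are dropped. Tortuosity is the straight-line displacement divided by
path length, computed in consecutive 50-min windows and averaged over the
cell cycle; cells tracked for less than 3 h are excluded. Sister contact is
the fraction of the pair's coexistence (within the first 16 aligned hours)
spent closer than a distance threshold — 13 μm by default, the mean
distance of visually confirmed touching pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import CellLife, LineageForest, euclidean

MIN_BIN_MINUTES = 40.0       # speed: minimum residence per 5-h bin
MIN_TORTUOSITY_CYCLE = 180.0  # tortuosity: minimum cell-cycle length (min)
CONTACT_THRESHOLD_UM = 13.0
CONTACT_WINDOW_MIN = 16 * 60.0
MIN_CONTACT_CYCLE = 4 * 60.0


@dataclass
class SpeedRecord:
    cell_id: str
    bin_start_min: float   # aligned clock
    bin_end_min: float
    speed_um_per_min: float
    duration_in_bin_min: float


@dataclass
class TortuosityRecord:
    cell_id: str
    window_min: float
    local_values: np.ndarray
    mean_tortuosity: float


@dataclass
class ContactRecord:
    cell_a: str
    cell_b: str
    generation: int
    threshold_um: float
    contact_time_min: float
    denominator_min: float
    ratio: float


def _segment_lengths(pos: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


def interval_speed(
    cell: CellLife,
    bin_hours: float = 5.0,
    alignment_offset_min: float = 0.0,
    min_bin_minutes: float = MIN_BIN_MINUTES,
) -> list[SpeedRecord]:
    """Mean speed of ``cell`` within each aligned ``bin_hours`` interval.

    Path length is summed point to point on the tracking grid; segments
    spanning a bin edge are split linearly. Bins where the cell resides less
    than ``min_bin_minutes`` are dropped.
    """
    t = cell.times() + alignment_offset_min
    pos = cell.positions()
    if len(t) < 2:
        return []
    bin_min = bin_hours * 60.0
    seg_len = _segment_lengths(pos)
    first_bin = int(t[0] // bin_min)
    last_bin = int(np.nextafter(t[-1], -np.inf) // bin_min)
    records = []
    for b in range(first_bin, last_bin + 1):
        lo, hi = b * bin_min, (b + 1) * bin_min
        dur = 0.0
        length = 0.0
        for k in range(len(seg_len)):
            a, c = t[k], t[k + 1]
            overlap = min(c, hi) - max(a, lo)
            if overlap <= 0 or c == a:
                continue
            frac = overlap / (c - a)
            dur += overlap
            length += seg_len[k] * frac
        if dur >= min_bin_minutes:
            records.append(SpeedRecord(cell.cell_id, lo, hi, length / dur, dur))
    return records


def track_speed(cell: CellLife) -> float:
    """Whole-track mean speed: total path length / tracked duration (μm/min)."""
    if cell.cycle_length_min <= 0:
        return 0.0
    return float(_segment_lengths(cell.positions()).sum() / cell.cycle_length_min)


def tortuosity(
    cell: CellLife,
    window_min: float = 50.0,
    min_cycle_min: float = MIN_TORTUOSITY_CYCLE,
) -> Optional[TortuosityRecord]:
    """Windowed tortuosity = straight-line distance / path distance, averaged.

    The track is cut into consecutive ``window_min`` windows; the final
    partial window is kept only if it covers at least half a window. A
    stationary window (zero path length) counts as 1: a cell that does not
    move does not meander. Returns None for cells tracked less than
    ``min_cycle_min``.
    """
    if cell.cycle_length_min < min_cycle_min:
        return None
    t = cell.times()
    pos = cell.positions()
    t0 = t[0]
    locals_: list[float] = []
    start = t0
    while start < t[-1] - 1e-9:
        end = min(start + window_min, t[-1])
        if end - start < window_min / 2:
            break
        mask = (t >= start - 1e-9) & (t <= end + 1e-9)
        p = pos[mask]
        if len(p) < 2:
            start += window_min
            continue
        total = float(_segment_lengths(p).sum())
        straight = euclidean(p[0], p[-1])
        locals_.append(1.0 if total == 0.0 else min(straight / total, 1.0))
        start += window_min
    if not locals_:
        return None
    arr = np.array(locals_)
    return TortuosityRecord(cell.cell_id, window_min, arr, float(arr.mean()))


def derive_contact_threshold(distance_samples: Sequence[float]) -> float:
    """Mean distance of visually confirmed contacting pairs (μm)."""
    samples = np.asarray(distance_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one confirmed-contact distance sample")
    return float(samples.mean())


def _pair_distance_series(a: CellLife, b: CellLife, alignment_offset_min: float,
                          window_min: float):
    """Common time grid (aligned) and inter-cell distances over coexistence."""
    ta, tb = a.times(), b.times()
    lo = max(ta[0], tb[0])
    hi = min(ta[-1], tb[-1])
    if hi <= lo:
        return None, None
    # clip to the analysis window on the aligned clock
    hi = min(hi, window_min - alignment_offset_min)
    if hi <= lo:
        return None, None
    grid = np.union1d(ta[(ta >= lo) & (ta <= hi)], tb[(tb >= lo) & (tb <= hi)])
    if len(grid) < 2:
        return None, None
    pa = np.stack([a.position_at(t) for t in grid])
    pb = np.stack([b.position_at(t) for t in grid])
    return grid, np.linalg.norm(pa - pb, axis=1)


def contact_ratio(
    sister_a: CellLife,
    sister_b: CellLife,
    threshold_um: float = CONTACT_THRESHOLD_UM,
    window_min: float = CONTACT_WINDOW_MIN,
    min_cycle_min: float = MIN_CONTACT_CYCLE,
    alignment_offset_min: float = 0.0,
) -> Optional[ContactRecord]:
    """Fraction of the sisters' coexistence spent closer than ``threshold_um``.

    Contact time need not be contiguous. The analysis window is the first
    ``window_min`` minutes of the aligned clock; pairs where either sister
    was tracked for less than ``min_cycle_min`` are excluded (returns None).
    """
    if min(sister_a.cycle_length_min, sister_b.cycle_length_min) < min_cycle_min:
        return None
    grid, dist = _pair_distance_series(sister_a, sister_b, alignment_offset_min,
                                       window_min)
    if grid is None:
        return None
    dt = np.diff(grid)
    in_contact = (dist[:-1] < threshold_um) & (dist[1:] < threshold_um)
    contact_time = float(dt[in_contact].sum())
    denom = float(grid[-1] - grid[0])
    gen = sister_a.generation if sister_a.generation_label else 0
    return ContactRecord(sister_a.cell_id, sister_b.cell_id, gen, threshold_um,
                         contact_time, denom, contact_time / denom if denom else 0.0)


def sister_pairs(forest: LineageForest, generations: Sequence[int] = (1, 2)):
    """Yield (a, b) sister cell lives at the requested generations."""
    for cell in forest.cells.values():
        if len(cell.children) == 2:
            a, b = forest.children_of(cell)
            if a.generation_label and a.generation in generations:
                yield a, b


def contact_retention_rate(
    pairs: Sequence[tuple[CellLife, CellLife]],
    threshold_um: float = CONTACT_THRESHOLD_UM,
) -> tuple[float, int]:
    """Fraction of sister pairs closer than threshold at first coexistence.

    Returns (fraction, n pairs evaluated).
    """
    n = 0
    hits = 0
    for a, b in pairs:
        t0 = max(a.birth_time, b.birth_time)
        pa, pb = a.position_at(t0), b.position_at(t0)
        if pa is None or pb is None:
            continue
        n += 1
        if euclidean(pa, pb) < threshold_um:
            hits += 1
    return (hits / n if n else 0.0), n
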