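"""Core domain model: spots, cell lives, lineage forests and per-movie metadata.

The unit of tracking is a *spot* — one detection of one cell at one frame,
with a calibrated 3D position in micrometres and raw reporter intensities.
A *cell life* is the time-ordered run of spots between two divisions (or
between appearance and the end of tracking). Cell lives are linked into
binary *lineage trees* rooted at mother cells; a movie contributes a forest
of such trees.

Generation labels follow the positional convention rooted at the mother M:
her daughters are D1 and D2, D1's daughters are D11 and D12, and so on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np


class FateLabel(enum.Enum):
    """Terminal fate classes assigned to tracked mesodermal cells."""

    LV_AVC = "LV_AVC"
    ATRIAL = "ATRIAL"
    ENDOCARDIUM = "ENDOCARDIUM"
    PERICARDIUM = "PERICARDIUM"
    EXEM = "EXEM"
    ENDOTHELIAL_LIKE = "ENDOTHELIAL_LIKE"
    MESO_GFP_NEG = "MESO_GFP_NEG"
    UNDETERMINED = "UNDETERMINED"


#: Fates counted as myocyte (cardiomyocyte reporter positive at differentiation).
MYOCYTE_FATES = frozenset({FateLabel.LV_AVC, FateLabel.ATRIAL})

#: Fates with a determined terminal identity (everything but UNDETERMINED).
DETERMINED_FATES = frozenset(f for f in FateLabel if f is not FateLabel.UNDETERMINED)


@dataclass
class Spot:
    """One detection of one cell at one frame."""

    spot_id: str
    cell_id: str
    frame: int
    t_min: float
    pos: np.ndarray  # shape (3,), micrometres
    gfp_raw: float
    tdtomato_raw: float = 0.0
    gfp_norm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,):
            raise ValueError(f"spot {self.spot_id}: pos must be a 3-vector")


@dataclass
class CellLife:
    """A cell's track between divisions, plus its place in the lineage tree.

    ``children`` has length 0 (track end) or 2 (binary division).
    ``generation_label`` is "M" for roots, else the mother's label with
    a "1"/"2" suffix ("M" drops to "D": the mother's daughters are D1, D2).
    """

    cell_id: str
    spots: list[Spot] = field(default_factory=list)
    parent: Optional[str] = None
    children: list[str] = field(default_factory=list)
    generation_label: Optional[str] = None
    fate: FateLabel = FateLabel.UNDETERMINED

    @property
    def birth_time(self) -> float:
        """Minutes at first spot (tdTomato onset for roots, division for others)."""
        return self.spots[0].t_min

    @property
    def end_time(self) -> float:
        return self.spots[-1].t_min

    @property
    def cycle_length_min(self) -> float:
        """Tracked duration of the cell life in minutes."""
        return self.end_time - self.birth_time

    @property
    def generation(self) -> int:
        """0 for the mother M, 1 for D1/D2, 2 for D11..D22, etc."""
        label = self.generation_label
        if label is None:
            raise ValueError(f"cell {self.cell_id} has no generation label")
        return 0 if label == "M" else len(label) - 1

    def times(self) -> np.ndarray:
        return np.array([s.t_min for s in self.spots])

    def positions(self) -> np.ndarray:
        return np.stack([s.pos for s in self.spots])

    def position_at(self, t_min: float) -> Optional[np.ndarray]:
        """Linearly interpolated position at ``t_min``; None outside the track."""
        t = self.times()
        if not (t[0] <= t_min <= t[-1]):
            return None
        pos = self.positions()
        out = np.empty(3)
        for k in range(3):
            out[k] = np.interp(t_min, t, pos[:, k])
        return out


@dataclass
class MovieMeta:
    """Per-movie clock, intensity scaling and optional anatomical landmarks."""

    movie_id: str
    frame_interval_min: float = 2.0
    background_samples: list[tuple[float, float]] = field(default_factory=list)
    gfp_max: Optional[float] = None
    alignment_offset_min: float = 0.0
    axis_landmarks: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        self.background_samples = sorted(self.background_samples)

    def aligned(self, t_min: float) -> float:
        """Movie time mapped onto the common (aligned) clock."""
        return t_min + self.alignment_offset_min


@dataclass
class LineageForest:
    """All lineage trees of one movie, indexed by cell id."""

    cells: dict[str, CellLife]
    movie_id: str
    meta: Optional[MovieMeta] = None

    @property
    def roots(self) -> list[CellLife]:
        return [c for c in self.cells.values() if c.parent is None]

    def children_of(self, cell: CellLife) -> list[CellLife]:
        return [self.cells[cid] for cid in cell.children]

    def subtree(self, cell: CellLife) -> Iterator[CellLife]:
        """Depth-first iteration over ``cell`` and its descendants."""
        stack = [cell]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children_of(node)))

    def leaves(self, cell: CellLife) -> list[CellLife]:
        return [c for c in self.subtree(cell) if not c.children]

    def tree_of(self, cell: CellLife) -> CellLife:
        """Root (mother) of the tree containing ``cell``."""
        while cell.parent is not None:
            cell = self.cells[cell.parent]
        return cell

    def __len__(self) -> int:
        return len(self.cells)


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return float(math.dist(a, b))
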