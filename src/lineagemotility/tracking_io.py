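"""Read, validate and export spot/link tracking tables as lineage forests.

The expected input is the tabular export of a manual-tracking session:

* a spot table, one row per detection, with columns
  ``spot_id, cell_id, frame, x_um, y_um, z_um, gfp, tdtomato``;
* a link table with columns ``source_spot_id, target_spot_id``.

Links between spots of the same cell express track continuity and are
redundant with the frame ordering; links whose endpoints belong to two
different cells encode a mother→daughter edge. A division is a cell whose
last spot has exactly two outgoing cross-cell links. Alternative column
names can be supplied through a mapping (``column_map``) so deposited
annotation schemas can be adapted without rewriting files.

Positions are assumed already calibrated to micrometres; frames are 0-based
and time in minutes is ``frame * frame_interval_min``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .model import CellLife, FateLabel, LineageForest, MovieMeta, Spot

SPOT_COLUMNS = ["spot_id", "cell_id", "frame", "x_um", "y_um", "z_um", "gfp", "tdtomato"]
LINK_COLUMNS = ["source_spot_id", "target_spot_id"]

#: Gaps of more than this many frames split a cell life during validation.
MAX_GAP_FRAMES = 5


class FormatError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class IntegrityError(ValueError):
    """Links or tree structure violate lineage invariants."""


def _apply_column_map(df: pd.DataFrame, required: list[str],
                      column_map: Optional[dict[str, str]], what: str) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing column(s): {', '.join(missing)}")
    return df


def read_tracking_table(
    spots_path: str | Path,
    links_path: str | Path,
    meta: MovieMeta,
    fates_path: str | Path | None = None,
    column_map: Optional[dict[str, str]] = None,
) -> LineageForest:
    """Assemble a validated :class:`LineageForest` from CSV tables.

    Raises :class:`FormatError` for missing columns, :class:`IntegrityError`
    for dangling links or non-binary divisions.
    """
    spots_df = _apply_column_map(pd.read_csv(spots_path, dtype={"spot_id": str, "cell_id": str}),
                                 SPOT_COLUMNS, column_map, "spot")
    links_df = _apply_column_map(
        pd.read_csv(links_path, dtype=str) if Path(links_path).stat().st_size > 1
        else pd.DataFrame(columns=LINK_COLUMNS),
        LINK_COLUMNS, column_map, "link")
    fates = {}
    if fates_path is not None:
        fdf = pd.read_csv(fates_path, dtype={"cell_id": str})
        if not {"cell_id", "fate"}.issubset(fdf.columns):
            raise FormatError("fate table is missing column(s): cell_id, fate")
        fates = {r.cell_id: FateLabel(r.fate) for r in fdf.itertuples()}
    forest = assemble_forest(spots_df, links_df, meta, fates)
    report = validate_forest(forest)
    if report:
        raise IntegrityError("; ".join(report))
    return forest


def assemble_forest(
    spots_df: pd.DataFrame,
    links_df: pd.DataFrame,
    meta: MovieMeta,
    fates: Optional[dict[str, FateLabel]] = None,
) -> LineageForest:
    """Build the forest from in-memory tables (no validation)."""
    fates = fates or {}
    cells: dict[str, CellLife] = {}
    spot_owner: dict[str, str] = {}
    for row in spots_df.itertuples():
        spot = Spot(
            spot_id=str(row.spot_id),
            cell_id=str(row.cell_id),
            frame=int(row.frame),
            t_min=int(row.frame) * meta.frame_interval_min,
            pos=(row.x_um, row.y_um, row.z_um),
            gfp_raw=float(row.gfp),
            tdtomato_raw=float(row.tdtomato),
        )
        cell = cells.setdefault(spot.cell_id, CellLife(cell_id=spot.cell_id))
        cell.spots.append(spot)
        spot_owner[spot.spot_id] = spot.cell_id
    for cell in cells.values():
        cell.spots.sort(key=lambda s: s.frame)
        cell.fate = fates.get(cell.cell_id, FateLabel.UNDETERMINED)

    for row in links_df.itertuples():
        src, tgt = str(row.source_spot_id), str(row.target_spot_id)
        dangling = [s for s in (src, tgt) if s not in spot_owner]
        if dangling:
            raise IntegrityError(f"link references unknown spot id(s): {', '.join(dangling)}")
        src_cell, tgt_cell = spot_owner[src], spot_owner[tgt]
        if src_cell == tgt_cell:
            continue  # intra-track continuity link
        child = cells[tgt_cell]
        if child.parent is not None and child.parent != src_cell:
            raise IntegrityError(f"cell {tgt_cell} has two parents: {child.parent}, {src_cell}")
        child.parent = src_cell
        if tgt_cell not in cells[src_cell].children:
            cells[src_cell].children.append(tgt_cell)

    bad = [c.cell_id for c in cells.values() if len(c.children) not in (0, 2)]
    if bad:
        raise IntegrityError(
            f"non-binary division(s) at cell(s): {', '.join(sorted(bad))} "
            "(every dividing cell must have exactly 2 daughters)")

    forest = LineageForest(cells=cells, movie_id=meta.movie_id, meta=meta)
    generation_labels(forest)
    return forest


def validate_forest(forest: LineageForest) -> list[str]:
    """Return a list of invariant violations; empty iff the forest is valid."""
    report: list[str] = []
    for cell in forest.cells.values():
        if not cell.spots:
            report.append(f"cell {cell.cell_id}: no spots")
            continue
        frames = [s.frame for s in cell.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            report.append(f"cell {cell.cell_id}: spot frames not strictly increasing")
        gaps = [b - a for a, b in zip(frames, frames[1:])]
        if gaps and max(gaps) > MAX_GAP_FRAMES:
            report.append(
                f"cell {cell.cell_id}: gap of {max(gaps)} frames exceeds "
                f"{MAX_GAP_FRAMES}; split the life")
        if len(cell.children) not in (0, 2):
            report.append(f"cell {cell.cell_id}: {len(cell.children)} children (must be 0 or 2)")
        for cid in cell.children:
            if cid not in forest.cells:
                report.append(f"cell {cell.cell_id}: unknown child {cid}")
            elif forest.cells[cid].parent != cell.cell_id:
                report.append(f"cell {cid}: parent mismatch")
        if cell.parent is not None and cell.parent not in forest.cells:
            report.append(f"cell {cell.cell_id}: unknown parent {cell.parent}")
    # cycle check: walking up from every node must terminate
    for cell in forest.cells.values():
        seen = set()
        cur = cell
        while cur.parent is not None:
            if cur.cell_id in seen:
                report.append(f"cycle through cell {cell.cell_id}")
                break
            seen.add(cur.cell_id)
            if cur.parent not in forest.cells:
                break
            cur = forest.cells[cur.parent]
    return report


def _spot_id_key(spot_id: str):
    try:
        return (0, int(spot_id), "")
    except ValueError:
        return (1, 0, spot_id)


def generation_labels(forest: LineageForest) -> LineageForest:
    """Assign positional labels M, D1, D2, D11, ... in place.

    The daughter whose first spot has the smaller id receives suffix "1";
    the labelling is therefore deterministic and independent of input row
    order.
    """
    for root in forest.roots:
        root.generation_label = "M"
        stack = [root]
        while stack:
            node = stack.pop()
            if not node.children:
                continue
            kids = sorted(forest.children_of(node),
                          key=lambda c: _spot_id_key(c.spots[0].spot_id))
            prefix = "D" if node.generation_label == "M" else node.generation_label
            for i, kid in enumerate(kids, start=1):
                kid.generation_label = f"{prefix}{i}"
                stack.append(kid)
            node.children = [k.cell_id for k in kids]
    return forest


def export_newick(forest: LineageForest) -> str:
    """Newick text, one tree per line, branch lengths = cell-cycle minutes."""

    def fmt(x: float) -> str:
        return str(int(x)) if float(x).is_integer() else repr(float(x))

    def render(cell: CellLife) -> str:
        name = cell.generation_label or cell.cell_id
        if not cell.children:
            return name
        inner = ",".join(render(forest.cells[c]) for c in cell.children)
        return f"({inner}){name}"

    lines = []
    for root in sorted(forest.roots, key=lambda c: c.cell_id):
        def with_len(cell: CellLife) -> str:
            name = cell.generation_label or cell.cell_id
            body = name if not cell.children else \
                "(" + ",".join(with_len(forest.cells[c]) for c in cell.children) + ")" + name
            if cell.parent is None:
                return body
            return f"{body}:{fmt(cell.cycle_length_min)}"
        lines.append(with_len(root) + ";")
    return "\n".join(lines)


def count_forest(forest: LineageForest) -> tuple[int, int]:
    """(number of mother cells, number of non-root descendants)."""
    n_mothers = len(forest.roots)
    return n_mothers, len(forest.cells) - n_mothers


def write_tracking_table(
    forest: LineageForest,
    spots_path: str | Path,
    links_path: str | Path,
    fates_path: str | Path | None = None,
) -> None:
    """Write the forest back to the CSV schema accepted by the reader."""
    spot_rows, link_rows = [], []
    for cell in forest.cells.values():
        prev = None
        for s in cell.spots:
            spot_rows.append({
                "spot_id": s.spot_id, "cell_id": s.cell_id, "frame": s.frame,
                "x_um": s.pos[0], "y_um": s.pos[1], "z_um": s.pos[2],
                "gfp": s.gfp_raw, "tdtomato": s.tdtomato_raw,
            })
            if prev is not None:
                link_rows.append({"source_spot_id": prev.spot_id, "target_spot_id": s.spot_id})
            prev = s
        for cid in cell.children:
            child = forest.cells[cid]
            link_rows.append({"source_spot_id": cell.spots[-1].spot_id,
                              "target_spot_id": child.spots[0].spot_id})
    pd.DataFrame(spot_rows, columns=SPOT_COLUMNS).to_csv(spots_path, index=False)
    pd.DataFrame(link_rows, columns=LINK_COLUMNS).to_csv(links_path, index=False)
    if fates_path is not None:
        pd.DataFrame(
            [{"cell_id": c.cell_id, "fate": c.fate.value} for c in forest.cells.values()]
        ).to_csv(fates_path, index=False)
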