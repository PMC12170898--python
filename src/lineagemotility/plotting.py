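"""Figure generation for pipeline results.

Boxplot conventions: boxes span the quartiles with the median line, and the
whiskers extend to the data minimum and maximum (no outlier trimming).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import LineageForest


def _boxplot(ax, groups: dict[str, np.ndarray], ylabel: str) -> None:
    present = {k: np.asarray(v, dtype=float) for k, v in groups.items()
               if len(v) > 0}
    skipped = [k for k in groups if k not in present]
    if present:
        ax.boxplot(list(present.values()), tick_labels=list(present.keys()),
                   whis=(0, 100))  # whiskers at data min/max
    for k in skipped:
        ax.annotate(f"{k}: no data", xy=(0.02, 0.95), xycoords="axes fraction",
                    fontsize=8, va="top")
    ax.set_ylabel(ylabel)


def plot_reports(results_dir: str | Path, outdir: Optional[str | Path] = None) -> list[Path]:
    """Render the standard figure set from a pipeline output directory.

    Returns the list of written files. Panels without data are omitted with
    an annotation rather than failing.
    """
    results_dir = Path(results_dir)
    outdir = Path(outdir) if outdir else results_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pairs = _read(results_dir / "dtw_pairs.csv")
    if pairs is not None and len(pairs):
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = {cat: pairs.loc[pairs["category"] == cat, "log_dtw"].dropna().values
                  for cat in ("Uni", "UniExEm", "Bi", "BiExEm")}
        _boxplot(ax, groups, "log DTW")
        ax.set_title("Sister-path similarity by fate category")
        written.append(_save(fig, outdir / "dtw_by_category.png"))

    speeds = _read(results_dir / "speeds.csv")
    if speeds is not None and len(speeds):
        fig, ax = plt.subplots(figsize=(6, 4))
        for fate, sub in speeds.groupby("fate"):
            binned = sub.groupby("bin_start_min")["speed_um_per_min"].mean()
            ax.plot(binned.index / 60.0, binned.values, marker="o", label=fate)
        ax.set_xlabel("aligned time (h)")
        ax.set_ylabel("mean speed (μm/min)")
        ax.legend(fontsize=7)
        written.append(_save(fig, outdir / "speed_by_fate.png"))

    contact = _read(results_dir / "contact.csv")
    if contact is not None and len(contact):
        fig, ax = plt.subplots(figsize=(4, 4))
        _boxplot(ax, {"all pairs": contact["ratio"].values}, "contact ratio")
        written.append(_save(fig, outdir / "contact_ratio.png"))

    tort = _read(results_dir / "tortuosity.csv")
    if tort is not None and len(tort):
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = {fate: sub["mean_tortuosity"].values
                  for fate, sub in tort.groupby("fate")}
        _boxplot(ax, groups, "tortuosity")
        plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
        written.append(_save(fig, outdir / "tortuosity_by_fate.png"))
    return written


def plot_dtw_curves(curves: dict[str, pd.DataFrame], out_path: str | Path) -> Path:
    """Per-step mean DTW curves with SE bands, one line per category."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, df in curves.items():
        ax.plot(df["step"], df["mean"], label=label)
        ax.fill_between(df["step"], df["mean"] - df["se"], df["mean"] + df["se"],
                        alpha=0.25)
    ax.set_xlabel("warping-path step")
    ax.set_ylabel("mean cumulative DTW (μm)")
    ax.legend()
    return _save(fig, Path(out_path))


def plot_lineage_tree(forest: LineageForest, root_id: str, out_path: str | Path,
                      color_by: str = "gfp_norm") -> Path:
    """Simple lineage dendrogram, branches coloured by a per-cell scalar."""
    root = forest.cells[root_id]
    nodes = list(forest.subtree(root))
    # leaf x-positions left to right, internal nodes midway over children
    xpos: dict[str, float] = {}
    next_x = [0.0]

    def assign(cell):
        if not cell.children:
            xpos[cell.cell_id] = next_x[0]
            next_x[0] += 1.0
        else:
            for c in forest.children_of(cell):
                assign(c)
            xs = [xpos[c] for c in cell.children]
            xpos[cell.cell_id] = sum(xs) / len(xs)

    assign(root)
    vals = {}
    for cell in nodes:
        if color_by == "gfp_norm":
            v = np.mean([s.gfp_norm for s in cell.spots
                         if s.gfp_norm is not None] or [0.0])
        else:
            v = 0.0
        vals[cell.cell_id] = v
    vmax = max(vals.values()) or 1.0
    cmap = plt.get_cmap("viridis")
    fig, ax = plt.subplots(figsize=(4, 4))
    for cell in nodes:
        x = xpos[cell.cell_id]
        ax.plot([x, x], [cell.birth_time, cell.end_time],
                color=cmap(vals[cell.cell_id] / vmax), lw=2)
        if cell.children:
            xs = [xpos[c] for c in cell.children]
            ax.plot([min(xs), max(xs)], [cell.end_time] * 2, color="grey", lw=1)
        ax.annotate(cell.generation_label or cell.cell_id,
                    (x, cell.birth_time), fontsize=6, ha="center", va="top")
    ax.invert_yaxis()
    ax.set_ylabel("time (min)")
    ax.set_xticks([])
    return _save(fig, Path(out_path))


def _read(path: Path) -> Optional[pd.DataFrame]:
    try:
        return pd.read_csv(path)
    except (FileNotFoundError, pd.errors.EmptyDataError):
        return None


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
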