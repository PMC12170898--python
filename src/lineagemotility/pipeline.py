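"""End-to-end orchestration: differentiation → alignment → metrics → inference.

``run_pipeline`` takes a :class:`PipelineConfig` (or a YAML file describing
one), runs every analysis stage over all movies and writes one tidy CSV per
analysis plus a JSON summary. Movies are either loaded from spot/link/fate
CSV tables or generated synthetically from a seed, so the whole pipeline is
runnable with no external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import differentiation as diff
from . import dtw_stats, lineage_metrics, motility, synthetic_data, tracking_io
from .model import FateLabel, LineageForest, MovieMeta

logger = logging.getLogger(__name__)


@dataclass
class MovieInputs:
    movie_id: str
    spots: Path
    links: Path
    fates: Optional[Path] = None
    background: Optional[Path] = None   # CSV with t_min,intensity
    frame_interval_min: float = 2.0


@dataclass
class PipelineConfig:
    movies: list[MovieInputs] = field(default_factory=list)
    simulate: Optional[synthetic_data.SimConfig] = None
    reference_movie: Optional[str] = None
    t0_offset_min: float = 20.0
    contact_threshold_um: float = 13.0
    dtw_cadence_frames: int = 5
    n_perm: int = 100_000
    persistence_frames: int = 1
    seed: int = 0
    outdir: Path = Path("results")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        movies = [MovieInputs(movie_id=m["movie_id"], spots=Path(m["spots"]),
                              links=Path(m["links"]),
                              fates=Path(m["fates"]) if m.get("fates") else None,
                              background=Path(m["background"]) if m.get("background") else None,
                              frame_interval_min=m.get("frame_interval_min", 2.0))
                  for m in raw.get("movies", [])]
        sim = synthetic_data.SimConfig(**raw["simulate"]) if raw.get("simulate") else None
        kwargs = {k: raw[k] for k in
                  ("reference_movie", "t0_offset_min", "contact_threshold_um",
                   "dtw_cadence_frames", "n_perm", "persistence_frames", "seed")
                  if k in raw}
        return cls(movies=movies, simulate=sim,
                   outdir=Path(raw.get("outdir", "results")), **kwargs)


def _load_movies(config: PipelineConfig) -> list[tuple[LineageForest, MovieMeta]]:
    out = []
    if config.simulate is not None:
        for i, sim in enumerate(synthetic_data.generate_cohort(config.simulate,
                                                               seed=config.seed)):
            forest = tracking_io.assemble_forest(
                sim.spots, sim.links, sim.meta,
                {r.cell_id: FateLabel(r.fate) for r in sim.fates.itertuples()})
            out.append((forest, sim.meta))
    for m in config.movies:
        meta = MovieMeta(movie_id=m.movie_id, frame_interval_min=m.frame_interval_min)
        if m.background:
            bg = pd.read_csv(m.background)
            meta.background_samples = list(zip(bg["t_min"], bg["intensity"]))
        forest = tracking_io.read_tracking_table(m.spots, m.links, meta,
                                                 fates_path=m.fates)
        out.append((forest, meta))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the summary dict and writes outputs.

    Raises the stage's own error annotated with the stage name. Deterministic
    given ``config.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    movies = _load_movies(config)
    summary: dict = {"movies": {}, "counts": {}}

    # -- stage: differentiation + alignment ---------------------------------
    thresholds: dict[str, diff.ThresholdModel] = {}
    class_means: dict[str, dict[FateLabel, float]] = {}
    gfp_positive: dict[str, set[str]] = {}
    for forest, meta in movies:
        try:
            diff.normalize_gfp(forest, meta)
            background = diff.fit_background(meta.background_samples)
            endo = [c for c in forest.cells.values()
                    if c.fate is FateLabel.ENDOCARDIUM]
            if not endo:
                raise diff.DataError("no endocardial cells to fit the threshold")
            thr = diff.find_threshold(endo, background)
            thresholds[meta.movie_id] = thr
            means = {}
            for fate in (FateLabel.LV_AVC, FateLabel.ATRIAL):
                try:
                    means[fate] = diff.mean_differentiation_time(
                        forest, fate, thr, config.persistence_frames)
                except diff.DataError:
                    pass
            class_means[meta.movie_id] = means
            gfp_positive[meta.movie_id] = {
                c.cell_id for c in forest.cells.values()
                if diff.call_differentiation(c, thr, config.persistence_frames).t_diff_min
                is not None}
        except Exception as e:  # annotate with stage context
            raise type(e)(f"[differentiation, movie {meta.movie_id}] {e}") from e

    reference = config.reference_movie or movies[0][1].movie_id
    frame_interval = movies[0][1].frame_interval_min
    offsets = diff.align_movies(class_means, reference, frame_interval)
    for forest, meta in movies:
        meta.alignment_offset_min = offsets[meta.movie_id]
        summary["movies"][meta.movie_id] = {
            "threshold_multiplier": thresholds[meta.movie_id].multiplier,
            "alignment_offset_min": offsets[meta.movie_id],
            "class_means_min": {f.value: t for f, t in class_means[meta.movie_id].items()},
        }

    # -- stage: lineage metrics ---------------------------------------------
    distance_rows, potency_rows, dispersion_rows = [], [], []
    disp_summaries = {"END_MIGRATION": [], "HEART_TUBE": []}
    for forest, meta in movies:
        try:
            end_mig = class_means[meta.movie_id].get(FateLabel.LV_AVC)
            for root in forest.roots:
                for s in lineage_metrics.family_distance_samples(
                        forest, root, end_of_migration=end_mig,
                        t0_offset_min=config.t0_offset_min):
                    distance_rows.append({"movie_id": meta.movie_id, **s.__dict__})
                potency, gen = lineage_metrics.classify_potency(forest, root)
                potency_rows.append({"movie_id": meta.movie_id,
                                     "mother": root.cell_id, "potency": potency,
                                     "restriction_generation": gen})
            for stage in ("END_MIGRATION", "HEART_TUBE"):
                samples, summ = lineage_metrics.sister_myocyte_dispersion(
                    forest, stage,
                    end_of_migration=end_mig if stage == "END_MIGRATION" else None,
                    gfp_positive=gfp_positive[meta.movie_id])
                disp_summaries[stage].append((summ, [s.distance_um for s in samples]))
                dispersion_rows += [{"movie_id": meta.movie_id, **s.__dict__}
                                    for s in samples]
        except Exception as e:
            raise type(e)(f"[lineage_metrics, movie {meta.movie_id}] {e}") from e

    # -- stage: motility ------------------------------------------------------
    speed_rows, tort_rows, contact_rows = [], [], []
    retention_pairs = []
    for forest, meta in movies:
        try:
            off = meta.alignment_offset_min
            for cell in forest.cells.values():
                fate = cell.fate.value
                for rec in motility.interval_speed(cell, alignment_offset_min=off):
                    speed_rows.append({"movie_id": meta.movie_id, "fate": fate,
                                       **rec.__dict__})
                t = motility.tortuosity(cell)
                if t is not None:
                    tort_rows.append({"movie_id": meta.movie_id, "fate": fate,
                                      "cell_id": t.cell_id,
                                      "mean_tortuosity": t.mean_tortuosity,
                                      "n_windows": len(t.local_values)})
            for a, b in motility.sister_pairs(forest):
                rec = motility.contact_ratio(
                    a, b, threshold_um=config.contact_threshold_um,
                    alignment_offset_min=off)
                if rec is not None:
                    contact_rows.append({"movie_id": meta.movie_id, **rec.__dict__})
                retention_pairs.append((a, b))
        except Exception as e:
            raise type(e)(f"[motility, movie {meta.movie_id}] {e}") from e
    retention, n_ret = motility.contact_retention_rate(
        retention_pairs, threshold_um=config.contact_threshold_um)

    # -- stage: DTW + inference ----------------------------------------------
    pair_tables = []
    for forest, meta in movies:
        try:
            end_mig = class_means[meta.movie_id].get(FateLabel.LV_AVC)
            tbl = dtw_stats.pair_dtw_table(
                forest, end_of_migration=end_mig,
                cadence_frames=config.dtw_cadence_frames)
            tbl.insert(0, "movie_id", meta.movie_id)
            pair_tables.append(tbl)
        except Exception as e:
            raise type(e)(f"[dtw_stats, movie {meta.movie_id}] {e}") from e
    pairs = pd.concat(pair_tables, ignore_index=True) if pair_tables else pd.DataFrame()
    perm = None
    if len(pairs):
        uni = pairs.loc[pairs["category"].isin(["Uni", "UniExEm"]), "log_dtw"].dropna()
        bi = pairs.loc[pairs["category"].isin(["Bi", "BiExEm"]), "log_dtw"].dropna()
        if len(uni) and len(bi):
            perm = dtw_stats.permutation_test(uni, bi, n_perm=config.n_perm,
                                              seed=config.seed)

    # -- outputs --------------------------------------------------------------
    frames = {
        "family_distances.csv": pd.DataFrame(distance_rows),
        "potency.csv": pd.DataFrame(potency_rows),
        "myocyte_dispersion.csv": pd.DataFrame(dispersion_rows),
        "speeds.csv": pd.DataFrame(speed_rows),
        "tortuosity.csv": pd.DataFrame(tort_rows),
        "contact.csv": pd.DataFrame(contact_rows),
        "dtw_pairs.csv": pairs,
    }
    for name, df in frames.items():
        df.to_csv(outdir / name, index=False)

    n_mothers = sum(len(f.roots) for f, _ in movies)
    n_cells = sum(len(f) for f, _ in movies)
    summary["counts"] = {
        "n_movies": len(movies), "n_mothers": n_mothers,
        "n_descendants": n_cells - n_mothers,
        "n_dtw_pairs": int(len(pairs)),
        "n_contact_pairs": len(contact_rows),
        "n_retention_pairs": n_ret,
    }
    summary["contact_retention_rate"] = retention
    for stage, entries in disp_summaries.items():
        pooled = np.concatenate([d for _, d in entries]) if entries else np.array([])
        summary[f"dispersion_{stage.lower()}"] = {
            "mean_um": float(pooled.mean()) if pooled.size else None,
            "sd_um": float(pooled.std(ddof=1)) if pooled.size > 1 else None,
            "n": int(pooled.size)}
    if perm is not None:
        summary["permutation"] = {
            "observed_diff": perm.observed_diff, "p_value": perm.p_value,
            "n_perm": perm.n_perm, "n_uni": int(len(uni)), "n_bi": int(len(bi))}
    summary["seed"] = config.seed
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
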