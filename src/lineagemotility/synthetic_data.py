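"""Synthetic tracked embryos with the statistical structure the analysis assumes.

The generator emulates five light-sheet movies of gastrulating embryos at a
2-min frame interval: binary lineage trees up to five generations; fate
classes with fate-specific birth windows, speed regimes over aligned 5-h
bins and directional persistence; GFP reporter traces with a drifting
background and a sigmoidal onset at fate-specific times (myocyte classes
only, endocardial lineages stay within a known margin of background); and
sister trajectories whose heading correlation depends on whether the mother
is uni-fated or bipotent.

Cells move as persistent random walks. Each family carries a shared heading
process; every cell blends that family heading with its own persistent
heading using a weight set by the mother's potency (``sister_corr_uni`` vs
``sister_corr_bi``), which is what makes uni-fated sisters travel on
parallel paths and bipotent sisters diverge. Step lengths are the
fate-and-time speed times the frame interval with multiplicative lognormal
noise of mean one, so realised mean speeds are unbiased for the configured
profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .model import FateLabel, MovieMeta
from .tracking_io import LINK_COLUMNS, SPOT_COLUMNS


class ConfigError(ValueError):
    pass


#: Aligned 5-h bin speeds (μm/min) per fate; index = bin number from time 0.
DEFAULT_SPEED_PROFILE: dict[FateLabel, tuple[float, ...]] = {
    FateLabel.EXEM:             (0.30, 0.35, 0.50, 0.60, 0.65, 0.72, 0.80, 0.80),
    FateLabel.LV_AVC:           (0.50, 0.56, 0.62, 0.60, 0.45, 0.40, 0.35, 0.35),
    FateLabel.PERICARDIUM:      (0.50, 0.48, 0.42, 0.38, 0.34, 0.30, 0.30, 0.30),
    FateLabel.ENDOCARDIUM:      (0.40, 0.42, 0.68, 0.72, 0.70, 0.70, 0.70, 0.70),
    FateLabel.ENDOTHELIAL_LIKE: (0.40, 0.44, 0.66, 0.70, 0.70, 0.70, 0.70, 0.70),
    FateLabel.ATRIAL:           (0.45, 0.50, 0.52, 0.50, 0.45, 0.42, 0.40, 0.40),
    FateLabel.MESO_GFP_NEG:     (0.50, 0.50, 0.50, 0.50, 0.50, 0.50, 0.50, 0.50),
}

DEFAULT_MOTHERS_PER_FATE: dict[FateLabel, int] = {
    FateLabel.LV_AVC: 12,
    FateLabel.ATRIAL: 6,
    FateLabel.ENDOCARDIUM: 8,
    FateLabel.PERICARDIUM: 8,
    FateLabel.EXEM: 6,
    FateLabel.ENDOTHELIAL_LIKE: 3,
    FateLabel.MESO_GFP_NEG: 2,
}

DEFAULT_BIPOTENT_MOTHERS: dict[tuple[FateLabel, FateLabel], int] = {
    (FateLabel.LV_AVC, FateLabel.ENDOCARDIUM): 1,
    (FateLabel.LV_AVC, FateLabel.PERICARDIUM): 1,
    (FateLabel.LV_AVC, FateLabel.EXEM): 1,
    (FateLabel.PERICARDIUM, FateLabel.EXEM): 1,
}

DEFAULT_BIRTH_WINDOWS: dict[FateLabel, tuple[float, float]] = {
    FateLabel.LV_AVC: (0.0, 300.0),
    FateLabel.ATRIAL: (300.0, 900.0),
    FateLabel.ENDOCARDIUM: (0.0, 300.0),
    FateLabel.PERICARDIUM: (0.0, 300.0),
    FateLabel.EXEM: (0.0, 300.0),
    FateLabel.ENDOTHELIAL_LIKE: (0.0, 600.0),
    FateLabel.MESO_GFP_NEG: (0.0, 600.0),
}

#: Reporter onset (mean min, sd min) on the common clock; None = never positive.
DEFAULT_GFP_ONSET: dict[FateLabel, Optional[tuple[float, float]]] = {
    FateLabel.LV_AVC: (1242.0, 90.0),   # ~20.7 h
    FateLabel.ATRIAL: (1746.0, 90.0),   # ~29.1 h
}


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic embryo generator."""

    n_movies: int = 5
    frames_per_movie: int = 1200
    frame_interval_min: float = 2.0
    n_mothers_per_fate: dict[FateLabel, int] = field(
        default_factory=lambda: dict(DEFAULT_MOTHERS_PER_FATE))
    n_bipotent_mothers: dict[tuple[FateLabel, FateLabel], int] = field(
        default_factory=lambda: dict(DEFAULT_BIPOTENT_MOTHERS))
    birth_time_windows: dict[FateLabel, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BIRTH_WINDOWS))
    cycle_length_mean_min: float = 480.0
    cycle_length_sd_min: float = 120.0
    max_generations: int = 5
    speed_profile: dict[FateLabel, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SPEED_PROFILE))
    speed_bin_hours: float = 5.0
    speed_noise_sd: float = 0.2          # lognormal sigma of step-length noise
    persistence: dict[FateLabel, float] = field(
        default_factory=lambda: {f: 0.8 for f in FateLabel})
    sister_corr_uni: float = 0.8
    sister_corr_bi: float = 0.2
    bi_separation_um_per_min: float = 0.05  # extra radial drift for bipotent sisters
    init_sister_sep_um: float = 11.0        # median post-division separation
    init_sister_sep_sigma: float = 0.6      # lognormal spread of that separation
    gfp_onset: dict[FateLabel, Optional[tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_GFP_ONSET))
    gfp_background: tuple[float, float, float] = (100.0, 0.05, 5.0)  # level, drift/min, noise sd
    gfp_amplitude: float = 8.0           # plateau, as multiple of background
    gfp_onset_rise_min: float = 60.0     # width of the logistic rise
    endo_margin: float = 1.5             # max endocardial GFP as multiple of background
    background_sample_interval_min: float = 60.0
    movie_lags_min: tuple[float, ...] = (-74.0, 0.0, -239.0, -373.0, -626.0)
    arena_um: float = 400.0              # initial positions drawn in this cube
    seed: int = 0


@dataclass
class SyntheticMovie:
    """One generated movie: tracking tables, metadata and ground truth."""

    spots: pd.DataFrame
    links: pd.DataFrame
    fates: pd.DataFrame
    meta: MovieMeta
    truth: dict


@dataclass
class _SimCell:
    cell_id: str
    fate: FateLabel
    frames: np.ndarray
    pos: np.ndarray
    gfp: np.ndarray
    tdt: np.ndarray
    parent: Optional[str]
    children: list[str] = field(default_factory=list)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _speed_at(profile: tuple[float, ...], aligned_t_min: float, bin_min: float) -> float:
    idx = int(max(aligned_t_min, 0.0) // bin_min)
    return profile[min(idx, len(profile) - 1)]


class _EmbryoBuilder:
    """Grows one movie's lineage forest cell by cell."""

    def __init__(self, config: SimConfig, movie_index: int, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.lag = config.movie_lags_min[movie_index % len(config.movie_lags_min)]
        self.movie_id = f"sim{movie_index}"
        self.cells: list[_SimCell] = []
        self._next_cell = 0
        self.family_onsets: dict[str, dict[str, float]] = {}
        self.mother_info: list[dict] = []
        lvl, drift, _ = config.gfp_background
        self.bg = lambda t: lvl + drift * t
        self.bin_min = config.speed_bin_hours * 60.0

    # -- clocks -------------------------------------------------------------
    def aligned(self, t_min: float) -> float:
        """Common biological clock; the movie clock runs ahead by -lag."""
        return t_min - self.lag

    # -- lineage construction ----------------------------------------------
    def build(self) -> None:
        cfg = self.cfg
        t_end = (cfg.frames_per_movie - 1) * cfg.frame_interval_min
        for fate, count in cfg.n_mothers_per_fate.items():
            for _ in range(count):
                self._spawn_family([fate, fate], fate)
        for (fa, fb), count in cfg.n_bipotent_mothers.items():
            for _ in range(count):
                self._spawn_family([fa, fb], fa)
        if not self.cells:
            return
        if min(c.frames[0] for c in self.cells) * cfg.frame_interval_min > t_end:
            raise ConfigError("birth window lies beyond the movie duration")

    def _draw_birth(self, fate: FateLabel) -> float:
        lo, hi = self.cfg.birth_time_windows.get(fate, (0.0, 300.0))
        t_end = (self.cfg.frames_per_movie - 1) * self.cfg.frame_interval_min
        birth = self.rng.uniform(lo, hi) + self.lag
        birth = max(birth, 0.0)
        if birth >= t_end:
            raise ConfigError(
                f"birth window ({lo}, {hi}) for {fate.value} falls beyond the movie")
        return birth

    def _draw_cycle(self) -> float:
        mean, sd = self.cfg.cycle_length_mean_min, self.cfg.cycle_length_sd_min
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return float(self.rng.lognormal(mu, math.sqrt(sigma2)))

    def _spawn_family(self, daughter_fates: list[FateLabel], mother_fate: FateLabel) -> None:
        cfg, rng = self.cfg, self.rng
        uni = daughter_fates[0] is daughter_fates[1]
        corr = cfg.sister_corr_uni if uni else cfg.sister_corr_bi
        family_id = f"F{len(self.mother_info)}"
        birth = self._draw_birth(mother_fate)
        origin = rng.uniform(0.0, cfg.arena_um, size=3)
        family_heading = _random_unit(rng)
        # family-synchronous reporter onsets on the common clock
        onsets = {}
        for fate in set(daughter_fates) | {mother_fate}:
            spec = cfg.gfp_onset.get(fate)
            if spec is not None:
                onsets[fate.value] = rng.normal(spec[0], spec[1]) + self.lag
        self.family_onsets[family_id] = onsets
        info = {
            "family_id": family_id, "uni": uni, "corr": corr,
            "daughter_fates": [f.value for f in daughter_fates],
            "birth_min": birth, "onsets": dict(onsets), "cell_ids": [],
        }
        self.mother_info.append(info)
        first_cell = len(self.cells)
        mother = self._grow_cell(mother_fate, birth, origin, _random_unit(rng),
                                 family_heading, corr, onsets, parent=None,
                                 generation=0, family_sep_dir=None)
        if mother is None:
            return
        self._maybe_divide(mother, daughter_fates, family_heading, corr, onsets,
                           generation=1)
        info["cell_ids"] = [c.cell_id for c in self.cells[first_cell:]]

    def _maybe_divide(self, mother: _SimCell, fates: list[FateLabel],
                      family_heading: np.ndarray, corr: float, onsets: dict,
                      generation: int) -> None:
        cfg, rng = self.cfg, self.rng
        if generation > cfg.max_generations:
            return
        t_div = (mother.frames[-1] + 1) * cfg.frame_interval_min
        t_end = (cfg.frames_per_movie - 1) * cfg.frame_interval_min
        if t_div >= t_end:
            return
        sep_dir = _random_unit(rng)
        sep = cfg.init_sister_sep_um * math.exp(rng.normal(0.0, cfg.init_sister_sep_sigma))
        uni = fates[0] is fates[1]
        daughters = []
        for k, fate in enumerate(fates):
            sign = 1.0 if k == 0 else -1.0
            start = mother.pos[-1] + sign * sep_dir * sep / 2.0
            fam_sep = sign * sep_dir if not uni else None
            cell = self._grow_cell(fate, t_div, start, _random_unit(rng),
                                   family_heading, corr, onsets,
                                   parent=mother.cell_id, generation=generation,
                                   family_sep_dir=fam_sep)
            if cell is not None:
                daughters.append((cell, fate))
        if len(daughters) == 2:
            mother.children = [d.cell_id for d, _ in daughters]
            for d, fate in daughters:
                self._maybe_divide(d, [fate, fate], family_heading, corr, onsets,
                                   generation + 1)
        # a division that cannot fit both daughters is dropped: mother stays a leaf

    def _grow_cell(self, fate: FateLabel, birth_min: float, start_pos: np.ndarray,
                   heading: np.ndarray, family_heading: np.ndarray, corr: float,
                   onsets: dict, parent: Optional[str], generation: int,
                   family_sep_dir: Optional[np.ndarray]) -> Optional[_SimCell]:
        cfg, rng = self.cfg, self.rng
        dt = cfg.frame_interval_min
        first_frame = int(math.ceil(birth_min / dt))
        t_end_frame = cfg.frames_per_movie - 1
        if first_frame > t_end_frame:
            return None
        cycle = self._draw_cycle()
        last_frame = min(int((birth_min + cycle) // dt), t_end_frame)
        if last_frame < first_frame:
            last_frame = first_frame
        frames = np.arange(first_frame, last_frame + 1)
        n = len(frames)
        pos = np.empty((n, 3))
        pos[0] = start_pos
        rho = cfg.persistence.get(fate, 0.8)
        profile = cfg.speed_profile[fate]
        sigma = cfg.speed_noise_sd
        h = heading.copy()
        for i in range(1, n):
            t = frames[i - 1] * dt
            h = _unit(rho * h + (1.0 - rho) * rng.normal(size=3))
            family_heading_step = family_heading  # frozen per family; drift below
            step_dir = _unit(corr * family_heading_step + (1.0 - corr) * h)
            speed = _speed_at(profile, self.aligned(t), self.bin_min)
            noise = math.exp(rng.normal(-sigma * sigma / 2.0, sigma))
            step = step_dir * speed * dt * noise
            if family_sep_dir is not None:
                step = step + family_sep_dir * cfg.bi_separation_um_per_min * dt
            pos[i] = pos[i - 1] + step
        gfp = self._gfp_trace(fate, frames * dt, onsets)
        tdt = 50.0 + rng.normal(0.0, 2.0, size=n)
        cell = _SimCell(cell_id=f"c{self._next_cell}", fate=fate, frames=frames,
                        pos=pos, gfp=gfp, tdt=np.abs(tdt), parent=parent)
        self._next_cell += 1
        self.cells.append(cell)
        return cell

    def _gfp_trace(self, fate: FateLabel, times: np.ndarray, onsets: dict) -> np.ndarray:
        cfg, rng = self.cfg, self.rng
        bg = self.bg(times)
        _, _, noise_sd = cfg.gfp_background
        if fate is FateLabel.ENDOCARDIUM:
            # bounded by a known margin of background; the max over many spots
            # approaches the margin, which is what the threshold fit recovers
            ratio = rng.uniform(0.3, cfg.endo_margin, size=len(times))
            return bg * ratio
        base = bg * rng.uniform(0.4, 0.8, size=len(times))
        onset = onsets.get(fate.value)
        if onset is None:
            return np.abs(base + rng.normal(0.0, noise_sd, size=len(times)))
        scale = cfg.gfp_onset_rise_min / 6.0
        frac = 1.0 / (1.0 + np.exp(-(times - onset) / scale))
        trace = base + frac * (cfg.gfp_amplitude * bg - base)
        return np.abs(trace + rng.normal(0.0, noise_sd, size=len(times)))

    # -- export -------------------------------------------------------------
    def tables(self) -> SyntheticMovie:
        cfg = self.cfg
        spot_rows, link_rows, fate_rows = [], [], []
        sid = 0
        first_spot: dict[str, int] = {}
        last_spot: dict[str, int] = {}
        for cell in self.cells:
            prev = None
            for i, f in enumerate(cell.frames):
                spot_rows.append((sid, cell.cell_id, int(f), cell.pos[i, 0],
                                  cell.pos[i, 1], cell.pos[i, 2],
                                  float(cell.gfp[i]), float(cell.tdt[i])))
                if prev is not None:
                    link_rows.append((prev, sid))
                else:
                    first_spot[cell.cell_id] = sid
                prev = sid
                sid += 1
            last_spot[cell.cell_id] = prev
            fate_rows.append((cell.cell_id, cell.fate.value))
        for cell in self.cells:
            for child in cell.children:
                link_rows.append((last_spot[cell.cell_id], first_spot[child]))
        spots = pd.DataFrame(spot_rows, columns=SPOT_COLUMNS)
        links = pd.DataFrame(link_rows, columns=LINK_COLUMNS)
        fates = pd.DataFrame(fate_rows, columns=["cell_id", "fate"])
        t_end = (cfg.frames_per_movie - 1) * cfg.frame_interval_min
        bg_t = np.arange(0.0, t_end + 1e-9, cfg.background_sample_interval_min)
        if bg_t[-1] < t_end:  # cover the whole movie so interpolation is exact
            bg_t = np.append(bg_t, t_end)
        meta = MovieMeta(
            movie_id=self.movie_id,
            frame_interval_min=cfg.frame_interval_min,
            background_samples=[(float(t), float(self.bg(t))) for t in bg_t],
            gfp_max=float(spots["gfp"].max()) if len(spots) else None,
            axis_landmarks={
                "AP": (np.array([0.0, 0.0, 0.0]), np.array([cfg.arena_um, 0.0, 0.0])),
                "DV": (np.array([0.0, 0.0, 0.0]), np.array([0.0, cfg.arena_um, 0.0])),
            },
        )
        truth = {
            "movie_id": self.movie_id,
            "lag_min": self.lag,
            "mothers": self.mother_info,
            "endo_margin": cfg.endo_margin,
            "speed_profile": {f.value: list(p) for f, p in cfg.speed_profile.items()},
            "sister_corr_uni": cfg.sister_corr_uni,
            "sister_corr_bi": cfg.sister_corr_bi,
        }
        return SyntheticMovie(spots, links, fates, meta, truth)


def generate_embryo(config: SimConfig, seed: Optional[int] = None,
                    movie_index: int = 0) -> SyntheticMovie:
    """Generate one movie's spot/link/fate tables plus metadata and truth.

    Identical ``config`` and ``seed`` give identical output. ``movie_index``
    selects the per-movie clock lag used for alignment scenarios.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, movie_index])
    builder = _EmbryoBuilder(config, movie_index, rng)
    builder.build()
    return builder.tables()


def generate_cohort(config: SimConfig, seed: Optional[int] = None) -> list[SyntheticMovie]:
    """All ``config.n_movies`` movies, each with its own clock lag."""
    return [generate_embryo(config, seed=seed, movie_index=i)
            for i in range(config.n_movies)]


def small_config(**overrides) -> SimConfig:
    """A scaled-down configuration for quick, fully in-memory analyses.

    Same structure as the study conditions but fewer mothers and shorter
    movies; intended for tests and demonstrations where runtime matters
    more than cohort size.
    """
    base = SimConfig(
        n_movies=2,
        frames_per_movie=450,
        n_mothers_per_fate={
            FateLabel.LV_AVC: 4, FateLabel.ATRIAL: 2, FateLabel.ENDOCARDIUM: 3,
            FateLabel.PERICARDIUM: 3, FateLabel.EXEM: 2,
        },
        n_bipotent_mothers={
            (FateLabel.LV_AVC, FateLabel.ENDOCARDIUM): 2,
            (FateLabel.LV_AVC, FateLabel.EXEM): 2,
        },
        cycle_length_mean_min=300.0,
        cycle_length_sd_min=60.0,
        max_generations=3,
        gfp_onset={FateLabel.LV_AVC: (500.0, 60.0), FateLabel.ATRIAL: (700.0, 60.0)},
        birth_time_windows={f: (0.0, 120.0) for f in FateLabel} |
                           {FateLabel.ATRIAL: (120.0, 360.0)},
        movie_lags_min=(0.0, -120.0),
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# deterministic worked example
# ---------------------------------------------------------------------------

def generate_worked_example() -> SyntheticMovie:
    """A fixed, hand-checkable two-tree dataset (no randomness).

    Tree A: mother ``a`` runs straight along +x at 1 μm/min for 20 min and
    divides into LV/AVC sisters ``a1``/``a2`` that travel parallel straight
    paths 10 μm apart (always in contact, DTW cost is pure offset).
    ``a1`` re-divides into ``a11``/``a12``. Tree B: mother ``b`` moves along
    +y and divides into ``b1`` (LV/AVC, continues +y) and ``b2`` (ExEm,
    reverses) so the sisters separate at 4 μm/frame. GFP: flat background
    10; ``a1`` and descendants jump from 10 to 40 at frame 20 (t = 40 min).
    """
    dt = 2.0
    rows = []
    links = []
    sid = [0]

    def add_cell(cell_id, frames, xyz, gfp):
        first = None
        prev = None
        for k, f in enumerate(frames):
            rows.append((sid[0], cell_id, int(f), *xyz[k], float(gfp[k]), 50.0))
            if prev is not None:
                links.append((prev, sid[0]))
            else:
                first = sid[0]
            prev = sid[0]
            sid[0] += 1
        return first, prev

    # --- tree A ---
    f_m = np.arange(0, 10)
    a_first, a_last = add_cell("a", f_m, [(2.0 * f, 0.0, 0.0) for f in f_m],
                               [10.0] * len(f_m))
    f_d = np.arange(10, 40)
    a1_first, a1_last = add_cell("a1", f_d, [(2.0 * f, 5.0, 0.0) for f in f_d],
                                 [10.0 if f < 20 else 40.0 for f in f_d])
    a2_first, a2_last = add_cell("a2", f_d, [(2.0 * f, -5.0, 0.0) for f in f_d],
                                 [10.0] * len(f_d))
    f_g = np.arange(40, 70)
    a11_first, _ = add_cell("a11", f_g, [(2.0 * f, 5.0, 0.0) for f in f_g],
                            [40.0] * len(f_g))
    a12_first, _ = add_cell("a12", f_g, [(2.0 * f, 8.0, 0.0) for f in f_g],
                            [40.0] * len(f_g))
    links += [(a_last, a1_first), (a_last, a2_first),
              (a1_last, a11_first), (a1_last, a12_first)]

    # --- tree B ---
    b_first, b_last = add_cell("b", f_m, [(100.0, 2.0 * f, 0.0) for f in f_m],
                               [10.0] * len(f_m))
    b1_first, _ = add_cell("b1", f_d, [(100.0, 2.0 * f, 0.0) for f in f_d],
                           [10.0] * len(f_d))
    b2_first, _ = add_cell("b2", f_d, [(100.0, 18.0 - 2.0 * (f - 10), 0.0) for f in f_d],
                           [10.0] * len(f_d))
    links += [(b_last, b1_first), (b_last, b2_first)]

    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    links_df = pd.DataFrame(links, columns=LINK_COLUMNS)
    fates = pd.DataFrame(
        [("a", "LV_AVC"), ("a1", "LV_AVC"), ("a2", "LV_AVC"),
         ("a11", "LV_AVC"), ("a12", "LV_AVC"),
         ("b", "UNDETERMINED"), ("b1", "LV_AVC"), ("b2", "EXEM")],
        columns=["cell_id", "fate"])
    meta = MovieMeta(
        movie_id="worked_example",
        frame_interval_min=dt,
        background_samples=[(0.0, 10.0), (140.0, 10.0)],
        gfp_max=40.0,
    )
    truth = {"threshold_multiplier": 1.5, "a1_t_diff_min": 40.0}
    return SyntheticMovie(spots, links_df, fates, meta, truth)
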