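"""Slope-constrained dynamic time warping of sister trajectories and inference.

Trajectory similarity between two tracked cells is the cumulative dynamic
time warping (DTW) cost under the Sakoe–Chiba *symmetricP1* step pattern —
the symmetric pattern with slope constraint P = 1, which forbids a warping
path from moving more than one step along one sequence per step along the
other beyond a 2:1 local slope. With 0-based indices and local Euclidean
distance d(i, j) between points A[i] and B[j], the programme is

    g(0,0) = d(0,0)
    g(i,j) = min( g(i-1, j-2) + 2 d(i, j-1) + d(i, j),
                  g(i-1, j-1) + 2 d(i, j),
                  g(i-2, j-1) + 2 d(i-1, j) + d(i, j) )

with unreachable cells +inf. The pattern is symmetric, so dtw(A, B) =
dtw(B, A), and requires len(B) <= 2 len(A) - 1 and vice versa to be
feasible. Normalisation divides by N + M.

Group-level inference compares log cumulative DTW between fate categories
of sister pairs with a one-sided permutation test on the difference of
means, alongside the Mann–Whitney rank-sum utility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

from .model import DETERMINED_FATES, CellLife, FateLabel, LineageForest


class InfeasibleWarpError(ValueError):
    """Sequence lengths violate the P = 1 global slope bound."""


@dataclass
class DTWResult:
    """Outcome of one pairwise alignment.

    ``path`` lists the 0-based index pairs visited from (0, 0) to
    (N-1, M-1); ``step_costs[k]`` is the weighted local-cost contribution of
    ``path[k+1]``, so ``d(0,0) + sum(step_costs)`` equals ``cumulative_cost``.
    """

    cumulative_cost: float
    normalized_cost: float
    path: list[tuple[int, int]]
    step_costs: np.ndarray

    def cumulative_at_steps(self) -> np.ndarray:
        """Cumulative cost after each warping-path step (length = len(path))."""
        first = self.cumulative_cost - float(np.sum(self.step_costs))
        return first + np.concatenate([[0.0], np.cumsum(self.step_costs)])


def dtw_distance(
    path_a: np.ndarray,
    path_b: np.ndarray,
    step_pattern: Literal["symmetricP1", "symmetric2"] = "symmetricP1",
) -> DTWResult:
    """Align two point sequences and return cost, path and per-step costs.

    Sequences are (N, k) arrays of positions (or 1-D arrays of scalars).
    Raises ``ValueError`` for sequences shorter than 2 points and
    :class:`InfeasibleWarpError` when the P = 1 slope bound makes a full
    alignment impossible (symmetricP1 only).
    """
    a = np.asarray(path_a, dtype=float)
    b = np.asarray(path_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n, m = len(a), len(b)
    if n < 2 or m < 2:
        raise ValueError(f"sequences must have >= 2 points (got {n}, {m})")
    if step_pattern == "symmetricP1" and (m > 2 * n - 1 or n > 2 * m - 1):
        raise InfeasibleWarpError(
            f"lengths ({n}, {m}) violate the P=1 bound M <= 2N-1 and N <= 2M-1")
    d = cdist(a, b)
    if step_pattern == "symmetricP1":
        g = _dp_symmetric_p1(d)
    elif step_pattern == "symmetric2":
        g = _dp_symmetric2(d)
    else:
        raise ValueError(f"unknown step pattern: {step_pattern}")
    cumulative = float(g[n - 1, m - 1])
    if not math.isfinite(cumulative):
        raise InfeasibleWarpError(f"no admissible warping path for lengths ({n}, {m})")
    path, step_costs = _backtrack(g, d, step_pattern)
    return DTWResult(
        cumulative_cost=cumulative,
        normalized_cost=cumulative / (n + m),
        path=path,
        step_costs=step_costs,
    )


def _dp_symmetric_p1(d: np.ndarray) -> np.ndarray:
    n, m = d.shape
    g = np.full((n, m), np.inf)
    g[0, 0] = d[0, 0]
    inf = np.inf
    for i in range(1, n):
        row = np.full(m, inf)
        # diagonal: g[i-1, j-1] + 2 d[i, j]
        row[1:] = g[i - 1, :-1] + 2.0 * d[i, 1:]
        # flat-in-B: g[i-1, j-2] + 2 d[i, j-1] + d[i, j]
        if m >= 3:
            cand = g[i - 1, :-2] + 2.0 * d[i, 1:-1] + d[i, 2:]
            row[2:] = np.minimum(row[2:], cand)
        # flat-in-A: g[i-2, j-1] + 2 d[i-1, j] + d[i, j]
        if i >= 2:
            cand = g[i - 2, :-1] + 2.0 * d[i - 1, 1:] + d[i, 1:]
            row[1:] = np.minimum(row[1:], cand)
        g[i] = row
    return g


def _dp_symmetric2(d: np.ndarray) -> np.ndarray:
    n, m = d.shape
    g = np.full((n, m), np.inf)
    g[0, 0] = d[0, 0]
    for j in range(1, m):
        g[0, j] = g[0, j - 1] + d[0, j]
    for i in range(1, n):
        g[i, 0] = g[i - 1, 0] + d[i, 0]
        for j in range(1, m):
            g[i, j] = min(g[i - 1, j - 1] + 2.0 * d[i, j],
                          g[i, j - 1] + d[i, j],
                          g[i - 1, j] + d[i, j])
    return g


def _backtrack(g: np.ndarray, d: np.ndarray, step_pattern: str):
    """Recover the warping path; ties prefer the diagonal, then the B-advancing step."""
    n, m = g.shape
    i, j = n - 1, m - 1
    rev_points: list[tuple[int, int]] = [(i, j)]
    rev_costs: list[float] = []
    tol = 1e-9
    while (i, j) != (0, 0):
        target = g[i, j]
        moved = False
        if step_pattern == "symmetricP1":
            # order encodes the tie-break
            candidates = [
                ("diag", i - 1, j - 1, g[i - 1, j - 1] + 2 * d[i, j] if i >= 1 and j >= 1 else np.inf),
                ("flatB", i - 1, j - 2, g[i - 1, j - 2] + 2 * d[i, j - 1] + d[i, j] if i >= 1 and j >= 2 else np.inf),
                ("flatA", i - 2, j - 1, g[i - 2, j - 1] + 2 * d[i - 1, j] + d[i, j] if i >= 2 and j >= 1 else np.inf),
            ]
            for kind, pi, pj, val in candidates:
                if math.isfinite(val) and abs(val - target) <= tol * max(1.0, abs(target)):
                    if kind == "diag":
                        rev_costs.append(2 * d[i, j])
                    elif kind == "flatB":
                        rev_costs.extend([d[i, j], 2 * d[i, j - 1]])
                        rev_points.append((i, j - 1))
                    else:
                        rev_costs.extend([d[i, j], 2 * d[i - 1, j]])
                        rev_points.append((i - 1, j))
                    i, j = pi, pj
                    rev_points.append((i, j))
                    moved = True
                    break
        else:
            candidates = [
                ("diag", i - 1, j - 1, g[i - 1, j - 1] + 2 * d[i, j] if i >= 1 and j >= 1 else np.inf),
                ("left", i, j - 1, g[i, j - 1] + d[i, j] if j >= 1 else np.inf),
                ("up", i - 1, j, g[i - 1, j] + d[i, j] if i >= 1 else np.inf),
            ]
            for kind, pi, pj, val in candidates:
                if math.isfinite(val) and abs(val - target) <= tol * max(1.0, abs(target)):
                    rev_costs.append(2 * d[i, j] if kind == "diag" else d[i, j])
                    i, j = pi, pj
                    rev_points.append((i, j))
                    moved = True
                    break
        if not moved:  # numerical corner: fall back to exact argmin
            raise RuntimeError(f"backtracking stalled at ({i}, {j})")
    return rev_points[::-1], np.array(rev_costs[::-1])


# ---------------------------------------------------------------------------
# pair tables over lineage forests
# ---------------------------------------------------------------------------

class PairCategory:
    """Fate-contrast categories for a pair of related branches."""

    UNI = "Uni"            # same cardiac fate, no ExEm contribution
    UNI_EXEM = "UniExEm"   # both branches extraembryonic mesoderm
    BI = "Bi"              # distinct fates, none ExEm
    BI_EXEM = "BiExEm"     # distinct fates, at least one ExEm

    @staticmethod
    def of(fate_a: FateLabel, fate_b: FateLabel) -> str:
        if fate_a is fate_b:
            return PairCategory.UNI_EXEM if fate_a is FateLabel.EXEM else PairCategory.UNI
        if FateLabel.EXEM in (fate_a, fate_b):
            return PairCategory.BI_EXEM
        return PairCategory.BI


def branch_fate(forest: LineageForest, cell: CellLife) -> Optional[FateLabel]:
    """Fate of a branch: the unique determined fate of its leaves, else None."""
    fates = {leaf.fate for leaf in forest.leaves(cell)}
    if FateLabel.UNDETERMINED in fates or len(fates) != 1:
        return None
    (fate,) = fates
    return fate if fate in DETERMINED_FATES else None


def _shared_samples(forest: LineageForest, a: CellLife, b: CellLife,
                    end_of_migration: Optional[float],
                    cadence_frames: int) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Trajectories of a and b sampled on a common grid over their shared window.

    Window = [division + 1 frame, min(first re-division of either, end of
    migration, last co-tracked time)].
    """
    meta = forest.meta
    dt = meta.frame_interval_min if meta else 2.0
    start = max(a.birth_time, b.birth_time) + dt
    end = min(a.end_time, b.end_time)
    if end_of_migration is not None:
        end = min(end, end_of_migration)
    if end - start < dt:
        return None
    step = cadence_frames * dt
    times = np.arange(start, end + 1e-9, step)
    if len(times) < 2:
        return None
    pa = [a.position_at(t) for t in times]
    pb = [b.position_at(t) for t in times]
    if any(p is None for p in pa) or any(p is None for p in pb):
        return None
    return np.stack(pa), np.stack(pb)


def pair_dtw_table(
    forest: LineageForest,
    generations: Sequence[int] = (1, 2),
    end_of_migration: Optional[float] = None,
    cadence_frames: int = 5,
    normalize: bool = False,
) -> pd.DataFrame:
    """Cumulative (or normalised) DTW per sister/cousin pair with fate categories.

    Sister pairs are (D1, D2) at generation 1 and (D11, D12), (D21, D22) at
    generation 2; cousin pairs cross the generation-1 split (D1x vs D2y).
    Trajectories run from one frame after the mother's division to the first
    re-division of either branch, clipped to the end of migration. Pairs
    whose branch fates cannot be resolved, or with fewer than 2 shared
    samples, are skipped.
    """
    rows = []
    for root in forest.roots:
        for node in forest.subtree(root):
            if not node.children:
                continue
            d1, d2 = forest.children_of(node)
            gen = d1.generation
            if gen in generations:
                rows.extend(_pair_row(forest, d1, d2, "sisters", end_of_migration,
                                      cadence_frames, normalize))
            # cousins: grandchildren across the generation-1 split
            if node.generation_label == "M" and d1.children and d2.children:
                for ca in forest.children_of(d1):
                    for cb in forest.children_of(d2):
                        if ca.generation in generations:
                            rows.extend(_pair_row(forest, ca, cb, "cousins",
                                                  end_of_migration, cadence_frames,
                                                  normalize))
    return pd.DataFrame(
        rows, columns=["cell_a", "cell_b", "label_a", "label_b", "relation",
                       "generation", "category", "dtw", "log_dtw", "n_steps"])


def _pair_row(forest, a, b, relation, end_of_migration, cadence_frames, normalize):
    fate_a, fate_b = branch_fate(forest, a), branch_fate(forest, b)
    if fate_a is None or fate_b is None:
        return []
    sampled = _shared_samples(forest, a, b, end_of_migration, cadence_frames)
    if sampled is None:
        return []
    try:
        res = dtw_distance(*sampled)
    except (ValueError, InfeasibleWarpError):
        return []
    cost = res.normalized_cost if normalize else res.cumulative_cost
    log_cost = math.log(cost) if cost > 0 else np.nan
    return [{
        "cell_a": a.cell_id, "cell_b": b.cell_id,
        "label_a": a.generation_label, "label_b": b.generation_label,
        "relation": relation, "generation": a.generation,
        "category": PairCategory.of(fate_a, fate_b),
        "dtw": cost, "log_dtw": log_cost, "n_steps": len(res.path),
    }]


def mean_dtw_curve(results: Sequence[DTWResult], n_steps: int = 40) -> pd.DataFrame:
    """Mean cumulative DTW cost at each of the first ``n_steps`` path steps.

    Pairs whose warping path is shorter than a given step drop out of that
    step's mean; the standard error reflects the pairs still present.
    """
    per_pair = [r.cumulative_at_steps() for r in results]
    rows = []
    for k in range(n_steps):
        vals = np.array([c[k] for c in per_pair if len(c) > k])
        if len(vals) == 0:
            break
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"step": k + 1, "mean": float(vals.mean()), "se": se, "n": len(vals)})
    return pd.DataFrame(rows, columns=["step", "mean", "se", "n"])


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_diff: float       # mean(log DTW, bipotent) - mean(log DTW, uni)
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    seed: Optional[int]


def permutation_test(
    log_dtw_uni: Sequence[float],
    log_dtw_bi: Sequence[float],
    n_perm: int = 100_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    exact: bool = False,
) -> PermutationResult:
    """One-sided permutation test that uni-fated sisters have smaller log DTW.

    Pools both groups, reassigns labels at random preserving group sizes, and
    compares the observed mean difference (bipotent − uni) with the null
    distribution of the same statistic; p = (#{null >= observed} + 1) /
    (n_perm + 1). With ``exact=True`` every distinct label assignment is
    enumerated instead and p = #{null >= observed} / #assignments (the
    identity assignment makes this strictly positive).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    uni = np.asarray(log_dtw_uni, dtype=float)
    bi = np.asarray(log_dtw_bi, dtype=float)
    if len(uni) == 0 or len(bi) == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(bi.mean() - uni.mean())
    pool = np.concatenate([uni, bi])
    n_uni, n_tot = len(uni), len(pool)
    total = pool.sum()
    if exact:
        import itertools

        null_list = []
        for idx in itertools.combinations(range(n_tot), n_uni):
            uni_sum = pool[list(idx)].sum()
            null_list.append((total - uni_sum) / (n_tot - n_uni) - uni_sum / n_uni)
        null = np.array(null_list)
        p = np.count_nonzero(null >= observed - 1e-12) / len(null)
        return PermutationResult(
            observed_diff=observed, null_mean=float(null.mean()),
            null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
            p_value=float(p), n_perm=len(null), seed=seed)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, 20_000_000 // max(n_tot, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(pool, (k, n_tot)).copy(), axis=1)
        uni_sum = perm[:, :n_uni].sum(axis=1)
        null[done:done + k] = (total - uni_sum) / (n_tot - n_uni) - uni_sum / n_uni
        done += k
    p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
    return PermutationResult(
        observed_diff=observed, null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_value=float(p), n_perm=n_perm, seed=seed)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U; exact when the smaller group has <= 8 values."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if min(len(a), len(b)) <= 8 and not has_ties else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def classify_by_logdtw(pair_table: pd.DataFrame, threshold: float = 4.5,
                       generation: int = 2) -> dict[str, int]:
    """Count divergent uni-fated pairs and convergent bipotent pairs.

    At the requested generation: uni pairs with log DTW above the threshold
    (divergent paths despite shared fate) and bi pairs below it (convergent
    paths despite distinct fates). Pairs with undefined log DTW (zero cost)
    are excluded with a warning.
    """
    sub = pair_table[pair_table["generation"] == generation]
    bad = sub["log_dtw"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pair(s) with zero DTW cost excluded "
                      "(log undefined)")
        sub = sub[~bad]
    uni = sub[sub["category"].isin([PairCategory.UNI, PairCategory.UNI_EXEM])]
    bi = sub[sub["category"].isin([PairCategory.BI, PairCategory.BI_EXEM])]
    return {
        "uni_divergent": int((uni["log_dtw"] > threshold).sum()),
        "uni_total": len(uni),
        "bi_convergent": int((bi["log_dtw"] < threshold).sum()),
        "bi_total": len(bi),
    }
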