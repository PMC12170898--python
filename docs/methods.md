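# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention exists.

## Data model

A *spot* is one detection of one cell at one frame: calibrated 3D position
(μm), raw GFP and tdTomato intensities. A *cell life* is the strictly
frame-ordered run of spots between divisions; divisions are binary, so a
cell has 0 or 2 children. Trees rooted at mother cells form a per-movie
*lineage forest*. Frames are 0-based; time in minutes is frame ×
frame interval (default 2 min). Input positions are assumed already
calibrated; the package applies no voxel scaling. A cell's birth date is
the time of its first spot (for roots, the time its tdTomato first became
detectable; for daughters, the first post-division frame). Generation
labels are positional: the mother is `M`; at each division the daughter
whose first spot has the smaller id receives suffix `1` — the ordering
inside a division carries no biological meaning, so any deterministic,
row-order-independent tie-break serves.

Track gaps of up to 5 frames are tolerated (metrics interpolate positions
linearly); larger gaps are flagged by validation as lives that should be
split.

## Reporter threshold and differentiation

GFP is normalised by the movie-wide maximum over tracked spots. The
background is a piecewise-linear interpolant of per-movie samples,
constant beyond the sampled range (constant extrapolation is the only
assumption-free choice at the movie edges; generated movies therefore
sample the background through the final frame). The positivity threshold is
`m·B(t)` with

    m = (1 + 1e-6) · max over endocardial spots of gfp_raw / B(t),

the least multiplier that classifies every endocardial spot as negative.
The factor 1 + 1e-6 makes "lowest multiplier" well defined on continuous
intensities (the supremum is attained strictly). Comparisons are made on
raw intensity against `m·B(t)`; dividing both sides by the movie maximum
gives the identical rule on normalised values, so the two published
phrasings coincide under this convention.

A cell differentiates at the first spot exceeding the threshold, with an
optional persistence requirement of k consecutive supra-threshold frames
(default 1). Class-mean differentiation times use only cells whose *own*
track shows the sub- to supra-threshold transition: a daughter born after
its lineage switched the reporter on is positive at its first frame and
carries no information about onset timing — including such cells would
drag the class mean towards their birth times. The first observed crossing
within a family is the natural family-level onset estimator and is what
the parameter-recovery checks use.

Movies are aligned by matching class-mean differentiation times (LV/AVC
and atrial myocytes) to a reference movie: a movie's offset is the mean,
over shared classes, of (reference mean − movie mean), rounded to the
frame grid. The original analysis states the alignment principle but not
the estimator; averaging class differences is the obvious unbiased choice
and is translation-equivariant by construction.

## Lineage metrics

Clone spread along an anatomical axis (AP or DV, supplied as two landmark
points — the axes are empirically established, never inferred) is the
range of eligible-cell projections divided by the axis length. Projections
outside the segment are clamped for the fraction, keeping it in [0, 1];
the raw pre-clamp range is reported separately. Eligibility: GFP-positive
and at least 4 h into the cell cycle, to avoid short-range post-division
artefacts.

Family distance analyses sample daughters at T0 (20 min after the mother's
division; one source states 10 min in a figure legend, so the offset is a
parameter), T1 (last frame before the first daughter re-divides) and T2
(last frame with all granddaughters coexisting, clipped to the end of
migration), tagging pairs homotypic/heterotypic by fate equality. The end
of migration is the per-movie aligned mean LV/AVC differentiation time
(atrial mean for atrial analyses). Myocyte dispersion pools pairwise
distances among same-family reporter-positive myocytes at the end of
migration and at the last co-tracked frame ("heart tube" stage).

Potency is the number of distinct determined fates among a mother's
leaves; any undetermined leaf makes the mother undetermined. The
restriction generation is the earliest generation at which every subtree
is fate-homogeneous.

## Motility

Speed is total path length divided by duration (μm/min) within aligned
5-h bins; segments spanning a bin edge are split linearly and bins holding
the cell for under 40 min are dropped. Tortuosity is straight-line
distance over path distance in consecutive 50-min windows, averaged per
cell; the final partial window is kept only if it covers ≥ 25 min; cells
tracked under 3 h are excluded; a stationary window scores 1 (a cell that
does not move does not meander — this resolves the 0/0 case). Path length
is summed point to point on the tracking grid, with no smoothing.

Sister contact uses a 13 μm threshold — the mean distance of visually
confirmed touching pairs; `derive_contact_threshold` recomputes it from
such samples. The contact ratio is time below threshold divided by the
pair's coexistence duration, both restricted to the first 16 aligned
hours, for generation-1 and -2 pairs with cycles ≥ 4 h. Coexistence is
used as the denominator because it is the only symmetric, well-defined
choice when the two sisters' track durations differ. Retention is the
fraction of pairs below threshold at their first coexistent frame.

## Slope-constrained DTW and inference

The dynamic programme implements the symmetric Sakoe–Chiba pattern with
slope constraint P = 1 exactly as stated in the README; unreachable cells
are +∞ and lengths violating M ≤ 2N − 1 (and symmetrically) are rejected
as infeasible. Backtracking resolves ties deterministically: diagonal
first, then the step advancing the second sequence. Costs are cumulative
by default (normalisation by N + M available behind a flag), and "log DTW"
is the natural logarithm. Sister trajectories run from one frame after the
mother's division to the first re-division of either branch, clipped to
the end of migration, sampled every 5 frames (the manual-tracking cadence;
configurable). Pair categories: Uni (same non-ExEm fate), UniExEm (both
ExEm), Bi (distinct, no ExEm), BiExEm (distinct, ≥ 1 ExEm); a branch's
fate is the unique determined fate of its leaves, and pairs with
unresolved branches are skipped. Cousin pairs cross the generation-1
split (all four D1x–D2y combinations).

Per-step curves report the mean cumulative cost at each of the first 40
warping-path steps, pairs dropping out when their paths end (an
alternative time-frame interpretation is available via the per-pair curves
themselves).

The permutation test pools both groups' log DTW values, reshuffles labels
preserving group sizes (default 100,000 permutations) and compares the
observed mean difference (bipotent − uni) one-sidedly, with the +1
finite-sample correction; tiny problems can be enumerated exhaustively.
The Mann–Whitney U utility delegates to scipy (exact when the smaller
group has ≤ 8 values and no ties, asymptotic with tie correction
otherwise).

## Synthetic embryos

Cells are persistent random walks: each cell keeps a unit heading updated
as `normalize(ρ·h + (1−ρ)·ξ)` with fate-specific persistence ρ and
Gaussian noise ξ; the realised step direction blends a family-shared
heading with the cell's own, weighted by the mother's potency
(`sister_corr_uni` = 0.8 vs `sister_corr_bi` = 0.2 by default) — this is
what makes uni-fated sisters run on near-parallel paths. Bipotent sisters
additionally drift apart radially (0.05 μm/min). Step length is the
fate-and-bin speed × Δt × lognormal noise of mean one, so realised mean
speeds are unbiased. The default speed table encodes the observed
phenomenology: extraembryonic mesoderm slow early then fastest; an
endocardial/endothelial speed step-up in the 10–15 h bin; pericardial
slow-down; myocytes decelerating late. Defaults: 5 movies × 1200 frames at
2 min, ~45 mothers per movie (≈ 225 per cohort), lognormal cycle lengths
(mean 8 h, sd 2 h), up to 5 generations, per-movie clock lags mirroring
the published alignment offsets.

GFP: background level 100 with drift 0.05/min and additive noise; myocyte
lineages switch on with a logistic rise over 60 min at family-synchronous
onsets (LV/AVC mean 20.7 h, atrial 29.1 h, sd 90 min on the common clock);
endocardial traces are uniform multiples of background bounded by a known
margin (1.5), whose sample maximum is what threshold fitting recovers.
Initial sister separation is lognormal (median 11 μm, σ = 0.6), putting
roughly 60% of pairs inside the 13 μm contact threshold at division.

The generator does *not* emulate: tissue mechanics or epithelial folding,
boundary effects or crowding, anisotropic imaging noise, depth-dependent
intensity attenuation, track gaps or mistracking, or cell death. Passing
recovery tests therefore demonstrates the estimators' correctness under
the assumed statistical structure, not robustness to those real-data
artefacts.

## Problem sizes and tolerances

Tests and the acceptance script run scaled-down cohorts (2 movies × 450
frames, ~18 mothers per movie; contrast replicates use one 240-frame movie
with 18 uni and 8 bipotent sister pairs, sized for adequate power at the
p < 0.01 detection criterion) — the statistical structure is identical to
the full defaults, only counts differ. Numerical tolerances: DTW oracle
agreement to 1e-9 relative; threshold recovery to 1%; onset recovery
within 60 min (half the logistic rise); backtracking tie tolerance 1e-9
relative. Degenerate inputs: zero-cost DTW pairs are excluded from log
analyses with a warning; empty groups, empty clones and zero backgrounds
raise typed errors rather than propagating NaN.

## Known limitations

The deposited-annotation schema of the original tracking data is not
standardised; the reader accepts a column-mapping so such exports can be
adapted, but field-testing against the archive is outside the desk-scale
suite. Alignment offsets depend mildly on the class-mean estimator, so
reproductions may differ from published offsets by minutes. DTW cost is
reported in μm-weighted units and depends on the sampling cadence; compare
only values computed at the same cadence.
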