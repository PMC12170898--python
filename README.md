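# lineagemotility

Lineage-aware migration analysis for manually tracked mesodermal cells in
time-lapse light-sheet movies of gastrulating mouse embryos.

During gastrulation, mesodermal cells destined for the heart (left
ventricle/atrioventricular canal and atrial myocytes, endocardium,
pericardium) and for extraembryonic mesoderm migrate over tens of hours
before the heart tube forms. Given manual tracking exports — one spot per
cell per frame with 3D positions in μm and reporter intensities, plus
parent→daughter links — this package reconstructs binary lineage forests
and asks how a progenitor's fate potential relates to the migratory
behaviour of its daughters.

## What it computes

* **Lineage forests** from spot/link CSV tables, with positional generation
  labels (mother `M`, daughters `D1`/`D2`, granddaughters `D11`…`D22`),
  validation, and Newick export with cell-cycle branch lengths.
* **Differentiation calling.** A cardiomyocyte reporter (GFP) is compared
  with a piecewise-linear background model `B(t)`; the positivity threshold
  is `m·B(t)` where `m` is the *lowest* multiplier keeping every
  endocardial-annotated spot (a lineage that never activates the reporter)
  sub-threshold. A cell differentiates at the first supra-threshold frame.
  Per-movie mean myocyte differentiation times align the movies onto a
  common clock and define the end of the migration period.
* **Clone dispersion** along user-supplied anatomical axes (spread fraction
  d/D), homotypic vs heterotypic distances among daughters/granddaughters at
  canonical timepoints T0/T1/T2, midpoint distances, and pairwise myocyte
  dispersion at the end of migration vs after heart-tube formation.
* **Motility metrics.** Mean speeds (track length / duration) in aligned
  5-h bins, windowed tortuosity (straight-line / path distance in 50-min
  windows, averaged per cell), and sister contact ratios (fraction of
  coexistence spent closer than 13 μm within the first 16 aligned hours).
* **Trajectory similarity by slope-constrained DTW.** Sister (and cousin)
  trajectories are compared with dynamic time warping under the symmetric
  Sakoe–Chiba step pattern with slope constraint P = 1 ("symmetricP1"):
  with local Euclidean cost d(i,j),

      g(0,0) = d(0,0)
      g(i,j) = min( g(i−1,j−2) + 2d(i,j−1) + d(i,j),
                    g(i−1,j−1) + 2d(i,j),
                    g(i−2,j−1) + 2d(i−1,j) + d(i,j) )

  Pairs are categorised by branch fates (Uni, UniExEm, Bi, BiExEm) and the
  hypothesis that uni-fated progenitors produce more similar sister
  trajectories than bipotent ones is tested with a one-sided permutation
  test on the difference of mean log DTW (pooling the two groups and
  reshuffling labels; p = (#{null ≥ observed} + 1)/(n_perm + 1)).
* **A synthetic-embryo generator** (persistent random walks with
  family-shared headings, fate-specific speed regimes and reporter onsets)
  so every stage is testable with no external data.

## Worked example

The deterministic worked example contains two hand-built families: in tree
A the LV/AVC sisters `a1`/`a2` travel straight parallel paths 10 μm apart;
in tree B the sisters adopt different fates and separate at 2 μm/min.

```python
from lineagemotility import (generate_worked_example, assemble_forest,
                             dtw_distance, contact_ratio, fit_background,
                             ThresholdModel, call_differentiation, FateLabel)
from lineagemotility.tracking_io import export_newick

sim = generate_worked_example()
fates = {r.cell_id: FateLabel(r.fate) for r in sim.fates.itertuples()}
forest = assemble_forest(sim.spots, sim.links, sim.meta, fates)
print(export_newick(forest))
a1, a2 = forest.cells["a1"], forest.cells["a2"]
res = dtw_distance(a1.positions(), a2.positions())
print(f"sister DTW cost: {res.cumulative_cost:.1f} um")
print(f"contact ratio: {contact_ratio(a1, a2, min_cycle_min=0.0).ratio:.3f}")
thr = ThresholdModel(multiplier=1.5,
                     background=fit_background(sim.meta.background_samples))
print("a1 differentiation at", call_differentiation(a1, thr).t_diff_min, "min")
```

prints

```
((D11:58,D12:58)D1:58,D2:58)M;
(D1:58,D2:58)M;
sister DTW cost: 590.0 um
contact ratio: 1.000
a1 differentiation at 40.0 min
```

The DTW cost is exactly the 10 μm offset times the symmetric path weights
(2·30 − 1 = 59 of them): two parallel trajectories align all-diagonally.
The sisters never separate beyond 13 μm, so their contact ratio is 1, and
`a1`'s GFP trace jumps from background (10) to 40 at frame 20, i.e. 40 min.

There is also a CLI for shell use: `lineagemotility simulate | run |
differentiate | speed | tortuosity | contact | dtw | plot` (see `--help`).

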