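# ryrarray

Spatial statistics of cardiac RyR2 tetramer arrays, dSTORM clusters and
Ca²⁺ sparks.

Type-2 ryanodine receptors (RyR2) are the Ca²⁺ release channels of the
cardiac dyad. Each channel is a homotetramer with a roughly square, ~27-nm
cytoplasmic footprint, and the channels sit in clusters on the junctional SR
membrane whose geometry — how tightly the squares pack, and how large the
clusters are — changes with regulatory state (immunophilin binding,
phosphorylation) and shapes Ca²⁺ spark behaviour. `ryrarray` packages the
quantitative machinery needed to study this:

- **Arrangement classification.** Two parallel tetramers whose facing edges
  are separated by a gap `g < 3 nm` are adjacent; the projected edge overlap
  `v` decides the arrangement: *checkerboard* for `0 < v < 2/3·s = 18 nm`
  (centre-to-centre spacing near 34 nm) and *side-by-side* for `v ≥ 18 nm`
  (spacing near 28 nm). Per tetramer the neighbour labels aggregate to
  checkerboard / side-by-side / both / isolated, and per treatment group to
  arrangement fraction tables.
- **Nearest-neighbour distances** (centre-to-centre, per dyad) and their
  empirical CDFs, compared between groups with the k-sample
  Anderson–Darling test (midrank ties, standardized statistic
  `T = (A² − (k−1)) / σ`).
- **dSTORM cluster pipeline.** Blink QC (σ_xy ≤ 10 nm, σ_z ≤ 40 nm,
  goodness of fit ≥ 0.9, 3D nearest neighbour ≤ 30 nm), rasterization onto a
  10-nm binary grid with a lone-blink rule, 50-nm single-linkage clustering,
  alpha-shape areas with a 1600-nm² noise filter, and tetramer counts
  `N = round(A · c / 729 nm²)` where `c` is the group's tomogram-measured
  coverage fraction.
- **Ca²⁺ spark statistics.** Spark mass (amplitude × FDHM × FWHM),
  frequency normalized to SR content, hierarchical (rat → cell → spark)
  bootstrap comparison of group means on the log scale, and the
  Holm–Bonferroni step-down ledger (`p(k) < α/(m−k+1)`).
- **Synthetic generators** for all three data streams, with ground truth,
  so every stage is testable without microscopy data.

## Worked example

```python
import numpy as np
import ryrarray as rr

# 1. simulate a control-like dyad and classify it
cfg = rr.ArrayGenConfig(
    n_tetramers=200, target_fractions=(0.50, 0.28, 0.08, 0.14), seed=42
)
array, truth = rr.gen_tetramer_array(cfg)
summary = rr.summarize_arrangements([array])["synthetic"]
for label, frac in summary.fractions.items():
    print(f"{label.value:>13s}: {100 * frac:.1f}%")

# 2. nearest-neighbour distances
nnd = np.array([d for _, d in rr.nearest_neighbour_distances(array)])
print(f"median NND: {np.median(nnd):.1f} nm")

# 3. tetramers per cluster from a median cluster area and coverage
params = rr.ClusterParams(coverage=0.495)
print("tetramers in a 12200 nm^2 cluster:", rr.estimate_tetramers(12.2e3, params))
```

prints

```
 checkerboard: 50.0%
 side_by_side: 28.0%
         both: 8.0%
     isolated: 14.0%
median NND: 33.6 nm
tetramers in a 12200 nm^2 cluster: 8
```

The classifier recovers the generator's target arrangement fractions
exactly at this size; the median nearest-neighbour distance of 33.6 nm
reflects the checkerboard-dominated mixture (modes at 28 and 34 nm); and a
median-sized 12 200-nm² cluster at 49.5 % coverage holds eight tetramers.

The same stages are scriptable from a shell:

```sh
ryrarray simulate --kind arrays --out work/ --seed 42 --n-tetramers 200
ryrarray classify --input work/tetramers.csv --summary work/summary.csv
ryrarray nnd --input work/tetramers.csv --out work/nnd.csv
```

## Layout

| module | contents |
| --- | --- |
| `ryrarray.geometry` | tetramer/array types, pair relations, NND, alpha shapes, coverage |
| `ryrarray.arrangement` | pair and tetramer classification, group summaries |
| `ryrarray.dstorm` | blink QC, rasterization, linkage clustering, areas, tetramer counts |
| `ryrarray.spatial_stats` | ECDFs, k-sample Anderson–Darling, pairwise comparison tables |
| `ryrarray.spark_stats` | spark mass, frequency normalization, hierarchical bootstrap, Holm ledger |
| `ryrarray.synthetic_data` | array, blink-cloud and spark-table generators |
| `ryrarray.io` / `ryrarray.cli` | CSV schemas, PGM export, provenance records, `ryrarray` CLI |

See `docs/methods.md` for the models, parameter choices and limitations.
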