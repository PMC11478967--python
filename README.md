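# spikequad

Wheat spike morphometry from 2D silhouette images.

Spike shape and size are central phenotypes in wheat diversity studies and
breeding: they separate hexaploid species, the Dorofeev spike types
(compact / normal / spelt) and even accessions within a species. Manual
measurement with a ruler captures only a handful of traits. `spikequad`
extracts a rich, interpretable trait set from a single photograph of a
spike laid on a uniform blue background, then runs the downstream
statistics such studies need.

## The model

Each half of the spike silhouette (above and below the rachis) is
approximated by a quadrangle anchored on the rachis: a basal segment rising
from the stem end to half-width *q_y1s* over length *q_x1s*, a central
segment running to half-width *q_y2s* over *q_x2s*, and an apical segment
falling back to the axis over *q_x3s*. The two sides are fitted
independently by least squares (piecewise-linear profile with endpoints
pinned to zero, exhaustive breakpoint search plus local refinement) and
averaged into one mirror-symmetric model with five independent parameters:

    q_x1s, q_x2s, q_x3s  (segment lengths, mm),  q_y1s, q_y2s  (widths, mm)

From these follow the derived traits — total length `q_L = q_x1s + q_x2s +
q_x3s`, segment areas `q_S1 = q_x1s·q_y1s/2`, `q_S2 = q_x2s·(q_y1s+q_y2s)/2`,
`q_S3 = q_x3s·q_y2s/2`, half-spike area `q_S`, width index `q_ym = q_S/q_L`,
and the length- and area-normalized shares — plus whole-contour descriptors:
perimeter `c_P`, projection area `c_SA`, awn area `c_AA`, circularity
`c_Ci = 4πA/P²`, roundness `c_R = 4A/(πF²)` (F = maximum Feret diameter),
solidity `c_So = A/A_hull` and rugosity `c_Ru = P/P_hull`. Together with the
five manual traits (SL, SFW, SSW, SSC and the density index
`SDI = (SSC−1)·100/SL`, SL in mm) this gives the standard 31-trait table.

On top of the trait table the package provides Shapiro–Wilk normality
scans, Pearson correlation matrices with UPGMA trait clustering (distance
1 − r), one-factor ANOVA / Brown–Forsythe / Kruskal–Wallis group tests,
per-group mean ± SE summaries, two-accession comparisons (pooled t, F and
Mann–Whitney tests, also directly from printed summary statistics), and
Box–Cox-regularized linear discriminant classification into species or
spike types with confusion matrices and biplot coordinates.

A synthetic generator renders spike-like silhouettes with known quadrangle
parameters, spikelet-scale boundary bumps, bends and awns, and samples
whole trait populations around published per-species means — so the entire
pipeline is testable without any photograph.

## Worked example

```python
import spikequad as sq

# render a synthetic spike with known ground truth, then analyze it
model = sq.SymmetricQuadrangleModel(30.0, 50.0, 10.0, 3.5, 4.0)
img, masks, arclength = sq.render_spike(sq.SpikeRenderSpec(model=model, scale=0.2, seed=1))
record = sq.analyze_image(img, plant="demo")
print(f"q_L  true {model.q_L:.1f}  measured {record.derived.q_L:.1f} mm")
print(f"q_ym true {sq.derive_traits(model).q_ym:.2f}  measured {record.derived.q_ym:.2f} mm")

# simulate a labelled 8-class population and classify it
table = sq.generate_population(sq.default_population_spec(n_per_class=25, seed=3))
grid, _ = sq.classification_report(table, "species")
print(grid.to_string(index=False))
```

prints

```
q_L  true 90.0  measured 89.7 mm
q_ym true 2.89  measured 2.87 mm
features transform  n_traits  accuracy_percent
  manual       raw         5              67.5
  manual    boxcox         5              67.0
 digital       raw        26              74.0
 digital    boxcox        26              77.0
combined       raw        31              86.5
combined    boxcox        31              93.0
```

The measured model parameters recover the generative ones to about 1%, and
the classification grid shows the characteristic ordering: combining the
manual and digital trait sets beats either alone, and Box–Cox
regularization helps the larger sets.

The same analyses are available from the shell:

```
spikequad simulate --n-per-class 10 --seed 1 --mode images --out sim/
spikequad analyze --images sim/ --scale-mm-per-px 0.2 --out traits.csv
spikequad stats --traits traits.csv --group species --out report/
spikequad classify --traits traits.csv --label species --out report/
spikequad render --traits traits.csv --group species --out figures/
```

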