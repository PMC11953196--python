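# macuhole

En-face OCT macular hole morphometry and cohort analysis:

* **`macuhole.segmentation`** — automated three-step measurement of an en-face
  raster: the full hole region bounded by the bright circumferential edge ring
  (total area, TA), the dark lumen inside it (luminal area, LA), and the
  photoreceptor annulus as their set difference (PRA = TA − LA). Precomputed
  masks can be supplied to mirror a manual grading workflow.
* **`macuhole.index`** — cohort-relative integrity scoring: min-max
  normalization of PRA and LA over the cohort, and the bounded index
  `norm_pra / (norm_la + 1)` ∈ [0, 1] (0 = poor photoreceptor survival at the
  hole edge, 1 = maximal surviving annulus). Also: |Δ| change variables
  between baseline and follow-up, and small/medium/large hole size classes
  from the minimum aperture diameter.
* **`macuhole.synthetic`** — phantom rasters with exact (analytic or
  quadrature) ground-truth areas, and Gaussian-copula synthetic cohorts whose
  marginals, index correlation structure, and intergrader concordance are
  calibrated to published summary statistics — so the whole pipeline is
  testable with no patient data.
* **`macuhole.stats`** — descriptives (median/quartiles/extrema), Jarque–Bera
  normality, Spearman correlations with listwise deletion (exact permutation
  p below n = 10), rank-sum / signed-rank change tests (exact for small
  tie-free samples), univariate OLS with adjusted R², and Lin's concordance
  correlation coefficient with a Fisher-z 95% interval.
* **`macuhole.cli` / `macuhole.io`** — command-line surface and lossless
  CSV table round-tripping (missing values as empty fields).

## Command line

```sh
# synthetic cohort table (marginals + correlation targets from the default config)
macuhole simulate cohort --n 38 --seed 1 --out cohort.csv

# one phantom raster with exact ground truth
macuhole simulate phantom --spec phantom.yaml --out eye.png --truth truth.json

# one phantom per cohort row
macuhole simulate imaging-cohort --cohort cohort.csv --outdir imgs/ --seed 1

# measure rasters into a table, score, and report
macuhole measure imgs/ --out measured.csv
macuhole score --in cohort.csv --out scored.csv
macuhole stats --in scored.csv --out report.json --text report.txt

# the full synthetic study in one command (deterministic per seed)
macuhole run-all --outdir run/ --seed 1
```

Configs are YAML or JSON; unknown keys are rejected. Every run logs the
resolved configuration, seeds, and package version. `score --clamp` clips
out-of-cohort values into [0, 1] for prospective eyes; the default errors
instead.

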