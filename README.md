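# sixmodel

Dose-response analysis and drug-sensitivity biomarker screening for small
cell-line panels.

Cytotoxicity assays (e.g. luminescent ATP viability readouts) produce, per
cell line, percent-growth values at a ladder of drug concentrations.
`sixmodel` estimates each line's half-maximal inhibitory concentration
(IC50) with a six-model ensemble of constrained logistic curves, classifies
lines as sensitive or resistant at an IC50 threshold, and screens a
genes × samples expression matrix for markers of that sensitivity. It is
aimed at labs running small pharmacogenomic panels — a handful of cell
lines, one compound, one expression profile per line.

## The model

Percent growth Y at arithmetic concentration X follows the four-parameter
logistic (4PL)

```
Y(X) = d + (a − d) / (1 + (X / c)^b)
```

with top plateau `a` (untreated growth), bottom plateau `d` (growth at
infinite dose), midpoint dose `c`, and Hill slope `b`. Six constrained
variants are fitted by unweighted nonlinear least squares:

| variant | constraints |
|---|---|
| `P3` | b = 1 |
| `P3_TOP100` | b = 1, a = 100 |
| `P3_BOTTOM0` | b = 1, d = 0 |
| `P4` | none |
| `P4_TOP100` | a = 100 |
| `P4_BOTTOM0` | d = 0 |

From each fit, six response metrics are read off the curve: IC50/IC90/IC95
(doses where the fitted curve crosses 50/90/95% growth, by the closed form
`X = c·((a−d)/(L−d) − 1)^(1/b)`), EC50 (the midpoint dose `c`), Amax
(`a − d`), and the activity area (sum of fitted growth over a 0.01 µM grid
spanning the tested range). Each variant's IC50 carries a delta-method
standard error propagated from the fit covariance; **the engine reports the
IC50 of the variant with the lowest standard error**. Lines with IC50 below
4 µM (configurable) are *sensitive*, at or above it *resistant*.

The biomarker screen scores every gene of a log2 expression matrix by an
unpaired t-test between the resistant and sensitive groups (Welch by
default), the linear fold change FC(R/S) = 2^(ΔmeanLog2), and the Pearson
correlation of expression with the per-sample IC50 vector (two-sided p via
`t = r·√((n−2)/(1−r²))`). Genes passing `p < 0.01`, `FC > 1` and `r > 0.8`
are selected; the selected signature is z-scored per gene and clustered on
both axes by complete linkage with Euclidean distance. qPCR validation data
are quantified by the ΔΔCt method (ratio `2^−ΔΔCt`).

A synthetic-data module generates panels and expression matrices with known
ground truth (the default scenario: seven cell lines, 4 sensitive /
3 resistant, 8-dose ladder 0.02–20 µM, a nine-gene planted signature), so
the whole pipeline is testable end to end without external data.

## Worked example

```python
import numpy as np
from sixmodel import default_scenario, fit_six_models, simulate_panel

panel, _ = default_scenario(seed=162)
table = simulate_panel(panel)[2]          # cell line M24, true IC50 = 2.0 uM
engine = fit_six_models(table)
print(f"cell {table.cell_id}: selected {engine.selected_variant_}")
print(f"  IC50  = {engine.ic50_:.3f} +/- {engine.ic50_se_:.3f} uM -> {engine.label_}")
m = engine.metrics_[engine.selected_variant_]
print(f"  IC90  = {m.ic90:.3f} uM, EC50 = {m.ec50:.3f} uM")
print(f"  Amax  = {m.amax:.1f}%, activity area = {m.activity_area:.0f}")
for vid, met in engine.metrics_.items():
    print(f"  {vid:<11} IC50 {met.ic50:7.3f}  SE {met.ic50_se:.4f}")
```

prints

```
cell M24: selected P4_BOTTOM0
  IC50  = 1.852 +/- 0.064 uM -> sensitive
  IC90  = 0.448 uM, EC50 = 1.821 uM
  Amax  = 101.3%, activity area = 33725
  P3          IC50   1.921  SE 0.1277
  P3_TOP100   IC50   2.007  SE 0.1595
  P3_BOTTOM0  IC50   1.818  SE 0.1475
  P4          IC50   1.836  SE 0.0677
  P4_TOP100   IC50   1.844  SE 0.0672
  P4_BOTTOM0  IC50   1.852  SE 0.0641
```

All six variants agree the line is sensitive; `P4_BOTTOM0` wins with the
smallest IC50 standard error, so its 1.85 µM is the reported estimate —
close to the 2.0 µM ground truth at the default noise level (SD 5
percent-growth units). The activity area sums fitted viability over 1,999
grid doses; smaller values mean a more sensitive line.

The same pipeline runs from the shell:

```sh
sixmodel run --simulate --seed 162 --out-dir out/   # full synthetic run
sixmodel fit --input panel.tsv --threshold 4        # fits on your own data
```

`run` writes an IC50 summary TSV, the biomarker records TSV, Newick
dendrograms for both axes and a JSON manifest (config + seed + versions)
that makes the run exactly reproducible.

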