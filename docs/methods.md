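# Methods

## Dose-response model

Percent growth at arithmetic concentration X (µM) is modelled by the
four-parameter logistic Y(X) = d + (a − d)/(1 + (X/c)^b). The four
parameters have direct assay readings: `a` is growth of untreated cells,
`d` growth at saturating dose, `c` the dose of the half-way response
(Y(c) = (a + d)/2 for any slope), and `b` the Hill slope. Fitting is by
unweighted nonlinear least squares on the arithmetic concentration scale —
consistent with the additive, dose-independent noise the generator assumes;
a heteroscedastic generator mode (SD proportional to signal) exists for
sensitivity checks but the fit remains unweighted.

Six constrained variants are fitted (`P3`, `P3_TOP100`, `P3_BOTTOM0`, `P4`,
`P4_TOP100`, `P4_BOTTOM0`): the "3-parameter" family fixes b = 1 (the
conventional slope-free reduction), and the top/bottom-anchored versions
pin a = 100 (growth is measured as percent of control) or d = 0 (complete
kill). Constraints are imposed exactly by removing the parameter from the
optimisation.

### Optimisation

`scipy.optimize.least_squares` (trust-region reflective, bounded), from a
deterministic start — a₀ = max observed growth, d₀ = min, c₀ = geometric
midpoint of the tested range, b₀ = 1 — plus 4 jittered restarts (seeded;
additive SD 10 on a₀/d₀, log-normal factors on c₀ and b₀). Bounds:
c ∈ (0, 100 × max dose], b ∈ [0.05, 20], a and d in ±500 (growth can
legitimately exceed [0, 100] through luminescence noise). The best of the
starts by SSE is kept; a fit is flagged not-converged (and excluded from
model selection, not raised) if no start succeeds.

### Uncertainty and model selection

The free-parameter covariance is the linearised (Gauss-Newton) covariance
s²(JᵀJ)⁻¹ with s² = RSS/(n − p), computed through the SVD of J. When J is
rank-deficient — some parameter combination unidentifiable from the data,
e.g. a flat table fitted with a forced zero bottom — the covariance is set
to +∞ rather than the pseudo-inverse's silent 0: an unidentifiable IC50
must never win selection by spurious certainty.

The IC50 standard error is the delta method applied to the closed form
x = c·((a−d)/(50−d) − 1)^(1/b), with analytic partials in the free
parameters. A parametric-bootstrap SE (refitting simulated datasets at the
fitted curve and residual SD) is available as a cross-check mode; tests
hold the two within 25% of each other at the default noise. The engine
selects the variant whose IC50 has the smallest SE; ties go to the earlier
variant in canonical order (the simpler 3-parameter family first). The
residual SE of the fit can be used as the selection criterion instead via
`selection_criterion="residual_se"`.

### Metric conventions and degenerate inputs

- IC50/IC90/IC95 are the doses where the *fitted growth* crosses 50/90/95%
  — on a viability scale IC90 therefore means 10% inhibition. A level is
  undefined (NaN) when it lies outside the open interval between the
  plateaus, and also when the implied dose exceeds 10× the highest tested
  concentration (`extrapolation_factor`): a crossing that far outside the
  assay window is an artifact of a constraint (a flat table with d pinned
  at 0 "crosses" 50% at an arbitrary large dose with zero residual), not an
  estimate. If no variant yields a defined IC50, the engine reports an
  explicit no-estimate and the line is `unclassified`.
- EC50 is the dose at the midpoint response (a + d)/2 — i.e. the fitted c.
- Amax = a − d exactly.
- The activity area is Σ Ŷ over the arithmetic grid from the lowest to the
  highest tested dose in 0.01 µM steps, endpoints included (1,999 points
  for 0.02–20 µM). It sums viability, so smaller = more sensitive.
- Classification: IC50 < threshold (default 4 µM) → sensitive, ≥ →
  resistant; the measure-zero boundary goes to the resistant side.

## Biomarker screen

Given a genes × samples matrix of normalised log2 intensities with a
per-sample IC50 and label, each gene is scored by: (1) an unpaired
two-sample t-test, Welch by default — the groups are small (4 vs 3 in the
default design) and there is no evidence for equal variances; Student's
pooled test is one flag away; (2) FC(R/S) = 2^(mean_R − mean_S) on the
log2 values, i.e. the ratio of geometric means on the intensity scale; and
(3) the Pearson correlation with the continuous IC50 vector (a
point-biserial mode against the binary label exists behind a flag), with
two-sided p from the t-transform on n − 2 df. Selection is the conjunction
p < 0.01, FC > 1, r > 0.8 on *raw* p-values; Benjamini–Hochberg-adjusted
p-values are reported alongside for transparency but do not gate selection.
Zero-variance genes get p = 1 (equal means) or p = 0 (unequal, flagged),
and an undefined correlation, so they are never selected spuriously.

The selected signature is z-scored per gene across samples (zero-variance
genes dropped with a warning) and both axes are clustered by agglomerative
complete linkage on Euclidean distances. The linkage is implemented
directly (O(n³), fine at signature scale) so the tie rule is explicit and
platform-independent: equal-distance candidate merges resolve to the
smaller (id, id) pair. Heights are nondecreasing (complete linkage is
monotone); trees serialize to Newick with height differences as branch
lengths, and leaf order puts the tighter (lower) subtree first.

qPCR validation uses the ΔΔCt statistic: with a reference gene (e.g.
GAPDH) and a calibrator sample, the expression ratio is 2^−ΔΔCt,
ΔΔCt = (Ct_target − Ct_ref)_case − (Ct_target − Ct_ref)_calibrator.

## Synthetic data

The generators exist so that every stage can be tested against known
truth; they are pure functions of (scenario, seed).

- **Panel**: growth = 4PL(truth) + Gaussian(0, SD 5 percent-growth units)
  at an 8-dose geometric ladder 0.02–20 µM with 3 replicate wells. The
  default seven-line panel has true IC50s 0.5/1.2/2.0/3.0 (sensitive) and
  8/9/10 µM (resistant): two clearly separated groups, tight within-group
  spread relative to the gap. That separation is a deliberate modelling
  choice — it is the regime in which a gene tracking the IC50 profile is
  also differentially expressed between the groups, which is what the
  reference biomarker set exhibits; with widely scattered resistant IC50s
  the profile-tracking signal itself inflates the within-group variance and
  the two criteria decouple. Plateaus (a 98–102, d 0–6) and slopes
  (0.8–1.5) vary mildly across lines; c is set so each line's true IC50
  lands exactly on target.
- **Expression**: background genes i.i.d. Gaussian(baseline 7.0, SD 0.5)
  log2 units; each of the 9 planted genes is baseline + β·z(IC50) + noise
  with β = 0.5 log2 units per SD of IC50 and noise SD β·√(1/r² − 1) so the
  planted population correlation is r = 0.95, putting sample correlations
  in the 0.90–0.97 band where the reference biomarkers sit. 2,000 genes by
  default (the array scale of ~13k genes is down-sampled for test-time
  economy; the screen is univariate per gene, so gene count only affects
  the null false-positive count, which tests verify separately against a
  direct Monte-Carlo estimate).

What the generator does *not* model: gene–gene correlation structure
(coexpression blocks), intensity-dependent variance, probe effects, batch
structure, and any dependence of expression noise on group. Passing tests
therefore demonstrate the statistics and plumbing are correct under the
stated noise model, not that the thresholds are well-calibrated for a real
microarray panel.

## Problem sizes and numerical tolerances

Test-suite simulation sizes (chosen as the package's own verification
budget): 200 panels for IC50-recovery (median relative error < 15%),
1,000 bootstrap refits for the SE cross-check, 500 seeds for screen power
(≥ 70% planted recovery) and for the null false-positive rate (within 10%
of a 4M-draw Monte-Carlo oracle). Closed-form identities are held to
1e-9–1e-12; noise-free parameter recovery to 1e-6.

## Known limitations

- The delta-method SE is a first-order approximation; for steep slopes or
  sparse ladders the bootstrap mode is more trustworthy.
- Model selection by minimum SE can favour over-constrained variants whose
  constraints happen to match the data; the full six-fit report is always
  retained for inspection.
- The screen is univariate; no multivariate signature learning, and no
  multiplicity correction in the selection path (by design — BH values are
  reported but not applied).
- Complete-linkage clustering is O(n³) and intended for selected
  signatures (tens of genes, handfuls of samples), not whole-array
  clustering.
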