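# Methods

This note records the models, conventions and numerical choices behind
`lumiqc`, and what the synthetic-data tests do and do not demonstrate.

## Plate model and units

Plates are 16×24 grids (rows A–P, columns 1–24) of non-negative raw
luminescence counts; both the matrix reader export (header `1..24`, row
labels, comma or tab) and a long CSV form (`plate_id, well, raw_signal`) are
accepted, since reader dialects vary. Well addresses are canonicalized to
zero-padded form (`B07`). Concentrations are converted to **µM** at parse
time (nM/µM/mM/M accepted); a single canonical unit avoids silent 1000×
errors when screening tables mix mM and µM.

## Control statistics and plate QC

Sample standard deviations (n−1 denominator) are used everywhere — for the
control SDs entering Z' and for CV. HTS practice computes control SDs from a
small number of wells (16 per group by default here), where the sample SD is
the standard choice; using one convention throughout keeps the PASS/RETEST
decision well defined.

The control-outlier removal is a **greedy leave-one-out Z' maximization**:
while Z' is below threshold, remove the single control well (from either
group, never shrinking a group below two wells) whose removal most increases
Z', up to `max_outliers` (default 2). A plate recovering to Z' ≥ threshold
passes with the removed wells recorded; otherwise it is flagged `RETEST` and
no removals are applied. "Recovery" is read strictly as reaching the 0.5
threshold, not merely improving. The greedy step never decreases Z' by
construction, and on a single-outlier plate it coincides with the exhaustive
best single removal (tested).

Spatial plate effects are screened with a reproducible proxy for the visual
heatmap check: least-squares slopes of % INHIBITION along row and column
indices. A plate is flagged when either |slope| exceeds a configurable
fraction (default 0.05) of the plate's interquartile range per index step,
with a floor of one percentage point on the IQR so that an exactly uniform
plate never flags and a single hot well among 384 stays below threshold.
This detects monotone gradients; it is intentionally blind to non-monotone
patterns (bowl/edge effects), which the non-goal B-score machinery would
address.

## Dose–response model

LL.4: f(x) = c + (d−c)/(1 + (x/e)^b), fitted on log10 concentration
(concentration 0, i.e. controls, is excluded — the log-logistic curve is
undefined there). The reported IC50 is the fitted inflection e (relative
IC50); the absolute 50%-crossing is used only by the censoring logic.
Responses default to the residual-%-signal scale (d near 100 at low dose);
an `inhibition` scale flag flips the censoring orientation.

Fitting: `scipy.optimize.least_squares` (trust-region reflective) on
θ = (b, c, d, log10 e); initialization d ← median response at the two lowest
concentrations, c ← at the two highest, e ← geometric mean of the range,
with a deterministic multi-start over b ∈ {0.5, 1, 2} (best objective wins;
near-ties go to the smallest slope, for reproducibility near identifiability
boundaries). Bounds: b ∈ [0.1, 20], e ∈ [cmin/100, cmax·100], c and d within
the observed response range ± 50 units. Objective tolerance 1e−8 with a
200-evaluation cap per start; a start that merely hits the cap still
contributes its best point, because the R² gate — not the optimizer's
convergence flag — decides whether a fit is usable. Noiseless data are
recovered to ≲1e−14 relative error under these settings.

Quality classes: `NO_FIT` when no start produces a finite solution or the
data carry no signal variation at all (SStot ≈ 0, e.g. a flat 100% profile);
`UNSUITABLE` when R² < 0.80; `EXTEND_RANGE` when the fitted inflection lies
outside the tested range or a plateau was not observed within 10 response
units of the fitted asymptote (the screening protocol's cue to extend the
concentration range); `OK` otherwise.

Censoring: the 50%-crossing is judged on per-concentration **mean**
responses, which is robust to an unstable fit. No mean on the inhibited side
⇒ `>cmax`; all means inhibited ⇒ `<cmin`; crossing bracketed in-range with
an `OK` in-range inflection ⇒ point estimate; crossing bracketed but the fit
unstable (low R², out-of-range inflection) ⇒ the bracketing interval between
the two adjacent tested concentrations; crossing present but no usable curve
at all ⇒ no value. With triplicate means and 10% CV the crossing judgement
is effectively noise-free (a false crossing would need a ~8 SD excursion).

## Screen-level conventions

Colour bands are half-open — [0,10) strong, [10,50) moderate, [50,80) weak,
[80,∞) none — so boundary values (10, 50, 80) land deterministically in the
upper band. Cell means marginally below 0 (noise on a fully quenched well)
are clamped to 0 for banding only. Significance stars use the equal-variance
Student's t-test at p < 0.05 per cell with no multiple-testing correction,
matching per-cell starring practice; zero-variance degenerate groups resolve
to p = 1 (equal constants) or p = 0 (unequal constants). In potency
rankings, left-censored IC50s sort before all point estimates and
right-censored after, giving a conservative total order; rank consistency
against the Irving–Williams reference is Spearman's ρ over the shared
compounds (≥ 3 required).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Controls**: Normal(μ, σ) clipped at 0 (σ ≪ μ in every preset, so
  clipping is numerically irrelevant); 16 negative + 16 positive wells in
  columns 23/24, a typical 384-well screening layout.
- **Samples**: raw = μp + f(dose)/100·(μn − μp) with f the LL.4 truth on the
  residual-% scale, times multiplicative Gaussian noise max(0, N(1, CV))
  with CV 10% by default — the simplest noise law consistent with positive
  counts and observed triplicate variability. Note % N_VALUE of such a well
  equals the truth plus an offset μp/μn·(1 − f/100) (≈ 0.7 points at
  S/B 136), since the truth lives on the inhibition window while % N_VALUE
  divides by μn alone.
- **Artefacts**: multiplicative linear row/column gradients and
  role-targeted outlier wells (count × multiplier), to exercise the
  plate-effect check and the outlier-removal path.
- **Determinism**: one stream per plate derived from (master seed, plate_id)
  via CRC32, so plate generation is order-independent; experiments seed
  their own `numpy` generator.

Scenario presets set (μn, μp, σn, σp) so that the closed-form Z' and S/B
equal the published per-assay values (e.g. NLuc H: Z' 0.88; FLuc SC:
S/B 136): μp = μn/(S/B), σn + σp = (1 − Z')(μn − μp)/3, with the SD budget
apportioned in proportion to the means so both groups have similar CVs. The
absolute μn per luciferase (10⁶ FLuc, 5·10⁶ NLuc, 2·10⁵ RLuc counts) is an
arbitrary realistic scale — every downstream statistic is scale-invariant.
LL.4 truths come from the published IC50 grid; right-censored entries
(">5000") are modelled with inflection at 5× the grid maximum and lower
plateau 60%, guaranteeing the censoring path is exercised, left-censored
entries put the inflection 5× below the bound, and interval entries use the
geometric midpoint. Modifier presets perturb an assay preset: EDTA raises
the truths' lower plateau to 90% (chelation rescues signal), 2 mM GSH on
FLuc collapses the whole control window to 0.5% of its span (no signal in
any well), and enzyme+metal pre-incubation divides inflections by 3.

What passing tests show — and do not show. The generator reproduces control
separability, replicate noise and LL.4-shaped inhibition, so the tests
demonstrate that the pipeline's statistics, gates and censoring behave
correctly under those assumptions and recover generating parameters at the
stated design (11 log-spaced concentrations, triplicates, 10% CV). Real
plates additionally exhibit reader drift, dispensing artefacts, luminescence
decay over read time, compound autoluminescence and non-LL.4 response
shapes; none of these are modelled, and the replicate-noise magnitude of the
original screens is unknown (10% CV is a default, swept in tests).

## Problem sizes

Recovery and censoring checks use 100 seeds per condition, which puts the
Monte-Carlo error on a median IC50 well under the 25% acceptance band; plate
pipeline checks use 100 simulated plates (16+16 controls, triplicate
samples). The whole test suite and the reproduction script each run in tens
of seconds on one CPU.

## Known limitations

- The outlier search scans both control groups; a pipeline restricting it
  to negative controls would differ on plates with aberrant positives.
- The interval-censoring rule (bracketing between adjacent tested
  concentrations when the fit is unstable) is one defensible formalization
  of a practice that is usually ad hoc; the point-vs-interval boundary
  depends on the R² gate.
- The plate-effect flag is a linear-trend test only.
- `EXTEND_RANGE` advises a wider grid but the package does not merge
  extended-range experiments automatically; callers concatenate the
  observations and refit.
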