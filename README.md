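# lumiqc

Plate quality control, control-based normalization and censoring-aware IC50
estimation for bioluminescent high-throughput screening (HTS), built around
the problem of **metal-ion interference in luciferase reporter assays**.

Luciferase readouts (firefly FLuc, *Renilla* RLuc, NanoLuc NLuc) are the
workhorse of HTS, and metal ions — ubiquitous in buffers, biological
matrices, plasticware and compound libraries — can quench or distort the
bioluminescent signal and generate false positives. Quantifying that
interference means running the full screening data-analysis stack: per-plate
QC, normalization against on-plate controls, dose–response fitting, and
screen-level summary tables. `lumiqc` implements that stack as a tested,
reusable library plus a synthetic plate generator, so every stage can be
validated without access to raw reader exports.

## What it computes

**Plate QC.** From the negative (vehicle, mean μn, SD SDn) and positive
(reference inhibitor, μp, SDp) control wells of each 384-well plate:

    Z' = 1 − 3·(SDp + SDn)/(μn − μp)        S/B = μn/μp        CV = SD/mean·100%

Plates with Z' below the threshold (0.5 by default) go through a greedy
leave-one-out control-outlier removal (up to 2 wells); plates that do not
recover are flagged `RETEST`. A least-squares row/column trend of the
%-inhibition heatmap screens for spatial plate effects.

**Normalization.** Per well with raw signal x:

    % INHIBITION = (1 − (x − μp)/(μn − μp))·100
    % N_VALUE    = x/μn·100            (residual signal)
    % N_SCh      = (x − μn)/μn·100     (≡ % N_VALUE − 100)

**Dose–response.** The four-parameter log-logistic (LL.4) model
f(x) = c + (d − c)/(1 + (x/e)^b) is fitted by nonlinear least squares on
log-concentration; the IC50 is the fitted inflection e. Fits are gated on
R² = 1 − SSres/SStot (< 0.80 ⇒ unsuitable) and RSE = √(SSres/(n − k)), and
IC50s that cannot be pinned inside the tested range are **censored**:
`>cmax`, `<cmin`, or a bracketing interval `lo < IC50 < hi`.

**Screen tables.** Residual-signal matrices with colour bands
(strong < 10% ≤ moderate < 50% ≤ weak < 80% ≤ none) and two-tailed Student's
t-test stars vs the plate's negative controls (p < 0.05); IC50 grids across
the 3 luciferases × 2 buffer systems; EDTA/GSH/pre-incubation modifier
contrasts; Spearman consistency of observed potency order against the
Irving–Williams series (Cu > Zn > Fe > Mn > Ca > Mg).

**Synthetic data.** `scenario_library` ships presets for all six assays whose
control distributions reproduce the published Z' (0.53–0.88) and S/B
(11–136) in closed form, with LL.4 truths taken from the published IC50
grid, plus modifier scenarios and artefact injectors (gradients, aberrant
controls).

## Worked example

```python
import numpy as np
from lumiqc import (DoseResponseData, control_stats, fit_ll4, join_plate,
                    normalize, qc_plate, render_ic50, scenario_library,
                    simulate_plate)

spec, truths = scenario_library("FLuc_SC")       # published FLuc SC conditions
ag = next(t for t in truths if t.compound_id == "Ag")
spec.seed = 11
doses = list(np.geomspace(0.001, 100.0, 11))     # µM, triplicate by default
plate, platemap = simulate_plate(spec, [ag], doses, plate_id="DEMO-001")

wells = join_plate(plate, platemap)
qc = qc_plate(wells, spec.assay)
norm = normalize(wells, control_stats(wells))
samples = norm[norm.role == "sample"]
fit = fit_ll4(DoseResponseData("Ag", samples.concentration_um.to_numpy(),
                               samples.pct_n_value.to_numpy()))
```

Printed output:

```
FLuc SC preset: Z' = 0.64, S/B = 136
plate DEMO-001: status=PASS, Z'=0.676, S/B=135.5
Ag LL.4 fit: b=1.04, c=1.1, d=106.8, e=0.211 µM
IC50 = 0.210948 µM  (R² = 0.989, RSE = 4.89, quality = OK)
```

The plate passes QC (empirical Z' 0.676 scatters around the preset's
closed-form 0.64), and the fitted inflection 0.21 µM recovers the generating
silver IC50 of 0.24 µM to within the replicate noise; `render_ic50` prints
censored results as `>5000`, `<0.01` or `0.016 < IC50 < 0.063`, with `*`
marking fits whose R² fails the 0.80 gate.

A thin CLI wraps the same stages:

```bash
lumiqc simulate --scenario FLuc_SC --seed 3 --out sim/
lumiqc screen --plates sim/ --platemaps sim/ --config assay.yaml --out results/
```

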