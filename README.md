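# renalreab

Physiologically-based prediction of **passive renal tubular reabsorption**
and **renal excretion clearance (CL_R)** from in vitro permeability data.

Renal excretion of a drug that is not actively secreted is the balance of
two processes: glomerular filtration of the unbound drug
(CL_filt = GFR · f_u,p) and passive reabsorption of the filtered drug back
across the tubule wall.  `renalreab` implements a minimal 5-compartment
model of the nephron — glomerulus plus proximal tubule (PT), loop of Henle
(LoH), distal tubule (DT) and collecting duct (CD) — that scales Caco-2
apparent permeability (P_app, measured under an apical pH 6.5 /
basolateral pH 7.4 gradient) to regional intrinsic reabsorption clearances
by in vitro–in vivo extrapolation (IVIVE):

```
CL_int,i = P_app · TSA_i                    F'_i = CL_int,i / (TFR_i + CL_int,i)
F' = 1 − Π(1 − F'_i)                        F_reab = F' · (CL_filt − UF·f_u,p)/CL_filt
CL_R = CL_filt · (1 − F_reab)
```

where TSA_i and TFR_i are the regional tubular surface areas and midpoint
flow rates, UF is the urine flow, and F' is the fraction of the
plasma–urine unbound-concentration equilibrium reached.  Predictions are
bounded by UF·f_u,p ≤ CL_R ≤ GFR·f_u,p.  The package is aimed at DMPK
scientists doing bottom-up CL_R prediction and at modellers embedding
tubular reabsorption in larger PBPK kidney models.

It ships with:

* a 45-drug evaluation panel (clinical CL_R, measured P_app, f_u,p,
  pKa/LogD annotations) and an 11-drug calibration reference subset;
* four model variants (`full`, `filtration_only`, `pt_only`,
  `no_microvilli`) plus a `calibrated` mode that first maps P_app through
  an inter-assay Hill-curve calibration;
* Hill regression of the P_app–F' relationship with confidence intervals;
* clinical-data statistics (study pooling, Cochran's Q / I² heterogeneity
  screening), ionisation classification at urinary pH, LogD_6.5
  estimation, and fold-error evaluation metrics;
* a synthetic panel generator for property testing;
* a `renalreab` command-line interface.

The scientific background, parameter choices and limitations are described
in [docs/methods.md](docs/methods.md).

## Worked example

```python
import pandas as pd
from renalreab import ReabsorptionModel, load_table2
from renalreab.evaluation import evaluate
from renalreab.model import observed_freab

panel = load_table2().drugs                     # the packaged 45-drug panel
model = ReabsorptionModel()                     # full 5-compartment variant
detail = model.fit(panel).predict_detail(panel)

cols = ["drug", "freab_prime", "freab", "clr_filt", "clr_pred", "fold_error"]
print(detail[detail["drug"].isin(["Caffeine", "Atenolol", "Metoprolol"])][cols]
      .round(3).to_string(index=False))
```

```
      drug  freab_prime  freab  clr_filt  clr_pred  fold_error
  Atenolol        0.015  0.015     116.4   114.675       1.264
  Caffeine        0.918  0.910      80.4     7.248       6.837
Metoprolol        0.550  0.545     104.4    47.477       2.317
```

Atenolol barely permeates (P_app 0.256×10⁻⁶ cm/s), so essentially all of
its filtered load (116.4 mL/min) is excreted.  Caffeine is highly permeable
(81×10⁻⁶ cm/s): the model predicts 91% of the filtered drug is reabsorbed,
collapsing CL_R from 80 to 7 mL/min — an over-prediction of reabsorption's
limit, 6.8-fold above the observed 1.06 mL/min, and the known worst case in
the panel.  Scoring the whole panel:

```python
obs = panel["clr_obs_ml_min"].to_numpy()
rep = evaluate(detail["clr_pred"], obs,
               ion_class=panel["ion_class"],
               freab_obs=observed_freab(obs, 120 * panel["fu_p"].to_numpy()))
print(f"n={rep.n}  gmfe={rep.gmfe:.2f}  "
      f"within 3-fold={rep.n_within_3fold}/{rep.n} ({rep.pct_within_3fold:.0f}%)  "
      f"R2={rep.r2:.2f}")
```

```
n=45  gmfe=1.97  within 3-fold=39/45 (87%)  R2=0.76
```

i.e. the mechanistic model predicts CL_R with a bias below 2-fold and 87%
of drugs within 3-fold of observed.  The same pipeline is available from
the shell:

```bash
renalreab predict --out runs/full                 # packaged panel, full model
renalreab calibrate --out runs/cal                # Hill fits + calibrated P_app
renalreab evaluate --predictions runs/full/predictions.csv --out runs/eval
renalreab sensitivity --param urine_flow --grid 0.5,1,2 --out runs/sens
```

## Estimators

The core objects follow scikit-learn conventions (`fit`/`predict`/
`transform`, `get_params`, fitted attributes with trailing underscores):

* `ReabsorptionModel(physiology=None, variant="full")` — mechanistic CL_R
  predictor over a drug table (`papp_1e6_cm_s`, `fu_p` columns).
* `HillCurve(fix_asymptote=True)` — nonlinear regression of F' on P_app;
  `a_`, `b_`, `ci95_b_`, ...
* `PappCalibrator(reference=None)` — fits the predicted- and observed-side
  Hill curves and maps measured P_app onto the model's permeability scale
  via `P_cal = b₁ (P/b₂)^(a₂/a₁)`.

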