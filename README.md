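# dpp3qsar

QSAR modelling of coumarin inhibitors of human dipeptidyl peptidase III
(hDPP III), a zinc-dependent exopeptidase of the M49 metalloproteinase
family and an emerging drug target in pain modulation, blood-pressure
regulation and oxidative-stress response.

The package is aimed at computational medicinal chemists who want to
rebuild, validate or apply a small, interpretable inhibition model for
2H-chromen-2-one (coumarin) derivatives: dataset encoding, structure
construction, descriptor computation, genetic-algorithm model search, the
full internal/external validation battery, and an applicability domain.

## The model

The response is the log-transformed percent inhibition of hDPP III at
10 µM inhibitor concentration. The frozen, published three-descriptor
multiple linear regression ships with the package:

```
log(% inh.) = −4.07 + 1.85·EEig05x + 1.60·Mor10u + 0.56·nArOH
```

with standardized coefficients β = (0.59, 0.52, 0.39), where

- **EEig05x** — 5th-largest eigenvalue of the edge-adjacency matrix with
  edge-degree weights on the diagonal; grows with molecular size,
  branching and cyclicity;
- **Mor10u** — unweighted 3D-MoRSE signal Σ_{i<j} sin(s·r_ij)/(s·r_ij) at
  scattering parameter s = 9 Å⁻¹, summarizing the interatomic distance
  spectrum;
- **nArOH** — number of hydroxyl groups on aromatic carbons.

All three coefficients are positive: larger, more unsaturated coumarins
carrying aromatic hydroxyls inhibit the enzyme more strongly.

The modelling protocol around the equation is implemented in full:
constant/intercorrelation descriptor pruning, random exclusion of
inactives, activity-sampling train/test splits, GA subset search (size ≤ 3,
leave-one-out Q² fitness), OLS fitting, and the validation battery —
R², R²_adj, s, F, RMSE/MAE, Lin's CCC, LOO Q²/PRESS, Y-scrambling,
Q²_F1/F2/F3, rm² metrics, K_xx/ΔK, and the Williams plot with warning
leverage h\* = 3p′/n.

## Worked example

Fit and validate a model on a synthetic study shaped like the real one
(32 compounds, 27/5 activity-sampled split, 3 informative descriptors
hidden among 50):

```sh
python examples/04_fit_and_validate.py
```

```
R2 = 0.828  Q2_LOO = 0.759  CCC_tr = 0.906
external: Q2_F1 = 0.799  Q2_F2 = 0.798  R2_ext = 0.915
robustness: R2_Yscr = 0.116  Q2_Yscr = -0.227
criteria: 14/14 pass
```

Training R² and cross-validated Q²_LOO well above their 0.60/0.50
thresholds show a predictive fit; the near-zero Y-scrambling statistics
rule out chance correlation; the external block measures transfer to the
held-out compounds (volatile with only 5 of them — rerun with other
seeds to see the spread).

The other scripts in `examples/` each demonstrate one capability:
dataset/structures, descriptors, IC50 arithmetic, GA subset search, and
the end-to-end pipeline (`run_paper_pipeline`), which writes structures,
descriptor tables, the fitted model, the validation report, Williams-plot
data and frozen-model predictions for the two proposed follow-up
compounds into an output directory.

A thin CLI wraps the same functions:

```sh
dpp3qsar run --out qsar_run
dpp3qsar ic50 doseresponse.csv
dpp3qsar predict --model published2 --descriptors new_compounds.csv
```

## Limitations

Per-compound numerical identity with the original descriptor values is
not attainable: the original geometries came from semi-empirical (PM3)
optimization and the descriptor software's exact matrix conventions are
not published. This package uses seeded distance-geometry embedding with
MMFF94 relaxation and documented descriptor conventions instead; see
`docs/methods.md` for the full account, including which validation
behaviours carry over (conventions, invariants, trends) and which do not
(exact descriptor values, hence exact Table-level statistics).
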