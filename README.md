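# maizeyield

County-level maize yield estimation with an attention-LSTM multi-task model,
and counterfactual attribution of extreme-year yield losses to individual
climate factors.

## The problem

Interannual maize yield variation at county scale is driven by accumulated
heat (growing degree days, GDD), damaging heat excess (killing degree days,
KDD), precipitation (PRCP), atmospheric dryness (vapor pressure deficit,
VPD) and canopy condition (NDVI), modulated by soil. Two questions matter to
agro-climatologists and yield forecasters:

1. **Estimation** — can a model trained on other years predict a held-out
   year's county yields, including an extreme drought/heat year?
2. **Attribution** — in an extreme year, how much of the loss is caused by
   each climate factor, and during which three-week growth stage?

The package implements a full workflow for both: spatial regionalization of
counties into contiguous production zones (k-means + contiguity repair), a
multi-task yield model

> f: (21-week × 5-variable sequence, 5 soil properties, region) → yield
> [Mg ha⁻¹]

with a shared encoder — a 3-layer LSTM pooled by a one-layer attention
network, plus a 3-layer soil ANN — and one linear output head per region
(MTL); a single-head ablation (ALSTM); LASSO and random-forest baselines;
leave-one-year-out cross-validation with RMSE / R² / ME; and the
counterfactual attribution

> ΔY(c, i, p) = f(x with factor i at stress-year values through stage p)
> − f(x at historical-average values),

whose whole-season losses, scaled by the trend-based average loss ΔȲ,
become relative contributions R_i (%). The neural network, including
backpropagation through time, is implemented in NumPy and verified against
finite differences.

Because the real data sources (county yield surveys, gridded weather,
satellite NDVI, soil databases) cannot be redistributed, the package ships a
first-class synthetic panel generator: 400 counties on a grid with
latitudinal climate gradients, six true production regions, a
silking-stage-peaked nonlinear stress response with known coefficients, NDVI
as a stress-scaled outcome, and one injectable extreme year (KDD × 2.3,
PRCP × 0.678, VPD × 1.37 over the mid-season stages). Its closed-form truth
is the oracle every estimator is tested against. See `docs/methods.md`.

## Worked example

```python
from maizeyield import SyntheticConfig, generate_panel, cluster_regions, run_cv
from maizeyield.nn import TrainingConfig
from maizeyield.panel import panel_to_arrays

bundle = generate_panel(SyntheticConfig(seed=1))     # 400 counties x 13 years
assignment, _ = cluster_regions(bundle, k=6, seed=1) # contiguous regions
arrays = panel_to_arrays(bundle)
regs = assignment.of(arrays["county_id"])
res = run_cv(arrays, regs, "mtl", assignment.k,
             model_config=TrainingConfig.reduced(), seed=1)
print(res.pooled)
```

The `examples/` directory holds one short script per capability:

* `01_simulate_panel.py` — generate the panel, verify the injected anomaly
  (seasonal KDD ratio ≈ 2.3 in the extreme year, ≈ 1.0 elsewhere).
* `02_cluster_regions.py` — regionalization; prints the adjusted Rand index
  against the generator's true regions and the t-SNE silhouette.
* `03_train_and_evaluate.py` — leave-one-year-out comparison of the
  multi-task model and the LASSO baseline.
* `04_attribute_loss.py` — the counterfactual attribution; prints each
  factor's relative contribution next to the generator's truth and flags the
  most damaging growth stage (stage 4, silking).

Running `python examples/03_train_and_evaluate.py` prints, for seed 1:

```
mtl    pooled RMSE 0.673 Mg/ha  R2 0.846  ME +0.035  annual RMSE 0.654 ± 0.169
lasso  pooled RMSE 0.824 Mg/ha  R2 0.769  ME -0.011  annual RMSE 0.810 ± 0.161
```

i.e. the multi-task model explains ~85 % of held-out county-year yield
variance, with ~18 % lower error than the linear baseline, which can
express neither the precipitation saturation nor the region-specific yield
levels. `python examples/04_attribute_loss.py` then prints the factor
contributions of the model trained without the extreme year, next to the
generator's closed-form truth:

```
trend-based average 2012 loss: -1.92 Mg/ha over 400 counties

factor  model dY  truth dY  model R_i
GDD       +0.000    +0.001      -0.0%
KDD       -1.565    -1.721     +81.5%
PRCP      -0.094    -0.083      +4.9%
VPD       -0.811    -0.188     +42.3%

most severe stage per factor: {'gdd': 4, 'kdd': 4, 'prcp': 4, 'vpd': 4}
```

Heat stress (KDD) is recovered as the dominant driver within ~8 percentage
points of the truth, and the most damaging stage is correctly identified as
stage 4 (silking). The VPD column shows a known limitation: the extreme
year's VPD excursion lies outside the training range, and the network's
extrapolated sensitivity over-attributes it (see `docs/methods.md`,
*Known limitations*).

A thin CLI wraps the same pipeline for shell use:

```bash
maizeyield run-all --seed 1 --out runs/demo     # simulate→cluster→evaluate→attribute
maizeyield report runs/demo                     # text tables
maizeyield default-config > my.yaml             # full config template
```

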