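"""Leave-one-year-out cross-validation and the RMSE / R^2 / ME metric suite.

Interannual generalization is the evaluation target: each calendar year in
turn is held out as the test set while the remaining years train the model,
so a 2006-2018 panel gives 13 folds of 12 training years.  Metrics are
reported per fold, pooled over all held-out predictions, per region, and per
county.  R^2 is the coefficient of determination (1 - SS_res / SS_tot), not
a squared correlation; the mean error ME = mean(estimated - actual) keeps
its sign so systematic under-estimation of losses is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import models as _models
from .nn import TrainingConfig


class MetricError(ValueError):
    """Metrics are undefined for the given vectors (too short, zero variance)."""


def loyo_split(years) -> list[tuple[list[int], int]]:
    """Ordered leave-one-year-out folds: (train years, test year) per year."""
    uniq = sorted(set(int(y) for y in years))
    if len(uniq) < 2:
        raise ValueError("leave-one-year-out needs at least two distinct years")
    return [([y for y in uniq if y != test], test) for test in uniq]


def metrics(actual, estimated) -> tuple[float, float, float]:
    """(rmse, r2, me) between paired yield vectors, in Mg/ha where applicable."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(estimated, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise MetricError("actual and estimated must be 1-d vectors of equal length")
    if len(y) < 2:
        raise MetricError("need at least two paired records")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("R^2 undefined: actual values have zero variance")
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err ** 2)))
    me = float(np.mean(err))
    r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    return rmse, r2, me


@dataclass
class CVResult:
    """All leave-one-year-out outputs for one model kind."""

    kind: str
    per_fold: pd.DataFrame      # year, rmse, r2, me, n
    pooled: dict                # rmse, r2, me, n over all held-out predictions
    per_region: pd.DataFrame    # region, rmse, r2, me, n (pooled across folds)
    per_county: pd.DataFrame    # county_id, rmse, n
    annual_rmse_mean: float = 0.0
    annual_rmse_sd: float = 0.0
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_cv(
    arrays: dict,
    regions: np.ndarray,
    kind: str,
    n_regions: int,
    model_config: TrainingConfig | None = None,
    baseline_config: "_models.BaselineConfig | None" = None,
    seed: int = 0,
    fold_hook: Callable | None = None,
) -> CVResult:
    """Leave-one-year-out evaluation of one model kind.

    ``arrays`` is the dense panel from :func:`maizeyield.panel.panel_to_arrays`;
    ``regions`` are 1-based labels aligned with its rows.  Folds and the
    per-fold seeds depend only on ``seed`` and the panel years, so different
    model kinds evaluated with the same seed see identical scenarios.
    ``fold_hook(fold_index, test_year, model)`` is called after each fit
    (used by tests to inspect leakage and by callers wanting the 2012-fold
    model for attribution).
    """
    Xt, Xs, y = arrays["Xt"], arrays["Xs"], arrays["y"]
    years = arrays["year"]
    counties = arrays["county_id"]
    regions = np.asarray(regions, dtype=int)
    folds = loyo_split(years)

    rows = []
    pred_frames = []
    for k_fold, (train_years, test_year) in enumerate(folds):
        train = np.isin(years, train_years)
        test = years == test_year
        fold_seed = (seed * 1009 + k_fold) % (2 ** 31)
        try:
            model = _models.train_model(
                kind, Xt[train], Xs[train], y[train], regions[train], n_regions,
                model_config=model_config, baseline_config=baseline_config,
                seed=fold_seed,
            )
        except Exception as exc:  # surface the failing fold
            raise RuntimeError(f"model {kind!r} failed in fold {test_year}: {exc}") from exc
        yhat = model.predict(Xt[test], Xs[test], regions[test])
        rmse, r2, me = metrics(y[test], yhat)
        rows.append({"year": test_year, "rmse": rmse, "r2": r2, "me": me, "n": int(test.sum())})
        pred_frames.append(pd.DataFrame({
            "county_id": counties[test], "year": years[test], "region": regions[test],
            "actual": y[test], "estimated": yhat,
        }))
        if fold_hook is not None:
            fold_hook(k_fold, test_year, model)

    per_fold = pd.DataFrame(rows)
    preds = pd.concat(pred_frames, ignore_index=True)
    rmse, r2, me = metrics(preds["actual"], preds["estimated"])
    pooled = {"rmse": rmse, "r2": r2, "me": me, "n": len(preds)}

    reg_rows = []
    for region, grp in preds.groupby("region"):
        r_rmse, r_r2, r_me = metrics(grp["actual"], grp["estimated"])
        reg_rows.append({"region": region, "rmse": r_rmse, "r2": r_r2, "me": r_me, "n": len(grp)})
    cty = (
        preds.assign(sq=(preds["estimated"] - preds["actual"]) ** 2)
        .groupby("county_id")["sq"].agg(["mean", "size"]).reset_index()
    )
    per_county = pd.DataFrame({
        "county_id": cty["county_id"],
        "rmse": np.sqrt(cty["mean"]),
        "n": cty["size"].astype(int),
    })
    return CVResult(
        kind=kind,
        per_fold=per_fold,
        pooled=pooled,
        per_region=pd.DataFrame(reg_rows),
        per_county=per_county,
        annual_rmse_mean=float(per_fold["rmse"].mean()),
        annual_rmse_sd=float(per_fold["rmse"].std(ddof=1)),
        predictions=preds,
    )
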