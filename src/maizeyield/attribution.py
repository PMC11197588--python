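"""Counterfactual attribution of extreme-year yield loss to climate factors.

The procedure asks a trained yield model f two questions per county: what
yield it predicts under the historical-average ("normal") input, and what it
predicts when one climate factor (GDD, KDD, PRCP or VPD) takes its
stress-year values cumulatively from planting up to a three-week growth
stage p (weeks 1..3p), everything else held at normal.  The difference

    dY[c, p, i] = f(x[c, p, i]) - f(x_normal[c])

is the estimated yield loss caused by factor i through stage p; stage 7
covers the whole 21-week season.  Averaged over counties and scaled by the
trend-based average loss (actual stress-year yield minus the county's linear
trend yield), the whole-season losses become relative contributions R_i in
percent.

NDVI is held at its historical-average trajectory in every scenario by
default: it is an outcome of climate stress, and letting the stress year's
NDVI into the counterfactual would double-count the very damage being
attributed (a config flag restores the stress-year NDVI for sensitivity
checks).  R_i uses the county-mean whole-season loss in the numerator so it
is a dimensionless percentage independent of the number of counties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CLIMATE_FACTORS, PanelBundle, SOIL_VARIABLES, panel_to_arrays

N_STAGES = 7
STAGES = tuple(range(1, N_STAGES + 1))


def normal_input(Xt_years: np.ndarray, years: np.ndarray, stress_year: int) -> np.ndarray:
    """Historical-average weekly input for one county, excluding the stress year.

    ``Xt_years`` is (n_years, 21, 5) for a single county.  NDVI is averaged
    along with the climate factors.  Requires at least two non-stress years.
    """
    mask = np.asarray(years) != stress_year
    if mask.sum() < 2:
        raise ValueError(f"need >=2 non-stress years, found {int(mask.sum())}")
    return Xt_years[mask].mean(axis=0)


def counterfactual_input(
    normal: np.ndarray,
    stress: np.ndarray,
    factor: str,
    stage: int,
    use_stress_ndvi: bool = False,
) -> np.ndarray:
    """Normal input with ``factor`` carrying stress values through ``stage``.

    Weeks 1..3*stage of the factor's column are replaced by the stress-year
    values; stage 0 is the identity (a testing anchor).  NDVI stays at the
    normal trajectory unless ``use_stress_ndvi``.
    """
    if factor not in CLIMATE_FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {CLIMATE_FACTORS}")
    if not 0 <= stage <= N_STAGES:
        raise ValueError(f"stage must be in 0..{N_STAGES}, got {stage}")
    out = normal.copy()
    j = CLIMATE_FACTORS.index(factor)
    out[: 3 * stage, j] = stress[: 3 * stage, j]
    if use_stress_ndvi:
        out[:, 4] = stress[:, 4]
    return out


def trend_yield(years, yields, target_year: int) -> float:
    """OLS linear trend of yield on year, fit excluding the target year,
    evaluated at the target year (the expected yield under normal climate)."""
    years = np.asarray(years, dtype=float)
    yields = np.asarray(yields, dtype=float)
    mask = years != target_year
    if mask.sum() < 3:
        raise ValueError(f"need >=3 records excluding {target_year}, found {int(mask.sum())}")
    slope, intercept = np.polyfit(years[mask], yields[mask], 1)
    return float(slope * target_year + intercept)


def average_yield_loss(actual: dict, trend: dict) -> tuple[float, int]:
    """Mean over counties of (actual stress-year yield - trend yield).

    Counties missing either quantity are excluded; returns (loss, n used).
    Negative when the stress year fell below trend.
    """
    common = sorted(set(actual) & set(trend))
    if not common:
        raise ValueError("no county has both an actual and a trend yield")
    diffs = [actual[c] - trend[c] for c in common]
    return float(np.mean(diffs)), len(common)


@dataclass
class ContributionSummary:
    """Eq.-style attribution summary for one stress year."""

    stress_year: int
    average_loss: float            # trend-based mean loss, Mg/ha (negative = loss)
    n_counties: int
    mean_factor_loss: dict         # factor -> county-mean whole-season dY, Mg/ha
    relative_contribution: dict    # factor -> percent of the average loss

    def ranked_factors(self) -> list:
        return sorted(self.relative_contribution, key=self.relative_contribution.get, reverse=True)


def relative_contribution(mean_factor_loss: dict, average_loss: float) -> dict:
    """R_i = county-mean whole-season loss of factor i / average loss, in %.

    Both quantities are negative for damaging factors, so damaging factors
    get positive percentages; a beneficial factor (positive mean dY against a
    negative average loss) gets a negative percentage.
    """
    if average_loss == 0.0:
        raise ValueError("average loss is zero; relative contributions undefined")
    return {f: 100.0 * loss / average_loss for f, loss in mean_factor_loss.items()}


@dataclass
class AttributionResult:
    table: pd.DataFrame             # county_id, factor, stage, y_normal, y_cf, delta
    summary: ContributionSummary
    stage_curves: pd.DataFrame      # factor, stage, mean_delta, incremental
    severe_stage: dict              # factor -> stage with worst incremental loss
    severe_county_fraction: dict    # factor -> fraction of counties losing > threshold


def attribution_report(
    model,
    bundle: PanelBundle,
    region_of,
    stress_year: int = 2012,
    use_stress_ndvi: bool = False,
    loss_fraction_threshold: float = 0.2,
) -> AttributionResult:
    """Run the full counterfactual grid and summarize contributions.

    ``model`` is anything with the uniform ``predict(Xt, Xs, regions)``
    contract — typically the multi-task model trained with the stress year
    held out, or the synthetic truth oracle in tests.  ``region_of`` maps
    county id -> region label.  The grid covers every county, the four
    climate factors and stages 1..7; predictions for all scenarios are made
    in one batched call.
    """
    arrays = panel_to_arrays(bundle)
    counties = sorted(set(arrays["county_id"].tolist()))
    soil = bundle.soil.set_index("county_id")[list(SOIL_VARIABLES)]

    normals, stresses, keep = {}, {}, []
    for county in counties:
        m = arrays["county_id"] == county
        yrs = arrays["year"][m]
        if stress_year not in yrs or (yrs != stress_year).sum() < 2:
            continue
        Xc = arrays["Xt"][m]
        normals[county] = normal_input(Xc, yrs, stress_year)
        stresses[county] = Xc[yrs == stress_year][0]
        keep.append(county)
    if not keep:
        raise ValueError(f"no county has the stress year {stress_year} plus history")

    # assemble the full scenario batch: per county, 1 normal + 4*7 counterfactuals
    scen_inputs, scen_meta = [], []
    for county in keep:
        scen_inputs.append(normals[county])
        scen_meta.append((county, "normal", 0))
        for factor in CLIMATE_FACTORS:
            for stage in STAGES:
                scen_inputs.append(
                    counterfactual_input(normals[county], stresses[county], factor, stage,
                                         use_stress_ndvi=use_stress_ndvi)
                )
                scen_meta.append((county, factor, stage))
    Xt_all = np.stack(scen_inputs)
    county_seq = [m[0] for m in scen_meta]
    Xs_all = soil.loc[county_seq].to_numpy(dtype=float)
    regions_all = np.array([region_of[c] for c in county_seq], dtype=int)
    preds = model.predict(Xt_all, Xs_all, regions_all)

    y_normal = {m[0]: p for m, p in zip(scen_meta, preds) if m[1] == "normal"}
    rows = [
        {"county_id": c, "factor": f, "stage": s, "y_normal": y_normal[c],
         "y_cf": p, "delta": p - y_normal[c]}
        for (c, f, s), p in zip(scen_meta, preds) if f != "normal"
    ]
    table = pd.DataFrame(rows)

    # trend-based average loss over the same counties
    actual, trend = {}, {}
    ydf = bundle.yields.set_index(["county_id", "year"])["yield_mg_ha"]
    for county in keep:
        hist = bundle.yields[bundle.yields["county_id"] == county]
        try:
            trend[county] = trend_yield(hist["year"], hist["yield_mg_ha"], stress_year)
        except ValueError:
            continue
        actual[county] = float(ydf.loc[(county, stress_year)])
    avg_loss, n_used = average_yield_loss(actual, trend)

    final = table[table["stage"] == N_STAGES]
    mean_loss = final.groupby("factor")["delta"].mean().to_dict()
    summary = ContributionSummary(
        stress_year=stress_year,
        average_loss=avg_loss,
        n_counties=n_used,
        mean_factor_loss={f: float(mean_loss[f]) for f in CLIMATE_FACTORS},
        relative_contribution=relative_contribution(
            {f: float(mean_loss[f]) for f in CLIMATE_FACTORS}, avg_loss
        ),
    )

    curves = (
        table.groupby(["factor", "stage"])["delta"].mean().rename("mean_delta").reset_index()
    )
    curves["incremental"] = curves.groupby("factor")["mean_delta"].diff()
    first = curves["stage"] == 1
    curves.loc[first, "incremental"] = curves.loc[first, "mean_delta"]
    severe = {
        f: int(grp.loc[grp["incremental"].idxmin(), "stage"])
        for f, grp in curves.groupby("factor")
    }
    severe_frac = {}
    for factor in CLIMATE_FACTORS:
        sub = final[final["factor"] == factor]
        rel = -sub["delta"].to_numpy() / np.array([max(y_normal[c], 1e-9) for c in sub["county_id"]])
        severe_frac[factor] = float(np.mean(rel > loss_fraction_threshold))

    return AttributionResult(
        table=table, summary=summary, stage_curves=curves,
        severe_stage=severe, severe_county_fraction=severe_frac,
    )
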