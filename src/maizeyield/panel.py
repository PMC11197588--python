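"""County-year panel data model and climatic-factor derivation.

The panel is the unit of analysis throughout the package: one county observed in
one year, carrying a 21-week temporal block of five variables (GDD, KDD, PRCP,
VPD, NDVI), a static five-component soil vector, and an annual maize yield in
Mg ha^-1.  This module derives the weekly climatic factors from daily weather,
aggregates satellite greenness (NDVI) to weekly medians, computes the length of
the potential growth period (LPGP), and reads/writes every tabular artifact the
pipeline exchanges.

Conventions
-----------
* Growing degree days (GDD) accumulate heat between a base and a cap
  temperature; killing degree days (KDD) accumulate excess above a damaging
  threshold.  Defaults follow the maize literature: base 10 degC, cap 30 degC,
  KDD threshold 29 degC.
* The season window spans calendar weeks 18-38 (21 weekly timesteps), with week
  ``w`` covering days-of-year ``7*(w-1)+1 .. 7*w``.
* Weekly GDD/KDD/PRCP/VPD are sums of daily values (so VPD carries hPa-day
  units); NDVI is a weekly median in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Order of the five temporal variables everywhere in the package.
TEMPORAL_VARIABLES = ("gdd", "kdd", "prcp", "vpd", "ndvi")
#: The four climatic factors (NDVI excluded) used in attribution and LASSO.
CLIMATE_FACTORS = ("gdd", "kdd", "prcp", "vpd")
#: Static soil properties: available water capacity, organic matter, texture.
SOIL_VARIABLES = ("awc", "om", "sand", "clay", "silt")

GDD_BASE_C = 10.0
GDD_CAP_C = 30.0
KDD_THRESHOLD_C = 29.0


class PanelSchemaError(ValueError):
    """A tabular artifact violates the panel schema or its invariants."""


class MissingDataError(ValueError):
    """Required observations are absent and cannot be silently filled."""


@dataclass(frozen=True)
class SeasonWindow:
    """The growing-season block of calendar weeks used as the model sequence.

    Week ``w`` of the year covers days-of-year ``7*(w-1)+1 .. 7*w``; the
    default window (weeks 18-38) yields 21 timesteps, the average maize season
    length in the US Corn Belt crop progress reports.
    """

    start_week_of_year: int = 18
    end_week_of_year: int = 38

    def __post_init__(self) -> None:
        if not 1 <= self.start_week_of_year <= self.end_week_of_year <= 52:
            raise ValueError("season window must satisfy 1 <= start <= end <= 52")

    @property
    def n_steps(self) -> int:
        return self.end_week_of_year - self.start_week_of_year + 1

    @property
    def weeks(self) -> np.ndarray:
        return np.arange(self.start_week_of_year, self.end_week_of_year + 1)


def week_of_year(day_of_year: np.ndarray | int) -> np.ndarray | int:
    """Fixed 7-day block index: day-of-year 1-7 -> week 1, 8-14 -> week 2, ..."""
    return (np.asarray(day_of_year) - 1) // 7 + 1


def compute_daily_factors(
    tmin,
    tmax,
    vpdmin,
    vpdmax,
    gdd_base: float = GDD_BASE_C,
    gdd_cap: float = GDD_CAP_C,
    kdd_threshold: float = KDD_THRESHOLD_C,
):
    """Derive daily GDD, KDD and VPD from daily weather.

    GDD uses the capped-average convention
    ``max(0, (min(tmax, cap) + max(tmin, base)) / 2 - base)``; KDD is the
    exceedance ``max(0, tmax - threshold)``; daily VPD is the mean of the
    daily minimum and maximum vapor pressure deficit.

    Parameters accept scalars or arrays.  Raises :class:`MissingDataError` if
    any input is NaN — missing weather must never become a silent zero.
    """
    if gdd_base >= gdd_cap:
        raise ValueError(f"gdd_base ({gdd_base}) must be below gdd_cap ({gdd_cap})")
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    vpdmin = np.asarray(vpdmin, dtype=float)
    vpdmax = np.asarray(vpdmax, dtype=float)
    for name, arr in (("tmin", tmin), ("tmax", tmax), ("vpdmin", vpdmin), ("vpdmax", vpdmax)):
        if np.any(np.isnan(arr)):
            raise MissingDataError(f"{name} contains missing values")
    gdd = np.maximum(0.0, (np.minimum(tmax, gdd_cap) + np.maximum(tmin, gdd_base)) / 2.0 - gdd_base)
    kdd = np.maximum(0.0, tmax - kdd_threshold)
    vpd = (vpdmin + vpdmax) / 2.0
    return gdd, kdd, vpd


def aggregate_weekly(
    daily: pd.DataFrame,
    window: SeasonWindow = SeasonWindow(),
    max_missing_days: int = 2,
) -> pd.DataFrame:
    """Sum daily factors into the weekly season window for one county-year.

    ``daily`` needs columns ``day_of_year, gdd, kdd, prcp, vpd``.  Weeks with
    at most ``max_missing_days`` absent days have their sums rescaled by
    ``7 / days_present`` (with a warning); weeks missing more days are
    rejected.  Returns one row per window week with columns
    ``week, gdd, kdd, prcp, vpd`` (``week`` indexed 1..n_steps).
    """
    required = {"day_of_year", "gdd", "kdd", "prcp", "vpd"}
    if not required.issubset(daily.columns):
        raise PanelSchemaError(f"daily frame needs columns {sorted(required)}")
    doy = daily["day_of_year"].to_numpy()
    if len(np.unique(doy)) != len(doy):
        raise PanelSchemaError("duplicate day_of_year rows in daily series")
    weeks = week_of_year(doy)
    rows = []
    for step, woy in enumerate(window.weeks, start=1):
        mask = weeks == woy
        present = int(mask.sum())
        if present < 7 - max_missing_days:
            raise MissingDataError(
                f"week {woy}: only {present} of 7 days present (> {max_missing_days} missing)"
            )
        scale = 7.0 / present
        if present < 7:
            logger.warning("week %d: %d missing days, rescaling sums by 7/%d", woy, 7 - present, present)
        sub = daily.loc[mask, ["gdd", "kdd", "prcp", "vpd"]]
        if sub.isna().any().any():
            raise MissingDataError(f"week {woy}: NaN factor values")
        sums = sub.sum() * scale
        rows.append({"week": step, **sums.to_dict()})
    return pd.DataFrame(rows)


def aggregate_ndvi_weekly(
    observations: pd.DataFrame,
    window: SeasonWindow = SeasonWindow(),
) -> np.ndarray:
    """Weekly-median NDVI over the season window, gap-filled by interpolation.

    ``observations`` needs columns ``day_of_year, ndvi``.  Each observation is
    assigned to its fixed 7-day week; the weekly value is the median of that
    week's observations (robust to cloud/extreme artifacts).  Weeks with no
    observation are filled by linear interpolation between the nearest
    observed weeks (constant extension at the edges).  Output is clipped to
    [-1, 1].  Raises :class:`MissingDataError` with fewer than two observed
    weeks in the window.
    """
    if not {"day_of_year", "ndvi"}.issubset(observations.columns):
        raise PanelSchemaError("NDVI observations need columns day_of_year, ndvi")
    obs = observations.dropna(subset=["ndvi"])
    weeks = week_of_year(obs["day_of_year"].to_numpy())
    values = np.full(window.n_steps, np.nan)
    for step, woy in enumerate(window.weeks):
        mask = weeks == woy
        if mask.any():
            values[step] = float(np.median(obs["ndvi"].to_numpy()[mask]))
    observed = np.flatnonzero(~np.isnan(values))
    if observed.size < 2:
        raise MissingDataError(
            f"only {observed.size} week(s) with NDVI observations in window; need >= 2"
        )
    filled = np.interp(np.arange(window.n_steps), observed, values[observed])
    return np.clip(filled, -1.0, 1.0)


def compute_lpgp(
    daily: pd.DataFrame,
    planting_threshold_c: float = 13.0,
    frost_threshold_c: float = 0.0,
    earliest_planting_doy: int = 60,
    earliest_frost_doy: int = 213,
) -> int:
    """Length of the potential growth period (days) for one county-year.

    The planting date is the first day-of-year >= ``earliest_planting_doy``
    whose 7-day trailing mean of ``tmean`` exceeds the planting threshold
    (smoothing guards against isolated winter warm spells); the frost date is
    the first day-of-year >= ``earliest_frost_doy`` with ``tmin`` below the
    frost threshold, defaulting to day 365 if no frost occurs.  Requires a
    full calendar year of daily temperatures sorted by day-of-year.
    """
    if not {"day_of_year", "tmean", "tmin"}.issubset(daily.columns):
        raise PanelSchemaError("daily frame needs columns day_of_year, tmean, tmin")
    d = daily.sort_values("day_of_year")
    doy = d["day_of_year"].to_numpy()
    tmean = d["tmean"].to_numpy(dtype=float)
    tmin = d["tmin"].to_numpy(dtype=float)
    trailing = pd.Series(tmean).rolling(7, min_periods=7).mean().to_numpy()
    warm = (doy >= earliest_planting_doy) & (trailing > planting_threshold_c)
    if not warm.any():
        raise MissingDataError("no planting date: trailing-mean temperature never exceeds threshold")
    planting_day = int(doy[np.argmax(warm)])
    frost = (doy >= earliest_frost_doy) & (tmin < frost_threshold_c)
    frost_day = int(doy[np.argmax(frost)]) if frost.any() else 365
    return frost_day - planting_day


# ---------------------------------------------------------------------------
# Panel container helpers and tabular I/O
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["county_id", "year", "week"] + list(TEMPORAL_VARIABLES)
SOIL_COLUMNS = ["county_id"] + list(SOIL_VARIABLES)
YIELD_COLUMNS = ["county_id", "year", "yield_mg_ha"]
ADJACENCY_COLUMNS = ["county_id_a", "county_id_b"]


def validate_panel(panel: pd.DataFrame, n_steps: int = 21) -> None:
    """Check the long-format weekly panel invariants, raising on violation."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelSchemaError(f"weekly panel missing columns {missing}")
    if panel.duplicated(["county_id", "year", "week"]).any():
        raise PanelSchemaError("duplicate (county, year, week) rows in weekly panel")
    counts = panel.groupby(["county_id", "year"], sort=False).size()
    bad = counts[counts != n_steps]
    if len(bad):
        key = bad.index[0]
        raise PanelSchemaError(
            f"county-year {key} has {bad.iloc[0]} week rows, expected {n_steps}"
        )
    for var in ("gdd", "kdd", "prcp", "vpd"):
        if (panel[var] < 0).any():
            raise PanelSchemaError(f"negative {var} values in weekly panel")
    if ((panel["ndvi"] < -1) | (panel["ndvi"] > 1)).any():
        raise PanelSchemaError("NDVI outside [-1, 1]")


def validate_soil(soil: pd.DataFrame, texture_tolerance: float = 1.0) -> None:
    missing = [c for c in SOIL_COLUMNS if c not in soil.columns]
    if missing:
        raise PanelSchemaError(f"soil table missing columns {missing}")
    if soil.duplicated("county_id").any():
        raise PanelSchemaError("duplicate county rows in soil table")
    if (soil[list(SOIL_VARIABLES)] < 0).any().any():
        raise PanelSchemaError("negative soil property values")
    texture = soil[["sand", "clay", "silt"]].sum(axis=1)
    off = (texture - 100.0).abs() > texture_tolerance
    if off.any():
        raise PanelSchemaError(
            f"soil texture fractions do not sum to 100 +- {texture_tolerance} "
            f"for counties {soil.loc[off, 'county_id'].tolist()[:5]}"
        )


def validate_yields(yields: pd.DataFrame) -> None:
    missing = [c for c in YIELD_COLUMNS if c not in yields.columns]
    if missing:
        raise PanelSchemaError(f"yield table missing columns {missing}")
    if yields.duplicated(["county_id", "year"]).any():
        raise PanelSchemaError("duplicate (county, year) rows in yield table")
    if (yields["yield_mg_ha"] < 0).any():
        raise PanelSchemaError("negative yields")


@dataclass
class PanelBundle:
    """All tabular artifacts of one study panel.

    ``lpgp`` (county_id, lpgp_days) is optional: it is a clustering feature
    only and real pipelines may not have daily temperatures for every county.
    """

    panel: pd.DataFrame
    soil: pd.DataFrame
    yields: pd.DataFrame
    adjacency: pd.DataFrame
    lpgp: pd.DataFrame | None = None

    @property
    def counties(self) -> list[str]:
        return sorted(self.soil["county_id"].astype(str))

    @property
    def years(self) -> list[int]:
        return sorted(self.panel["year"].unique().tolist())

    def validate(self, n_steps: int = 21) -> None:
        validate_panel(self.panel, n_steps=n_steps)
        validate_soil(self.soil)
        validate_yields(self.yields)
        if not {"county_id_a", "county_id_b"}.issubset(self.adjacency.columns):
            raise PanelSchemaError("adjacency needs columns county_id_a, county_id_b")


def write_panel(bundle: PanelBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact as a headered CSV under ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    paths = {
        "panel": out / "weekly_panel.csv",
        "soil": out / "soil.csv",
        "yields": out / "yields.csv",
        "adjacency": out / "adjacency.csv",
    }
    bundle.panel.to_csv(paths["panel"], index=False, float_format="%.10g")
    bundle.soil.to_csv(paths["soil"], index=False, float_format="%.10g")
    bundle.yields.to_csv(paths["yields"], index=False, float_format="%.10g")
    bundle.adjacency.to_csv(paths["adjacency"], index=False)
    if bundle.lpgp is not None:
        paths["lpgp"] = out / "lpgp.csv"
        bundle.lpgp.to_csv(paths["lpgp"], index=False, float_format="%.10g")
    return paths


def read_panel(in_dir: str | Path, n_steps: int = 21) -> PanelBundle:
    """Read and validate a panel directory written by :func:`write_panel`."""
    p = Path(in_dir)
    panel = pd.read_csv(p / "weekly_panel.csv", dtype={"county_id": str})
    soil = pd.read_csv(p / "soil.csv", dtype={"county_id": str})
    yields = pd.read_csv(p / "yields.csv", dtype={"county_id": str})
    adjacency = pd.read_csv(p / "adjacency.csv", dtype=str)
    lpgp_path = p / "lpgp.csv"
    lpgp = pd.read_csv(lpgp_path, dtype={"county_id": str}) if lpgp_path.exists() else None
    bundle = PanelBundle(panel=panel, soil=soil, yields=yields, adjacency=adjacency, lpgp=lpgp)
    bundle.validate(n_steps=n_steps)
    return bundle


def panel_to_arrays(bundle: PanelBundle, n_steps: int = 21):
    """Align the tabular panel into dense model inputs.

    Returns a dict with ``Xt`` (n, n_steps, 5 temporal variables), ``Xs``
    (n, 5 soil properties), ``y`` (n yields), and parallel ``county_id`` /
    ``year`` arrays, restricted to county-years that have both a complete
    weekly block and a yield record.
    """
    panel = bundle.panel.sort_values(["county_id", "year", "week"])
    yields = bundle.yields.set_index(["county_id", "year"])["yield_mg_ha"]
    soil = bundle.soil.set_index("county_id")[list(SOIL_VARIABLES)]
    keys = panel[["county_id", "year"]].drop_duplicates()
    keep = [
        (c, y)
        for c, y in keys.itertuples(index=False)
        if (c, y) in yields.index and c in soil.index
    ]
    if not keep:
        raise PanelSchemaError("no county-years with both weekly block and yield record")
    index = pd.MultiIndex.from_tuples(keep, names=["county_id", "year"])
    wide = panel.set_index(["county_id", "year", "week"])[list(TEMPORAL_VARIABLES)]
    n = len(keep)
    Xt = np.empty((n, n_steps, len(TEMPORAL_VARIABLES)))
    for i, (c, y) in enumerate(keep):
        block = wide.loc[(c, y)]
        if len(block) != n_steps:
            raise PanelSchemaError(f"county-year ({c}, {y}) has {len(block)} weeks")
        Xt[i] = block.to_numpy()
    counties = index.get_level_values("county_id").to_numpy()
    return {
        "Xt": Xt,
        "Xs": soil.loc[counties].to_numpy(dtype=float),
        "y": yields.loc[index].to_numpy(dtype=float),
        "county_id": counties,
        "year": index.get_level_values("year").to_numpy(),
    }
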