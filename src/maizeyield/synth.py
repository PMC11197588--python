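"""Synthetic Corn-Belt-like county-year panels with known ground truth.

The generator emulates the joint structure the yield model and the
counterfactual attribution analysis assume: counties on a grid with rook
adjacency, latitudinal climate gradients, regionally heterogeneous soil and
yield response, a stage-weighted nonlinear climate response concentrated at
silking (weeks 10-12 of the 21-week season), NDVI generated as a stress-scaled
green-up outcome, and one injectable extreme year whose heat/drought anomaly
is fully specified by three stress multipliers.

The true yield function is additive across weeks and factors,

    y = a_r + b (year - year0)
        + sum_w s_w [ bG GDD_w - bK_r KDD_w + bP min(PRCP_w, sat)
                      - bV max(0, VPD_w - thr) ]
        + gamma (AWC - awc_ref) + eps,

so every counterfactual of the attribution procedure has a closed-form truth
(:class:`TruthBundle`), which the analysis modules are tested against.
Nonlinearity enters through the per-week precipitation saturation and the VPD
exceedance threshold, mirroring the empirically observed ~300 mm seasonal
precipitation and ~2300 hPa seasonal VPD stress thresholds (here expressed per
week as seasonal / 21).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CLIMATE_FACTORS, PanelBundle

N_WEEKS = 21
#: stage p (1..7) covers weeks 3p-2 .. 3p (1-based)
N_STAGES = 7


def stage_weeks(p: int) -> np.ndarray:
    """1-based season weeks belonging to three-week stage ``p`` (1..7)."""
    if not 1 <= p <= N_STAGES:
        raise ValueError(f"stage must be in 1..{N_STAGES}, got {p}")
    return np.arange(3 * p - 2, 3 * p + 1)


def default_stage_sensitivity(peak_week: int = 11, width: float = 2.5, floor: float = 0.25) -> np.ndarray:
    """Stage-sensitivity profile s_w: uniform floor plus a silking-stage peak.

    Normalized to sum to one; the maximum falls at ``peak_week`` (default 11,
    the middle of stage 4, the silking phase).
    """
    w = np.arange(1, N_WEEKS + 1)
    bump = np.exp(-0.5 * ((w - peak_week) / width) ** 2)
    s = floor / N_WEEKS + (1 - floor) * bump / bump.sum()
    return s / s.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic panel.

    Stress multipliers default to the anomaly magnitudes observed in the 2012
    US Corn Belt extreme: seasonal KDD 2.3x the historical average, seasonal
    precipitation reduced by 32.2% and VPD increased by 37.0%.  The extreme
    anomaly is applied over stages 3-5 (weeks 7-15), bracketing silking, so
    the stage-recovery analysis has a known sensitivity peak.
    """

    n_cols: int = 20
    n_rows: int = 20
    years: tuple[int, ...] = tuple(range(2006, 2019))
    n_true_regions: int = 6
    extreme_year: int | None = 2012
    kdd_mult: float = 2.3
    prcp_mult: float = 0.678
    vpd_mult: float = 1.370
    stress_weeks: tuple[int, ...] = tuple(range(7, 16))  # stages 3-5
    # response coefficients, Mg/ha per stage-weighted factor unit
    beta_gdd: float = 0.02
    beta_kdd: float = 0.30
    beta_prcp: float = 0.06
    beta_vpd: float = 0.012
    region_kdd_spread: float = 0.2  # +-20% regional variation in heat sensitivity
    gamma_awc: float = 8.0  # Mg/ha per unit AWC above reference
    awc_ref: float = 0.15
    prcp_sat_week: float = 300.0 / 21.0  # mm/week, seasonal 300 mm scaled
    vpd_threshold_week: float = 2300.0 / 21.0  # hPa-day/week, seasonal 2300 scaled
    trend: float = 0.1  # Mg/ha per year technology trend
    intercept: float = 8.0
    intercept_spread: float = 1.2
    noise_sd: float = 0.4  # Mg/ha county-year residual
    ndvi_stress_coupling: float = 0.08
    ndvi_noise_sd: float = 0.04
    stage_sensitivity: tuple[float, ...] = tuple(float(x) for x in default_stage_sensitivity())
    seed: int = 0

    def __post_init__(self):
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be positive")
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        if min(self.kdd_mult, self.prcp_mult, self.vpd_mult) <= 0:
            raise ValueError("stress multipliers must be positive")
        s = np.asarray(self.stage_sensitivity)
        if len(s) != N_WEEKS or (s < 0).any():
            raise ValueError("stage_sensitivity must be 21 non-negative weights")
        peak = int(np.argmax(s)) + 1
        if not 10 <= peak <= 12:
            raise ValueError("stage sensitivity must peak in weeks 10-12 (silking)")

    @property
    def n_counties(self) -> int:
        return self.n_cols * self.n_rows


@dataclass
class TruthBundle:
    """Everything needed to evaluate the true response on any input.

    Stores the generator parameters, each county's true region, the stored
    noise draws (so yields and NDVI can be regenerated deterministically from
    any modified climate), and — once a panel exists — the per-county
    empirical normal (historical-average) and stress-year input matrices used
    by the closed-form attribution oracle.
    """

    config: SyntheticConfig
    county_ids: np.ndarray  # (C,) str
    region_of: dict[str, int]  # county -> 1..K
    region_intercepts: np.ndarray  # (K,)
    region_kdd_beta: np.ndarray  # (K,) region-specific KDD sensitivity
    soil_awc: dict[str, float]
    yield_eps: np.ndarray  # (C, Y)
    ndvi_eps: np.ndarray  # (C, Y, W)
    normal_inputs: dict[str, np.ndarray] = field(default_factory=dict)  # 21x5
    stress_inputs: dict[str, np.ndarray] = field(default_factory=dict)  # 21x5

    # -- true response -----------------------------------------------------
    def climate_contribution(self, climate: np.ndarray, region: int) -> np.ndarray:
        """Stage-weighted climate term for inputs ``climate`` (..., 21, >=4).

        Columns follow the panel variable order (GDD, KDD, PRCP, VPD, ...);
        an NDVI column, if present, is ignored: NDVI is an outcome, not a
        driver, in the true response.
        """
        cfg = self.config
        s = np.asarray(cfg.stage_sensitivity)
        g, k, p, v = (climate[..., i] for i in range(4))
        bk = self.region_kdd_beta[region - 1]
        term = (
            cfg.beta_gdd * g
            - bk * k
            + cfg.beta_prcp * np.minimum(p, cfg.prcp_sat_week)
            - cfg.beta_vpd * np.maximum(0.0, v - cfg.vpd_threshold_week)
        )
        return (term * s).sum(axis=-1)

    def predict(self, Xt: np.ndarray, Xs: np.ndarray | None, regions: np.ndarray, year: int | None = None) -> np.ndarray:
        """Noise-free true yield for batched inputs (the attribution oracle's f).

        ``year`` defaults to the extreme year; the trend term is constant
        across counterfactuals of a fixed year, so it cancels in every yield
        difference the attribution computes.
        """
        cfg = self.config
        if year is None:
            year = cfg.extreme_year if cfg.extreme_year is not None else cfg.years[0]
        regions = np.asarray(regions, dtype=int)
        out = np.empty(len(Xt))
        for r in np.unique(regions):
            m = regions == r
            out[m] = self.region_intercepts[r - 1] + self.climate_contribution(Xt[m], int(r))
        out += cfg.trend * (year - cfg.years[0])
        if Xs is not None:
            out += cfg.gamma_awc * (np.asarray(Xs)[:, 0] - cfg.awc_ref)
        return out

    def true_stage_loss(self, county: str, factor: str, p: int) -> float:
        """Closed-form counterfactual stage loss ΔY for one county and factor.

        Equals the true-response yield under the input whose ``factor`` column
        carries stress-year values in weeks 1..3p (historical-average values
        elsewhere) minus the true-response yield under the all-normal input.
        ``p=0`` is the identity counterfactual and returns exactly 0.
        """
        if county not in self.normal_inputs:
            raise KeyError(f"unknown county {county!r}")
        if factor not in CLIMATE_FACTORS:
            raise KeyError(f"unknown factor {factor!r}; expected one of {CLIMATE_FACTORS}")
        if not 0 <= p <= N_STAGES:
            raise ValueError(f"stage must be in 0..{N_STAGES}")
        if p == 0:
            return 0.0
        cfg = self.config
        s = np.asarray(cfg.stage_sensitivity)
        region = self.region_of[county]
        j = CLIMATE_FACTORS.index(factor)
        normal = self.normal_inputs[county][:, j]
        stress = self.stress_inputs[county][:, j]
        weeks = slice(0, 3 * p)
        if factor == "gdd":
            diff = cfg.beta_gdd * (stress - normal)
        elif factor == "kdd":
            diff = -self.region_kdd_beta[region - 1] * (stress - normal)
        elif factor == "prcp":
            diff = cfg.beta_prcp * (
                np.minimum(stress, cfg.prcp_sat_week) - np.minimum(normal, cfg.prcp_sat_week)
            )
        else:
            diff = -cfg.beta_vpd * (
                np.maximum(0.0, stress - cfg.vpd_threshold_week)
                - np.maximum(0.0, normal - cfg.vpd_threshold_week)
            )
        return float((s[weeks] * diff[weeks]).sum())


def true_attribution(truth: TruthBundle, county: str, factor: str, p: int) -> float:
    """Module-level alias for :meth:`TruthBundle.true_stage_loss`."""
    return truth.true_stage_loss(county, factor, p)


@dataclass
class SyntheticPanel(PanelBundle):
    """A generated panel plus its ground truth."""

    truth: TruthBundle | None = None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _block_regions(n_rows: int, n_cols: int, k: int) -> np.ndarray:
    """Partition the grid into k contiguous rectangular blocks, labels 1..k."""
    br = max(d for d in range(1, int(np.sqrt(k)) + 1) if k % d == 0)
    bc = k // br
    row_edges = np.linspace(0, n_rows, br + 1).astype(int)
    col_edges = np.linspace(0, n_cols, bc + 1).astype(int)
    labels = np.empty((n_rows, n_cols), dtype=int)
    for i in range(br):
        for j in range(bc):
            labels[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = i * bc + j + 1
    return labels


def _smooth_grid(noise: np.ndarray) -> np.ndarray:
    """3x3 neighborhood mean on the county grid (edge-aware)."""
    padded = np.pad(noise, 1, mode="edge")
    out = np.zeros_like(noise)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            out += padded[1 + di:1 + di + noise.shape[0], 1 + dj:1 + dj + noise.shape[1]]
    return out / 9.0


def _lognormal_meanone(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1."""
    return rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=size)


def _ndvi_base_curve() -> np.ndarray:
    w = np.arange(1, N_WEEKS + 1)
    rise = 1.0 / (1.0 + np.exp(-(w - 6.0) / 1.6))
    fall = 1.0 / (1.0 + np.exp((w - 19.0) / 1.8))
    return 0.18 + 0.62 * rise * fall


def generate_panel(config: SyntheticConfig = SyntheticConfig()) -> SyntheticPanel:
    """Generate a full synthetic study panel, deterministic given the seed.

    Returns a :class:`SyntheticPanel` whose ``truth`` attribute evaluates the
    exact response on arbitrary counterfactual inputs.  With all stress
    multipliers at 1 (or ``extreme_year=None``) the panel has no injected
    anomaly; otherwise the designated year's KDD, PRCP and VPD are rescaled
    over the configured stress weeks and NDVI and yields are regenerated
    through the truth function.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    C, Y = cfg.n_counties, len(cfg.years)
    rows, cols = np.divmod(np.arange(C), cfg.n_cols)
    county_ids = np.array([f"C{i:04d}" for i in range(C)])
    phi = rows / max(cfg.n_rows - 1, 1)  # 0 = south (hot), 1 = north
    wet = 0.85 + 0.30 * cols / max(cfg.n_cols - 1, 1)

    # adjacency: rook neighbors on the grid
    edges = []
    for i in range(C):
        r, c = divmod(i, cfg.n_cols)
        if c + 1 < cfg.n_cols:
            edges.append((county_ids[i], county_ids[i + 1]))
        if r + 1 < cfg.n_rows:
            edges.append((county_ids[i], county_ids[i + cfg.n_cols]))
    adjacency = pd.DataFrame(edges, columns=["county_id_a", "county_id_b"])

    region_grid = _block_regions(cfg.n_rows, cfg.n_cols, cfg.n_true_regions)
    regions = region_grid[rows, cols]
    K = cfg.n_true_regions
    offsets = np.linspace(-1.0, 1.0, K) if K > 1 else np.zeros(1)
    region_intercepts = cfg.intercept + cfg.intercept_spread * offsets
    region_kdd_beta = cfg.beta_kdd * (1.0 + cfg.region_kdd_spread * offsets)

    # --- soil: region means plus spatially smoothed noise -----------------
    soil_means = {
        "awc": 0.12 + 0.016 * np.arange(K) % 0.10,
        "om": 1.5 + 0.5 * np.arange(K),
        "sand": 45.0 - 3.0 * np.arange(K),
        "clay": 20.0 + 2.0 * np.arange(K),
    }
    soil = pd.DataFrame({"county_id": county_ids})
    for var, means in soil_means.items():
        sd = {"awc": 0.015, "om": 0.3, "sand": 3.0, "clay": 1.5}[var]
        noise = _smooth_grid(rng.normal(0.0, sd * 1.8, size=(cfg.n_rows, cfg.n_cols)))
        soil[var] = np.maximum(means[regions - 1] + noise[rows, cols], 0.01)
    soil["sand"] = soil["sand"].clip(5, 80)
    soil["clay"] = soil["clay"].clip(5, 60)
    soil["silt"] = 100.0 - soil["sand"] - soil["clay"]
    soil["awc"] = soil["awc"].clip(0.03, 0.30)

    # --- weekly climate: climatology x year effect x local noise ----------
    w = np.arange(1, N_WEEKS + 1)
    # strong south-north KDD gradient: southern counties routinely experience
    # high heat loads, which is what lets a data-driven model learn the heat
    # response it must extrapolate in the extreme year
    gdd_clim = (45.0 + 30.0 * np.sin(np.pi * w / 22.0))[None, :] * (1.15 - 0.30 * phi)[:, None]
    kdd_clim = (8.0 * np.exp(-0.5 * ((w - 11.0) / 1.8) ** 2))[None, :] * (2.20 - 2.00 * phi)[:, None]
    prcp_clim = (21.0 + 3.0 * np.sin(np.pi * w / 21.0))[None, :] * wet[:, None]
    vpd_clim = (60.0 + 45.0 * np.exp(-0.5 * ((w - 11.0) / 3.0) ** 2))[None, :] * (1.10 - 0.25 * phi)[:, None]
    clim = np.stack([gdd_clim, kdd_clim, prcp_clim, vpd_clim], axis=-1)  # (C, W, 4)

    # interannual effects are stratified (shuffled normal quantiles) rather
    # than iid draws: every realized panel then carries the designed
    # interannual spread — as the real multi-year record does, with its mix
    # of hot, wet and dry seasons — instead of occasionally collapsing to a
    # near-constant dozen years that cannot identify the response
    from statistics import NormalDist
    year_sd = np.array([0.03, 0.35, 0.15, 0.08])
    quantiles = np.array([NormalDist().inv_cdf((i + 0.5) / Y) for i in range(Y)])
    z = np.stack([rng.permutation(quantiles) for _ in range(4)], axis=1)
    year_eff = np.exp(z * year_sd)
    normal_mask = np.ones(Y, dtype=bool)
    if cfg.extreme_year in cfg.years:
        normal_mask[cfg.years.index(cfg.extreme_year)] = False
    # center so the normal-year mean effect is exactly 1: the climatology then
    # IS the historical average, and the extreme anomaly is purely the
    # configured multipliers
    year_eff /= year_eff[normal_mask].mean(axis=0)
    if cfg.extreme_year in cfg.years:
        year_eff[cfg.years.index(cfg.extreme_year)] = 1.0  # anomaly comes from injection only
    local_sd = np.array([0.05, 0.45, 0.40, 0.08])
    local = _lognormal_meanone(rng, local_sd, size=(C, Y, N_WEEKS, 4))
    climate = clim[:, None, :, :] * year_eff[None, :, None, :] * local
    climate = np.maximum(climate, 0.0)

    truth = TruthBundle(
        config=cfg,
        county_ids=county_ids,
        region_of={cid: int(r) for cid, r in zip(county_ids, regions)},
        region_intercepts=region_intercepts,
        region_kdd_beta=region_kdd_beta,
        soil_awc={cid: float(a) for cid, a in zip(county_ids, soil["awc"])},
        yield_eps=rng.normal(0.0, 1.0, size=(C, Y)),
        ndvi_eps=rng.normal(0.0, 1.0, size=(C, Y, N_WEEKS)),
    )

    natural = _assemble(climate, soil, adjacency, truth)
    return inject_extreme_year(natural, cfg)


def _climate_array(panel: pd.DataFrame, county_ids: np.ndarray, years) -> np.ndarray:
    """(C, Y, W, 4) climate tensor from the long panel, in id/year order."""
    wide = panel.sort_values(["county_id", "year", "week"])
    arr = wide[list(CLIMATE_FACTORS)].to_numpy().reshape(len(county_ids), len(years), N_WEEKS, 4)
    return arr


def _assemble(climate: np.ndarray, soil: pd.DataFrame, adjacency: pd.DataFrame, truth: TruthBundle) -> SyntheticPanel:
    """Regenerate NDVI, yields and the tabular panel from a climate tensor."""
    cfg = truth.config
    C, Y = len(truth.county_ids), len(cfg.years)
    regions = np.array([truth.region_of[c] for c in truth.county_ids])
    s = np.asarray(cfg.stage_sensitivity)

    bk = truth.region_kdd_beta[regions - 1][:, None, None]
    g, k, p, v = (climate[..., i] for i in range(4))
    weekly_gain = (
        cfg.beta_gdd * g
        - bk * k
        + cfg.beta_prcp * np.minimum(p, cfg.prcp_sat_week)
        - cfg.beta_vpd * np.maximum(0.0, v - cfg.vpd_threshold_week)
    ) * s[None, None, :]
    contrib = weekly_gain.sum(axis=-1)  # (C, Y)

    # stress index for NDVI: cumulative stage-weighted damage, normalized
    damage = (
        bk * k
        + cfg.beta_prcp * (cfg.prcp_sat_week - np.minimum(p, cfg.prcp_sat_week))
        + cfg.beta_vpd * np.maximum(0.0, v - cfg.vpd_threshold_week)
    ) * s[None, None, :]
    cum_damage = np.cumsum(damage, axis=-1)
    norm = np.quantile(cum_damage[..., -1], 0.95) + 1e-9
    stress_scale = 1.0 - cfg.ndvi_stress_coupling * np.minimum(1.0, cum_damage / norm)
    ndvi = _ndvi_base_curve()[None, None, :] * stress_scale + cfg.ndvi_noise_sd * truth.ndvi_eps
    ndvi = np.clip(ndvi, -1.0, 1.0)

    years_arr = np.asarray(cfg.years)
    awc = np.array([truth.soil_awc[c] for c in truth.county_ids])
    yields = (
        truth.region_intercepts[regions - 1][:, None]
        + cfg.trend * (years_arr - years_arr[0])[None, :]
        + contrib
        + cfg.gamma_awc * (awc - cfg.awc_ref)[:, None]
        + cfg.noise_sd * truth.yield_eps
    )
    yields = np.maximum(yields, 0.0)

    # long-format frames
    cid_col = np.repeat(truth.county_ids, Y * N_WEEKS)
    year_col = np.tile(np.repeat(years_arr, N_WEEKS), C)
    week_col = np.tile(np.arange(1, N_WEEKS + 1), C * Y)
    panel = pd.DataFrame({"county_id": cid_col, "year": year_col, "week": week_col})
    flat = climate.reshape(-1, 4)
    for j, var in enumerate(CLIMATE_FACTORS):
        panel[var] = flat[:, j]
    panel["ndvi"] = ndvi.reshape(-1)
    yields_df = pd.DataFrame({
        "county_id": np.repeat(truth.county_ids, Y),
        "year": np.tile(years_arr, C),
        "yield_mg_ha": yields.reshape(-1),
    })
    # LPGP: longer potential growth period in the warm south, for clustering
    rows = np.arange(C) // cfg.n_cols
    phi = rows / max(cfg.n_rows - 1, 1)
    lpgp_rng = np.random.default_rng(cfg.seed + 1)
    lpgp = pd.DataFrame({
        "county_id": truth.county_ids,
        "lpgp_days": np.round(150.0 + 60.0 * (1.0 - phi) + lpgp_rng.normal(0.0, 3.0, C)),
    })

    # reference inputs for the closed-form attribution oracle
    Xt = np.concatenate([climate, ndvi[..., None]], axis=-1)  # (C, Y, W, 5)
    if cfg.extreme_year in cfg.years:
        yi = list(cfg.years).index(cfg.extreme_year)
        mask = np.ones(Y, dtype=bool)
        mask[yi] = False
        normal = Xt[:, mask].mean(axis=1)
        stressm = Xt[:, yi]
        truth.normal_inputs = {c: normal[i] for i, c in enumerate(truth.county_ids)}
        truth.stress_inputs = {c: stressm[i] for i, c in enumerate(truth.county_ids)}

    return SyntheticPanel(panel=panel, soil=soil, yields=yields_df,
                          adjacency=adjacency, lpgp=lpgp, truth=truth)


def inject_extreme_year(bundle: SyntheticPanel, config: SyntheticConfig | None = None) -> SyntheticPanel:
    """Rescale the designated year's stress factors and regenerate outcomes.

    KDD, PRCP and VPD in the configured stress weeks of the extreme year are
    multiplied by (kdd_mult, prcp_mult, vpd_mult); every other county-year is
    untouched.  NDVI and yields are recomputed through the truth function with
    the originally drawn noise, so multipliers of 1 reproduce the input panel
    exactly.
    """
    if bundle.truth is None:
        raise ValueError("inject_extreme_year requires a panel with a TruthBundle")
    cfg = config if config is not None else bundle.truth.config
    if cfg.extreme_year is None:
        return bundle
    if cfg.extreme_year not in cfg.years:
        raise ValueError(f"extreme year {cfg.extreme_year} not among panel years")
    truth = bundle.truth
    climate = _climate_array(bundle.panel, truth.county_ids, cfg.years)
    yi = list(cfg.years).index(cfg.extreme_year)
    widx = np.asarray(cfg.stress_weeks) - 1
    mults = {"kdd": cfg.kdd_mult, "prcp": cfg.prcp_mult, "vpd": cfg.vpd_mult}
    climate = climate.copy()
    for var, m in mults.items():
        j = CLIMATE_FACTORS.index(var)
        climate[:, yi, widx, j] *= m
    return _assemble(climate, bundle.soil, bundle.adjacency, truth)


def summarize_panel(bundle: SyntheticPanel | PanelBundle, extreme_year: int | None = None) -> pd.DataFrame:
    """Seasonal county-mean sums per factor and year, with anomaly ratios.

    The ratio column divides each year's county-mean seasonal sum by the mean
    over all non-extreme years, so the designated extreme year's row reads off
    the realized anomaly magnitude (e.g. ~2.3 for KDD at default settings).
    """
    if extreme_year is None and getattr(bundle, "truth", None) is not None:
        extreme_year = bundle.truth.config.extreme_year
    seasonal = (
        bundle.panel.groupby(["county_id", "year"])[list(CLIMATE_FACTORS)].sum().reset_index()
    )
    by_year = seasonal.groupby("year")[list(CLIMATE_FACTORS)].mean()
    normal_years = [y for y in by_year.index if y != extreme_year]
    baseline = by_year.loc[normal_years].mean()
    out = by_year.copy()
    for var in CLIMATE_FACTORS:
        out[f"{var}_ratio"] = by_year[var] / baseline[var]
    out["n_records"] = seasonal.groupby("year").size()
    return out.reset_index()
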