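"""Uniform train/predict contract over the four yield-model families.

Every model kind — the multi-task attention-LSTM (``mtl``), the single-head
attention-LSTM (``alstm``), L1-penalized linear regression on weekly climate
factors and their stress interactions (``lasso``), and a random forest on the
flattened 110-dimensional design (``rf``) — is fitted through
:func:`train_model` and exposes ``predict(Xt, Xs, regions)`` on the same
inputs: a (n, 21, 5) temporal block, a (n, 5) soil matrix and 1-based region
labels.  This uniform contract is what the cross-validation and attribution
machinery programs against.

The LASSO design follows the convention of four weekly climate factors plus
the three stress interactions KDD*PRCP, KDD*VPD and PRCP*VPD per week
(7 x 21 = 147 columns, climate only); the random forest sees all five
temporal variables per week plus the five soil properties (110 columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso

from .nn import NeuralYieldModel, NetworkSpec, Standardizer, TrainingConfig, fit_network

MODEL_KINDS = ("mtl", "alstm", "lasso", "rf")

#: per-week column layout of the LASSO design, in order
LASSO_WEEK_TERMS = ("gdd", "kdd", "prcp", "vpd", "kdd*prcp", "kdd*vpd", "prcp*vpd")


@dataclass(frozen=True)
class BaselineConfig:
    """Hyperparameters of the two non-neural baselines."""

    lasso_lambda: float = 0.005
    rf_trees: int = 5000
    rf_mtry: int = 37
    rf_max_nodes: int = 300

    def __post_init__(self):
        if min(self.lasso_lambda, self.rf_trees, self.rf_mtry, self.rf_max_nodes) <= 0:
            raise ValueError("baseline hyperparameters must be positive")


def build_lasso_design(Xt: np.ndarray) -> np.ndarray:
    """147-column design: per week, 4 climate factors + 3 stress interactions.

    Column order is week-major: week 1's (gdd, kdd, prcp, vpd, kdd*prcp,
    kdd*vpd, prcp*vpd), then week 2's, and so on.  Interactions are formed on
    the raw weekly values; standardization happens column-wise at fit time.
    NDVI and soil are excluded: this baseline is a pure climate regression.
    """
    Xt = np.asarray(Xt)
    if Xt.ndim != 3 or Xt.shape[2] < 4:
        raise ValueError("expected (n, weeks, >=4 factors) temporal block")
    g, k, p, v = (Xt[:, :, j] for j in range(4))
    per_week = np.stack([g, k, p, v, k * p, k * v, p * v], axis=2)
    return per_week.reshape(len(Xt), -1)


def build_rf_design(Xt: np.ndarray, Xs: np.ndarray) -> np.ndarray:
    """110-column design: 5 temporal variables x 21 weeks + 5 soil properties."""
    return np.hstack([np.asarray(Xt).reshape(len(Xt), -1), np.asarray(Xs)])


@dataclass
class LassoYieldModel:
    kind: str
    model: Lasso
    stats: Standardizer

    def predict(self, Xt, Xs, regions) -> np.ndarray:
        return self.model.predict(self.stats.transform(build_lasso_design(Xt)))


@dataclass
class ForestYieldModel:
    kind: str
    model: RandomForestRegressor

    def predict(self, Xt, Xs, regions) -> np.ndarray:
        return self.model.predict(build_rf_design(Xt, Xs))


@dataclass
class MtlYieldModel:
    """Neural model behind the uniform contract; routes regions to heads.

    ``nets`` holds one or more independently initialized fits; predictions
    are the ensemble mean (a single-member list is an ordinary model).
    """

    kind: str
    nets: list[NeuralYieldModel]

    def predict(self, Xt, Xs, regions) -> np.ndarray:
        Xt, Xs, regions = np.asarray(Xt), np.asarray(Xs), np.asarray(regions)
        preds = [net.predict(Xt, Xs, regions) for net in self.nets]
        return np.mean(preds, axis=0)

    @property
    def net(self) -> NeuralYieldModel:
        return self.nets[0]

    @property
    def attention_weights(self):
        return self.net.temporal_feature


def fit_lasso(Xt: np.ndarray, y: np.ndarray, lasso_lambda: float = 0.005) -> LassoYieldModel:
    """L1-penalized least squares on standardized design columns at fixed λ."""
    design = build_lasso_design(Xt)
    stats = Standardizer.fit(design, axes=(0,))
    model = Lasso(alpha=lasso_lambda, max_iter=50000)
    model.fit(stats.transform(design), y)
    return LassoYieldModel(kind="lasso", model=model, stats=stats)


def fit_rf(Xt: np.ndarray, Xs: np.ndarray, y: np.ndarray,
           config: BaselineConfig = BaselineConfig(), seed: int = 0,
           n_jobs: int = 1) -> ForestYieldModel:
    """Random forest with fixed tree count, mtry and leaf budget."""
    design = build_rf_design(Xt, Xs)
    if design.shape[1] < config.rf_mtry:
        raise ValueError(
            f"rf_mtry={config.rf_mtry} exceeds design width {design.shape[1]}"
        )
    model = RandomForestRegressor(
        n_estimators=config.rf_trees,
        max_features=config.rf_mtry,
        max_leaf_nodes=config.rf_max_nodes,
        random_state=seed,
        n_jobs=n_jobs,
    )
    model.fit(design, y)
    return ForestYieldModel(kind="rf", model=model)


def train_model(
    kind: str,
    Xt: np.ndarray,
    Xs: np.ndarray,
    y: np.ndarray,
    regions: np.ndarray,
    n_regions: int,
    model_config: TrainingConfig | None = None,
    baseline_config: BaselineConfig | None = None,
    seed: int | None = None,
):
    """Fit any model kind on a training set; returns an object with .predict.

    ``regions`` are 1-based labels; only ``mtl`` uses them (one output head
    per region).  ``seed`` overrides the seed embedded in ``model_config``.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    if len(Xt) == 0:
        raise ValueError("training set is empty")
    baseline_config = baseline_config or BaselineConfig()
    if kind in ("mtl", "alstm"):
        from dataclasses import replace as dc_replace
        config = model_config or TrainingConfig.reduced()
        if seed is not None:
            config = dc_replace(config, seed=seed)
        heads = n_regions if kind == "mtl" else 1
        nets = [
            fit_network(Xt, Xs, y, regions, heads,
                        dc_replace(config, seed=(config.seed * 31 + member) % (2 ** 31)))
            for member in range(max(1, config.ensemble))
        ]
        return MtlYieldModel(kind=kind, nets=nets)
    if kind == "lasso":
        return fit_lasso(Xt, y, baseline_config.lasso_lambda)
    return fit_rf(Xt, Xs, y, baseline_config, seed=seed or 0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a fitted model to a single file.

    Neural models are stored as a compressed numpy archive carrying the
    architecture, standardization statistics and every member's weights;
    baseline models delegate to joblib.
    """
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, MtlYieldModel):
        import dataclasses

        import numpy as _np

        meta = {
            "kind": model.kind,
            "spec": dataclasses.asdict(model.net.spec),
            "config": dataclasses.asdict(model.net.config),
            "n_members": len(model.nets),
        }
        arrays = {"__meta__": _np.frombuffer(json.dumps(meta).encode(), dtype=_np.uint8)}
        for m, net in enumerate(model.nets):
            for k, v in net.params.items():
                arrays[f"m{m}/{k}"] = v
            arrays[f"m{m}/xt_mean"] = net.xt_stats.mean
            arrays[f"m{m}/xt_sd"] = net.xt_stats.sd
            arrays[f"m{m}/xs_mean"] = net.xs_stats.mean
            arrays[f"m{m}/xs_sd"] = net.xs_stats.sd
            arrays[f"m{m}/y_stats"] = _np.array([net.y_mean, net.y_sd])
        _np.savez_compressed(path, **arrays)
    else:
        import joblib

        joblib.dump(model, path)


def load_model(path):
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    import numpy as _np

    path = Path(path)
    try:
        data = _np.load(path, allow_pickle=False)
    except (ValueError, OSError):
        import joblib

        return joblib.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    spec = NetworkSpec(**meta["spec"])
    config = TrainingConfig(**meta["config"])
    nets = []
    for m in range(meta["n_members"]):
        params = {k.split("/", 1)[1]: data[k] for k in data.files
                  if k.startswith(f"m{m}/") and not k.split("/", 1)[1].startswith(("xt_", "xs_", "y_"))}
        y_stats = data[f"m{m}/y_stats"]
        nets.append(NeuralYieldModel(
            spec=spec, params=params,
            xt_stats=Standardizer(mean=data[f"m{m}/xt_mean"], sd=data[f"m{m}/xt_sd"]),
            xs_stats=Standardizer(mean=data[f"m{m}/xs_mean"], sd=data[f"m{m}/xs_sd"]),
            y_mean=float(y_stats[0]), y_sd=float(y_stats[1]), config=config,
        ))
    return MtlYieldModel(kind=meta["kind"], nets=nets)
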