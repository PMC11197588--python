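"""End-to-end orchestration: simulate -> cluster -> train -> evaluate -> attribute.

Each stage reads and writes plain tabular artifacts in the run directory and
derives its randomness from the master seed and its own stage name, so the
whole run is reproducible from the configuration file alone.  ``report``
renders the comparison and attribution tables as text.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import evaluation, models, regions as regions_mod, synth
from .attribution import attribution_report
from .config import RunConfig, write_manifest
from .panel import PanelBundle, panel_to_arrays, read_panel, write_panel

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _load_bundle(config: RunConfig, run_dir: Path) -> PanelBundle:
    panel_dir = Path(config.panel_dir) if config.panel_dir else run_dir / "panel"
    if not panel_dir.exists():
        raise StageError(f"panel directory {panel_dir} not found; run simulate first")
    return read_panel(panel_dir)


def stage_simulate(config: RunConfig, run_dir: Path) -> synth.SyntheticPanel:
    from dataclasses import replace
    cfg = replace(config.synthetic, seed=config.stage_seed("simulate"))
    bundle = synth.generate_panel(cfg)
    write_panel(bundle, run_dir / "panel")
    truth_meta = {
        "region_of": bundle.truth.region_of,
        "region_intercepts": bundle.truth.region_intercepts.tolist(),
        "region_kdd_beta": bundle.truth.region_kdd_beta.tolist(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
    }
    (run_dir / "panel" / "truth.json").write_text(json.dumps(truth_meta, indent=2))
    return bundle


def stage_cluster(config: RunConfig, run_dir: Path, bundle: PanelBundle) -> regions_mod.RegionAssignment:
    seed = config.stage_seed("cluster")
    cl = config.clustering
    if cl.select_k:
        k, table = regions_mod.select_k(
            bundle, cl.candidate_ks, extreme_year=config.stress_year, seed=seed,
            model_config=config.training,
        )
        table.to_csv(run_dir / "select_k.csv", index=False)
    else:
        k = cl.k
    assignment, report = regions_mod.cluster_regions(
        bundle, k, extreme_year=config.stress_year, seed=seed, n_restarts=cl.n_restarts,
    )
    assignment.to_frame().to_csv(run_dir / "regions.csv", index=False)
    coords, silhouette = regions_mod.tsne_embedding(report.features, assignment.labels, seed=seed)
    diag = {
        "k": assignment.k,
        "silhouette_tsne": silhouette,
        "dropped_counties": report.dropped,
        "constant_feature_columns": report.constant_columns,
    }
    (run_dir / "cluster_diagnostics.json").write_text(json.dumps(diag, indent=2))
    return assignment


def stage_evaluate(config: RunConfig, run_dir: Path, bundle: PanelBundle,
                   assignment: regions_mod.RegionAssignment,
                   kinds=("mtl", "alstm", "lasso", "rf")) -> dict:
    arrays = panel_to_arrays(bundle)
    regs = assignment.of(arrays["county_id"])
    seed = config.stage_seed("evaluate")
    results = {}
    for kind in kinds:
        res = evaluation.run_cv(
            arrays, regs, kind, assignment.k,
            model_config=config.training, baseline_config=config.baselines, seed=seed,
        )
        results[kind] = res
        res.per_fold.to_csv(run_dir / f"cv_{kind}_per_fold.csv", index=False)
        res.per_region.to_csv(run_dir / f"cv_{kind}_per_region.csv", index=False)
        res.per_county.to_csv(run_dir / f"cv_{kind}_per_county.csv", index=False)
    summary = {
        kind: {**res.pooled, "annual_rmse_mean": res.annual_rmse_mean,
               "annual_rmse_sd": res.annual_rmse_sd}
        for kind, res in results.items()
    }
    (run_dir / "cv_summary.json").write_text(json.dumps(summary, indent=2))
    return results


def stage_attribute(config: RunConfig, run_dir: Path, bundle: PanelBundle,
                    assignment: regions_mod.RegionAssignment, kind: str = "mtl"):
    arrays = panel_to_arrays(bundle)
    regs = assignment.of(arrays["county_id"])
    train = arrays["year"] != config.stress_year
    model = models.train_model(
        kind, arrays["Xt"][train], arrays["Xs"][train], arrays["y"][train],
        regs[train], assignment.k,
        model_config=config.attribution_training,
        baseline_config=config.baselines,
        seed=config.stage_seed("attribute"),
    )
    region_of = dict(zip(assignment.labels.index, assignment.labels.to_numpy()))
    result = attribution_report(model, bundle, region_of, stress_year=config.stress_year)
    result.table.to_csv(run_dir / f"attribution_{kind}.csv", index=False)
    result.stage_curves.to_csv(run_dir / f"attribution_{kind}_stage_curves.csv", index=False)
    summary = {
        "stress_year": result.summary.stress_year,
        "average_loss_mg_ha": result.summary.average_loss,
        "n_counties": result.summary.n_counties,
        "mean_factor_loss": result.summary.mean_factor_loss,
        "relative_contribution_pct": result.summary.relative_contribution,
        "severe_stage": result.severe_stage,
        "severe_county_fraction": result.severe_county_fraction,
    }
    (run_dir / f"attribution_{kind}_summary.json").write_text(json.dumps(summary, indent=2))
    return result


def run_pipeline(config: RunConfig, kinds=("mtl", "alstm", "lasso", "rf")) -> Path:
    """Execute every stage and write a manifest; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages_run = []
    stage = "simulate"
    try:
        if config.panel_dir is None:
            bundle = stage_simulate(config, run_dir)
        else:
            bundle = _load_bundle(config, run_dir)
        stages_run.append(stage)
        stage = "cluster"
        assignment = stage_cluster(config, run_dir, bundle)
        stages_run.append(stage)
        stage = "evaluate"
        stage_evaluate(config, run_dir, bundle, assignment, kinds=kinds)
        stages_run.append(stage)
        stage = "attribute"
        stage_attribute(config, run_dir, bundle, assignment)
        stages_run.append(stage)
    except Exception as exc:
        write_manifest(run_dir, config, stages_run + [f"FAILED:{stage}"])
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    write_manifest(run_dir, config, stages_run)
    return run_dir


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    lines = []
    cv_path = run_dir / "cv_summary.json"
    if cv_path.exists():
        cv = json.loads(cv_path.read_text())
        lines.append("Leave-one-year-out comparison (pooled over held-out years):")
        lines.append(f"{'model':8s} {'RMSE':>7s} {'R2':>7s} {'ME':>7s} {'annual RMSE':>18s}")
        for kind, row in cv.items():
            lines.append(
                f"{kind:8s} {row['rmse']:7.3f} {row['r2']:7.3f} {row['me']:+7.3f} "
                f"{row['annual_rmse_mean']:9.3f} ± {row['annual_rmse_sd']:.3f}"
            )
    for attr_path in sorted(run_dir.glob("attribution_*_summary.json")):
        a = json.loads(attr_path.read_text())
        kind = attr_path.stem.replace("attribution_", "").replace("_summary", "")
        lines.append("")
        lines.append(f"Attribution of the {a['stress_year']} loss ({kind} model, "
                     f"{a['n_counties']} counties):")
        lines.append(f"  trend-based average loss: {a['average_loss_mg_ha']:+.3f} Mg/ha")
        for f, pct in a["relative_contribution_pct"].items():
            lines.append(
                f"  {f.upper():5s} contribution {pct:+6.1f}%  "
                f"(mean dY {a['mean_factor_loss'][f]:+.3f} Mg/ha, "
                f"worst stage {a['severe_stage'][f]})"
            )
        curves = run_dir / f"attribution_{kind}_stage_curves.csv"
        if curves.exists():
            sc = pd.read_csv(curves)
            lines.append("  cumulative mean loss by stage (Mg/ha):")
            wide = sc.pivot(index="stage", columns="factor", values="mean_delta")
            lines.append("    " + " ".join(f"{c:>8s}" for c in wide.columns))
            for stage, row in wide.iterrows():
                lines.append(f"  s{stage}: " + " ".join(f"{v:8.3f}" for v in row))
    if not lines:
        lines.append(f"no artifacts found under {run_dir}")
    return "\n".join(lines)
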