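"""Spatial regionalization: cluster counties into homogeneous production zones.

Counties are clustered with k-means on twelve standardized features — mean
yield in the pre- and post-extreme periods, length of the potential growth
period, mean seasonal GDD/KDD/PRCP/VPD, and the five soil properties — and
the raw labels are then repaired so every region is a connected subgraph of
the county adjacency graph.  K is chosen by comparing multi-task model
accuracy over a small set of candidate cluster counts, and a t-SNE embedding
with a silhouette score serves as the separability diagnostic.

The contiguity repair rule: for each label, the largest connected component
keeps the label (ties broken by smallest member county id); every county in
a smaller component is reassigned to the neighboring label with the most
adjacent counties (ties to the lower label id), iterating until all regions
are connected.  A region reduced to a single county is then dissolved into
its most-adjacent neighbor — an isolated county never stands as a region of
its own.  The number of labels never increases and empty labels are
squeezed out, so the result is a clean 1..K assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .panel import CLIMATE_FACTORS, PanelBundle, SOIL_VARIABLES

logger = logging.getLogger(__name__)

CLUSTER_FEATURES = (
    ["yield_period_a", "yield_period_b", "lpgp_days"]
    + [f"seasonal_{v}" for v in CLIMATE_FACTORS]
    + list(SOIL_VARIABLES)
)


@dataclass
class RegionAssignment:
    """county -> region label in 1..k, every region connected and non-empty."""

    labels: pd.Series  # index county_id, values int
    k: int

    def __post_init__(self):
        present = sorted(self.labels.unique().tolist())
        if present != list(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k} with no gaps, got {present}")

    def of(self, county_ids) -> np.ndarray:
        return self.labels.loc[np.asarray(county_ids, dtype=object)].to_numpy(dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("region").rename_axis("county_id").reset_index()


@dataclass
class ClusterFeatureReport:
    features: pd.DataFrame          # standardized, index county_id
    dropped: list                  # counties removed by the record filter
    constant_columns: list = field(default_factory=list)


def build_cluster_features(
    bundle: PanelBundle,
    extreme_year: int | None = 2012,
    min_records_per_period: int = 3,
) -> ClusterFeatureReport:
    """Standardized clustering features per county.

    The extreme year's yields are excluded everywhere; counties with fewer
    than ``min_records_per_period`` yield records in either the pre- or
    post-extreme period are dropped (they are not representative of the main
    production area) and reported.  Seasonal climate means are taken over all
    non-extreme years.  Constant columns standardize to zero with a warning
    rather than dividing by zero.
    """
    yields = bundle.yields
    if extreme_year is not None:
        years = sorted(yields["year"].unique())
        period_a = [y for y in years if y < extreme_year]
        period_b = [y for y in years if y > extreme_year]
    else:
        years = sorted(yields["year"].unique())
        half = len(years) // 2
        period_a, period_b = years[:half], years[half:]
    rows = {}
    dropped = []
    soil = bundle.soil.set_index("county_id")
    lpgp = bundle.lpgp.set_index("county_id")["lpgp_days"] if bundle.lpgp is not None else None
    seasonal = (
        bundle.panel[bundle.panel["year"] != extreme_year]
        .groupby(["county_id", "year"])[list(CLIMATE_FACTORS)].sum()
        .groupby("county_id").mean()
    )
    for county, grp in yields.groupby("county_id"):
        grp = grp[grp["year"] != extreme_year]
        in_a = grp[grp["year"].isin(period_a)]
        in_b = grp[grp["year"].isin(period_b)]
        if len(in_a) < min_records_per_period or len(in_b) < min_records_per_period:
            dropped.append(county)
            continue
        if county not in soil.index or soil.loc[county].isna().all():
            raise ValueError(f"county {county} has no usable soil record")
        row = {
            "yield_period_a": in_a["yield_mg_ha"].mean(),
            "yield_period_b": in_b["yield_mg_ha"].mean(),
            "lpgp_days": float(lpgp.loc[county]) if lpgp is not None else 0.0,
        }
        for v in CLIMATE_FACTORS:
            row[f"seasonal_{v}"] = seasonal.loc[county, v]
        for v in SOIL_VARIABLES:
            row[v] = soil.loc[county, v]
        rows[county] = row
    if not rows:
        raise ValueError("no counties passed the yield-record filter")
    feats = pd.DataFrame.from_dict(rows, orient="index")[CLUSTER_FEATURES]
    sd = feats.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        logger.warning("constant feature columns standardized to zero: %s", constant)
    sd = sd.replace(0.0, 1.0)
    standardized = (feats - feats.mean()) / sd
    standardized.index.name = "county_id"
    if dropped:
        logger.info("dropped %d counties with <%d records per period", len(dropped), min_records_per_period)
    return ClusterFeatureReport(features=standardized, dropped=sorted(dropped), constant_columns=constant)


def kmeans_regions(features: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 25) -> pd.Series:
    """Best-of-``n_restarts`` k-means labels (1..k), deterministic per seed."""
    if not 1 <= k <= len(features):
        raise ValueError(f"k={k} must be in 1..{len(features)} (n counties)")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(features.to_numpy())
    return pd.Series(raw + 1, index=features.index, name="region")


def _adjacency_graph(adjacency: pd.DataFrame, counties) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(counties)
    known = set(counties)
    for a, b in adjacency[["county_id_a", "county_id_b"]].itertuples(index=False):
        if a in known and b in known:
            graph.add_edge(a, b)
    return graph


def enforce_contiguity(labels: pd.Series, adjacency: pd.DataFrame, max_rounds: int = 100) -> RegionAssignment:
    """Merge every non-largest component of each label into a neighbor region."""
    labels = labels.copy()
    graph = _adjacency_graph(adjacency, labels.index)
    if graph.number_of_nodes() and not nx.is_connected(graph):
        comps = sorted(nx.connected_components(graph), key=len)
        raise ValueError(
            f"adjacency graph is disconnected; smallest isolated group: {sorted(comps[0])[:8]}"
        )
    for _ in range(max_rounds):
        flagged: list[str] = []
        for label in sorted(labels.unique()):
            members = labels.index[labels == label]
            comps = sorted(
                nx.connected_components(graph.subgraph(members)),
                key=lambda c: (-len(c), min(c)),
            )
            for comp in comps[1:]:
                flagged.extend(comp)
        if not flagged:
            break
        pending = set(flagged)
        # counties adjacent to settled territory move first
        while pending:
            movable = []
            for county in sorted(pending):
                votes: dict[int, int] = {}
                for nb in graph.neighbors(county):
                    if nb in pending:
                        continue
                    votes[labels[nb]] = votes.get(labels[nb], 0) + 1
                if votes:
                    best = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
                    movable.append((county, best))
            if not movable:  # pending set surrounded by itself; peel arbitrarily
                county = sorted(pending)[0]
                nb_labels = sorted(labels[nb] for nb in graph.neighbors(county))
                movable = [(county, nb_labels[0])]
            for county, new_label in movable:
                labels[county] = new_label
                pending.discard(county)
    # an "isolated" county — a region consisting of one county — is dissolved
    # into the neighboring region with the most shared borders (ties -> lower
    # label), unless it is the only region left
    for _ in range(max_rounds):
        sizes = labels.value_counts()
        singles = sorted(sizes.index[sizes == 1])
        if not singles or labels.nunique() == 1:
            break
        county = labels.index[labels == singles[0]][0]
        votes: dict[int, int] = {}
        for nb in graph.neighbors(county):
            votes[labels[nb]] = votes.get(labels[nb], 0) + 1
        labels[county] = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    # squeeze labels to 1..K
    remap = {old: new for new, old in enumerate(sorted(labels.unique()), start=1)}
    labels = labels.map(remap)
    assignment = RegionAssignment(labels=labels, k=len(remap))
    for label in range(1, assignment.k + 1):
        members = labels.index[labels == label]
        if not nx.is_connected(graph.subgraph(members)):
            raise RuntimeError(f"contiguity repair failed to converge for region {label}")
    return assignment


def cluster_regions(
    bundle: PanelBundle,
    k: int,
    extreme_year: int | None = 2012,
    seed: int = 0,
    n_restarts: int = 25,
) -> tuple[RegionAssignment, ClusterFeatureReport]:
    """Features -> k-means -> contiguity repair, the full regionalization step."""
    report = build_cluster_features(bundle, extreme_year=extreme_year)
    raw = kmeans_regions(report.features, k, seed=seed, n_restarts=n_restarts)
    assignment = enforce_contiguity(raw, bundle.adjacency)
    return assignment, report


def select_k(
    bundle: PanelBundle,
    candidate_ks=(2, 4, 6, 8),
    extreme_year: int | None = 2012,
    n_holdout_years: int = 3,
    seed: int = 0,
    model_config=None,
) -> tuple[int, pd.DataFrame]:
    """Pick the cluster count whose multi-task model generalizes best.

    For each candidate k the panel is clustered, and the multi-task model is
    trained with each of the ``n_holdout_years`` most recent non-extreme
    years held out in turn (a reduced stand-in for full leave-one-year-out,
    which would be 13x more expensive); the k with the lowest mean held-out
    RMSE wins.  Returns the winner and the full comparison table.
    """
    from .evaluation import metrics as _metrics
    from .models import train_model
    from .nn import TrainingConfig
    from .panel import panel_to_arrays

    if not candidate_ks:
        raise ValueError("candidate_ks must be non-empty")
    arrays = panel_to_arrays(bundle)
    years = sorted(set(arrays["year"].tolist()))
    holdout = [y for y in years if y != extreme_year][-n_holdout_years:]
    config = model_config or TrainingConfig.reduced()
    rows = []
    for k in sorted(set(candidate_ks)):
        try:
            assignment, _ = cluster_regions(bundle, k, extreme_year=extreme_year, seed=seed)
        except (ValueError, RuntimeError) as exc:
            logger.warning("k=%d skipped: %s", k, exc)
            continue
        regs = assignment.of(arrays["county_id"])
        rmses = []
        for test_year in holdout:
            train = arrays["year"] != test_year
            model = train_model(
                "mtl", arrays["Xt"][train], arrays["Xs"][train], arrays["y"][train],
                regs[train], assignment.k, model_config=config, seed=seed,
            )
            yhat = model.predict(arrays["Xt"][~train], arrays["Xs"][~train], regs[~train])
            rmse, _, _ = _metrics(arrays["y"][~train], yhat)
            rmses.append(rmse)
        rows.append({"k": k, "k_effective": assignment.k, "mean_rmse": float(np.mean(rmses)),
                     **{f"rmse_{y}": r for y, r in zip(holdout, rmses)}})
    if not rows:
        raise ValueError("every candidate k failed clustering")
    table = pd.DataFrame(rows)
    winner = int(table.loc[table["mean_rmse"].idxmin(), "k"])
    return winner, table


def tsne_embedding(features: pd.DataFrame, labels: pd.Series, seed: int = 0):
    """2-d t-SNE embedding of the cluster features plus a silhouette score.

    The silhouette on the embedding is the quantitative proxy for the visual
    separability check; scores above ~0.5 indicate well-separated regions.
    """
    n = len(features)
    perplexity = min(30.0, max(2.0, (n - 1) / 3))
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    coords = ts.fit_transform(features.to_numpy())
    aligned = labels.loc[features.index]
    score = float("nan")
    if aligned.nunique() > 1:
        score = float(silhouette_score(coords, aligned.to_numpy()))
    return coords, score
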