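"""Regionalization: features, k-means, contiguity repair, k selection, t-SNE."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from maizeyield.regions import (
    RegionAssignment,
    build_cluster_features,
    cluster_regions,
    enforce_contiguity,
    kmeans_regions,
    select_k,
    tsne_embedding,
)


class TestClusterFeatures:
    def test_twelve_standardized_features(self, small_panel):
        report = build_cluster_features(small_panel, extreme_year=2012)
        assert report.features.shape[1] == 12
        np.testing.assert_allclose(report.features.mean(), 0.0, atol=1e-9)
        sds = report.features.std(ddof=0)
        assert ((np.isclose(sds, 1.0)) | (np.isclose(sds, 0.0))).all()

    def test_extreme_year_excluded_from_means(self, small_panel):
        """Perturbing 2012 yields must not change any feature."""
        report = build_cluster_features(small_panel, extreme_year=2012)
        mutated = small_panel
        yields = mutated.yields.copy()
        yields.loc[yields["year"] == 2012, "yield_mg_ha"] += 5.0
        from dataclasses import replace as dc_replace
        bundle2 = dc_replace(small_panel, yields=yields)
        report2 = build_cluster_features(bundle2, extreme_year=2012)
        pd.testing.assert_frame_equal(report.features, report2.features)

    def test_county_with_one_sided_records_dropped(self, small_panel):
        from dataclasses import replace as dc_replace
        county = small_panel.counties[0]
        yields = small_panel.yields
        keep = ~((yields["county_id"] == county) & (yields["year"] > 2012))
        bundle2 = dc_replace(small_panel, yields=yields[keep])
        report = build_cluster_features(bundle2, extreme_year=2012)
        assert county in report.dropped
        assert county not in report.features.index


class TestKmeans:
    def test_k_one_collapses_to_single_label(self, small_panel):
        report = build_cluster_features(small_panel)
        labels = kmeans_regions(report.features, k=1, seed=0)
        assert set(labels) == {1}

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (10, 3))
        b = rng.normal(8, 0.1, (10, 3))
        feats = pd.DataFrame(np.vstack([a, b]), index=[f"C{i}" for i in range(20)])
        labels = kmeans_regions(feats, k=2, seed=1)
        assert labels.iloc[:10].nunique() == 1 and labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_above_n_rejected(self, small_panel):
        report = build_cluster_features(small_panel)
        with pytest.raises(ValueError):
            kmeans_regions(report.features, k=len(report.features) + 1)


def _grid_adjacency(n):
    edges = []
    ids = [f"C{i:02d}" for i in range(n * n)]
    for i in range(n * n):
        r, c = divmod(i, n)
        if c + 1 < n:
            edges.append((ids[i], ids[i + 1]))
        if r + 1 < n:
            edges.append((ids[i], ids[i + n]))
    return ids, pd.DataFrame(edges, columns=["county_id_a", "county_id_b"])


class TestContiguity:
    def test_contiguous_labels_unchanged(self):
        ids, adj = _grid_adjacency(3)
        labels = pd.Series([1, 1, 2, 1, 1, 2, 1, 2, 2], index=ids)
        result = enforce_contiguity(labels, adj)
        pd.testing.assert_series_equal(result.labels, labels, check_names=False)

    def test_isolated_center_county_merged(self):
        """A lone label-2 county surrounded by label 1 joins label 1."""
        ids, adj = _grid_adjacency(3)
        labels = pd.Series([1, 1, 1, 1, 2, 1, 1, 1, 1], index=ids)
        result = enforce_contiguity(labels, adj)
        assert result.k == 1
        assert set(result.labels) == {1}

    def test_split_label_components_merged_down(self):
        # label 2 in two opposite corners: the non-largest component merges
        # first (tie broken by lowest county id keeping the label), and the
        # surviving single-county region is then dissolved as isolated
        ids, adj = _grid_adjacency(3)
        labels = pd.Series([2, 1, 2, 1, 1, 1, 1, 1, 1], index=ids)
        result = enforce_contiguity(labels, adj)
        assert result.k == 1
        assert set(result.labels) == {1}

    def test_two_county_region_survives(self):
        # a connected two-county region is legitimate and must not dissolve
        ids, adj = _grid_adjacency(3)
        labels = pd.Series([2, 2, 1, 1, 1, 1, 1, 1, 1], index=ids)
        result = enforce_contiguity(labels, adj)
        assert result.k == 2
        assert result.labels["C00"] == result.labels["C01"]

    def test_never_increases_label_count_and_stays_connected(self, small_panel):
        rng = np.random.default_rng(5)
        counties = small_panel.counties
        labels = pd.Series(rng.integers(1, 5, len(counties)), index=counties)
        result = enforce_contiguity(labels, small_panel.adjacency)
        assert result.k <= labels.nunique()
        graph = nx.Graph()
        graph.add_nodes_from(counties)
        graph.add_edges_from(small_panel.adjacency.itertuples(index=False))
        for label in range(1, result.k + 1):
            members = result.labels.index[result.labels == label]
            assert len(members) > 0
            assert nx.is_connected(graph.subgraph(members))

    def test_disconnected_adjacency_rejected(self):
        ids, adj = _grid_adjacency(3)
        broken = adj[~adj["county_id_a"].isin(["C00"]) & ~adj["county_id_b"].isin(["C00"])]
        labels = pd.Series(1, index=ids)
        with pytest.raises(ValueError, match="disconnected"):
            enforce_contiguity(labels, broken)


def test_zero_noise_block_features_recover_truth(small_panel):
    """On noiseless block-structured features k-means + repair = truth (ARI 1)."""
    truth = {c: small_panel.truth.region_of[c] for c in small_panel.counties}
    feats = pd.DataFrame(
        {"f1": [truth[c] * 10.0 for c in small_panel.counties],
         "f2": [-truth[c] * 3.0 for c in small_panel.counties]},
        index=small_panel.counties,
    )
    labels = kmeans_regions(feats, k=4, seed=0)
    assignment = enforce_contiguity(labels, small_panel.adjacency)
    ari = adjusted_rand_score([truth[c] for c in assignment.labels.index],
                              assignment.labels.to_numpy())
    assert ari == pytest.approx(1.0)


def test_full_clustering_recovers_generator_regions(small_panel):
    assignment, report = cluster_regions(small_panel, k=4, seed=1)
    truth = [small_panel.truth.region_of[c] for c in assignment.labels.index]
    ari = adjusted_rand_score(truth, assignment.labels.to_numpy())
    assert ari > 0.6  # noisy features, but regional structure dominates


class TestSelectK:
    def test_single_candidate_returned(self, small_panel):
        from maizeyield.nn import TrainingConfig
        tiny = TrainingConfig.reduced(max_epochs=2)
        k, table = select_k(small_panel, candidate_ks=(4,), seed=1, model_config=tiny)
        assert k == 4
        assert set(table["k"]) == {4}

    def test_result_among_candidates(self, small_panel):
        from maizeyield.nn import TrainingConfig
        tiny = TrainingConfig.reduced(max_epochs=2)
        k, _ = select_k(small_panel, candidate_ks=(2, 4), seed=1, model_config=tiny)
        assert k in (2, 4)


class TestTsne:
    def test_embedding_runs_and_scores_blobs(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(
            np.vstack([rng.normal(0, 0.2, (15, 4)), rng.normal(6, 0.2, (15, 4))]),
            index=[f"C{i}" for i in range(30)],
        )
        labels = pd.Series([1] * 15 + [2] * 15, index=feats.index)
        coords, score = tsne_embedding(feats, labels, seed=1)
        assert coords.shape == (30, 2)
        assert score > 0.5

    def test_deterministic_given_seed(self, small_panel):
        report = build_cluster_features(small_panel)
        labels = kmeans_regions(report.features, k=4, seed=0)
        c1, s1 = tsne_embedding(report.features, labels, seed=3)
        c2, s2 = tsne_embedding(report.features, labels, seed=3)
        np.testing.assert_allclose(c1, c2)
        assert s1 == s2
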