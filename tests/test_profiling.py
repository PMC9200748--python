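"""Profile construction, the four selection rules, grouped correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from brightstain.feature_table import FeatureTable
from brightstain.profiling import (aggregate_profiles, embed_profiles,
                                   extract_standin_features,
                                   grouped_feature_correlation, select_features)
from brightstain.synthetic_data import generate_feature_table


def _simple_table(values: dict, roles=None, index=None):
    data = pd.DataFrame(values, index=index)
    ann = pd.DataFrame({"compartment": "cell", "channel": "DNA",
                        "feature_type": "intensity"}, index=list(values))
    meta = pd.DataFrame({"well_id": data.index, "batch": "A",
                         "role": roles if roles is not None else "treatment",
                         "source": "ground_truth"}, index=data.index)
    return FeatureTable(data, ann, meta)


class TestStandinExtractor:
    @pytest.fixture(scope="class")
    def circle_scene(self):
        S = 64
        yy, xx = np.mgrid[0:S, 0:S]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2).astype(np.int32)
        nucleus = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 8 ** 2).astype(np.int32)
        images = np.ones((5, S, S))
        return images, {"cells": disk, "nuclei": nucleus}

    def test_ring_fractions_proportional_to_ring_areas(self, circle_scene):
        """Uniform intensity in a disk: ring k holds ≈ ((k+1)² − k²)/9 of it."""
        images, masks = circle_scene
        feats = extract_standin_features(images, masks)
        fracs = [feats[f"cell_radial_distribution_DNA_ring{k}"] for k in range(3)]
        expected = [1 / 9, 3 / 9, 5 / 9]
        assert np.allclose(fracs, expected, atol=0.05)

    def test_intensity_features_scale_linearly(self, circle_scene):
        images, masks = circle_scene
        f1 = extract_standin_features(images, masks)
        f3 = extract_standin_features(3.0 * images, masks)
        assert f3["cell_intensity_DNA_mean"] == pytest.approx(
            3 * f1["cell_intensity_DNA_mean"])
        assert f3["cytoplasm_intensity_Mito_integrated"] == pytest.approx(
            3 * f1["cytoplasm_intensity_Mito_integrated"])

    def test_nucleus_area_equals_mask_pixel_count(self, circle_scene):
        images, masks = circle_scene
        feats = extract_standin_features(images, masks)
        assert feats["nuclei_area_shape_none_area"] == masks["nuclei"].astype(bool).sum()

    def test_empty_mask_gives_missing_row(self):
        feats = extract_standin_features(
            np.zeros((5, 32, 32)),
            {"cells": np.zeros((32, 32), np.int32), "nuclei": np.zeros((32, 32), np.int32)})
        assert feats.isna().all()


class TestAggregateProfiles:
    def test_median_rules(self):
        t = _simple_table({"f1": [1.0, 2.0, 9.0, 1.0, 3.0],
                           "f2": [np.nan, np.nan, np.nan, 1.0, 2.0]},
                          index=list("abcde"))
        t.meta["well_id"] = ["w1", "w1", "w1", "w2", "w2"]
        agg = aggregate_profiles(t)
        assert agg.data.loc["w1", "f1"] == 2.0      # odd count
        assert agg.data.loc["w2", "f1"] == 2.0      # even count: mean of middle two
        assert np.isnan(agg.data.loc["w1", "f2"])   # all-missing group stays missing
        assert agg.data.loc["w2", "f2"] == 1.5


class TestSelectFeatures:
    def test_each_rule_removes_exactly_its_planted_violators(self):
        t = generate_feature_table(n_wells=80, n_features=40, fraction_nan=0.15,
                                   n_duplicate_pairs=3, n_toxic=8,
                                   effect_size=1.0, seed=11)
        # plant a rule-4 violator: near-constant (no zeros, so rule 1 passes it)
        # except one extreme DMSO outlier driving the control SD far above 15
        outlier_feature = t.features[20]
        assert outlier_feature not in t.planted["nan_features"]
        col = np.random.default_rng(0).normal(1.0, 0.1, t.n_rows)
        dmso_rows = np.flatnonzero((t.meta["role"] == "negative_control").to_numpy())
        col[dmso_rows[0]] = 200.0  # SD over DMSO wells >> 15
        t.data[outlier_feature] = col
        report = select_features(t)
        assert set(report.rule1_missing) == set(t.planted["nan_features"])
        dup_dropped = set(report.rule3_correlated)
        planted_pairs = t.planted["duplicate_pairs"]
        assert len(dup_dropped) == len(planted_pairs)
        for a, b in planted_pairs:
            assert (a in dup_dropped) != (b in dup_dropped)  # exactly one of each pair
        assert report.rule4_variable == [outlier_feature]

    def test_blocklist_rule(self):
        t = generate_feature_table(n_wells=40, n_features=20, fraction_nan=0.0,
                                   n_duplicate_pairs=0, seed=2)
        block = [t.features[5], t.features[7]]
        report = select_features(t, blocklist=block)
        assert set(report.rule2_blocklist) == set(block)

    def test_selection_is_idempotent(self):
        t = generate_feature_table(n_wells=60, n_features=30, seed=3)
        first = select_features(t)
        survivors = t.select(first.survivors)
        second = select_features(survivors)
        assert second.survivors == first.survivors
        assert not second.dropped

    def test_selection_is_blind_to_predicted_values(self, rng):
        t = generate_feature_table(n_wells=60, n_features=30, seed=4)
        report = select_features(t)
        pred = t.copy()
        pred.data = pred.data + rng.normal(size=pred.data.shape)  # perturb predictions
        # selection runs on the ground-truth table only; the predicted source
        # is reduced with the same survivor list
        assert select_features(t).survivors == report.survivors
        assert list(pred.select(report.survivors).features) == report.survivors

    def test_six_percent_missing_crosses_threshold(self):
        vals = np.random.default_rng(0).normal(size=50)
        col = vals.copy()
        col[:3] = np.nan  # 6% > 5%
        t = _simple_table({"ok": vals, "missing6": col},
                          roles=["negative_control"] * 10 + ["treatment"] * 40,
                          index=[f"w{i}" for i in range(50)])
        report = select_features(t)
        assert report.rule1_missing == ["missing6"]

    def test_empty_table_raises(self):
        t = generate_feature_table(n_wells=20, n_features=10, seed=5)
        with pytest.raises(ValueError):
            select_features(t.rows_where(np.zeros(20, dtype=bool)))


class TestGroupedCorrelation:
    def _paired_tables(self, rng, transform=None):
        truth = generate_feature_table(n_wells=40, n_features=21, fraction_nan=0.0,
                                       n_duplicate_pairs=0, seed=6)
        pred = truth.copy()
        if transform is not None:
            pred.data = transform(pred.data)
        return pred, truth

    def test_identity_gives_all_ones(self, rng):
        pred, truth = self._paired_tables(rng)
        groups, per_feature, summary = grouped_feature_correlation(pred, truth)
        assert np.allclose(per_feature.dropna(), 1.0)
        assert np.allclose(groups["mean_r"].dropna(), 1.0)
        assert summary["overall_mean"] == pytest.approx(1.0)

    def test_monotone_transform_preserves_rank_correlation(self, rng):
        pred, truth = self._paired_tables(rng, transform=lambda d: d ** 3)
        _, per_feature, _ = grouped_feature_correlation(pred, truth)
        assert np.allclose(per_feature.dropna(), 1.0)

    def test_matches_midrank_pearson_oracle_with_ties(self, rng):
        truth = generate_feature_table(n_wells=30, n_features=7, fraction_nan=0.0,
                                       n_duplicate_pairs=0, seed=7)
        truth.data = truth.data.round(0)  # force ties
        pred = truth.copy()
        pred.data = pred.data + rng.normal(0, 0.5, size=pred.data.shape).round(0)
        _, per_feature, _ = grouped_feature_correlation(pred, truth)
        for f in truth.features[:3]:
            a = rankdata(pred.data[f])
            b = rankdata(truth.data[f])
            want = np.corrcoef(a, b)[0, 1]
            assert per_feature[f] == pytest.approx(want, abs=1e-12)

    def test_group_means_are_feature_count_weighted(self, rng):
        pred, truth = self._paired_tables(rng, transform=lambda d: d + np.random.default_rng(0).normal(size=d.shape))
        groups, per_feature, summary = grouped_feature_correlation(pred, truth)
        weighted = (groups["mean_r"] * groups["n_features"]).sum() / groups["n_features"].sum()
        assert summary["overall_mean"] == pytest.approx(weighted)

    def test_mismatched_features_raise(self, rng):
        pred, truth = self._paired_tables(rng)
        with pytest.raises(ValueError, match="differ"):
            grouped_feature_correlation(pred.select(pred.features[:-1]), truth)


class TestEmbedding:
    def test_two_clusters_stay_separated(self):
        r = np.random.default_rng(8)
        X = np.vstack([r.normal(0, 1, (30, 10)), r.normal(8, 1, (30, 10))])
        names = [f"f{i}" for i in range(10)]
        t = _simple_table({n: X[:, i] for i, n in enumerate(names)},
                          index=[f"w{i}" for i in range(60)])
        emb = embed_profiles(t, seed=0)
        a, b = emb.iloc[:30].to_numpy(), emb.iloc[30:].to_numpy()
        gap = np.linalg.norm(a.mean(0) - b.mean(0))
        ra = np.percentile(np.linalg.norm(a - a.mean(0), axis=1), 95)
        rb = np.percentile(np.linalg.norm(b - b.mean(0), axis=1), 95)
        assert gap > max(ra, rb)

    def test_output_has_two_coordinates_per_row(self):
        t = generate_feature_table(n_wells=30, n_features=10, seed=9)
        emb = embed_profiles(t, seed=1)
        assert emb.shape == (30, 2)
        emb_pca = embed_profiles(t, method="pca", seed=1)
        assert emb_pca.shape == (30, 2)

    def test_too_few_rows_raise(self):
        t = generate_feature_table(n_wells=10, n_features=8, n_toxic=2, seed=10)
        with pytest.raises(ValueError, match="n_neighbors"):
            embed_profiles(t, n_neighbors=15)


class TestPlotting:
    def test_heatmap_and_embedding_render(self):
        from brightstain.plotting import plot_embedding, plot_group_correlation_heatmap

        truth = generate_feature_table(n_wells=30, n_features=21, fraction_nan=0.0,
                                       n_duplicate_pairs=0, seed=12)
        pred = truth.copy()
        pred.data = pred.data + np.random.default_rng(1).normal(size=pred.data.shape)
        groups, _, _ = grouped_feature_correlation(pred, truth)
        ax = plot_group_correlation_heatmap(groups)
        assert ax.get_title()
        coords = pd.DataFrame(np.random.default_rng(2).normal(size=(30, 2)),
                              index=truth.data.index, columns=["dim1", "dim2"])
        ax2 = plot_embedding(coords, truth.meta["role"])
        assert len(ax2.collections) == len(truth.meta["role"].unique())
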