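import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from momicnet.preprocess import AnnotationTable
from momicnet.synthetic import LayerSpec, SyntheticConfig, generate_multiomics
from momicnet.wcna import (
    WCNA,
    ModulePartition,
    NetworkParams,
    _scale_free_fit,
    adjacency,
    detect_modules,
    feature_correlation,
    merge_close_modules,
    module_eigengenes,
    module_membership,
    module_trait_correlation,
    pick_soft_threshold,
    sample_contributions,
    tom_similarity,
)

from conftest import make_layer


def brute_force_tom(a):
    """Triple-loop reference implementation of topological overlap."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(seed, n=15):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestFeatureCorrelation:
    def test_duplicate_and_negated_features(self, rng):
        x = rng.normal(size=(10, 1))
        layer = make_layer(np.hstack([x, x, -x]))
        corr = feature_correlation(layer).to_numpy()
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(size=(12, 2))
        warped = np.column_stack([np.exp(x[:, 0]), x[:, 1]])
        r1 = feature_correlation(make_layer(x), "spearman").iloc[0, 1]
        r2 = feature_correlation(make_layer(warped), "spearman").iloc[0, 1]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_named(self, rng):
        x = rng.normal(size=(8, 3))
        x[:, 2] = 5.0
        with pytest.raises(ValueError, match="f3"):
            feature_correlation(make_layer(x))


class TestAdjacency:
    def test_hand_power(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = adjacency(r, NetworkParams(power=6))
        assert a[0, 1] == pytest.approx(0.015625)

    def test_signed_perfect_negative_is_zero(self):
        r = np.array([[1.0, -1.0], [-1.0, 1.0]])
        a = adjacency(r, NetworkParams(network_type="signed", power=4))
        assert a[0, 1] == 0.0

    def test_power_one_is_absolute_value(self, rng):
        r = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (5, 5))), -1, 1)
        np.fill_diagonal(r, 1.0)
        a = adjacency(r, NetworkParams(power=1))
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(a[off], np.abs(r)[off])

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(power=0.5)

    @given(beta1=st.floats(1, 10), beta2=st.floats(1, 10))
    @settings(max_examples=25, deadline=None)
    def test_unsigned_monotone_in_power(self, beta1, beta2):
        lo, hi = sorted([beta1, beta2])
        r = np.array([[1.0, 0.9, -0.4], [0.9, 1.0, 0.2], [-0.4, 0.2, 1.0]])
        a_lo = adjacency(r, NetworkParams(power=lo))
        a_hi = adjacency(r, NetworkParams(power=hi))
        off = ~np.eye(3, dtype=bool)
        assert np.all(a_hi[off] <= a_lo[off] + 1e-12)


class TestSoftThreshold:
    def test_exact_power_law_fits_perfectly(self):
        # ten distinct degree values with counts following k^-2 exactly
        ks, counts = [], []
        for b in range(10):
            k = 10.0 + 10.0 * b
            ks.append(k)
            counts.append(int(round(1e6 * k**-2)))
        degrees = np.repeat(ks, counts)
        r2, slope = _scale_free_fit(degrees)
        assert r2 == pytest.approx(1.0, abs=1e-4)
        assert slope < 0

    def test_all_equal_degrees_undefined(self):
        r2, _ = _scale_free_fit(np.full(50, 3.0))
        assert np.isnan(r2)

    def test_degenerate_equal_correlations_warns_and_chooses_nothing(self):
        r = np.full((20, 20), 0.5)
        np.fill_diagonal(r, 1.0)
        with pytest.warns(UserWarning):
            rep = pick_soft_threshold(r, NetworkParams(), candidates=(2, 4, 6))
        assert rep.chosen_power is None
        assert rep.table["r2"].isna().all()

    def test_planted_modules_reach_target(self):
        cfg = SyntheticConfig(
            n_samples=60, layers=(LayerSpec("L", 150, (40, 40, 40), 0.7),), seed=1
        )
        layers, _, _ = generate_multiomics(cfg)
        corr = feature_correlation(layers[0])
        rep = pick_soft_threshold(corr, NetworkParams())
        chosen = rep.table.loc[rep.table["power"] == rep.chosen_power, "r2"]
        assert float(chosen.iloc[0]) >= 0.8


class TestTom:
    def test_complete_graph(self):
        a = np.ones((5, 5))
        tom = tom_similarity(a)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(tom[off], 1.0)

    def test_star_leaf_pair(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1.0
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert tom[1, 2] == pytest.approx(0.5)

    def test_empty_graph(self):
        tom = tom_similarity(np.eye(6))
        off = ~np.eye(6, dtype=bool)
        assert np.all(tom[off] == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        a = random_adjacency(seed)
        assert np.abs(tom_similarity(a) - brute_force_tom(a)).max() < 1e-10

    def test_asymmetric_rejected(self):
        a = np.eye(4)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestDetectModules:
    def test_two_perfect_blocks(self, rng):
        f1, f2 = rng.normal(size=10), rng.normal(size=10)
        x = np.column_stack([f1] * 4 + [f2] * 4)
        x += rng.normal(size=x.shape) * 1e-6
        layer = make_layer(x)
        params = NetworkParams(power=6, min_module_size=3)
        tom = tom_similarity(adjacency(feature_correlation(layer), params))
        part = detect_modules(tom, params, layer.feature_ids)
        assert part.sizes() == {1: 4, 2: 4}
        assert len({part.labels[0], part.labels[4]}) == 2

    def test_iid_noise_mostly_unassigned(self):
        majority = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=(60, 60))
            layer = make_layer(x)
            params = NetworkParams(power=6, min_module_size=5)
            tom = tom_similarity(adjacency(feature_correlation(layer), params))
            part = detect_modules(tom, params, layer.feature_ids)
            majority += (part.labels == 0).mean() > 0.5
        assert majority > 10

    def test_oversized_min_module_all_grey(self, rng):
        tom = np.eye(5)
        with pytest.warns(UserWarning, match="unassigned"):
            part = detect_modules(tom, NetworkParams(min_module_size=6))
        assert np.all(part.labels == 0)


class TestEigengenes:
    def _partitioned_layer(self, rng, n=20, sizes=(5, 4)):
        f = rng.normal(size=(n, len(sizes)))
        cols, labels = [], []
        for m, size in enumerate(sizes, start=1):
            block = np.outer(f[:, m - 1], rng.uniform(0.8, 1.2, size))
            cols.append(block + rng.normal(size=(n, size)) * 0.4)
            labels += [m] * size
        layer = make_layer(np.hstack(cols))
        return layer, ModulePartition(layer.feature_ids, np.array(labels))

    def test_matches_dense_svd_oracle(self, rng):
        layer, part = self._partitioned_layer(rng)
        eig = module_eigengenes(layer, part)
        for m in part.module_ids:
            sub = layer.data[part.members(m)].to_numpy()
            sub = (sub - sub.mean(0)) / sub.std(0, ddof=1)
            u = np.linalg.svd(sub, full_matrices=False)[0][:, 0]
            u = u / u.std(ddof=1)
            got = eig[f"ME{m}"].to_numpy()
            assert min(
                np.abs(got - u).max(), np.abs(got + u).max()
            ) < 1e-8

    def test_sign_convention_follows_mean_profile(self, rng):
        layer, part = self._partitioned_layer(rng)
        eig = module_eigengenes(layer, part)
        for m in part.module_ids:
            sub = layer.data[part.members(m)].to_numpy()
            sub = (sub - sub.mean(0)) / sub.std(0, ddof=1)
            assert np.corrcoef(eig[f"ME{m}"], sub.mean(axis=1))[0, 1] >= 0

    def test_duplicated_module_features_leave_eigengene_unchanged(self, rng):
        layer, part = self._partitioned_layer(rng, sizes=(5,))
        eig1 = module_eigengenes(layer, part)["ME1"].to_numpy()
        doubled = make_layer(
            np.hstack([layer.values, layer.values]),
            features=[f"f{i}" for i in range(10)],
        )
        part2 = ModulePartition(doubled.feature_ids, np.ones(10, dtype=int))
        eig2 = module_eigengenes(doubled, part2)["ME1"].to_numpy()
        assert np.abs(eig1 - eig2).max() < 1e-10

    def test_singleton_module_is_standardized_feature(self, rng):
        x = rng.normal(size=(10, 1))
        layer = make_layer(x)
        part = ModulePartition(layer.feature_ids, np.array([1]))
        eig = module_eigengenes(layer, part)["ME1"].to_numpy()
        z = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std(ddof=1)
        np.testing.assert_allclose(eig, z, atol=1e-12)

    def test_unit_variance_columns(self, rng):
        layer, part = self._partitioned_layer(rng)
        eig = module_eigengenes(layer, part)
        np.testing.assert_allclose(eig.std(ddof=1), 1.0, atol=1e-10)


class TestMergeModules:
    def _split_factor_layer(self, rng):
        f = rng.normal(size=30)
        x = np.outer(f, np.ones(12)) + rng.normal(size=(30, 12)) * 0.3
        layer = make_layer(x)
        labels = np.array([1] * 6 + [2] * 6)
        return layer, ModulePartition(layer.feature_ids, labels)

    def test_zero_cut_is_identity(self, rng):
        layer, part = self._split_factor_layer(rng)
        merged, _ = merge_close_modules(layer, part, merge_cut=0.0)
        assert merged.sizes() == part.sizes()

    def test_same_factor_modules_merge(self, rng):
        layer, part = self._split_factor_layer(rng)
        merged, eig = merge_close_modules(layer, part, merge_cut=0.25)
        assert merged.module_ids == [1]
        assert eig.shape[1] == 1

    def test_merges_monotone_in_cut(self, rng):
        layer, part = self._split_factor_layer(rng)
        counts = []
        for cut in (0.0, 0.25, 0.8):
            merged, _ = merge_close_modules(layer, part, merge_cut=cut)
            counts.append(len(merged.module_ids))
        assert counts[0] >= counts[1] >= counts[2]


class TestModuleTrait:
    def _eig(self, values):
        idx = [f"S{i+1}" for i in range(len(values))]
        return pd.DataFrame({"ME1": values}, index=idx)

    def test_eigengene_equal_to_trait(self):
        v = np.linspace(-1, 1, 10)
        ann = AnnotationTable(
            pd.DataFrame({"t": v}, index=[f"S{i+1}" for i in range(10)])
        )
        rep = module_trait_correlation(self._eig(v), ann)
        assert rep.r.loc["ME1", "t"] == pytest.approx(1.0)
        assert rep.p.loc["ME1", "t"] < 1e-12

    def test_orthogonal_trait_p_one(self):
        v = np.array([1.0, -1.0] * 5)
        t = np.array([1.0, 1.0, -1.0, -1.0] * 2 + [1.0, 1.0])
        ann = AnnotationTable(
            pd.DataFrame({"t": t}, index=[f"S{i+1}" for i in range(10)])
        )
        rep = module_trait_correlation(self._eig(v), ann)
        assert rep.p.loc["ME1", "t"] == pytest.approx(1.0)

    def test_t_distribution_hand_check(self):
        from momicnet._stats import correlation_pvalues

        p = correlation_pvalues(np.array([0.632]), n=10)[0]
        assert p == pytest.approx(0.05, abs=0.002)

    def test_constant_trait_is_nan(self):
        v = np.linspace(0, 1, 10)
        ann = AnnotationTable(
            pd.DataFrame(
                {"c": np.ones(10), "t": v}, index=[f"S{i+1}" for i in range(10)]
            )
        )
        rep = module_trait_correlation(self._eig(v), ann)
        assert np.isnan(rep.r.loc["ME1", "c"])
        assert rep.q.loc["ME1", "t"] <= 1.0

    def test_qualitative_trait_expanded(self, annotation, rng):
        eig = pd.DataFrame(
            {"ME1": rng.normal(size=12)}, index=annotation.sample_ids
        )
        rep = module_trait_correlation(eig, annotation)
        assert {"depth", "site=north", "site=south"} <= set(rep.r.columns)


class TestSampleContributionsAndMembership:
    def test_contributions_table(self, rng, annotation):
        eig = pd.DataFrame(
            {"ME1": rng.normal(size=12)}, index=annotation.sample_ids
        )
        out = sample_contributions(eig, 1, annotation, "site")
        assert len(out) == 12 and "site" in out.columns

    def test_group_trait_separates_contribution_signs(self):
        rng = np.random.default_rng(8)
        group = np.array([1.0] * 15 + [-1.0] * 15)
        x = np.outer(group, np.ones(8)) + rng.normal(size=(30, 8)) * 0.3
        layer = make_layer(x)
        part = ModulePartition(layer.feature_ids, np.ones(8, dtype=int))
        eig = module_eigengenes(layer, part)
        out = sample_contributions(eig, 1)
        means = out["contribution"].groupby(group).mean()
        assert means[1.0] * means[-1.0] < 0

    def test_unknown_module(self, rng, annotation):
        eig = pd.DataFrame(
            {"ME1": rng.normal(size=12)}, index=annotation.sample_ids
        )
        with pytest.raises(KeyError):
            sample_contributions(eig, 9)

    def test_kme_bounds_and_own_module_dominance(self):
        cfg = SyntheticConfig(
            n_samples=50, layers=(LayerSpec("L", 60, (20, 20), 0.7),), seed=2
        )
        layers, _, truth = generate_multiomics(cfg)
        layer = layers[0]
        labels = truth.module_map["L"].to_numpy()
        part = ModulePartition(layer.feature_ids, labels)
        eig = module_eigengenes(layer, part)
        kme = module_membership(layer, eig)
        assert kme.to_numpy().min() >= -1 and kme.to_numpy().max() <= 1
        own = kme.loc[labels == 1, "ME1"].abs().mean()
        other = kme.loc[labels == 2, "ME1"].abs().mean()
        assert own > other


class TestWcnaModel:
    def test_fit_recovers_planted_modules(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = SyntheticConfig(
            n_samples=60, layers=(LayerSpec("L", 150, (40, 40, 40), 0.7),), seed=4
        )
        layers, _, truth = generate_multiomics(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = WCNA(layers[0], NetworkParams(min_module_size=10)).fit("auto")
        ari = adjusted_rand_score(truth.module_map["L"].to_numpy(), res.partition.labels)
        assert ari >= 0.8
        assert set(res.eigengenes.columns) == {
            f"ME{m}" for m in res.partition.module_ids
        }
        summ = res.summary()
        assert summ["n_features"].sum() == 150
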