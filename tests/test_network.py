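"""Correlation network, static-cut clustering, eigengenes, merging, kME."""

import numpy as np
import pandas as pd
import pytest

from coexmod import (
    CorrelationModel,
    assign_membership,
    attach_eigengenes,
    cluster_and_cut,
    compute_eigengene,
    correlation_model,
    merge_modules,
    static_cut_height,
)
from coexmod.datasets import ModuleSet

from conftest import correlated_profiles, make_dataset
from oracles import complete_linkage_partition, pc1_scores


def labels_to_partition(labels: pd.Series) -> set[frozenset]:
    """Positional partition implied by a label series (NA = singleton)."""
    groups: dict = {}
    for i, lab in enumerate(labels):
        key = lab if not pd.isna(lab) else ("NA", i)
        groups.setdefault(key, []).append(i)
    return {frozenset(g) for g in groups.values()}


class TestCorrelationModel:
    @pytest.mark.parametrize(
        "a, b, expected_cor",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # hand evaluation of Pearson
        ],
    )
    def test_pairwise_values(self, a, b, expected_cor):
        data = make_dataset(np.array([a, b], dtype=float))
        model = correlation_model(data)
        assert model.correlation.iloc[0, 1] == pytest.approx(expected_cor, abs=1e-12)
        assert model.distance.iloc[0, 1] == pytest.approx(1 - expected_cor, abs=1e-12)

    def test_symmetric_unit_diagonal_distance_range(self, rng):
        data = make_dataset(rng.normal(size=(20, 8)))
        model = correlation_model(data)
        C = model.correlation.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        D = model.distance.to_numpy()
        assert D.min() >= 0.0 and D.max() <= 2.0

    def test_zero_variance_probe_strict_vs_drop(self, rng):
        X = rng.normal(size=(5, 6))
        X[2] = 7.0
        data = make_dataset(X)
        with pytest.raises(ValueError, match="p0002"):
            correlation_model(data)
        model = correlation_model(data, on_zero_variance="drop")
        assert "p0002" not in model.probe_ids


class TestStaticCutHeight:
    def model_from_pairs(self, pairs: np.ndarray) -> CorrelationModel:
        # symmetric matrix whose upper triangle is exactly `pairs`
        n = int((1 + np.sqrt(1 + 8 * len(pairs))) // 2)
        C = np.eye(n)
        C[np.triu_indices(n, k=1)] = pairs
        C = np.triu(C) + np.triu(C, k=1).T
        ids = [f"p{i}" for i in range(n)]
        return CorrelationModel(pd.DataFrame(C, index=ids, columns=ids))

    def test_constant_correlations_degenerate(self):
        model = self.model_from_pairs(np.full(6, 0.3))
        with pytest.warns(UserWarning, match="degenerate"):
            assert static_cut_height(model, 0.02) == pytest.approx(0.7)

    def test_quantile_convention_on_ten_values(self):
        pairs = np.arange(10) / 10.0  # {0.0, 0.1, ..., 0.9}
        model = self.model_from_pairs(pairs)
        # linear-interpolation 0.8-quantile of the sorted 10-vector
        expected_q = np.quantile(pairs, 0.8, method="linear")
        assert expected_q == pytest.approx(0.72)
        assert static_cut_height(model, 0.2) == pytest.approx(1 - expected_q)

    def test_two_percent_tail_reproduces_characteristic_height(self, rng):
        # correlations built so the 98th percentile sits at 0.359: the cut
        # height 1 - q then lands at the characteristic ~0.641
        n_pairs = 46 * 45 // 2  # 1035
        pairs = rng.uniform(-0.3, 0.35, size=n_pairs)
        k = int(np.ceil(0.02 * n_pairs))
        pairs[-k:] = rng.uniform(0.3592, 0.8, size=k)
        pairs[np.argsort(pairs)[n_pairs - k - 1]] = 0.3588
        model = self.model_from_pairs(pairs)
        assert static_cut_height(model, 0.02) == pytest.approx(0.641, abs=0.005)


class TestClusterAndCut:
    def planted_two_block_model(self, rng):
        prof = correlated_profiles(np.eye(2), 12, rng)
        X = np.vstack(
            [
                prof[0] + rng.normal(0, 0.05, size=(15, 12)),
                prof[1] + rng.normal(0, 0.05, size=(15, 12)),
            ]
        )
        return correlation_model(make_dataset(X))

    def test_two_noise_free_blocks_recovered(self, rng):
        model = self.planted_two_block_model(rng)
        modules = cluster_and_cut(model, cut_height=0.5, min_size=10)
        labels = modules.labels
        assert labels.notna().all()
        assert len(set(labels.iloc[:15])) == 1 and len(set(labels.iloc[15:])) == 1
        assert labels.iloc[0] != labels.iloc[15]

    def test_min_size_boundary_unassigns_small_clusters(self, rng):
        prof = correlated_profiles(np.eye(2), 12, rng)
        X = np.vstack(
            [
                prof[0] + rng.normal(0, 0.05, size=(9, 12)),
                rng.normal(size=(30, 12)),
            ]
        )
        modules = cluster_and_cut(correlation_model(make_dataset(X)), 0.5, min_size=10)
        assert modules.labels.isna().all()
        modules9 = cluster_and_cut(correlation_model(make_dataset(X)), 0.5, min_size=9)
        assert set(modules9.labels.dropna().index) == {f"p{i:04d}" for i in range(9)}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_agglomeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 55))
        X = rng.normal(size=(n, 10))
        if seed % 2:  # mix in block structure half the time
            X[: n // 2] += rng.normal(size=10) * 2
        model = correlation_model(make_dataset(X))
        cut = float(rng.uniform(0.3, 1.3))
        ours = labels_to_partition(cluster_and_cut(model, cut, min_size=1).labels)
        D = model.distance.to_numpy()
        np.fill_diagonal(D, 0.0)
        assert ours == complete_linkage_partition(D, cut)

    def test_merge_heights_monotone(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        model = self.planted_two_block_model(rng)
        D = model.distance.to_numpy()
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="complete")
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


class TestEigengene:
    def test_identical_profiles(self, rng):
        profile = rng.normal(size=10)
        data = make_dataset(np.tile(profile, (6, 1)))
        eig, var = compute_eigengene(data, list(data.probe_ids))
        assert var == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eig.to_numpy(), z, atol=1e-9)

    def test_sign_tie_broken_by_first_loading(self, rng):
        x = rng.normal(size=9)
        x -= x.mean()
        data = make_dataset(np.vstack([x, -x, x, -x]))
        eig, var = compute_eigengene(data, list(data.probe_ids))
        assert var == pytest.approx(1.0)
        # mean standardized profile is 0 => sign fixed by first probe (+x)
        assert np.corrcoef(eig, x)[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_decomposition_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        data = make_dataset(rng.normal(size=(12, 8)))
        eig, _ = compute_eigengene(data, list(data.probe_ids))
        ref = pc1_scores(data.values.to_numpy())
        assert abs(np.corrcoef(eig, ref)[0, 1]) > 1 - 1e-9

    def test_variance_explained_invariant_to_orderings(self, rng):
        X = rng.normal(size=(10, 8))
        data = make_dataset(X)
        _, v0 = compute_eigengene(data, list(data.probe_ids))
        perm_p = rng.permutation(10)
        perm_s = rng.permutation(8)
        shuffled = make_dataset(X[perm_p][:, perm_s])
        _, v1 = compute_eigengene(shuffled, list(shuffled.probe_ids))
        assert v1 == pytest.approx(v0, abs=1e-12)

    def test_too_few_members_rejected(self, rng):
        data = make_dataset(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError, match=">= 2"):
            compute_eigengene(data, ["p0000"])


def build_three_module_dataset(rng, cors=(0.95, 0.90, 0.75), size=8, n_samples=14):
    """Noise-free modules whose eigengene correlations are `cors` exactly."""
    g = np.array(
        [[1.0, cors[0], cors[1]], [cors[0], 1.0, cors[2]], [cors[1], cors[2], 1.0]]
    )
    prof = correlated_profiles(g, n_samples, rng)
    X = np.vstack([np.tile(p, (size, 1)) for p in prof])
    data = make_dataset(X)
    labels = pd.Series(
        ["M1"] * size + ["M2"] * size + ["M3"] * size, index=data.probe_ids
    )
    modules = ModuleSet(labels=labels, cut_height=0.5, min_size=2)
    return data, attach_eigengenes(data, modules)


class TestMergeModules:
    def test_shared_latent_modules_merge_into_one(self, rng):
        data, modules = build_three_module_dataset(rng, cors=(0.999, 0.999, 0.999))
        merged = merge_modules(data, modules, threshold=0.85)
        assert len(merged.eigengenes) == 1
        assert merged.labels.nunique() == 1

    def test_threshold_is_strict(self, rng):
        data, modules = build_three_module_dataset(rng, cors=(0.9, 0.2, 0.1))
        cor = float(
            np.corrcoef(
                modules.eigengenes.loc["M1"], modules.eigengenes.loc["M2"]
            )[0, 1]
        )
        # exactly at the threshold: "exceeded" means strictly greater
        merged = merge_modules(data, modules, threshold=cor)
        assert len(merged.eigengenes) == 3
        assert merged.merge_log == []

    def test_greedy_order_and_recomputation(self, rng):
        # three modules with pairwise eigengene correlations 0.95/0.90/0.75
        # (the closest realizable triple with one dominant pair: two pairs at
        # 0.95 and 0.90 force the third above ~0.72 by positive-definiteness)
        data, modules = build_three_module_dataset(rng, cors=(0.95, 0.90, 0.75))
        merged = merge_modules(data, modules, threshold=0.85)
        # first merge must take the highest pair (M1-M2 at 0.95)
        first = merged.merge_log[0]
        assert set(first["merged"]) == {"M1", "M2"}
        assert first["correlation"] == pytest.approx(0.95, abs=1e-9)
        # oracle: replay the greedy process by hand to decide the second step
        e12, _ = compute_eigengene(data, [f"p{i:04d}" for i in range(16)])
        c = float(np.corrcoef(e12, modules.eigengenes.loc["M3"])[0, 1])
        if c > 0.85:
            assert len(merged.merge_log) == 2
        else:
            assert len(merged.merge_log) == 1
            assert set(merged.eigengenes.index) == {"M1", "M3"}

    def test_no_pair_exceeds_threshold_after_merging(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            data, modules = build_three_module_dataset(
                r, cors=tuple(r.uniform(0.0, 0.99, size=3))
            )
            merged = merge_modules(data, modules, threshold=0.85)
            E = merged.eigengenes.to_numpy()
            if len(E) > 1:
                C = np.corrcoef(E)
                assert C[np.triu_indices_from(C, k=1)].max() <= 0.85 + 1e-12


class TestAssignMembership:
    def test_probe_identical_to_eigengene_assigned(self, rng):
        data, modules = build_three_module_dataset(rng, cors=(0.3, 0.2, 0.1))
        mem = assign_membership(data, modules, alpha=0.05)
        first = data.probe_ids[0]  # an M1 member, noise-free copy of the latent
        assert abs(mem.kme.loc[first, "M1"]) == pytest.approx(1.0, abs=1e-9)
        assert mem.p_value.loc[first, "M1"] == 0.0
        assert mem.assigned.loc[first] == "M1"

    def test_all_negative_kme_never_assigned(self, rng):
        data, modules = build_three_module_dataset(rng, cors=(0.3, 0.2, 0.1))
        flipped = data.values.copy()
        flipped.loc["anti"] = -data.values.iloc[0]
        meta = data.sample_meta
        from coexmod import ExpressionDataset

        data2 = ExpressionDataset(flipped, meta)
        modules2 = ModuleSet(
            labels=modules.labels.reindex(flipped.index),
            cut_height=0.5,
            min_size=2,
            eigengenes=modules.eigengenes,
            var_explained=modules.var_explained,
        )
        mem = assign_membership(data2, modules2, alpha=0.05)
        assert (mem.kme.loc["anti"] < 0).all()
        assert pd.isna(mem.assigned.loc["anti"])

    def test_bonferroni_threshold_arithmetic(self, rng):
        data = make_dataset(rng.normal(size=(1000, 10)))
        labels = pd.Series(pd.NA, index=data.probe_ids, dtype="object")
        labels.iloc[:100] = [f"M{1 + i % 10}" for i in range(100)]
        modules = attach_eigengenes(
            data, ModuleSet(labels=labels, cut_height=0.5, min_size=2)
        )
        mem = assign_membership(data, modules, alpha=0.05)
        assert mem.bonferroni_alpha == pytest.approx(5e-6)

    def test_assignment_refines_strong_cluster_structure(self, rng):
        # noise-free distinct modules: every clustered probe keeps its label
        data, modules = build_three_module_dataset(rng, cors=(0.3, 0.2, 0.1))
        mem = assign_membership(data, modules, alpha=0.05)
        agree = mem.assigned.loc[modules.labels.index] == modules.labels
        assert agree.all()

    def test_unclustered_probes_receive_kme_and_can_join(self, rng):
        data, modules = build_three_module_dataset(rng, cors=(0.3, 0.2, 0.1))
        from coexmod import ExpressionDataset

        values = data.values.copy()
        values.loc["extra"] = values.iloc[0] + rng.normal(0, 0.01, size=values.shape[1])
        data2 = ExpressionDataset(values, data.sample_meta)
        modules2 = ModuleSet(
            labels=modules.labels.reindex(values.index),
            cut_height=0.5,
            min_size=2,
            eigengenes=modules.eigengenes,
        )
        mem = assign_membership(data2, modules2, alpha=0.05)
        assert "extra" in mem.kme.index
        assert mem.assigned.loc["extra"] == "M1"
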