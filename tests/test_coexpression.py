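import numpy as np
import pandas as pd
import pytest

from mirtfnet.coexpression import (
    CoexpressionResult,
    adjacency,
    detect_modules,
    module_eigengene,
    module_trait_stats,
    pick_soft_threshold,
    run_coexpression,
    select_trait_module,
    tom_similarity,
)
from mirtfnet.preprocess import ExpressionProfile

from conftest import make_block_profile
from oracles import tom_oracle


def profile_from(values: np.ndarray, prefix="g") -> ExpressionProfile:
    n_genes, n_samples = values.shape
    frame = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    group = pd.Series(
        [1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2), index=frame.columns
    )
    return ExpressionProfile(frame, group)


def hub_profile(n_genes=150, n_samples=60, n_factors=3, seed=42) -> ExpressionProfile:
    """Noisy copies of a few latent factors with heterogeneous loadings."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_factors, n_samples))
    rows = []
    for _ in range(n_genes):
        factor = rng.integers(n_factors)
        loading = rng.uniform(0.2, 3.0)
        rows.append(loading * z[factor] + rng.normal(size=n_samples))
    return profile_from(np.array(rows))


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.arange(10.0)
        prof = profile_from(np.array([x, 2 * x + 3]))
        for beta in (1, 5, 12):
            assert adjacency(prof, beta).iloc[0, 1] == pytest.approx(1.0)

    def test_unsigned_power(self):
        rng = np.random.default_rng(4)
        prof = profile_from(rng.normal(size=(5, 30)))
        cor = np.corrcoef(prof.values.to_numpy())
        adj = adjacency(prof, 2).to_numpy()
        expect = np.abs(cor) ** 2
        np.fill_diagonal(expect, 0.0)
        np.testing.assert_allclose(adj, expect, atol=1e-12)

    def test_negative_correlation_enters_unsigned(self):
        x = np.random.default_rng(1).normal(size=20)
        prof = profile_from(np.array([x, -x]))
        assert adjacency(prof, 2).iloc[0, 1] == pytest.approx(1.0)

    def test_zero_variance_gene_named(self):
        prof = profile_from(np.vstack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="g0"):
            adjacency(prof, 2)

    def test_raising_beta_never_increases_entries(self):
        rng = np.random.default_rng(9)
        prof = profile_from(rng.normal(size=(12, 25)))
        prev = adjacency(prof, 1).to_numpy()
        for beta in (2, 4, 8):
            nxt = adjacency(prof, beta).to_numpy()
            assert np.all(nxt <= prev + 1e-12)
            prev = nxt


class TestTOM:
    def test_two_gene_unit_adjacency(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert tom_similarity(a)[0, 1] == pytest.approx(1.0)

    def test_unit_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(tom_similarity(a), np.ones((3, 3)), atol=1e-12)

    def test_empty_adjacency_gives_identity_like(self):
        tom = tom_similarity(np.zeros((4, 4)))
        np.testing.assert_allclose(tom, np.eye(4), atol=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.uniform(0, 1, size=(15, 15))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            np.testing.assert_allclose(tom_similarity(a), tom_oracle(a), atol=1e-12)


class TestSoftThreshold:
    def test_hub_topology_regression_fixture(self):
        scan, beta = pick_soft_threshold(hub_profile(seed=42), betas=range(1, 21))
        assert beta == 9  # frozen for this seed
        assert scan.loc[scan["beta"] == beta, "fit_r2"].iloc[0] >= 0.85

    def test_mean_connectivity_decreases_with_beta(self):
        scan, _ = pick_soft_threshold(hub_profile(seed=42), betas=range(1, 21))
        assert np.all(np.diff(scan["mean_k"]) <= 1e-9)

    def test_independent_genes_fit_poorly_at_small_beta(self):
        fits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = profile_from(rng.normal(size=(40, 30)))
            scan, _ = pick_soft_threshold(prof, betas=[1, 2, 3])
            fits.append(scan["fit_r2"].max())
        assert np.median(fits) < 0.5

    def test_needs_three_betas(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(hub_profile(), betas=[6, 7])


class TestDetectModules:
    def run(self, profile, beta=6, **kwargs):
        return detect_modules(tom_similarity(adjacency(profile, beta)), **kwargs)

    def test_two_planted_blocks_recovered(self):
        prof, members = make_block_profile([(30, 0.81), (30, 0.81)], 0, seed=42)
        labels = self.run(prof)
        found = [set(labels.index[labels == m]) for m in set(labels) if m != "grey"]
        assert len(found) == 2
        for truth in members:
            best = max(
                len(truth & f) / len(truth | f) for f in found
            )
            assert best >= 0.9

    def test_uncorrelated_genes_all_grey(self):
        rng = np.random.default_rng(42)
        prof = profile_from(rng.normal(size=(50, 40)))
        labels = self.run(prof)
        assert set(labels) == {"grey"}

    def test_single_block_with_noise(self):
        prof, members = make_block_profile([(25, 0.81)], 10, seed=42)
        labels = self.run(prof)
        modules = [m for m in set(labels) if m != "grey"]
        assert len(modules) == 1
        found = set(labels.index[labels == modules[0]])
        assert len(found & members[0]) >= 23

    def test_too_few_genes_all_grey_with_warning(self):
        rng = np.random.default_rng(0)
        prof = profile_from(rng.normal(size=(5, 20)))
        with pytest.warns(UserWarning, match="min_module_size"):
            labels = self.run(prof, min_module_size=20)
        assert set(labels) == {"grey"}

    def test_permutation_equivariance(self):
        prof, _ = make_block_profile([(25, 0.81), (22, 0.75)], 12, seed=3)
        labels = self.run(prof)
        rng = np.random.default_rng(5)
        perm = rng.permutation(prof.n_features)
        permuted = ExpressionProfile(prof.values.iloc[perm], prof.group)
        labels_perm = self.run(permuted)

        def partition(lab):
            return {
                frozenset(lab.index[lab == m]) for m in set(lab) if m != "grey"
            }

        assert partition(labels) == partition(labels_perm)


class TestEigengene:
    def test_copies_of_one_profile(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=30)
        prof = profile_from(np.array([z, 2 * z + 1, 0.5 * z - 3]))
        labels = pd.Series("M1", index=prof.feature_ids)
        eg = module_eigengene(prof, labels).loc["M1"].to_numpy()
        assert abs(np.corrcoef(eg, z)[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(eg) == pytest.approx(1.0)

    def test_antagonistic_pair_sign_rule(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=24)
        prof = profile_from(np.array([x, -x]))
        labels = pd.Series("M1", index=prof.feature_ids)
        eg = module_eigengene(prof, labels).loc["M1"].to_numpy()
        assert abs(np.corrcoef(eg, x)[0, 1]) == pytest.approx(1.0)
        # sign: non-negative correlation with the average standardized profile
        xs = (prof.values - prof.values.mean(axis=1).to_numpy()[:, None]).div(
            prof.values.std(axis=1, ddof=1), axis=0
        )
        assert np.dot(eg, xs.mean(axis=0)) >= -1e-12

    def test_explains_at_least_any_single_gene_direction(self):
        rng = np.random.default_rng(13)
        prof = profile_from(rng.normal(size=(6, 40)) + rng.normal(size=40))
        labels = pd.Series("M1", index=prof.feature_ids)
        eg = module_eigengene(prof, labels).loc["M1"].to_numpy()
        x = prof.values.to_numpy()
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        var_eg = np.sum((xs @ eg) ** 2)
        for row in xs:
            direction = row / np.linalg.norm(row)
            assert var_eg >= np.sum((xs @ direction) ** 2) - 1e-9


class TestTraitStats:
    def test_eigengene_equal_to_centered_labels(self):
        g = pd.Series([1] * 5 + [0] * 5, index=[f"s{i}" for i in range(10)])
        eg = pd.DataFrame([(g - g.mean()).to_numpy()], index=["M1"], columns=g.index)
        r, p = module_trait_stats(eg, g)
        assert r["M1"] == pytest.approx(1.0)
        assert p["M1"] < 1e-12

    def test_orthogonal_eigengene(self):
        g = pd.Series([1, 1, 0, 0], index=list("abcd"))
        eg = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]], index=["M1"], columns=g.index)
        r, p = module_trait_stats(eg, g)
        assert r["M1"] == pytest.approx(0.0, abs=1e-12)
        assert p["M1"] == pytest.approx(1.0)

    def test_t_transform_closed_form(self):
        # r = 0.5 with n = 27 gives t = 2.887 on 25 df, two-sided p = 0.0079
        rng = np.random.default_rng(21)
        n = 27
        g = pd.Series([1] * 13 + [0] * 14, index=[f"s{i}" for i in range(n)])
        gc = (g - g.mean()) / g.std()
        noise = rng.normal(size=n)
        noise = noise - noise.mean()
        noise -= gc.to_numpy() * np.dot(noise, gc.to_numpy()) / np.dot(gc, gc)
        target_r = 0.5
        e = target_r * gc.to_numpy() / np.linalg.norm(gc) + np.sqrt(
            1 - target_r**2
        ) * noise / np.linalg.norm(noise)
        eg = pd.DataFrame([e], index=["M1"], columns=g.index)
        r, p = module_trait_stats(eg, g)
        assert r["M1"] == pytest.approx(0.5, abs=1e-9)
        assert p["M1"] == pytest.approx(0.0079, abs=2e-4)


class TestSelectTraitModule:
    def make_result(self, r_by_module, sizes):
        labels = pd.Series(
            sum(([m] * n for m, n in sizes.items()), []),
            index=[f"g{i}" for i in range(sum(sizes.values()))],
        )
        r = pd.Series(r_by_module)
        return CoexpressionResult(labels, pd.DataFrame(), r, r * 0, beta_used=6)

    def test_single_module(self):
        result = self.make_result({"M1": 0.4}, {"M1": 20})
        assert select_trait_module(result)[0] == "M1"

    def test_absolute_value_wins(self):
        result = self.make_result({"M1": 0.9, "M2": -0.95}, {"M1": 20, "M2": 20})
        assert select_trait_module(result)[0] == "M2"

    def test_tie_broken_by_size(self):
        result = self.make_result({"M1": 0.9, "M2": 0.9}, {"M1": 10, "M2": 30})
        assert select_trait_module(result)[0] == "M2"

    def test_all_grey_is_error(self):
        labels = pd.Series("grey", index=["g0", "g1"])
        result = CoexpressionResult(
            labels, pd.DataFrame(), pd.Series(dtype=float), pd.Series(dtype=float), 6
        )
        with pytest.raises(ValueError):
            select_trait_module(result)


def test_trait_module_recovery_end_to_end():
    """A planted trait-correlated module is found and ranked first."""
    from mirtfnet.synthetic import generate_expression_cohort

    profile, truth = generate_expression_cohort(
        n_features=160,
        n_tumor=30,
        n_normal=30,
        n_de=0,
        effect=0.0,
        n_modules=1,
        module_size=40,
        module_trait_r=0.9,
        seed=7,
    )
    result, _ = run_coexpression(profile, betas=range(1, 13), min_module_size=20)
    module, members = select_trait_module(result)
    planted = truth.module_members["mod1"]
    jaccard = len(planted & set(members)) / len(planted | set(members))
    assert jaccard >= 0.9
    assert abs(result.module_trait_r[module]) > 0.7
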