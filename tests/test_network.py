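"""Co-expression network: adjacency/TOM formulas against brute-force
oracles, module detection and merging, eigengenes, module-trait
correlation and overlap tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import colonysig as cs
from colonysig.network import (BACKGROUND, CoexpressionNetwork, _eigengene_table,
                               module_set_overlap)


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


def make_module_expr(n_modules=5, module_size=40, n_background=800,
                     n_samples=64, seed=0, factor_sd=1.0):
    """Expression with planted correlated blocks over iid background."""
    rng = np.random.default_rng(seed)
    blocks, truth = [], []
    for m in range(n_modules):
        latent = rng.normal(0, factor_sd, n_samples)
        load = rng.uniform(0.6, 1.0, module_size)
        block = load[:, None] * latent + rng.normal(0, 0.5, (module_size, n_samples))
        blocks.append(block)
        truth += [f"M{m + 1}"] * module_size
    background = rng.normal(0, 1, (n_background, n_samples))
    truth += [BACKGROUND] * n_background
    expr = _expr(np.vstack(blocks + [background]))
    return expr, pd.Series(truth, index=expr.index)


class TestNetworkGeneFilter:
    def test_all_high_retained(self):
        counts = _expr(np.full((1, 20), 50))
        assert len(cs.network_gene_filter(counts)) == 1

    def test_91_of_100_low_removed(self):
        row = np.r_[np.full(91, 5), np.full(9, 50)]
        assert len(cs.network_gene_filter(_expr(row[None, :]))) == 0

    def test_exactly_90_low_retained(self):
        row = np.r_[np.full(90, 5), np.full(10, 50)]
        assert len(cs.network_gene_filter(_expr(row[None, :]))) == 1


class TestVarianceStabilize:
    def test_zero_maps_to_zero(self):
        counts = _expr([[0, 10], [5, 5]])
        out = cs.variance_stabilize(counts, sizes=np.ones(2))
        assert out.iloc[0, 0] == 0.0

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(2)
        counts = _expr(rng.poisson(30, (50, 10)))
        sf = cs.size_factors(counts)
        a = cs.variance_stabilize(counts, sizes=sf)
        b = cs.variance_stabilize(counts * 2, sizes=np.asarray(sf) * 2)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("method", ["log", "asinh"])
    def test_flattens_variance_mean_slope(self, method):
        rng = np.random.default_rng(3)
        mus = np.exp(rng.uniform(np.log(5), np.log(500), 300))
        counts = rng.negative_binomial(1 / 0.15, 1 / (1 + 0.15 * mus[:, None]),
                                       size=(300, 40))
        counts = _expr(counts)
        def slope(mat):
            m, s = mat.mean(axis=1), mat.std(axis=1)
            keep = (m > 0) & (s > 0)
            return stats.linregress(np.log(m[keep]), np.log(s[keep])).slope
        raw = slope(counts)
        stab = slope(cs.variance_stabilize(counts, sizes=np.ones(40), method=method))
        assert abs(stab) < abs(raw)


class TestAdjacency:
    def test_signed_hybrid_rules(self):
        t = np.linspace(0, 2 * np.pi, 30)
        expr = _expr([np.sin(t), np.sin(t), -np.sin(t)])
        adj = cs.signed_hybrid_adjacency(expr, beta=6)
        assert adj.iloc[0, 1] == pytest.approx(1.0)
        assert adj.iloc[0, 2] == 0.0
        assert np.allclose(np.diag(adj), 1.0)

    def test_power_applied(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        y = 0.5 * x / np.std(x)
        y = 0.5 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.25) * rng.normal(size=2000)
        expr = _expr([x, y])
        adj = cs.signed_hybrid_adjacency(expr, beta=6)
        r = np.corrcoef(x, y)[0, 1]
        assert adj.iloc[0, 1] == pytest.approx(r**6, rel=1e-9)

    def test_beta_validation(self):
        with pytest.raises(ValueError):
            cs.signed_hybrid_adjacency(_expr(np.eye(3)), beta=0)


class TestPickSoftThreshold:
    def test_scale_free_input_selects_low_power(self):
        expr, _ = make_module_expr(6, 30, 200, 80, seed=5)
        res = cs.pick_soft_threshold(expr, candidate_powers=(2, 4, 6, 8, 10))
        assert res.beta in (2, 4, 6, 8, 10)

    def test_independent_genes_flagged(self):
        rng = np.random.default_rng(6)
        expr = _expr(rng.normal(size=(60, 200)))
        with pytest.warns(UserWarning):
            res = cs.pick_soft_threshold(expr, candidate_powers=(2, 4, 6))
        assert not res.reached_target

    def test_explicit_power_bypasses_selection(self):
        expr, _ = make_module_expr(3, 20, 50, 40, seed=7)
        model = CoexpressionNetwork(expr, power=6.0)
        assert model.power == 6.0


class TestTopologicalOverlap:
    def test_two_gene_formula(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        tom = cs.topological_overlap(A)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_identical_rows_full_overlap(self):
        # binary adjacency with identical rows and a_ij = 1: full overlap
        A = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            A[i, j] = A[j, i] = 1.0
        np.fill_diagonal(A, 1.0)
        tom = cs.topological_overlap(A)
        assert tom[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, (6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = cs.topological_overlap(A)
        n = 6
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                ki = sum(A[i, u] for u in range(n) if u != i)
                kj = sum(A[j, u] for u in range(n) if u != j)
                expected = (shared + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0, 1, (30, 30))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = cs.topological_overlap(A)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1


class TestDetectAndMerge:
    def test_planted_blocks_recovered(self):
        expr, truth = make_module_expr(5, 40, 800, 64, seed=10)
        adj = cs.signed_hybrid_adjacency(expr, beta=6)
        tom = cs.topological_overlap(adj)
        labels = cs.detect_modules(tom, min_module_size=20)
        ari = adjusted_rand_score(truth.loc[labels.index], labels)
        assert ari >= 0.8

    def test_single_latent_factor_single_module(self):
        rng = np.random.default_rng(11)
        latent = rng.normal(size=50)
        expr = _expr(np.outer(rng.uniform(0.8, 1.2, 30), latent)
                     + rng.normal(0, 0.1, (30, 50)))
        adj = cs.signed_hybrid_adjacency(expr, beta=6)
        labels = cs.detect_modules(cs.topological_overlap(adj), min_module_size=5)
        assert labels.nunique() == 1 and labels.iloc[0] != BACKGROUND

    def test_background_only_goes_grey(self):
        rng = np.random.default_rng(12)
        expr = _expr(rng.normal(size=(80, 60)))
        adj = cs.signed_hybrid_adjacency(expr, beta=6)
        labels = cs.detect_modules(cs.topological_overlap(adj), min_module_size=25)
        assert (labels == BACKGROUND).mean() > 0.9

    def test_shared_latent_modules_merge(self):
        rng = np.random.default_rng(13)
        latent = rng.normal(size=60)
        a = np.outer(rng.uniform(0.7, 1.0, 25), latent) + rng.normal(0, 0.4, (25, 60))
        b = np.outer(rng.uniform(0.7, 1.0, 25), latent) + rng.normal(0, 0.4, (25, 60))
        expr = _expr(np.vstack([a, b]))
        labels = pd.Series(["A"] * 25 + ["B"] * 25, index=expr.index)
        merged = cs.merge_modules(expr, labels, merge_threshold=0.75)
        assert merged.nunique() == 1

    def test_no_merge_below_threshold(self):
        expr, truth = make_module_expr(3, 25, 0, 60, seed=14)
        merged = cs.merge_modules(expr, truth, merge_threshold=0.75)
        assert merged.nunique() == truth.nunique()

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_fixed_point_invariant(self, seed):
        """After merging, no eigengene pair correlates above threshold."""
        expr, truth = make_module_expr(4, 20, 100, 50, seed=seed, factor_sd=0.8)
        adj = cs.signed_hybrid_adjacency(expr, beta=6)
        labels = cs.detect_modules(cs.topological_overlap(adj), min_module_size=10)
        merged = cs.merge_modules(expr, labels, merge_threshold=0.75)
        eig = _eigengene_table(expr, merged)
        if eig.shape[1] >= 2:
            cor = eig.corr().to_numpy()
            np.fill_diagonal(cor, 0.0)
            assert cor.max() <= 0.75 + 1e-9


class TestEigengene:
    def test_single_gene_module_is_standardized_profile(self):
        rng = np.random.default_rng(15)
        expr = _expr(rng.normal(size=(3, 20)))
        eig = cs.module_eigengene(expr, ["g0"])
        z = (expr.loc["g0"] - expr.loc["g0"].mean()) / expr.loc["g0"].std(ddof=0)
        z = z / np.linalg.norm(z)
        assert np.allclose(np.abs(eig), np.abs(z), atol=1e-9)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(16)
        expr = _expr(rng.normal(size=(12, 25)))
        eig = cs.module_eigengene(expr, list(expr.index))
        vals = expr.to_numpy()
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        assert np.allclose(np.abs(eig), np.abs(vt[0]), atol=1e-9)

    def test_duplicated_gene_set_invariance(self):
        rng = np.random.default_rng(17)
        latent = rng.normal(size=30)
        expr = _expr(np.outer(np.ones(4), latent) + rng.normal(0, 0.1, (4, 30)))
        e1 = cs.module_eigengene(expr, list(expr.index))
        dup = pd.concat([expr, expr.set_index(expr.index + "_copy")])
        e2 = cs.module_eigengene(dup, list(dup.index))
        assert np.allclose(e1, e2, atol=1e-9)

    def test_sign_aligned_to_mean_profile(self):
        rng = np.random.default_rng(18)
        latent = rng.normal(size=40)
        expr = _expr(np.outer(rng.uniform(0.5, 1, 10), latent) + rng.normal(0, 0.2, (10, 40)))
        eig = cs.module_eigengene(expr, list(expr.index))
        zmean = (expr - expr.mean(axis=1).values[:, None]).mean(axis=0)
        assert np.corrcoef(eig, zmean)[0, 1] > 0


class TestModuleTrait:
    def test_identity_trait(self):
        rng = np.random.default_rng(19)
        eig = pd.DataFrame({"M1": rng.normal(size=30)})
        traits = pd.DataFrame({"t": eig["M1"]})
        table = cs.module_trait_correlation(eig, traits)
        assert table.r.loc["M1", "t"] == pytest.approx(1.0)
        assert table.p.loc["M1", "t"] < 1e-20

    def test_effort_module_power_at_study_size(self):
        """A planted effort-coupled module reaches |r| >= 0.4 at n=64 in
        >= 80% of simulations."""
        hits = 0
        n_sims = 50
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            effort = rng.uniform(0, 1, 64)
            z = (effort - effort.mean()) / effort.std()
            latent = 0.8 * z + 0.6 * rng.normal(size=64)
            expr = _expr(np.outer(rng.uniform(0.6, 1.0, 40), latent)
                         + rng.normal(0, 0.5, (40, 64)))
            eig = cs.module_eigengene(expr, list(expr.index))
            r, _ = stats.pearsonr(eig, effort)
            hits += abs(r) >= 0.4
        assert hits >= 0.8 * n_sims

    def test_null_p_uniform(self):
        rng = np.random.default_rng(20)
        ps = []
        for _ in range(1000):
            e = rng.normal(size=40)
            t = rng.normal(size=40)
            ps.append(stats.pearsonr(e, t).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_trait_flagged_nan(self):
        eig = pd.DataFrame({"M1": np.arange(10.0)})
        traits = pd.DataFrame({"t": np.ones(10)})
        table = cs.module_trait_correlation(eig, traits)
        assert np.isnan(table.r.loc["M1", "t"])

    def test_bh_is_across_all_cells(self):
        rng = np.random.default_rng(21)
        eig = pd.DataFrame(rng.normal(size=(30, 3)), columns=["M1", "M2", "M3"])
        traits = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        table = cs.module_trait_correlation(eig, traits)
        flat = table.p.to_numpy().ravel()
        assert np.allclose(np.sort(table.p_adj.to_numpy().ravel()),
                           np.sort(cs.bh_adjust(flat)), equal_nan=True)


class TestModuleMembership:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(22)
        e = pd.Series(rng.normal(size=20), index=[f"s{j}" for j in range(20)])
        expr = pd.DataFrame([e, -e], index=["up", "down"])
        kme = cs.module_membership(expr, e)
        assert kme["up"] == pytest.approx(1.0)
        assert kme["down"] == pytest.approx(-1.0)

    def test_planted_genes_have_higher_kme(self):
        expr, truth = make_module_expr(2, 30, 100, 50, seed=23)
        m1 = truth.index[truth == "M1"]
        eig = cs.module_eigengene(expr, m1)
        kme = cs.module_membership(expr, eig).abs()
        assert kme.loc[m1].mean() > kme.loc[truth == BACKGROUND].mean() + 0.3


class TestModuleSetOverlap:
    def test_identical_sets_minimal_p(self):
        universe = [f"g{i}" for i in range(100)]
        p = module_set_overlap(universe[:10], universe[:10], universe)
        assert p < 1e-10

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(24)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            universe = [f"g{i}" for i in range(n)]
            a = list(rng.choice(universe, size=int(rng.integers(1, n // 2)), replace=False))
            b = list(rng.choice(universe, size=int(rng.integers(1, n // 2)), replace=False))
            p = module_set_overlap(a, b, universe)
            x = len(set(a) & set(b))
            pmf = stats.hypergeom(n, len(a), len(b))
            obs = pmf.pmf(x)
            total = sum(pmf.pmf(k) for k in range(0, min(len(a), len(b)) + 1)
                        if pmf.pmf(k) <= obs * (1 + 1e-9))
            assert p == pytest.approx(total, rel=1e-6)

    def test_expected_overlap_near_one(self):
        universe = [f"g{i}" for i in range(1000)]
        a = universe[:100]
        b = universe[90:190]  # overlap 10 = expected 100*100/1000
        assert module_set_overlap(a, b, universe) > 0.5

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            module_set_overlap([], [], [])


class TestEndToEnd:
    def test_model_fit_on_planted_data(self):
        expr, truth = make_module_expr(3, 30, 150, 60, seed=25)
        rng = np.random.default_rng(26)
        traits = pd.DataFrame({"effort": rng.uniform(0, 1, 60)}, index=expr.columns)
        net = CoexpressionNetwork(expr, power=6, min_module_size=15, traits=traits).fit()
        found = net.assignments
        ari = adjusted_rand_score(truth.loc[found.index], found)
        assert ari >= 0.8
        assert set(net.eigengenes.columns) == set(m for m in found.unique()
                                                  if m != BACKGROUND)
        assert net.module_trait is not None
        print(net.summary())
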