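"""Coexpression network: adjacency, TOM oracle, modules, eigengenes, MPV mode."""

import numpy as np
import pandas as pd
import pytest

from heteroseq.network import (
    InsufficientSamplesError,
    NetworkConfig,
    UNASSIGNED,
    adjacency,
    detect_modules,
    fit_modules,
    module_eigengene,
    module_trait,
    mpv_transform,
    tom_similarity,
)
from heteroseq.simulate import SimulationConfig, simulate_coexpression


def tom_oracle(a):
    """Double-loop unsigned TOM, independent of the vectorized path."""
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0  # diagonal is 1
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def _expr(n_genes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestAdjacency:
    def test_perfect_and_anti_correlation_give_one(self):
        x = np.arange(6, dtype=float)
        expr = pd.DataFrame([x, 2 * x + 1, -x + 3], index=["a", "b", "c"])
        adj = adjacency(expr, beta=11)
        assert adj.loc["a", "b"] == pytest.approx(1.0)
        assert adj.loc["a", "c"] == pytest.approx(1.0)  # unsigned network

    def test_soft_threshold_power(self):
        # two genes correlated at exactly 0.5 via a shared component
        assert 0.5**11 == pytest.approx(4.8828125e-4)
        expr = _expr(10, 30, seed=1)
        adj = adjacency(expr, beta=11)
        corr = np.corrcoef(expr.to_numpy())
        assert adj.to_numpy() == pytest.approx(np.abs(corr) ** 11, abs=1e-12)

    def test_zero_variance_genes_removed(self):
        expr = _expr(4, 10)
        expr.loc["g0"] = 7.0
        adj = adjacency(expr, beta=2)
        assert "g0" not in adj.index

    def test_too_few_samples(self):
        with pytest.raises(InsufficientSamplesError):
            adjacency(_expr(5, 2), beta=2)


class TestTOM:
    def test_complete_triangle(self):
        a = np.ones((3, 3))
        tom = tom_similarity(pd.DataFrame(a))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_isolated_pair(self):
        a = np.eye(4)
        tom = tom_similarity(pd.DataFrame(a))
        assert tom.iloc[0, 1] == pytest.approx(0.0)
        assert tom.iloc[0, 0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a))
        assert tom.to_numpy() == pytest.approx(tom_oracle(a), abs=1e-10)

    def test_bounds_and_symmetry(self):
        adj = adjacency(_expr(20, 15, seed=2), beta=6)
        tom = tom_similarity(adj).to_numpy()
        assert ((tom >= 0) & (tom <= 1)).all()
        assert tom == pytest.approx(tom.T)


class TestModules:
    def test_fewer_genes_than_min_size_all_unassigned(self):
        adj = adjacency(_expr(5, 10), beta=2)
        tom = tom_similarity(adj)
        labels = detect_modules(tom, NetworkConfig(beta=2, min_module_size=50))
        assert (labels == UNASSIGNED).all()

    def test_two_planted_blocks_recovered_exactly(self):
        cfg = SimulationConfig(
            n_genes=30, seed=5, module_spec=[(10, 1.0, 0.0), (10, 1.0, 0.0)]
        )
        expr, _, truth = simulate_coexpression(cfg)
        res = fit_modules(expr, NetworkConfig(beta=6, min_module_size=5, cut_height=0.9))
        members = truth.gene_truth["module"] != "none"
        got = res.labels[members]
        # each planted module maps to exactly one detected label
        mapping = truth.gene_truth.loc[members, "module"].groupby(got).nunique()
        assert set(got) <= {"M1", "M2"}
        assert (mapping == 1).all()

    def test_rerun_identical_labels(self):
        adj = adjacency(_expr(30, 12, seed=3), beta=4)
        tom = tom_similarity(adj)
        cfg = NetworkConfig(beta=4, min_module_size=5, cut_height=0.99)
        assert detect_modules(tom, cfg).equals(detect_modules(tom, cfg))


class TestEigengene:
    def test_identical_genes_recover_common_profile(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        expr = pd.DataFrame([profile, profile, profile], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(5)])
        eig, var = module_eigengene(expr, ["a", "b", "c"])
        z = (profile - profile.mean()) / profile.std()
        assert var == pytest.approx(1.0)
        assert np.corrcoef(eig, z)[0, 1] == pytest.approx(1.0)

    def test_two_gene_closed_form(self):
        # standardized 2-gene module: first PC direction (1,1)/sqrt(2) when
        # correlation positive; variance explained (1+r)/2
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = 0.8 * x + 0.6 * rng.normal(size=20)
        expr = pd.DataFrame([x, y], index=["a", "b"], columns=[f"s{i}" for i in range(20)])
        eig, var = module_eigengene(expr, ["a", "b"])
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        r = float(np.corrcoef(x, y)[0, 1])
        assert var == pytest.approx((1 + r) / 2)
        expected = zx + zy
        expected /= np.linalg.norm(expected)
        assert eig.to_numpy() == pytest.approx(expected, abs=1e-8)

    def test_sign_orientation_stable_under_member_flips(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(4, 12))
        expr = pd.DataFrame(base, index=list("abcd"))
        eig1, _ = module_eigengene(expr, list("abcd"))
        eig2, _ = module_eigengene(-expr, list("abcd"))
        assert np.corrcoef(eig1, -eig2)[0, 1] == pytest.approx(1.0)

    def test_constant_module_rejected(self):
        expr = pd.DataFrame(np.ones((2, 5)), index=["a", "b"])
        with pytest.raises(ValueError):
            module_eigengene(expr, ["a", "b"])


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(6)
        eig = pd.DataFrame([rng.normal(size=10)], index=["M1"], columns=[f"s{i}" for i in range(10)])
        trait = pd.Series(eig.loc["M1"].to_numpy(), index=eig.columns)
        res = module_trait(eig, trait)
        assert res.loc["M1", "r"] == pytest.approx(1.0)
        assert res.loc["M1", "p"] < 1e-10

    def test_orthogonal_trait_zero_r(self):
        e = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        t = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0]) - 1 / 3
        t -= t @ e / (e @ e) * e  # explicit orthogonalization
        eig = pd.DataFrame([e], index=["M1"], columns=[f"s{i}" for i in range(6)])
        res = module_trait(eig, pd.Series(t, index=eig.columns))
        assert res.loc["M1", "r"] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_t_transform(self):
        # r = 0.8 at n = 10: t = 0.8 sqrt(8 / 0.36) = 3.771, p ~ 0.0055
        from scipy import stats
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        eig = pd.DataFrame([x], index=["M1"], columns=[f"s{i}" for i in range(10)])
        res = module_trait(eig, pd.Series(y, index=eig.columns))
        r = res.loc["M1", "r"]
        t = r * np.sqrt(8 / (1 - r**2))
        assert res.loc["M1", "p"] == pytest.approx(2 * stats.t.sf(abs(t), df=8), rel=1e-9)
        t_ref = 0.8 * np.sqrt(8 / 0.36)
        assert t_ref == pytest.approx(3.771, abs=2e-3)
        assert 2 * stats.t.sf(t_ref, df=8) == pytest.approx(0.0055, abs=5e-4)


class TestMPVTransform:
    def test_hybrid_at_midparent_gives_zeros(self, toy_fpkm):
        fpkm, samples, design = toy_fpkm
        out = mpv_transform(fpkm, samples, design)
        assert out.loc["AE", "g2"] == pytest.approx(0.0)  # F=M=H=5

    def test_hand_value_and_scale_invariance(self, toy_fpkm):
        fpkm, samples, design = toy_fpkm
        out = mpv_transform(fpkm, samples, design)
        assert out.loc["AE", "g1"] == pytest.approx(50.0)  # F=2, M=6, H=6
        scaled = mpv_transform(fpkm * 7.5, samples, design)
        assert scaled.to_numpy() == pytest.approx(out.to_numpy())

    def test_zero_midparent_gene_dropped(self, toy_fpkm):
        fpkm, samples, design = toy_fpkm
        fpkm.loc["g3"] = 0.0
        fpkm.loc["g3", ["AE_r1", "AE_r2"]] = 4.0
        out = mpv_transform(fpkm, samples, design)
        assert "g3" not in out.columns

    def test_missing_parent_raises(self, toy_fpkm):
        fpkm, samples, design = toy_fpkm
        bad = design.assign(male=["Z"])
        with pytest.raises(KeyError):
            mpv_transform(fpkm, samples, bad)


class TestSimulateCoexpression:
    def test_zero_noise_gives_unit_correlations(self):
        cfg = SimulationConfig(n_genes=12, seed=8, module_spec=[(6, 1.0, 0.0)])
        expr, _, truth = simulate_coexpression(cfg)
        block = expr.loc[truth.module_members["M1"]]
        corr = np.corrcoef(block.to_numpy())
        assert np.abs(corr) == pytest.approx(np.ones_like(corr))

    def test_null_trait_uncorrelated_with_nontarget_module(self):
        """|r| between the trait and the second module's eigengene stays
        small across seeds when trait_module_r = 0 (n = 24 samples): the
        null sampling sd of r is ~1/sqrt(23) ~ 0.21, so individual seeds
        can graze 0.3 but the average absolute r stays well below it."""
        rs = []
        for seed in range(8):
            cfg = SimulationConfig(
                n_genes=60, seed=seed, trait_module_r=0.0,
                module_spec=[(20, 0.9, 0.2), (20, 0.9, 0.2)],
            )
            expr, trait, truth = simulate_coexpression(cfg)
            eig, _ = module_eigengene(expr, truth.module_members["M2"])
            rs.append(abs(np.corrcoef(eig, trait.to_numpy())[0, 1]))
        assert np.mean(rs) < 0.3
        assert max(rs) < 3.5 / np.sqrt(23)  # ~3.5 null sds

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=40, seed=9, module_spec=[(10, 0.9, 0.1)])
        e1, t1, _ = simulate_coexpression(cfg)
        e2, t2, _ = simulate_coexpression(cfg)
        assert e1.equals(e2) and t1.equals(t2)

    def test_oversized_module_rejected(self):
        with pytest.raises(ValueError):
            simulate_coexpression(SimulationConfig(n_genes=10, module_spec=[(20, 0.9, 0.1)]))
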