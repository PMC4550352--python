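import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendropart.canonical import (
    forward_select,
    hellinger,
    jackknife1_richness,
    permutation_test,
    rda_fit,
    variation_partition,
)


class TestHellinger:
    def test_row_example(self):
        out = hellinger(np.array([[1.0, 3.0]]))
        assert np.allclose(out, [[0.5, np.sqrt(3) / 2]])
        assert out[0, 1] == pytest.approx(0.86603, abs=1e-5)

    def test_one_taxon_community_all_ones(self):
        out = hellinger(np.array([[4.0], [9.0], [1.0]]))
        assert np.allclose(out, 1.0)

    def test_rows_unit_norm_on_default_community(self, default_dataset):
        y = hellinger(default_dataset.community.to_numpy(float))
        assert y.shape == default_dataset.community.shape
        assert np.allclose(np.sum(y**2, axis=1), 1.0, atol=1e-12)

    def test_zero_row_rejected_with_site(self):
        with pytest.raises(ValueError, match="\\[1\\]"):
            hellinger(np.array([[1.0, 2.0], [0.0, 0.0]]))

    def test_idempotent_only_for_one_taxon_rows(self):
        one = np.array([[7.0]])
        assert np.allclose(hellinger(hellinger(one)), hellinger(one))
        y = np.array([[1.0, 3.0]])
        assert not np.allclose(hellinger(hellinger(y)), hellinger(y))


class TestRdaFit:
    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 3))
        y = x @ rng.normal(size=(3, 6))
        assert rda_fit(y, x).r2 == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_predictor_r2_zero(self):
        y = np.array([[1.0, 0], [-1, 0], [1, 0], [-1, 0]])
        x = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        fit = rda_fit(y, x)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.adj_r2 <= 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(20, 5))
        x = rng.normal(size=(20, 3))
        fit = rda_fit(y, x)
        yc = y - y.mean(axis=0)
        xc = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(xc.T @ xc, xc.T @ yc)
        resid = yc - xc @ beta
        r2 = 1 - resid.var(axis=0).sum() / yc.var(axis=0).sum()
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_ezekiel_adjustment_arithmetic(self):
        # n=51, m=1, r2=0.5 -> adj = 1 - 0.5 * 50/49
        rng = np.random.default_rng(5)
        x = rng.normal(size=(51, 1))
        signal = (x - x.mean()) / np.linalg.norm(x - x.mean())
        noise = rng.normal(size=(51, 1))
        noise -= noise.mean()
        noise -= signal * (signal.T @ noise)
        noise /= np.linalg.norm(noise)
        y = signal + noise  # exactly half the variance on x
        fit = rda_fit(y, x)
        assert fit.r2 == pytest.approx(0.5, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1 - 0.5 * 50 / 49, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(0.48980, abs=1e-5)

    def test_invariant_to_invertible_mixing_of_predictors(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(25, 4))
        x = rng.normal(size=(25, 3))
        base = rda_fit(y, x).r2
        for seed in range(5):
            m = np.random.default_rng(seed).normal(size=(3, 3))
            while abs(np.linalg.det(m)) < 1e-3:
                m = np.random.default_rng(seed + 100).normal(size=(3, 3))
            assert rda_fit(y, x @ m).r2 == pytest.approx(base, abs=1e-10)

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="saturated"):
            rda_fit(rng.normal(size=(5, 2)), rng.normal(size=(5, 6)))

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 2))
        xx = np.column_stack([x, x[:, 0] + x[:, 1]])
        y = rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="collinear"):
            fit = rda_fit(y, xx)
        assert fit.rank == 2


class TestPermutationTest:
    def test_strong_signal_attains_minimum_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 2))
        y = x @ rng.normal(size=(2, 5)) + 0.01 * rng.normal(size=(30, 5))
        res = permutation_test(y, x, n_perm=999, seed=1)
        assert res.p == pytest.approx(1 / 1000)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(7)
        y, x = rng.normal(size=(25, 4)), rng.normal(size=(25, 2))
        a = permutation_test(y, x, n_perm=199, seed=42)
        b = permutation_test(y, x, n_perm=199, seed=42)
        assert a.p == b.p and a.f == b.f

    def test_invariant_to_joint_row_permutation(self):
        # the F statistic is exactly invariant; the p-value is exactly
        # invariant under full enumeration (sampled permutations would
        # draw a different subset after relabelling)
        rng = np.random.default_rng(8)
        y, x, c = (
            rng.normal(size=(6, 3)),
            rng.normal(size=(6, 2)),
            rng.normal(size=(6, 1)),
        )
        perm = rng.permutation(6)
        with pytest.warns(UserWarning, match="enumerat"):
            a = permutation_test(y, x, condition=c, n_perm=720, seed=5)
        with pytest.warns(UserWarning, match="enumerat"):
            b = permutation_test(
                y[perm], x[perm], condition=c[perm], n_perm=720, seed=5
            )
        assert a.f == pytest.approx(b.f, rel=1e-10)
        assert a.p == b.p

    def test_tiny_n_exact_enumeration(self):
        rng = np.random.default_rng(9)
        y, x = rng.normal(size=(4, 2)), rng.normal(size=(4, 1))
        with pytest.warns(UserWarning, match="enumerat"):
            res = permutation_test(y, x, n_perm=999, seed=0)
        assert res.n_perm == 24


class TestForwardSelect:
    def test_true_single_candidate_selected(self):
        rng = np.random.default_rng(10)
        cands = rng.normal(size=(30, 5))
        y = np.outer(cands[:, 2], rng.normal(size=4)) + 0.3 * rng.normal(size=(30, 4))
        sel = forward_select(y, cands, n_perm=199, seed=3)
        assert 2 in sel.selected
        assert sel.step_adj_r2[-1] <= sel.global_adj_r2 + 1e-12

    def test_duplicated_selected_column_never_reselected(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(30, 3))
        cands = np.column_stack([base, base[:, 0]])
        y = np.outer(base[:, 0], rng.normal(size=4)) + 0.2 * rng.normal(size=(30, 4))
        sel = forward_select(y, cands, n_perm=199, seed=4)
        assert not (0 in sel.selected and 3 in sel.selected)

    def test_null_gate_blocks_most_noise(self):
        rng = np.random.default_rng(12)
        hits = 0
        for i in range(40):
            y = rng.normal(size=(30, 5))
            cands = rng.normal(size=(30, 10))
            sel = forward_select(y, cands, n_perm=99, seed=int(rng.integers(2**31)))
            hits += sel.any_selected
        assert hits <= 8  # ~alpha-level gating, generous small-sample bound


class TestVariationPartition:
    def test_identical_blocks_share_everything(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(30, 2))
        y = x @ rng.normal(size=(2, 5)) + rng.normal(size=(30, 5))
        vp = variation_partition(y, {"A": x, "B": x.copy()}, n_perm=99, seed=0)
        assert vp.fractions[frozenset(["A"])] == pytest.approx(0.0, abs=1e-10)
        assert vp.fractions[frozenset(["B"])] == pytest.approx(0.0, abs=1e-10)
        assert vp.fractions[frozenset(["A", "B"])] == pytest.approx(
            rda_fit(y, x).adj_r2, abs=1e-10
        )

    def test_orthogonal_blocks_split_cleanly(self):
        n = 40
        t = np.arange(n)
        a = np.cos(2 * np.pi * t / n)[:, None]
        b = np.cos(4 * np.pi * t / n)[:, None]
        a -= a.mean()
        b -= b.mean()
        y = np.column_stack([a, b]) @ np.random.default_rng(14).normal(size=(2, 6))
        vp = variation_partition(y, {"A": a, "B": b}, n_perm=99, seed=1)
        # unadjusted R2 decomposes exactly under orthogonality ...
        r2a, r2b = rda_fit(y, a).r2, rda_fit(y, b).r2
        r2ab = rda_fit(y, np.column_stack([a, b])).r2
        assert r2a + r2b == pytest.approx(r2ab, abs=1e-10)
        # ... while the adjusted shared fraction carries only the (known)
        # Ezekiel penalty: adjA + adjB - adjAB, small but nonzero
        adj = {
            "A": rda_fit(y, a).adj_r2,
            "B": rda_fit(y, b).adj_r2,
            "AB": rda_fit(y, np.column_stack([a, b])).adj_r2,
        }
        expect_shared = adj["A"] + adj["B"] - adj["AB"]
        assert vp.fractions[frozenset(["A", "B"])] == pytest.approx(
            expect_shared, abs=1e-10
        )
        assert abs(expect_shared) < 0.05
        assert vp.fractions[frozenset(["A"])] == pytest.approx(
            adj["AB"] - adj["B"], abs=1e-10
        )

    def test_three_block_fractions_sum_to_one(self):
        rng = np.random.default_rng(15)
        y = rng.normal(size=(30, 6))
        blocks = {k: rng.normal(size=(30, 2)) for k in "ABC"}
        vp = variation_partition(y, blocks, n_perm=99, seed=2)
        total = sum(vp.fractions.values()) + vp.residual
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_single_block_reduces_to_rda(self):
        rng = np.random.default_rng(16)
        y, x = rng.normal(size=(25, 4)), rng.normal(size=(25, 2))
        vp = variation_partition(y, {"A": x}, n_perm=99, seed=3)
        assert vp.fractions[frozenset(["A"])] == pytest.approx(
            rda_fit(y, x).adj_r2, abs=1e-12
        )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_unique_fraction_two_path_consistency(self, k):
        rng = np.random.default_rng(17 + k)
        y = rng.normal(size=(35, 5))
        names = list("ABCD")[:k]
        blocks = {nm: rng.normal(size=(35, 2)) for nm in names}
        vp = variation_partition(y, blocks, n_perm=99, seed=4)
        mats = {nm: blocks[nm] for nm in names}
        all_x = np.hstack(list(mats.values()))
        for nm in names:
            others = np.hstack([mats[o] for o in names if o != nm])
            direct = rda_fit(y, all_x).adj_r2 - rda_fit(y, others).adj_r2
            assert vp.fractions[frozenset([nm])] == pytest.approx(direct, abs=1e-10)

    def test_more_than_four_blocks_rejected(self):
        rng = np.random.default_rng(18)
        y = rng.normal(size=(30, 3))
        blocks = {k: rng.normal(size=(30, 1)) for k in "ABCDE"}
        with pytest.raises(ValueError, match="1-4"):
            variation_partition(y, blocks, n_perm=99, seed=0)


class TestJackknife:
    def test_no_uniques_equals_observed(self):
        inc = np.ones((5, 8))
        assert jackknife1_richness(inc) == pytest.approx(8.0)

    def test_formula_arithmetic(self):
        # S_obs = 10, f1 = 4, m = 5 -> 10 + 4*4/5 = 13.2
        inc = np.zeros((5, 10))
        inc[:, :6] = 1  # 6 taxa everywhere
        for t in range(6, 10):  # 4 singletons
            inc[t - 6, t] = 1
        assert jackknife1_richness(inc) == pytest.approx(13.2)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2"):
            jackknife1_richness(np.ones((1, 4)))


@pytest.mark.parametrize("seed", range(5))
def test_rda_against_vegan_oracle(tmp_path, seed):
    """Cross-check R2 and adjusted R2 against vegan's rda/RsquareAdj."""
    rng = np.random.default_rng(seed)
    y = rng.poisson(3.0, size=(15, 6)).astype(float)
    y[y.sum(axis=1) == 0, 0] = 1
    x = rng.normal(size=(15, 2))
    np.savetxt(tmp_path / "y.csv", hellinger(y), delimiter=",")
    np.savetxt(tmp_path / "x.csv", x, delimiter=",")
    script = textwrap.dedent(
        """
        suppressMessages(library(vegan))
        y <- as.matrix(read.csv("y.csv", header=FALSE))
        x <- as.data.frame(read.csv("x.csv", header=FALSE))
        m <- rda(y ~ ., data=x)
        r <- RsquareAdj(m)
        cat(sprintf("%.12f %.12f", r$r.squared, r$adj.r.squared))
        """
    )
    (tmp_path / "check.R").write_text(script)
    out = subprocess.run(
        ["Rscript", "check.R"], cwd=tmp_path, capture_output=True, text=True
    )
    assert out.returncode == 0, out.stderr
    r2_vegan, adj_vegan = map(float, out.stdout.split())
    fit = rda_fit(hellinger(y), x)
    assert fit.r2 == pytest.approx(r2_vegan, abs=1e-8)
    assert fit.adj_r2 == pytest.approx(adj_vegan, abs=1e-8)
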