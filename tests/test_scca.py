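"""Sparse CCA: PMD operator, constraints, tuning, CV significance, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mucolink import (
    CcaPenalty,
    enrich_gene_sets,
    loo_significance,
    pmd_rank1,
    read_gmt,
    soft_threshold,
    sparse_cca,
    tune_penalties,
)
from mucolink.synth import SynthConfig, generate_cohort


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,delta,expected",
        [
            ([2.0, -1.0, 0.5], 0.0, [2.0, -1.0, 0.5]),  # identity
            ([2.0], 3.0, [0.0]),  # full shrinkage
            ([-5.0], 2.0, [-3.0]),  # sign preserved
        ],
    )
    def test_elementwise(self, x, delta, expected):
        assert np.allclose(soft_threshold(np.array(x), delta), expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)


class TestPmdRank1:
    def test_inactive_penalty_recovers_leading_singular_vectors(self):
        rng = np.random.default_rng(0)
        K = rng.normal(size=(5, 5))
        u, v, d, conv = pmd_rank1(K, c1=np.sqrt(5), c2=np.sqrt(5))
        U, S, Vt = np.linalg.svd(K)
        u0, v0 = U[:, 0], Vt[0]
        if u0 @ u < 0:
            u0, v0 = -u0, -v0
        assert conv
        assert d == pytest.approx(S[0], abs=1e-6)
        assert np.allclose(u, u0, atol=1e-5)
        assert np.allclose(v, v0, atol=1e-5)

    def test_rank_one_sparse_matrix_is_fixed_point(self):
        a = np.array([0.8, 0.6, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        K = 3.0 * np.outer(a, b)
        u, v, d, conv = pmd_rank1(K, c1=np.abs(a).sum() + 1e-9, c2=1.0)
        assert d == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(np.abs(u), a, atol=1e-8)
        assert np.allclose(np.abs(v), b, atol=1e-8)

    def test_constraints_hold_on_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            K = rng.normal(size=(8, 12))
            c1 = rng.uniform(1.0, np.sqrt(8))
            c2 = rng.uniform(1.0, np.sqrt(12))
            u, v, d, _ = pmd_rank1(K, c1, c2)
            assert np.abs(u).sum() <= c1 + 1e-6
            assert np.abs(v).sum() <= c2 + 1e-6
            for w in (u, v):
                assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-8) or not np.any(w)
            assert d >= 0

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            pmd_rank1(np.zeros((3, 3)), 1.5, 1.5)


class TestSparseCca:
    def test_identical_sides_give_unit_correlation(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        model = sparse_cca(X, X.copy(), CcaPenalty(1.0, 1.0), n_components=1)
        assert model.components[0].r == pytest.approx(1.0, abs=1e-6)

    def test_deflation_exhausts_rank(self):
        """Extracting K components from a rank-K matrix with inactive
        penalties leaves a negligible residual."""
        rng = np.random.default_rng(3)
        A = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 3))
        X = pd.DataFrame(A @ rng.normal(size=(3, 6)))
        Y = pd.DataFrame(A @ rng.normal(size=(3, 8)) + 1e-9 * rng.normal(size=(30, 8)))
        n = 30
        Xs = (X - X.mean()) / X.std()
        Ys = (Y - Y.mean()) / Y.std()
        K0 = Xs.to_numpy().T @ Ys.to_numpy() / (n - 1)
        model = sparse_cca(X, Y, CcaPenalty(1.0, 1.0), n_components=6, tol=1e-10)
        K = K0.copy()
        for comp in model.components:
            K -= comp.d * np.outer(comp.u.to_numpy(), comp.v.to_numpy())
        # rank of K0 is 3 (X has 6 cols but only 3 latent dims)
        assert np.linalg.norm(K, "fro") < 1e-5

    def test_in_sample_correlation_shows_optimism_on_noise(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(200, 15)))
        Y = pd.DataFrame(rng.normal(size=(200, 40)))
        model = sparse_cca(X.iloc[:150], Y.iloc[:150], CcaPenalty(0.5, 0.5), n_components=1)
        comp = model.components[0]
        Xh = (X.iloc[150:] - X.iloc[:150].mean()) / X.iloc[:150].std()
        Yh = (Y.iloc[150:] - Y.iloc[:150].mean()) / Y.iloc[:150].std()
        r_held = np.corrcoef(Xh.to_numpy() @ comp.u.to_numpy(), Yh.to_numpy() @ comp.v.to_numpy())[0, 1]
        assert comp.r > r_held + 0.1  # optimism gap motivates CV significance

    def test_planted_modules_recovered(self, residual_pair, cohort):
        X, Y = residual_pair
        model = sparse_cca(X, Y, CcaPenalty(0.3, 0.3), n_components=2)
        all_planted = set()
        for mm in cohort.truth.module_members:
            all_planted |= set(mm["genes"]) | set(mm["taxa"])
        selected_union = set()
        for comp in model.components:
            taxa_sel, gene_sel = comp.members()
            selected = set(taxa_sel) | set(gene_sel)
            selected_union |= selected
            jac = max(
                len(selected & (set(mm["genes"]) | set(mm["taxa"])))
                / len(selected | set(mm["genes"]) | set(mm["taxa"]))
                for mm in cohort.truth.module_members
            )
            assert jac >= 0.5
        assert len(selected_union & all_planted) / len(all_planted) >= 0.8

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="10 samples"):
            sparse_cca(X, X, CcaPenalty(0.5, 0.5))


class TestTunePenalties:
    def test_single_cell_grid_returned(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(50, 8)))
        Y = pd.DataFrame(rng.normal(size=(50, 10)))
        pen = tune_penalties(X, Y, grid=[0.4], seed=0)
        assert pen == CcaPenalty(0.4, 0.4)

    def test_empty_grid_rejected(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(50, 5)))
        with pytest.raises(ValueError, match="empty"):
            tune_penalties(X, X, grid=[])

    def test_noise_data_shows_no_significant_heldout_correlation(self):
        """On pure noise the tuned penalty's held-out correlation should not
        be significantly positive."""
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(8):
            X = pd.DataFrame(rng.normal(size=(60, 8)))
            Y = pd.DataFrame(rng.normal(size=(60, 12)))
            pen = tune_penalties(X, Y, grid=[0.3, 0.6], n_folds=3, seed=0)
            # refit and evaluate on fresh noise from the same distribution
            model = sparse_cca(X, Y, pen, n_components=1)
            Xn = rng.normal(size=(60, 8))
            Yn = rng.normal(size=(60, 12))
            rs.append(np.corrcoef(Xn @ model.components[0].u, Yn @ model.components[0].v)[0, 1])
        t = sps.ttest_1samp(rs, 0.0)
        assert not (t.pvalue < 0.05 and np.mean(rs) > 0)

    def test_planted_signal_keeps_support_tight(self):
        """Tuned penalties select at most ~2x the true support in component 1."""
        ok = 0
        for seed in range(3):
            c = generate_cohort(
                SynthConfig(seed=seed, n_modules=1, module_gene_size=20, module_taxon_size=5)
            )
            from mucolink import OmicsMatrix, clr_transform, residualize
            from conftest import COVARIATES

            clr = clr_transform(c.taxa, pseudocount=0.5)
            X = residualize(OmicsMatrix(clr.values.T, kind="taxon", unit="clr"), c.meta, COVARIATES).data.T
            Y = residualize(c.genes, c.meta, COVARIATES).data.T
            pen = tune_penalties(X, Y, grid=[0.1, 0.2, 0.3, 0.4], n_folds=3, seed=0)
            model = sparse_cca(X, Y, pen, n_components=1)
            taxa_sel, gene_sel = model.components[0].members()
            if len(taxa_sel) <= 10 and len(gene_sel) <= 40:
                ok += 1
        assert ok >= 2


class TestCvSignificance:
    def test_deterministic(self, residual_pair):
        X, Y = residual_pair
        a = loo_significance(X, Y, CcaPenalty(0.3, 0.3), n_components=3)
        b = loo_significance(X, Y, CcaPenalty(0.3, 0.3), n_components=3)
        assert [c.cv_p for c in a.components] == [c.cv_p for c in b.components]

    def test_planted_components_kept(self, residual_pair):
        X, Y = residual_pair
        model = loo_significance(X, Y, CcaPenalty(0.3, 0.3), n_components=10)
        assert model.components[0].keep and model.components[1].keep
        for comp in model.components:
            assert (comp.p_adj >= comp.cv_p - 1e-12) or np.isnan(comp.cv_p)

    def test_null_keep_fraction_at_most_alpha(self):
        kept = tot = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(120, 15)), columns=[f"T{j}" for j in range(15)])
            Y = pd.DataFrame(rng.normal(size=(120, 40)), columns=[f"G{j}" for j in range(40)])
            m = loo_significance(X, Y, CcaPenalty(0.3, 0.3), n_components=10, alpha=0.1)
            kept += sum(bool(c.keep) for c in m.components)
            tot += len(m.components)
        assert kept / tot <= 0.1

    def test_refit_cap_enforced(self, residual_pair):
        X, Y = residual_pair
        with pytest.raises(ValueError, match="cap"):
            loo_significance(X, Y, CcaPenalty(0.3, 0.3), n_folds=60, max_n=50)


class TestEnrichment:
    def test_full_set_hits_hypergeometric_minimum(self):
        background = [f"g{i}" for i in range(40)]
        sets = {"hit": set(background[:8]), "miss": set(background[30:])}
        out = enrich_gene_sets(background[:8], background, sets).set_index("set")
        # drawing exactly the full 8-member set: p = 1 / C(40, 8)
        from scipy.special import comb

        assert out.loc["hit", "p"] == pytest.approx(1.0 / comb(40, 8), rel=1e-9)
        assert out.loc["miss", "p"] == pytest.approx(1.0)

    def test_empty_selection_gives_p_one(self):
        background = [f"g{i}" for i in range(20)]
        out = enrich_gene_sets([], background, {"s": set(background[:5])})
        assert (out.p == 1.0).all()

    def test_uniform_selection_gives_uniform_p(self):
        rng = np.random.default_rng(9)
        background = [f"g{i}" for i in range(200)]
        sets = {"s": set(background[:40])}
        pvals = [
            enrich_gene_sets(list(rng.choice(background, 30, replace=False)), background, sets).p.iloc[0]
            for _ in range(300)
        ]
        # discrete p-values are super-uniform; check no inflation of small p
        assert np.mean(np.array(pvals) < 0.05) <= 0.07

    def test_selected_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich_gene_sets(["x"], ["a", "b", "c"], {})

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
        sets = read_gmt(path)
        assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g4"}}
        with pytest.raises(ValueError, match="malformed"):
            bad = tmp_path / "bad.gmt"
            bad.write_text("only_name\n")
            read_gmt(bad)
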