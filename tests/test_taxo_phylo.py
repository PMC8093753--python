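import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_taxonomy
from microtraits.synthetic_data import SyntheticConfig, generate_taxonomy
from microtraits.taxo_phylo import (
    TaxonomyTree,
    build_tree,
    covariance,
    ols_fit,
    pgls_fit,
    simulate_brownian,
    simulate_correlated_brownian,
)


def shared_prefix_oracle(taxonomies):
    """Independent covariance oracle: count shared leading ranks per pair."""
    n = len(taxonomies)
    V = np.full((n, n), 7.0)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = 0
                for a, b in zip(taxonomies[i], taxonomies[j]):
                    if a != b:
                        break
                    d += 1
                V[i, j] = d
    return V


def random_taxonomy(seed, n_max=12):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    cfg = SyntheticConfig(n_species=n, taxonomy_branching=(2, 2, 2, 2, 2, 2), seed=seed)
    return generate_taxonomy(cfg, rng)


class TestBuildTree:
    def test_congeneric_mrca_depth(self):
        taxs = make_taxonomy(
            [("P", "C", "O", "F", "G", "sp a"), ("P", "C", "O", "F", "G", "sp b")]
        )
        tree = build_tree(taxs)
        assert tree.mrca_depth("sp a", "sp b") == 6

    def test_interdomain_mrca_is_root(self):
        taxs = [
            ("Bacteria", "P", "C", "O", "F", "G", "sp a"),
            ("Archaea", "P2", "C2", "O2", "F2", "G2", "sp b"),
        ]
        tree = build_tree(taxs)
        assert tree.mrca_depth("sp a", "sp b") == 0

    def test_newick_nesting_and_sister_tips(self):
        taxs = make_taxonomy(
            [
                ("P1", "C1", "O1", "F1", "G1", "spa"),
                ("P1", "C1", "O1", "F1", "G1", "spb"),
                ("P2", "C2", "O2", "F2", "G2", "spc"),
            ]
        )
        nwk = build_tree(taxs).to_newick()
        depth, max_depth = 0, 0
        for ch in nwk:
            depth += ch == "("
            max_depth = max(max_depth, depth)
            depth -= ch == ")"
        assert max_depth == 7  # root + six internal ranks above each tip
        assert "spa:1,spb:1" in nwk  # congenerics are sister tips
        assert nwk.startswith("(") and nwk.endswith(";")

    def test_newick_round_trip(self):
        taxs = random_taxonomy(seed=11)
        tree = build_tree(taxs)
        back = TaxonomyTree.from_newick(tree.to_newick())
        assert sorted(back.species) == sorted(tree.species)
        Va = covariance(tree).to_dataframe()
        Vb = covariance(back).to_dataframe()
        assert np.allclose(Va, Vb.loc[Va.index, Va.columns])

    def test_duplicate_species_rejected(self):
        taxs = make_taxonomy(
            [("P", "C", "O", "F", "G", "dup"), ("P", "C", "O", "F", "G2", "dup")]
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_tree(taxs)

    def test_incomplete_taxonomy_rejected(self):
        with pytest.raises(ValueError, match="7"):
            build_tree([("Bacteria", "P", "C", "O", "F", "G")])


class TestCovariance:
    def test_single_species(self):
        V = covariance(build_tree(make_taxonomy([("P", "C", "O", "F", "G", "s")])))
        assert V.matrix.tolist() == [[7.0]]

    def test_congenerics_share_six(self):
        taxs = make_taxonomy(
            [("P", "C", "O", "F", "G", "sa"), ("P", "C", "O", "F", "G", "sb")]
        )
        V = covariance(build_tree(taxs)).matrix
        assert V[0, 1] == 6.0 and V[0, 0] == 7.0

    @given(st.integers(0, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_shared_prefix_oracle(self, seed):
        taxs = random_taxonomy(seed)
        V = covariance(build_tree(taxs)).matrix
        assert np.array_equal(V, shared_prefix_oracle(taxs))

    def test_random_tree_positive_semidefinite(self):
        taxs = random_taxonomy(seed=20, n_max=20)
        V = covariance(build_tree(taxs)).matrix
        assert np.linalg.eigvalsh(V).min() >= -1e-9


class TestSimulateBrownian:
    def test_zero_rate_returns_root_value(self):
        tree = build_tree(random_taxonomy(3))
        tips = simulate_brownian(tree, 0.0, root_value=2.5, seed=0)
        assert np.allclose(tips, 2.5)

    def test_seed_reproducibility(self):
        tree = build_tree(random_taxonomy(4))
        a = simulate_brownian(tree, 0.3, seed=9)
        b = simulate_brownian(tree, 0.3, seed=9)
        assert np.array_equal(a, b)

    def test_negative_rate_rejected(self):
        tree = build_tree(random_taxonomy(5))
        with pytest.raises(ValueError):
            simulate_brownian(tree, -1.0, seed=0)

    def test_correlated_tips_match_target_rho(self):
        cfg = SyntheticConfig(n_species=4000, seed=2)
        tree = build_tree(generate_taxonomy(cfg))
        rho = np.array([[1.0, 0.8], [0.8, 1.0]])
        tips = simulate_correlated_brownian(
            tree, [0.01, 0.02], rho, seed=2, depth_weights=cfg.depth_weights
        )
        r = np.corrcoef(tips[:, 0], tips[:, 1])[0, 1]
        assert r == pytest.approx(0.8, abs=0.03)

    def test_non_psd_rho_rejected(self):
        tree = build_tree(random_taxonomy(6))
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_correlated_brownian(tree, [1.0, 1.0], bad, seed=0)


class TestPgls:
    def _problem(self, seed, n=40, p=3):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        return y, X

    def test_identity_covariance_reduces_to_ols(self):
        y, X = self._problem(0)
        V = 3.7 * np.eye(len(y))
        g = pgls_fit(y, X, V)
        o = ols_fit(y, X)
        assert np.allclose(g.beta, o.beta, rtol=1e-10)
        assert np.allclose(g.tvalues, o.tvalues, rtol=1e-10)
        assert g.r2 == pytest.approx(o.r2, rel=1e-10)

    def test_matches_explicit_inverse_oracle(self):
        y, X = self._problem(1)
        V = covariance(build_tree(random_taxonomy(8, n_max=12))).matrix
        n = V.shape[0]
        y, X = y[:n], X[:n]
        fit = pgls_fit(y, X, V)
        Vinv = np.linalg.inv(V)
        beta_oracle = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        assert np.allclose(fit.beta, beta_oracle, rtol=1e-8)

    def test_permutation_invariance(self):
        taxs = random_taxonomy(13, n_max=20)
        tree = build_tree(taxs)
        V = covariance(tree).matrix
        n = V.shape[0]
        rng = np.random.default_rng(0)
        x = simulate_brownian(tree, 1.0, seed=1)
        y = 0.3 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        perm = rng.permutation(n)
        a = pgls_fit(y, X, V)
        b = pgls_fit(y[perm], X[perm], V[np.ix_(perm, perm)])
        assert np.allclose(a.beta, b.beta, rtol=1e-8)
        assert a.aic == pytest.approx(b.aic, rel=1e-10)

    def test_residual_quadratic_form_is_minimal(self):
        y, X = self._problem(2, n=25)
        V = covariance(build_tree(random_taxonomy(9, n_max=12))).matrix
        n = V.shape[0]
        y, X = y[:n], X[:n]
        fit = pgls_fit(y, X, V)
        Vinv = np.linalg.inv(V)

        def qform(b):
            r = y - X @ b
            return r @ Vinv @ r

        q0 = qform(fit.beta)
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert qform(fit.beta + rng.normal(0, 0.05, size=len(fit.beta))) >= q0

    def test_rank_deficiency_reports_offending_column(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank-deficient"):
            ols_fit(y, X, terms=("const", "x", "x_copy"))

    def test_ols_matches_statsmodels(self):
        import statsmodels.api as sm

        y, X = self._problem(7, n=60, p=4)
        ours = ols_fit(y, X)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(ours.beta, ref.params, rtol=1e-10)
        assert np.allclose(ours.se, ref.bse, rtol=1e-10)
        assert ours.r2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert ours.loglik == pytest.approx(ref.llf, rel=1e-10)
        # same AIC convention apart from counting the residual variance
        assert ours.aic == pytest.approx(ref.aic + 2.0, rel=1e-10)
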