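import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microtraits.stats_suite import (
    ModelSuiteResult,
    aic,
    density_contours,
    fit_model_suite,
    group_separation,
    pairwise_r2,
    variance_partition,
)
from microtraits.taxo_phylo import ols_fit


def _species_frame(n, seed, rho=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.3, size=n)
    y = rho * x + math.sqrt(max(1 - rho**2, 0.0)) * rng.normal(0, 0.3, size=n)
    return pd.DataFrame(
        {
            "g_adj": rng.normal(0, 0.4, size=n),
            "cell_diameter_um": 10.0**x,
            "genome_size_bp": 10.0 ** (6.5 + y),
            "rrn_copies": np.maximum(np.round(10 ** rng.normal(0.4, 0.3, size=n)), 1),
        }
    )


class TestPairwiseR2:
    def test_perfect_log_linearity(self):
        d = np.array([0.2, 0.5, 1.0, 2.0, 3.0])
        df = pd.DataFrame(
            {"cell_diameter_um": d, "genome_size_bp": 1e6 * d**2.0}
        )
        corr = pairwise_r2(df, ("cell_diameter_um", "genome_size_bp"))
        assert corr.r2.loc["cell_diameter_um", "genome_size_bp"] == pytest.approx(1.0)

    def test_independent_traits_near_zero(self):
        df = _species_frame(10_000, seed=0, rho=0.0)
        corr = pairwise_r2(df, ("cell_diameter_um", "genome_size_bp"))
        assert corr.r2.loc["cell_diameter_um", "genome_size_bp"] < 0.001

    def test_pairwise_complete_counts(self):
        df = _species_frame(50, seed=1)
        df.loc[:9, "genome_size_bp"] = np.nan
        corr = pairwise_r2(df)
        assert corr.n.loc["g_adj", "genome_size_bp"] == 40
        assert corr.n.loc["g_adj", "cell_diameter_um"] == 50

    def test_too_few_pairs_reported_missing(self):
        df = _species_frame(30, seed=2)
        df.loc[2:, "genome_size_bp"] = np.nan
        corr = pairwise_r2(df)
        assert np.isnan(corr.r2.loc["g_adj", "genome_size_bp"])

    @given(st.integers(0, 100), st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_and_scale_invariant(self, seed, c):
        df = _species_frame(60, seed=seed, rho=0.4)
        base = pairwise_r2(df, ("cell_diameter_um", "genome_size_bp"))
        df2 = df.assign(genome_size_bp=df.genome_size_bp * c)
        scaled = pairwise_r2(df2, ("cell_diameter_um", "genome_size_bp"))
        a = base.r2.loc["cell_diameter_um", "genome_size_bp"]
        assert a == pytest.approx(base.r2.loc["genome_size_bp", "cell_diameter_um"])
        assert a == pytest.approx(
            scaled.r2.loc["cell_diameter_um", "genome_size_bp"], rel=1e-9
        )


def _suite_frame(n, seed, habitats=("soil", "marine_water", "host_endotherm")):
    rng = np.random.default_rng(seed)
    ld = rng.normal(-0.1, 0.25, size=n)
    hab = rng.choice(habitats, size=n)
    eff = {h: v for h, v in zip(habitats, (0.0, -0.2, 0.2))}
    ldc = ld - ld.mean()
    g = -1.2 * ldc**2 + np.array([eff[h] for h in hab]) + rng.normal(0, 0.3, size=n)
    return pd.DataFrame(
        {
            "g_adj": g,
            "cell_diameter_um": 10.0**ld,
            "genome_size_bp": 10 ** rng.normal(6.5, 0.35, size=n),
            "habitat": hab,
        }
    )


@pytest.fixture(scope="module")
def suite():
    return fit_model_suite(_suite_frame(386, seed=0))


class TestModelSuite:
    def test_df_accounting(self, suite):
        # intercept + slope leaves n - 2 residual df
        assert suite.n == 386
        assert suite.models[0].df_resid == 384

    def test_common_row_set(self, suite):
        assert len({m.n for m in suite.models}) == 1

    def test_nested_r2_monotone(self, suite):
        r2 = [m.r2 for m in suite.models]
        for lo, hi in [(0, 3), (3, 6), (6, 7), (1, 4)]:  # chains 1->4->7->8, 2->5
            assert r2[hi] >= r2[lo] - 1e-12

    def test_quadratic_plus_habitat_structure_recovered(self, suite):
        assert suite.best_label.startswith("7.")

    def test_single_habitat_level_skips_factor_models(self):
        df = _suite_frame(100, seed=1, habitats=("soil",))
        with pytest.warns(UserWarning, match="single level"):
            suite = fit_model_suite(df)
        assert len(suite.models) == 5

    def test_too_few_complete_cases(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_model_suite(_suite_frame(20, seed=2))


class TestAic:
    def test_closed_form(self):
        m = ols_fit(np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 4.0]), np.ones((10, 1)))
        n, rss, p = m.n, m.rss, m.p
        expected = n * (math.log(2 * math.pi * rss / n) + 1) + 2 * (p + 1)
        assert aic(m) == pytest.approx(expected, rel=1e-12)
        assert m.aic == pytest.approx(expected, rel=1e-12)

    def test_location_invariance_of_differences(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        X1 = np.column_stack([np.ones(50), x])
        X2 = np.column_stack([np.ones(50), x, x**2])
        d0 = ols_fit(y, X2).aic - ols_fit(y, X1).aic
        d1 = ols_fit(y + 100.0, X2).aic - ols_fit(y + 100.0, X1).aic
        assert d0 == pytest.approx(d1, abs=1e-8)

    def test_noise_predictor_usually_raises_aic(self):
        rng = np.random.default_rng(1)
        worse = 0
        for _ in range(500):
            x = rng.normal(size=40)
            y = 0.8 * x + rng.normal(size=40)
            X1 = np.column_stack([np.ones(40), x])
            X2 = np.column_stack([X1, rng.normal(size=40)])
            worse += ols_fit(y, X2).aic > ols_fit(y, X1).aic
        assert worse > 250


class TestVariancePartition:
    def test_shares_from_component_r2(self):
        # partition arithmetic on externally supplied R^2 values
        class _M:
            def __init__(self, r2):
                self.r2 = r2

        suite = ModelSuiteResult(
            models=[_M(v) for v in [0, 0, 0, 0.0600, 0, 0.106, 0.167]],
            labels=tuple("1234567"),
            n=386,
        )
        part = variance_partition(suite)
        assert part["habitat_share"] == pytest.approx(0.107)
        assert part["diameter_quadratic_share"] == pytest.approx(0.061)
        assert part["total"] == pytest.approx(0.167)

    def test_shares_bounded_by_total(self):
        suite = fit_model_suite(_suite_frame(386, seed=3))
        part = variance_partition(suite)
        assert 0 <= part["habitat_share"] <= part["total"]
        assert 0 <= part["diameter_quadratic_share"] <= part["total"]


class TestGroupSeparation:
    def _frame(self, olig, copi):
        return pd.DataFrame(
            {
                "g_adj": np.concatenate([olig, copi]),
                "trophic": ["oligotroph"] * len(olig) + ["copiotroph"] * len(copi),
            }
        )

    def test_identical_groups_zero_difference(self):
        df = self._frame(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert group_separation(df)["standardized_mean_difference"] == 0.0

    def test_unit_sd_groups_at_plus_minus_one(self):
        rng = np.random.default_rng(0)
        olig = rng.normal(-1, 1, size=20_000)
        copi = rng.normal(1, 1, size=20_000)
        out = group_separation(self._frame(olig, copi))
        assert out["standardized_mean_difference"] == pytest.approx(2.0, abs=0.05)

    def test_sign_convention_copiotrophs_higher_positive(self):
        df = self._frame(np.array([0.0, 0.1, -0.1]), np.array([1.0, 1.1, 0.9]))
        assert group_separation(df)["standardized_mean_difference"] > 0

    def test_missing_labels_error(self):
        df = pd.DataFrame({"g_adj": [1.0, 2.0]})
        with pytest.raises(ValueError, match="label"):
            group_separation(df)


class TestDensityContours:
    def test_standard_normal_half_max_contour_is_circular(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        cts = density_contours(x, y, levels=(0.5,))
        ring = max(cts[0.5], key=len)
        # principal-axis ratio of the ring: a circle gives 1
        centered = ring - ring.mean(axis=0)
        lam = np.linalg.eigvalsh(centered.T @ centered / len(ring))
        axis_ratio = np.sqrt(lam[1] / lam[0])
        assert axis_ratio == pytest.approx(1.0, abs=0.1)

    def test_level_one_degenerates_to_mode(self):
        rng = np.random.default_rng(1)
        cts = density_contours(rng.normal(size=500), rng.normal(size=500), levels=(1.0,))
        assert cts[1.0][0].shape == (1, 2)

    def test_zero_variance_axis_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            density_contours(np.ones(50), np.arange(50.0), levels=(0.5,))
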