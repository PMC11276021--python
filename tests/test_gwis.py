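"""Regression core: OLS, sandwich covariance, Wald tests, filters, scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gxescan as gx
from gxescan.gwis import (
    FilterConfig,
    GwisModel,
    fit_variant,
    ols_fit,
    robust_covariance,
    scan,
    variant_filters,
    wald_1df,
    wald_2df,
)


def brute_force_sandwich(x, r, kind="hc0"):
    """Triple-product oracle: explicit sum over per-observation outer products."""
    n, p = x.shape
    bread = np.linalg.inv(x.T @ x)
    if kind == "hc3":
        h = np.array([x[i] @ bread @ x[i] for i in range(n)])
        w = (r / (1 - h)) ** 2
    elif kind == "hc1":
        w = r**2 * n / (n - p)
    else:
        w = r**2
    meat = sum(w[i] * np.outer(x[i], x[i]) for i in range(n))
    return bread @ meat @ bread


class TestOls:
    def test_exact_line(self):
        x = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
        y = 2.0 + 3.0 * x[:, 1]
        beta, resid = ols_fit(x, y)
        assert np.allclose(beta, [2.0, 3.0])
        assert np.allclose(resid, 0.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 6))
        y = rng.normal(size=200)
        beta, resid = ols_fit(x, y)
        beta_ne = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.allclose(beta, beta_ne, atol=1e-10)
        # residuals orthogonal to the column space
        assert np.allclose(x.T @ resid, 0.0, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        x = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError):
            ols_fit(x, np.arange(10.0))


class TestSandwich:
    @pytest.mark.parametrize("kind", ["hc0", "hc1", "hc3"])
    def test_matches_brute_force(self, kind):
        rng = np.random.default_rng(1)
        x = np.column_stack([np.ones(80), rng.normal(size=(80, 4))])
        y = rng.normal(size=80) * (1 + np.abs(x[:, 1]))  # heteroskedastic
        _, r = ols_fit(x, y)
        v = robust_covariance(x, r, kind)
        assert np.allclose(v, brute_force_sandwich(x, r, kind), rtol=1e-10)

    @pytest.mark.parametrize("kind", ["hc0", "hc3"])
    def test_matches_statsmodels(self, kind):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        x = np.column_stack([np.ones(150), rng.normal(size=(150, 3))])
        y = x @ np.array([1.0, 0.5, -0.5, 2.0]) + rng.normal(size=150) * (
            1 + x[:, 1] ** 2
        )
        beta, r = ols_fit(x, y)
        v = robust_covariance(x, r, kind)
        res = sm.OLS(y, x).fit(cov_type=kind.upper())
        assert np.allclose(beta, res.params, atol=1e-10)
        assert np.allclose(v, res.cov_params(), rtol=1e-8)

    def test_homoskedastic_limit(self):
        # constant residuals: HC0 collapses to sigma^2 (X'X)^-1
        x = np.column_stack([np.ones(50), np.arange(50.0)])
        r = np.full(50, 2.0)
        v = robust_covariance(x, r, "hc0")
        assert np.allclose(v, 4.0 * np.linalg.inv(x.T @ x), rtol=1e-12)

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            robust_covariance(np.ones((5, 1)), np.zeros(5), "hc9")


class TestWald:
    def test_genome_wide_scale_examples(self):
        # mmHg-per-allele effects with robust SEs at the scale a large BP
        # interaction scan produces, against the two-sided normal tail
        _, p, _ = wald_1df(-8.71, 1.23)
        assert p == pytest.approx(1.428e-12, rel=0.01)
        _, p, _ = wald_1df(-5.09, 0.86)
        assert p == pytest.approx(3.247e-9, rel=0.01)
        _, p, _ = wald_1df(-7.23, 1.18)
        assert p == pytest.approx(8.95e-10, rel=0.01)

    def test_z_and_symmetry(self):
        z1, p1, lnp1 = wald_1df(2.0, 1.0)
        z2, p2, _ = wald_1df(-2.0, 1.0)
        assert z1 == 2.0 and z2 == -2.0
        assert p1 == p2 == pytest.approx(2 * stats.norm.sf(2.0))
        assert lnp1 == pytest.approx(np.log(p1))

    def test_extreme_z_stays_positive(self):
        _, p, lnp = wald_1df(100.0, 1.0)
        assert 0 < p <= 1 and np.isfinite(lnp) and lnp < -1000

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            wald_1df(1.0, 0.0)

    def test_2df_identity_covariance(self):
        chi2, p, lnp = wald_2df(np.array([2.0, 2.0]), np.eye(2))
        assert chi2 == pytest.approx(8.0)
        assert p == pytest.approx(np.exp(-4.0))  # chi2_2 tail = exp(-x/2)
        assert lnp == pytest.approx(-4.0)

    def test_2df_matches_solve_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(2, 2))
        v = a @ a.T + 0.1 * np.eye(2)
        b = rng.normal(size=2)
        chi2, _, _ = wald_2df(b, v)
        assert chi2 == pytest.approx(b @ np.linalg.solve(v, b), rel=1e-12)

    def test_2df_singular_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            wald_2df(np.array([1.0, 1.0]), np.ones((2, 2)))


class TestVariantFilters:
    def _variants(self, n):
        return pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(n)],
                "chrom": [1] * n,
                "pos": np.arange(1, n + 1) * 1000,
                "ea": ["A"] * n,
                "oa": ["G"] * n,
                "rsq": [1.0] * n,
            }
        )

    def test_mac_rsq_boundary(self):
        # variant 0: MAC x R^2 just under 20 in the exposed stratum -> drop;
        # variant 1: exactly 20 everywhere -> keep
        n = 400
        e = np.zeros(n)
        e[:200] = 1
        dos = np.zeros((n, 2))
        variants = self._variants(2)
        variants.loc[0, "rsq"] = 0.995
        dos[:20, 0] = 1.0  # exposed MAC 20 * 0.995 = 19.9
        dos[180:220, 1] = 1.0  # 20 carriers in each stratum
        dos[220:300, 1] = 1.0  # keep total comfortably above the floor
        keep, diag = variant_filters(variants, dos, e, FilterConfig())
        assert not keep[0] and diag.loc[0, "drop_reason"] == "df"
        assert keep[1]
        assert diag.loc[0, "df_exp"] == pytest.approx(19.9)

    def test_duplicates_and_monomorphic_dropped(self):
        n = 300
        e = np.zeros(n)
        e[:150] = 1
        variants = self._variants(3)
        variants.loc[1, "pos"] = variants.loc[0, "pos"]  # duplicate key
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        dos[:, 2] = 1.0  # monomorphic
        keep, diag = variant_filters(variants, dos, e)
        assert keep[0] and not keep[1] and not keep[2]
        assert diag.loc[1, "drop_reason"] == "duplicate"
        assert diag.loc[2, "drop_reason"] == "monomorphic"

    def test_low_maf_and_rsq_dropped(self):
        n = 2000
        e = np.zeros(n)
        e[:1000] = 1
        variants = self._variants(2)
        variants.loc[1, "rsq"] = 0.29
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, [0.0004, 0.3], size=(n, 2)).astype(float)
        keep, diag = variant_filters(variants, dos, e)
        assert not keep.any()
        assert diag.loc[1, "drop_reason"] == "rsq"


class TestFitVariant:
    def test_recovers_planted_interaction(self, planted_cohort):
        hc, truth = planted_cohort
        c1, c2, mask = hc.design("STST", "combined")
        j = list(hc.variants["id"]).index(truth[0].variant_id)
        res = fit_variant(
            hc.dosages[mask][:, j],
            hc.traits["SBP"][mask],
            c1.to_numpy(float),
            c2.to_numpy(float),
            hc.exposures["STST"][mask].astype(float),
        )
        assert abs(res["BETA_INT"] - truth[0].beta_gxe) < 3 * res["SE_INT"]
        assert res["P_INT"] < 1e-4

    def test_degenerate_variant_returns_none(self, small_cohort):
        hc = small_cohort
        c1, c2, mask = hc.design("STST", "combined")
        g = np.ones(int(mask.sum()))
        out = fit_variant(
            g, hc.traits["SBP"][mask], c1.to_numpy(float), c2.to_numpy(float),
            hc.exposures["STST"][mask].astype(float),
        )
        assert out is None

    def test_null_interaction_pvalues_calibrated(self, small_cohort):
        # permutation-style null: no planted effects, so P_INT over variants
        # should look uniform
        hc = small_cohort
        model = GwisModel(hc, "SBP", "STST", "combined")
        frame = model.fit().frame
        assert len(frame) >= 30
        ks = stats.kstest(frame["P_INT"], "uniform")
        assert ks.pvalue > 0.01


class TestScan:
    def test_all_eighteen_combinations(self, small_cohort):
        results = scan(small_cohort)
        assert len(results) == 18
        keys = {k[0] for k in results} | {k[1] for k in results} | {k[2] for k in results}
        assert keys == {"SBP", "DBP", "PP", "STST", "LTST", "combined", "female", "male"}

    def test_sex_strata_partition_sample(self, small_cohort):
        res = scan(small_cohort, traits=("SBP",), exposures=("STST",))
        nf = small_cohort.sex_mask("female").sum()
        nm = small_cohort.sex_mask("male").sum()
        comb = res[("SBP", "STST", "combined")].frame
        assert (comb["N"] == nf + nm).all()

    def test_fit_deterministic(self, small_cohort):
        a = GwisModel(small_cohort, "DBP", "LTST").fit().frame
        b = GwisModel(small_cohort, "DBP", "LTST").fit().frame
        pd.testing.assert_frame_equal(a, b)

    def test_summary_mentions_analysis(self, small_cohort):
        res = GwisModel(small_cohort, "SBP", "STST").fit()
        text = res.summary()
        assert "SBP x STST" in text
        assert str(res.n_variants) in text

    def test_tsv_roundtrip(self, small_cohort, tmp_path):
        res = GwisModel(small_cohort, "SBP", "STST").fit()
        res.to_tsv(tmp_path / "s.tsv")
        back = pd.read_csv(tmp_path / "s.tsv", sep="\t")
        assert list(back.columns) == gx.gwis.SUMMARY_COLUMNS
        assert len(back) == res.n_variants

    def test_invalid_arguments_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            GwisModel(small_cohort, "BMI", "STST")
        with pytest.raises(ValueError):
            GwisModel(small_cohort, "SBP", "NAPS")
        with pytest.raises(ValueError):
            GwisModel(small_cohort, "SBP", "STST", robust="hc9")
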