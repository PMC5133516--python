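import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hdscan import (
    HomozygosityProfile,
    ResponseSpec,
    WindowSpec,
    adjust_medication,
    define_htn,
    estimate_profile,
    expression_regulation,
    fdr_adjust,
    gee_association,
    gee_fit,
    homozygosity_indicator,
    prepare_phenotypes,
    significant_hd_regions,
    transform_bp,
)


def bh_oracle(p):
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def make_pheno(n, rng, ped_size=5):
    return pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "ped": [f"P{k // ped_size}" for k in range(n)],
            "age": rng.uniform(20, 80, n).round(1),
            "sex": rng.integers(0, 2, n),
            "dbp": rng.normal(80, 10, n).clip(50),
            "sbp": rng.normal(125, 15, n).clip(80),
            "med": rng.integers(0, 2, n),
        }
    )


class TestPhenotypePrep:
    def test_medication_adjustment(self):
        ph = pd.DataFrame(
            {"id": ["a", "b"], "dbp": [80.0, 80.0], "sbp": [130.0, 130.0], "med": [1, 0]}
        )
        out = adjust_medication(ph)
        assert out.loc[0, "dbp"] == 85 and out.loc[0, "sbp"] == 140
        assert out.loc[1, "dbp"] == 80 and out.loc[1, "sbp"] == 130

    def test_adjustment_is_idempotent(self):
        ph = pd.DataFrame({"id": ["a"], "dbp": [80.0], "sbp": [130.0], "med": [1]})
        twice = adjust_medication(adjust_medication(ph))
        assert twice.loc[0, "dbp"] == 85 and twice.loc[0, "sbp"] == 140

    def test_missing_med_flag_excluded_with_warning(self):
        ph = pd.DataFrame(
            {"id": ["a", "b"], "dbp": [80.0, 80], "sbp": [130.0, 130], "med": [np.nan, 0]}
        )
        with pytest.warns(UserWarning, match="missing medication"):
            out = adjust_medication(ph)
        assert out["id"].tolist() == ["b"]

    @pytest.mark.parametrize(
        "dbp,sbp,med,expected",
        [
            (91, 120, 0, 1),  # DBP exceeds 90
            (90, 140, 0, 0),  # boundaries are strict
            (80, 141, 0, 1),  # SBP exceeds 140
            (80, 120, 1, 1),  # ever medicated
            (80, 120, 0, 0),
        ],
    )
    def test_htn_rule(self, dbp, sbp, med, expected):
        ph = pd.DataFrame({"id": ["a"], "dbp": [float(dbp)], "sbp": [float(sbp)], "med": [med]})
        assert define_htn(ph).loc[0, "htn"] == expected

    def test_htn_requires_raw_bp(self):
        ph = adjust_medication(
            pd.DataFrame({"id": ["a"], "dbp": [80.0], "sbp": [130.0], "med": [1]})
        )
        with pytest.raises(ValueError, match="pre-adjustment"):
            define_htn(ph)

    def test_prepare_chain_defines_htn_before_adjustment(self):
        # DBP 88 + 5 = 93 after adjustment, but HTN must use the raw 88
        ph = pd.DataFrame({"id": ["a"], "dbp": [88.0], "sbp": [120.0], "med": [0]})
        ph2 = pd.DataFrame({"id": ["a"], "dbp": [88.0], "sbp": [120.0], "med": [1]})
        assert prepare_phenotypes(pd.concat([ph]).reset_index(drop=True)).loc[0, "htn"] == 0
        assert prepare_phenotypes(ph2).loc[0, "htn"] == 1  # via medication


class TestTransformBP:
    def test_identical_values_unchanged_by_winsorisation(self):
        v = np.full(50, 120.0)
        np.testing.assert_allclose(transform_bp(v), np.log(120.0))

    def test_extremes_capped_at_percentiles(self):
        v = np.arange(1, 101, dtype=float)  # 1..100
        out = transform_bp(v, winsor_q=0.01)
        logv = np.log(v)
        lo, hi = np.quantile(logv, [0.01, 0.99])  # type-7 order statistics
        assert out.min() == pytest.approx(lo)
        assert out.max() == pytest.approx(hi)
        assert out[0] == pytest.approx(lo) and out[-1] == pytest.approx(hi)
        np.testing.assert_allclose(out[2:-2], logv[2:-2])

    def test_log_of_one_is_zero_before_winsorisation(self):
        out = transform_bp(np.array([1.0] * 10))
        np.testing.assert_allclose(out, 0.0)

    def test_nonpositive_value_names_individual(self):
        with pytest.raises(ValueError, match="ind7"):
            transform_bp(np.array([120.0, -1.0]), ids=np.array(["ind3", "ind7"]))


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.05])[0] == pytest.approx(0.05)

    def test_hand_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_nan_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.04])
        out = fdr_adjust(p)
        np.testing.assert_allclose(out[[0, 2]], bh_oracle([0.01, 0.04]))
        assert np.isnan(out[1])

    def test_adjusted_at_least_raw_and_bounded(self, rng):
        p = rng.random(50)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestGEE:
    def test_singleton_clusters_match_robust_ols(self, rng):
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [1.0, 0.4, -0.2] + rng.normal(size=n)
        fit = gee_fit(y, X, np.arange(n))
        ols = sm.OLS(y, X).fit(cov_type="HC0")
        from scipy.stats import norm

        p_oracle = 2 * norm.sf(np.abs(ols.params / ols.bse))
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ols.bse, atol=1e-8)
        np.testing.assert_allclose(fit.pvalues, p_oracle, atol=1e-8)

    def test_matches_statsmodels_gee_gaussian(self, rng):
        n, ped = 250, 25
        groups = rng.integers(0, ped, size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [0.5, 0.8, -0.1] + rng.normal(size=ped)[groups] + rng.normal(size=n)
        fit = gee_fit(y, X, groups)
        ref = sm.GEE(
            y, X, groups=groups, cov_struct=sm.cov_struct.Exchangeable(),
            family=sm.families.Gaussian(),
        ).fit()
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-8)
        assert fit.alpha == pytest.approx(float(ref.cov_struct.dep_params), abs=1e-6)

    def test_matches_statsmodels_gee_logit(self, rng):
        n, ped = 300, 30
        groups = rng.integers(0, ped, size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        eta = X @ [-0.3, 0.8] + 0.5 * rng.normal(size=ped)[groups]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = gee_fit(y, X, groups, link="logit")
        ref = sm.GEE(
            y, X, groups=groups, cov_struct=sm.cov_struct.Exchangeable(),
            family=sm.families.Binomial(),
        ).fit()
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)


def sim_profile_pheno(n_pedigrees=5, n_sites=400, seed=5, stride=None):
    from hdscan import SimulationConfig, simulate_genotypes

    cfg = SimulationConfig(n_pedigrees=n_pedigrees, n_sites=n_sites)
    g = simulate_genotypes(cfg, np.random.default_rng(seed))
    spec = WindowSpec(anchor_stride=stride or max(1, n_sites // 40))
    prof = estimate_profile(homozygosity_indicator(g), g, spec)
    rng = np.random.default_rng(seed + 1)
    pheno = pd.DataFrame(
        {
            "id": g.sample_ids,
            "ped": g.samples["ped"],
            "age": rng.uniform(20, 80, g.n_samples).round(1),
            "sex": rng.integers(0, 2, g.n_samples),
        }
    )
    return g, prof, pheno, rng


class TestAssociationScan:
    def test_null_scan_raw_pvalues_calibrated(self):
        # disjoint windows (stride = k) over independent sites give ~independent
        # tests; pooled over 10 independent traits the rejection fraction at
        # 0.05 must sit inside its binomial 99% band
        g, prof, pheno, rng = sim_profile_pheno(
            n_pedigrees=12, n_sites=2000, stride=100
        )
        pvals = []
        for _ in range(10):
            pheno["q1"] = rng.normal(10, 2, g.n_samples)
            res = gee_association(prof, ResponseSpec("Q1"), pheno)
            pvals.extend(res["p_value"].dropna().tolist())
        pvals = np.asarray(pvals)
        frac = (pvals < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / len(pvals))
        assert abs(frac - 0.05) < half_width + 0.02

    def test_constant_intensity_flagged_untestable(self):
        g, prof, pheno, rng = sim_profile_pheno()
        prof.intensity[:, 0] = 0.7  # no variance at the first window
        pheno["q1"] = rng.normal(10, 2, g.n_samples)
        res = gee_association(prof, ResponseSpec("Q1"), pheno)
        assert res.loc[0, "status"] == "constant_intensity"
        assert np.isnan(res.loc[0, "p_value"])
        assert res["status"].iloc[1:].eq("ok").all()

    def test_scan_invariant_to_individual_order(self):
        g, prof, pheno, rng = sim_profile_pheno(n_pedigrees=3, n_sites=200)
        pheno["q1"] = rng.normal(10, 2, g.n_samples)
        res1 = gee_association(prof, ResponseSpec("Q1"), pheno)
        perm = rng.permutation(g.n_samples)
        prof2 = HomozygosityProfile(
            anchors=prof.anchors,
            intensity=prof.intensity[perm],
            individuals=[prof.individuals[i] for i in perm],
        )
        res2 = gee_association(prof2, ResponseSpec("Q1"), pheno)
        np.testing.assert_allclose(res1["p_value"], res2["p_value"], atol=1e-8)

    def test_significant_region_bounds_from_anchor_runs(self):
        res = pd.DataFrame(
            {
                "chrom": ["1"] * 6,
                "response": ["Q1"] * 6,
                "pos": [10, 20, 30, 40, 50, 60],
                "p_adjusted": [0.9, 0.01, 0.04, 0.9, 0.02, 0.9],
            }
        )
        sig = significant_hd_regions(res, alpha=0.05)
        assert len(sig) == 2
        assert sig.loc[0, ["start_bp", "end_bp"]].tolist() == [20, 30]
        assert sig.loc[0, "min_p_adjusted"] == pytest.approx(0.01)


class TestExpressionRegulation:
    def _region_setup(self):
        # 20 pedigrees: the sandwich estimator needs enough clusters for
        # its robust variance to be calibrated
        g, prof, pheno, rng = sim_profile_pheno(n_pedigrees=20, n_sites=400, seed=9)
        pos = prof.anchors["pos"]
        region = {"chrom": "1", "start_bp": int(pos.iloc[5]), "end_bp": int(pos.iloc[15])}
        return g, prof, pheno, rng, region

    def test_planted_transcript_significant_among_nulls(self):
        from hdscan.association import region_intensity

        g, prof, pheno, rng, region = self._region_setup()
        lam = region_intensity(prof, region)
        n_tr = 1000
        expr = rng.normal(5, 1, size=(n_tr, g.n_samples))
        expr[0] += 2.0 * lam * 10  # strongly intensity-driven transcript
        edf = pd.DataFrame(expr, index=[f"tr{k}" for k in range(n_tr)], columns=g.sample_ids)
        res = expression_regulation(edf, prof, region, pheno)
        planted = res.set_index("transcript").loc["tr0"]
        assert planted["p_adjusted"] < 0.05
        nulls = res.set_index("transcript").drop("tr0")
        # FDR-controlled: very few null transcripts declared
        assert (nulls["p_adjusted"] < 0.05).mean() < 0.01

    def test_constant_transcript_untestable(self):
        g, prof, pheno, rng, region = self._region_setup()
        edf = pd.DataFrame(
            np.full((1, g.n_samples), 3.0), index=["flat"], columns=g.sample_ids
        )
        res = expression_regulation(edf, prof, region, pheno)
        assert res.loc[0, "status"] == "untestable"
        assert np.isnan(res.loc[0, "p_value"])
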