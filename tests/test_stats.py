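"""Oracles and invariants for the ANOVA, LMM, CLMM and Kruskal-Wallis."""

import dataclasses
import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prehension.stats import clmm_fit, kruskal_wallis, lmm_fit, rm_anova
from prehension.synthetic_data import (
    RatingsConfig,
    SimulationConfig,
    simulate_feature_table,
    simulate_ratings,
)

warnings.filterwarnings("ignore", category=UserWarning, module="prehension.stats")


def feature_table(seed=0, n_participants=10, n_blocks=2, null=False, **kw):
    cfg = SimulationConfig(n_participants=n_participants, n_blocks=n_blocks, seed=seed)
    if null:
        cfg = cfg.null()
    if kw:
        cfg = dataclasses.replace(cfg, **kw)
    return simulate_feature_table(cfg, np.random.default_rng(seed))


def gloss_frame(rng, **kw):
    cfg = dataclasses.replace(RatingsConfig(), **kw)
    df = pd.DataFrame([dataclasses.asdict(r) for r in simulate_ratings(cfg, rng)])
    df = df[df.dimension == "glossiness"].copy()
    df["surface"] = df.stimulus_id.str[0].map({"m": "matte", "s": "shiny"})
    df["content"] = df.stimulus_id.str[1].map({"e": "empty", "f": "filled"})
    return df


class TestRmAnova:
    def test_matches_statsmodels_anova_rm(self):
        """Oracle: AnovaRM on the identical subject-by-cell means."""
        from statsmodels.stats.anova import AnovaRM

        ft = feature_table(seed=4)
        res = rm_anova(ft, "adjustment_time_ms", ["surface", "content", "feedback"])
        agg = ft.groupby(["participant_id", "surface", "content", "feedback"],
                         as_index=False)["adjustment_time_ms"].mean()
        want = AnovaRM(agg, "adjustment_time_ms", "participant_id",
                       within=["surface", "content", "feedback"]).fit().anova_table
        for t in res.terms:
            # AnovaRM labels interactions with ':' in the same factor order
            assert t["name"] in want.index, f"term {t['name']} missing from oracle"
            row = want.loc[t["name"]]
            assert t["F"] == pytest.approx(row["F Value"], rel=1e-8)
            assert t["p"] == pytest.approx(row["Pr > F"], abs=1e-10)

    def test_two_condition_design_equals_paired_t_squared(self, rng):
        subjects = [f"S{i}" for i in range(12)]
        a = rng.normal(10, 2, 12)
        b = a + rng.normal(1, 1.5, 12)
        df = pd.DataFrame({
            "participant_id": subjects * 2,
            "cond": ["x"] * 12 + ["y"] * 12,
            "dv": np.concatenate([a, b]),
        })
        res = rm_anova(df, "dv", ["cond"])
        t, p = sps.ttest_rel(a, b)
        assert res.terms[0]["F"] == pytest.approx(t**2, rel=1e-8)
        assert res.terms[0]["p"] == pytest.approx(p, rel=1e-8)

    def test_eta_squared_matches_pingouin_two_factor(self):
        pingouin = pytest.importorskip("pingouin")
        ft = feature_table(seed=8)
        res = rm_anova(ft, "adjustment_time_ms", ["surface", "content"])
        agg = ft.groupby(["participant_id", "surface", "content"],
                         as_index=False)["adjustment_time_ms"].mean()
        want = pingouin.rm_anova(
            data=agg, dv="adjustment_time_ms", within=["surface", "content"],
            subject="participant_id", detailed=True, effsize="ng2",
        )
        for t in res.terms:
            name = t["name"].replace(":", " * ")
            row = want[want.Source == name].iloc[0]
            assert t["F"] == pytest.approx(row["F"], rel=1e-6)
            assert res.effect_sizes[t["name"]] == pytest.approx(row["ng2"], rel=1e-6)

    def test_constant_dv_is_flagged_degenerate(self):
        ft = feature_table(seed=1)
        ft["const"] = 5.0
        res = rm_anova(ft, "const", ["surface", "content", "feedback"])
        assert res.degenerate

    def test_missing_cell_raises_with_explicit_message(self):
        ft = feature_table(seed=1)
        ft = ft[~((ft.participant_id == "P01") & (ft.content == "filled"))]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(ft, "adjustment_time_ms", ["surface", "content", "feedback"])

    def test_f_invariant_under_affine_dv_rescale(self):
        ft = feature_table(seed=6)
        a = rm_anova(ft, "adjustment_time_ms", ["content"])
        ft["scaled"] = 3.7 * ft["adjustment_time_ms"] + 100.0
        b = rm_anova(ft, "scaled", ["content"])
        assert a.terms[0]["F"] == pytest.approx(b.terms[0]["F"], rel=1e-9)


class TestLmm:
    def test_zero_subject_variance_reduces_to_ols(self):
        import statsmodels.formula.api as smf

        ft = feature_table(seed=2, subject_sd={k: 0.0 for k in
                           ("duration", "adjustment", "transport_peak",
                            "mga_rel", "mga", "deviation")})
        res = lmm_fit(ft, "adjustment_time_ms", ["content"], lrt=False)
        ols = smf.ols("adjustment_time_ms ~ content", ft).fit()
        assert res.term("content")["estimate"] == pytest.approx(
            ols.params["content[T.filled]"], abs=1e-6
        )

    def test_estimate_is_the_content_mean_difference_when_balanced(self):
        ft = feature_table(seed=3)
        res = lmm_fit(ft, "adjustment_time_ms", ["content"])
        means = ft.groupby("content")["adjustment_time_ms"].mean()
        assert res.term("content")["estimate"] == pytest.approx(
            means["filled"] - means["empty"], abs=1e-4
        )

    def test_lrt_chi_square_nonnegative_and_loglik_monotone(self):
        ft = feature_table(seed=5)
        small = lmm_fit(ft, "adjustment_time_ms", ["content"])
        big = lmm_fit(ft, "adjustment_time_ms", ["content", "surface", "feedback"])
        assert all(t["chi_square"] >= 0 for t in big.terms)
        assert big.loglik >= small.loglik - 1e-6

    def test_estimate_equivariant_under_dv_scaling(self):
        ft = feature_table(seed=7)
        a = lmm_fit(ft, "adjustment_time_ms", ["content"], lrt=False)
        ft["scaled"] = 2.5 * ft["adjustment_time_ms"]
        b = lmm_fit(ft, "scaled", ["content"], lrt=False)
        assert b.term("content")["estimate"] == pytest.approx(
            2.5 * a.term("content")["estimate"], rel=1e-6
        )

    def test_lrt_p_uniform_under_permutation_null(self):
        """Permute the dv across all rows: LRT p-values must look uniform."""
        ft = feature_table(seed=11, n_participants=8, n_blocks=1)
        rng = np.random.default_rng(99)
        pvals = []
        y = ft["adjustment_time_ms"].to_numpy()
        for _ in range(100):
            ft = ft.assign(adjustment_time_ms=rng.permutation(y))
            pvals.append(
                lmm_fit(ft, "adjustment_time_ms", ["content"]).term("content")["p"]
            )
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestClmm:
    def test_sigma_zero_data_matches_plain_cumulative_link(self):
        """Oracle: statsmodels OrderedModel on the same pooled data."""
        from patsy import dmatrix
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(11)
        df = gloss_frame(rng, subject_sd=0.0, n_participants=40,
                         effects={"glossiness": {"surface": 1.5, "content": 0.3}})
        res = clmm_fit(df, ["content", "surface"], lrt=False, fix_sigma=0.0)
        X = dmatrix("content + surface", df, return_type="dataframe").drop(
            columns="Intercept")
        y = df["value"].map(
            {v: i for i, v in enumerate(np.sort(df["value"].unique()))})
        om = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        got = res.extra["beta"]
        assert got["content[T.filled]"] == pytest.approx(om.params.iloc[0], abs=1e-3)
        assert got["surface[T.shiny]"] == pytest.approx(om.params.iloc[1], abs=1e-3)
        k = X.shape[1]
        want_th = np.concatenate(
            [[om.params.iloc[k]], om.params.iloc[k] + np.cumsum(np.exp(om.params.iloc[k + 1:]))]
        )
        np.testing.assert_allclose(res.extra["thresholds"], want_th, atol=1e-3)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_binary_collapse_matches_lme4_glmer(self, tmp_path):
        """Oracle: mixed logistic fit (lme4::glmer, matched quadrature)."""
        rng = np.random.default_rng(21)
        df = gloss_frame(rng, subject_sd=1.0, n_participants=30,
                         effects={"glossiness": {"surface": 1.2, "content": 0.4}})
        df["ybin"] = (df.value >= 4).astype(int)
        res = clmm_fit(df, ["surface"], dv="ybin", lrt=False, n_quad_nodes=25)
        csv = tmp_path / "bin.csv"
        df[["participant_id", "surface", "ybin"]].to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(ybin ~ surface + (1|participant_id), data=d,
                   family=binomial, nAGQ=25)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        intercept, beta, sd = (float(x) for x in out.stdout.split())
        # our first threshold is the negated glmer intercept
        assert res.extra["thresholds"][0] == pytest.approx(-intercept, abs=1e-3)
        assert res.term("surface")["estimate"] == pytest.approx(beta, abs=1e-3)
        assert res.extra["sigma"] == pytest.approx(sd, abs=1e-3)

    def test_loglik_plateaus_with_quadrature_nodes(self):
        rng = np.random.default_rng(5)
        df = gloss_frame(rng, subject_sd=1.5)
        lls = [clmm_fit(df, ["surface"], lrt=False, n_quad_nodes=q).loglik
               for q in (7, 15, 21)]
        assert lls[1] >= lls[0] - 1e-6
        assert abs(lls[2] - lls[1]) <= abs(lls[1] - lls[0]) + 1e-9

    def test_thresholds_strictly_increasing(self):
        rng = np.random.default_rng(13)
        df = gloss_frame(rng)
        res = clmm_fit(df, ["surface"], lrt=False)
        assert np.all(np.diff(res.extra["thresholds"]) > 0)

    def test_single_category_response_rejected(self):
        rng = np.random.default_rng(1)
        df = gloss_frame(rng)
        df["value"] = 4
        with pytest.raises(ValueError):
            clmm_fit(df, ["surface"])


class TestKruskalWallis:
    def test_two_groups_equal_mann_whitney_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 25)
        df = pd.DataFrame({"dv": np.concatenate([a, b]),
                           "block": [1] * 30 + [2] * 25})
        out = kruskal_wallis(df, "dv", "block")
        u = sps.mannwhitneyu(a, b, use_continuity=False,
                             alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert out["H"] == pytest.approx(z**2, rel=1e-8)

    def test_identical_distributions_give_uniform_p(self, rng):
        pvals = []
        base = rng.normal(size=100)
        for _ in range(300):
            df = pd.DataFrame({"dv": rng.permutation(base),
                               "block": np.repeat([1, 2, 3, 4, 5], 20)})
            pvals.append(kruskal_wallis(df, "dv", "block")["p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_all_tied_data_flagged_degenerate(self):
        df = pd.DataFrame({"dv": [3.0] * 20, "block": [1, 2, 3, 4] * 5})
        assert kruskal_wallis(df, "dv", "block")["degenerate"]

    def test_h_invariant_under_monotone_rescale(self, rng):
        df = pd.DataFrame({"dv": rng.normal(size=60),
                           "block": np.repeat([1, 2, 3], 20)})
        a = kruskal_wallis(df, "dv", "block")
        df["dv"] = 10 * df["dv"] + 3
        b = kruskal_wallis(df, "dv", "block")
        assert a["H"] == pytest.approx(b["H"], rel=1e-12)
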