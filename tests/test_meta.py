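"""Multilevel meta-model: closed-form oracles, REML behaviour, Wald tests,
publication-bias diagnostics, and a cross-check against R metafor."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import befmeta as b
from befmeta.meta import MetaSpec


def iv_weighted_mean(y, v):
    """Independent closed-form oracle: inverse-variance weighted mean."""
    w = 1.0 / np.asarray(v)
    mu = np.sum(w * y) / np.sum(w)
    return mu, np.sqrt(1.0 / np.sum(w))


def fit(df, **kw):
    defaults = dict(outcome="z", variance_column="var_z")
    defaults.update(kw)
    return b.fit_meta(df, MetaSpec(**defaults))


class TestFixedEffectOracle:
    def test_two_study_worked_example(self):
        df = pd.DataFrame({"z": [0.2, 0.6], "var_z": [0.04, 0.01],
                           "case_study_id": ["a", "b"]})
        f = fit(df, fixed_components={"study": 0.0})
        assert f.coefficients["intercept"] == pytest.approx(0.52, abs=1e-10)
        assert f.se["intercept"] == pytest.approx(np.sqrt(1 / 125), abs=1e-10)

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            k = int(rng.integers(3, 12))
            y = rng.normal(0, 0.5, k)
            v = rng.uniform(0.01, 0.3, k)
            df = pd.DataFrame({"z": y, "var_z": v, "case_study_id": np.arange(k)})
            f = fit(df, fixed_components={"study": 0.0})
            mu, se = iv_weighted_mean(y, v)
            assert f.coefficients["intercept"] == pytest.approx(mu, abs=1e-8)
            assert f.se["intercept"] == pytest.approx(se, abs=1e-8)

    def test_identical_effects_give_zero_heterogeneity(self):
        df = pd.DataFrame({"z": [0.3] * 6, "var_z": [0.05] * 6,
                           "case_study_id": list("abcdef")})
        f = fit(df)
        assert f.sigma2["study"] == pytest.approx(0.0, abs=1e-6)
        assert f.coefficients["intercept"] == pytest.approx(0.3, abs=1e-8)


def dense_reml_grid(y, v, grid):
    """Brute-force restricted likelihood over a tau2 grid (one obs/study)."""
    V = v[:, None] + grid[None, :]
    w = 1.0 / V
    mu = (w * y[:, None]).sum(0) / w.sum(0)
    ll = -0.5 * (
        np.log(V).sum(0) + np.log(w.sum(0)) + (w * (y[:, None] - mu) ** 2).sum(0)
    )
    return grid[np.argmax(ll)]


class TestRemlOracle:
    def test_matches_grid_search(self):
        rng = np.random.default_rng(3)
        grid = np.arange(0.0, 2.0001, 1e-4)
        for _ in range(8):
            k = int(rng.integers(6, 11))
            v = 1.0 / (rng.integers(5, 25, k) - 3)
            tau = rng.uniform(0.0, 0.6)
            y = rng.normal(-0.3, np.sqrt(v + tau**2))
            df = pd.DataFrame({"z": y, "var_z": v, "case_study_id": np.arange(k)})
            f = fit(df)
            assert f.sigma2["study"] == pytest.approx(
                dense_reml_grid(y, v, grid), abs=1.5e-4
            )

    def test_recovers_grand_mean(self, small_meta_table):
        f = fit(small_meta_table, random=("study", "observation"))
        assert f.coefficients["intercept"] == pytest.approx(-0.3, abs=3 * f.se["intercept"])
        assert f.converged


class TestShiftInvariance:
    def test_adding_constant_shifts_only_intercept(self, small_meta_table):
        f1 = fit(small_meta_table, moderators=("x",))
        shifted = small_meta_table.assign(z=small_meta_table["z"] + 0.7)
        f2 = fit(shifted, moderators=("x",))
        assert f2.coefficients["intercept"] == pytest.approx(
            f1.coefficients["intercept"] + 0.7, abs=1e-4
        )
        assert f2.coefficients["x"] == pytest.approx(f1.coefficients["x"], abs=1e-4)
        assert f2.sigma2["study"] == pytest.approx(f1.sigma2["study"], abs=1e-4)


class TestWaldQM:
    def test_single_coefficient_value(self):
        df = pd.DataFrame({"z": [0.2, 0.6], "var_z": [0.04, 0.01],
                           "case_study_id": ["a", "b"]})
        f = fit(df, fixed_components={"study": 0.0})
        qm, dfree, p = b.wald_qm(f, "intercept")
        # exact: 0.52^2 * 125 = 33.80 (33.84 arises only from rounding the SE)
        assert qm == pytest.approx((0.52 / np.sqrt(1 / 125)) ** 2, rel=1e-6)
        assert qm == pytest.approx(33.80, abs=0.01)
        assert dfree == 1

    def test_null_moderator_gives_small_qm(self, small_meta_table):
        f = fit(small_meta_table, moderators=("group",),
                random=("study", "observation"))
        qm, dfree, p = b.wald_qm(f, "group")
        assert dfree == 1 and qm >= 0.0

    def test_type_one_error_calibrated(self):
        # Wald test of a null categorical moderator over many simulated metas
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 600
        for _ in range(n_sim):
            k = 40
            v = 1.0 / (rng.integers(8, 25, k) - 3)
            y = rng.normal(0, np.sqrt(v + 0.04))
            df = pd.DataFrame({
                "z": y, "var_z": v, "case_study_id": np.arange(k),
                "g": rng.choice(["a", "b"], k),
            })
            f = fit(df, moderators=("g",))
            rejections += b.wald_qm(f, "g")[2] < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.025)

    def test_unknown_term_rejected(self, small_meta_table):
        f = fit(small_meta_table)
        with pytest.raises(ValueError):
            b.wald_qm(f, "nope")


class TestGrandMeans:
    def test_ci_width_and_duality(self):
        rng = np.random.default_rng(4)
        k = 60
        v = np.full(k, 0.04)
        driver = np.where(np.arange(k) % 2 == 0, "stressor", "nutrient")
        y = np.where(driver == "stressor", -0.4, 0.0) + rng.normal(0, np.sqrt(v))
        df = pd.DataFrame({"z": y, "var_z": v, "case_study_id": np.arange(k),
                           "driver": driver})
        f = fit(df, moderators=("driver",))
        gm = b.grand_means(f, "driver")
        for _, row in gm.iterrows():
            assert row["ci_high"] - row["estimate"] == pytest.approx(
                1.96 * row["se"], abs=1e-3
            )
            excludes_zero = row["ci_low"] > 0 or row["ci_high"] < 0
            assert excludes_zero == (row["p"] < 0.05)
        s = gm.set_index("group").loc["stressor"]
        assert s["estimate"] == pytest.approx(-0.4, abs=3 * s["se"])


class TestEgger:
    def test_symmetric_funnel_small_intercept(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.02, 0.4, 200)
        df = pd.DataFrame({"z": rng.normal(0.2, np.sqrt(v)), "var_z": v})
        res = b.egger_test(df)
        assert abs(res.t) < 3

    def test_preconditions(self):
        with pytest.raises(ValueError):
            b.egger_test(pd.DataFrame({"z": [0.1, 0.2], "var_z": [0.1, 0.2]}))
        with pytest.raises(ValueError):
            b.egger_test(pd.DataFrame({"z": [0.1, 0.2, 0.3],
                                       "var_z": [0.1, 0.1, 0.1]}))


class TestFunnelData:
    def test_rows_and_groups_preserved(self, effects_dataset):
        eff = effects_dataset.effects
        out = b.funnel_data(eff)
        assert len(out) == len(eff)
        assert set(out["group"]) == set(eff["driver"])


class TestRankDeficiency:
    def test_aliased_terms_named(self, small_meta_table):
        df = small_meta_table.assign(x2=small_meta_table["x"])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit(df, moderators=("x", "x2"))

    def test_constant_moderator_rejected(self, small_meta_table):
        df = small_meta_table.assign(c="same")
        with pytest.raises(ValueError, match="single level"):
            fit(df, moderators=("c",))


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R not available for the cross-check")
def test_against_metafor_rma_mv(tmp_path):
    """Independent oracle: metafor's rma.mv on a small nested dataset."""
    rng = np.random.default_rng(11)
    k, m = 12, 2
    sidx = np.repeat(np.arange(k), m)
    v = 1.0 / (rng.integers(5, 25, k * m) - 3)
    u = rng.normal(0, 0.3, k)[sidx]
    x = rng.normal(0, 1, k * m)
    y = -0.2 + 0.3 * x + u + rng.normal(0, 0.15, k * m) + rng.normal(0, np.sqrt(v))
    df = pd.DataFrame({"z": y, "var_z": v, "x": x, "case_study_id": sidx,
                       "obs": np.arange(k * m)})
    csv = tmp_path / "fixture.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        "suppressMessages(library(metafor))\n"
        f"d <- read.csv('{csv}')\n"
        "f <- rma.mv(z, var_z, mods=~x, random=~1|case_study_id/obs, data=d,"
        " method='REML')\n"
        "fm <- rma.mv(z, var_z, mods=~x, random=~1|case_study_id/obs, data=d,"
        " method='ML')\n"
        "cat(coef(f), f$se, f$sigma2, logLik(f), AIC(fm), sep='\\n')\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=300)
    assert out.returncode == 0, out.stderr
    vals = [float(t) for t in out.stdout.split()]
    icpt, slope, se_i, se_s, s2_study, s2_obs, ll, aic_ml = vals
    f = fit(df, moderators=("x",), random=("study", "observation"))
    assert f.coefficients["intercept"] == pytest.approx(icpt, abs=2e-4)
    assert f.coefficients["x"] == pytest.approx(slope, abs=2e-4)
    assert f.se["intercept"] == pytest.approx(se_i, abs=2e-4)
    assert f.se["x"] == pytest.approx(se_s, abs=2e-4)
    assert f.sigma2["study"] == pytest.approx(s2_study, abs=5e-4)
    assert f.sigma2["observation"] == pytest.approx(s2_obs, abs=5e-4)
    assert f.loglik == pytest.approx(ll, abs=1e-3)
    assert f.AIC_ML == pytest.approx(aic_ml, abs=1e-3)
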