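"""Group statistics: psychometric fit, mixed ANOVA, OLS, mediation."""

import numpy as np
import pandas as pd
import pytest

from assrlab import stats as ast


def _logistic(x, loc, scale=1.0):
    return 1.0 / (1.0 + np.exp(-(x - loc) / scale))


class TestSnr50:
    def test_step_crossing_at_2db(self):
        levels = np.array([-4.0, 0.0, 1.0, 3.0, 4.0, 8.0])
        y = (levels > 2.0).astype(float)
        fit = ast.fit_snr50(levels, y)
        assert fit.snr50_db == pytest.approx(2.0, abs=0.3)
        assert fit.sin_loss_db == pytest.approx(fit.snr50_db + 2.0)

    def test_logistic_recovery(self):
        rng = np.random.default_rng(0)
        levels = np.linspace(-6, 9, 8)
        n = 500
        y = rng.binomial(n, _logistic(levels, 1.5)) / n
        fit = ast.fit_snr50(levels, y)
        assert fit.snr50_db == pytest.approx(1.5, abs=0.2)

    def test_shift_equivariance(self):
        levels = np.linspace(-6, 9, 8)
        y = _logistic(levels, 1.0)
        f0 = ast.fit_snr50(levels, y)
        f3 = ast.fit_snr50(levels + 3.0, y)
        assert f3.snr50_db == pytest.approx(f0.snr50_db + 3.0, abs=1e-3)

    def test_degenerate_data_rejected(self):
        levels = np.linspace(-6, 9, 6)
        with pytest.raises(ValueError):
            ast.fit_snr50(levels, np.ones(6))
        with pytest.raises(ValueError):
            ast.fit_snr50(levels[:3], np.array([0.2, 0.5, 0.9]))


def _toy_mixed_table(rng=None, effects=None):
    """Balanced 2-group x 2x2-within table with known cell structure."""
    rng = rng or np.random.default_rng(0)
    effects = effects or {}
    rows = []
    for g, group in enumerate(("young", "older")):
        for s in range(6):
            subj = f"{group}{s}"
            base = rng.normal(0, 1.0)
            for h, hemi in enumerate(("left", "right")):
                for c, cond in enumerate(("quiet", "noise")):
                    val = (base + g * effects.get("group", 0.0)
                           + h * effects.get("hemisphere", 0.0)
                           + c * effects.get("condition", 0.0)
                           + g * c * effects.get("group*condition", 0.0)
                           + rng.normal(0, 0.3))
                    rows.append({"id": subj, "group": group,
                                 "hemisphere": hemi, "condition": cond,
                                 "amplitude": val})
    return pd.DataFrame(rows)


def _brute_force_mixed_anova(df):
    """Independent sums-of-squares oracle via explicit mean arithmetic."""
    ids = sorted(df["id"].unique())
    g_of = {i: df[df["id"] == i]["group"].iloc[0] for i in ids}
    hs = sorted(df["hemisphere"].unique())
    cs = sorted(df["condition"].unique())
    y = {(i, h, c): df[(df["id"] == i) & (df["hemisphere"] == h)
                       & (df["condition"] == c)]["amplitude"].mean()
         for i in ids for h in hs for c in cs}
    grand = np.mean(list(y.values()))

    def mean_over(pred):
        vals = [v for k, v in y.items() if pred(k)]
        return np.mean(vals), len(vals)

    ss = {}
    groups = sorted(set(g_of.values()))
    ss["group"] = sum(
        mean_over(lambda k, g=g: g_of[k[0]] == g)[1]
        * (mean_over(lambda k, g=g: g_of[k[0]] == g)[0] - grand) ** 2
        for g in groups)
    ss["hemisphere"] = sum(
        mean_over(lambda k, h=h: k[1] == h)[1]
        * (mean_over(lambda k, h=h: k[1] == h)[0] - grand) ** 2 for h in hs)
    ss["condition"] = sum(
        mean_over(lambda k, c=c: k[2] == c)[1]
        * (mean_over(lambda k, c=c: k[2] == c)[0] - grand) ** 2 for c in cs)
    ss_subj = sum(
        mean_over(lambda k, i=i: k[0] == i)[1]
        * (mean_over(lambda k, i=i: k[0] == i)[0] - grand) ** 2 for i in ids)
    ss["subject"] = ss_subj
    ss["s_within"] = ss_subj - ss["group"]

    def inter(cols_pred_levels, mains):
        total = 0.0
        for pred, _ in cols_pred_levels:
            m, n = mean_over(pred)
            total += n * (m - grand) ** 2
        return total - sum(mains)

    gh = [(lambda k, g=g, h=h: g_of[k[0]] == g and k[1] == h, None)
          for g in groups for h in hs]
    ss["group*hemisphere"] = inter(gh, [ss["group"], ss["hemisphere"]])
    gc = [(lambda k, g=g, c=c: g_of[k[0]] == g and k[2] == c, None)
          for g in groups for c in cs]
    ss["group*condition"] = inter(gc, [ss["group"], ss["condition"]])
    hc = [(lambda k, h=h, c=c: k[1] == h and k[2] == c, None)
          for h in hs for c in cs]
    ss["hemisphere*condition"] = inter(hc, [ss["hemisphere"],
                                            ss["condition"]])
    sh = [(lambda k, i=i, h=h: k[0] == i and k[1] == h, None)
          for i in ids for h in hs]
    ss["s*hemisphere"] = inter(sh, [ss["subject"], ss["hemisphere"],
                                    ss["group*hemisphere"]])
    sc = [(lambda k, i=i, c=c: k[0] == i and k[2] == c, None)
          for i in ids for c in cs]
    ss["s*condition"] = inter(sc, [ss["subject"], ss["condition"],
                                   ss["group*condition"]])
    ghc = [(lambda k, g=g, h=h, c=c: g_of[k[0]] == g and k[1] == h
            and k[2] == c, None) for g in groups for h in hs for c in cs]
    ss["group*hemisphere*condition"] = inter(
        ghc, [ss["group"], ss["hemisphere"], ss["condition"],
              ss["group*hemisphere"], ss["group*condition"],
              ss["hemisphere*condition"]])
    ss_total = sum((v - grand) ** 2 for v in y.values())
    ss["s*hemisphere*condition"] = (
        ss_total - ss["subject"] - ss["hemisphere"] - ss["condition"]
        - ss["group*hemisphere"] - ss["group*condition"]
        - ss["hemisphere*condition"] - ss["group*hemisphere*condition"]
        - ss["s*hemisphere"] - ss["s*condition"])

    n_subj, n_groups = len(ids), len(groups)
    df_s = n_subj - n_groups
    out = {}
    out["group"] = (ss["group"] / (n_groups - 1)) / (ss["s_within"] / df_s)
    out["hemisphere"] = (ss["hemisphere"] / 1) / (ss["s*hemisphere"] / df_s)
    out["condition"] = (ss["condition"] / 1) / (ss["s*condition"] / df_s)
    out["group*condition"] = (ss["group*condition"] / 1) \
        / (ss["s*condition"] / df_s)
    out["hemisphere*condition"] = (ss["hemisphere*condition"] / 1) \
        / (ss["s*hemisphere*condition"] / df_s)
    return out


class TestMixedAnova:
    def test_matches_brute_force_oracle(self):
        df = _toy_mixed_table(effects={"condition": 1.0,
                                       "group*condition": 0.5,
                                       "hemisphere": 0.3})
        res = ast.mixed_anova(df, dv="amplitude", subject="id",
                              within=["hemisphere", "condition"],
                              between="group")
        oracle = _brute_force_mixed_anova(df)
        for effect, f_expected in oracle.items():
            f_got = res.effect(effect)["F"]
            assert f_got == pytest.approx(f_expected, rel=1e-10), effect

    def test_matches_pingouin_on_collapsed_design(self):
        """Collapsing one within factor, F values agree with an
        independent mixed-ANOVA implementation."""
        import pingouin as pg
        df = _toy_mixed_table(effects={"condition": 1.5,
                                       "group*condition": 0.6})
        collapsed = (df.groupby(["id", "group", "condition"],
                                as_index=False)["amplitude"].mean())
        collapsed["hemisphere"] = "both"
        # duplicate the collapsed factor so the 2x2 machinery still runs
        doubled = pd.concat([collapsed,
                             collapsed.assign(hemisphere="both2")])
        res = ast.mixed_anova(doubled, dv="amplitude", subject="id",
                              within=["hemisphere", "condition"],
                              between="group")
        ref = pg.mixed_anova(collapsed, dv="amplitude", within="condition",
                             subject="id", between="group")
        f_ref = {r["Source"]: r["F"] for _, r in ref.iterrows()}
        assert res.effect("group")["F"] == pytest.approx(f_ref["group"],
                                                         rel=1e-9)
        assert res.effect("condition")["F"] == pytest.approx(
            f_ref["condition"], rel=1e-9)
        assert res.effect("group*condition")["F"] == pytest.approx(
            f_ref["Interaction"], rel=1e-9)

    def test_all_cells_equal_gives_zero_f(self):
        df = _toy_mixed_table()
        df["amplitude"] = 1.0
        res = ast.mixed_anova(df, dv="amplitude", subject="id",
                              within=["hemisphere", "condition"],
                              between="group")
        assert (res.table["F"].abs() < 1e-20).all()

    def test_pure_condition_effect_detected(self):
        df = _toy_mixed_table(effects={"condition": 2.0})
        res = ast.mixed_anova(df, dv="amplitude", subject="id",
                              within=["hemisphere", "condition"],
                              between="group")
        assert res.effect("condition")["p"] < 0.001
        assert res.effect("hemisphere")["p"] > 0.01

    def test_ges_in_unit_interval(self):
        df = _toy_mixed_table(effects={"condition": 1.0, "group": 0.8})
        res = ast.mixed_anova(df, dv="amplitude", subject="id",
                              within=["hemisphere", "condition"],
                              between="group")
        assert res.table["ges"].between(0, 1).all()

    def test_missing_cells_rejected(self):
        df = _toy_mixed_table().iloc[:-1]
        with pytest.raises(ValueError):
            ast.mixed_anova(df, dv="amplitude", subject="id",
                            within=["hemisphere", "condition"],
                            between="group")

    def test_row_order_invariance(self):
        df = _toy_mixed_table(effects={"condition": 1.0})
        shuffled = df.sample(frac=1.0, random_state=1)
        a = ast.mixed_anova(df, dv="amplitude", subject="id",
                            within=["hemisphere", "condition"],
                            between="group").table
        b = ast.mixed_anova(shuffled, dv="amplitude", subject="id",
                            within=["hemisphere", "condition"],
                            between="group").table
        assert np.allclose(a["F"], b["F"])


class TestLinearAndContrasts:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ast.fit_linear(x, 2 * x)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ast.fit_linear(np.ones(5), np.arange(5.0))

    def test_t_matches_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        res = ast.group_contrast(a, b, equal_var=True)
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.t_stat == pytest.approx(t_manual, abs=1e-12)

    def test_identical_groups_t_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        res = ast.group_contrast(a, a.copy())
        assert res.t_stat == 0.0

    def test_paired_contrast_ci_covers_difference(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 1, 30)
        b = a - 1.0 + rng.normal(0, 0.2, 30)
        res = ast.paired_contrast(a, b)
        assert res.ci95[0] < 1.0 < res.ci95[1]
        assert res.p_value < 1e-6

    def test_null_p_uniformity(self):
        """Under independence the OLS F-test p-value is uniform."""
        from scipy.stats import kstest
        rng = np.random.default_rng(1)
        ps = [ast.fit_linear(rng.standard_normal(20),
                             rng.standard_normal(20)).p_value
              for _ in range(300)]
        assert kstest(ps, "uniform").pvalue > 0.01


class TestMediation:
    def test_path_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal(40)
        M = 0.7 * X + rng.standard_normal(40)
        Y = 0.3 * X + 0.5 * M + rng.standard_normal(40)
        res = ast.mediate(X, M, Y, n_boot=50, seed=0)
        assert res.c == pytest.approx(res.c_prime + res.a * res.b,
                                      abs=1e-10)

    def test_chain_recovery(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = rng.standard_normal(n)
        M = 0.5 * X + rng.standard_normal(n) * 0.5
        Y = 0.5 * M + rng.standard_normal(n) * 0.5
        res = ast.mediate(X, M, Y, n_boot=300, seed=2)
        assert res.indirect == pytest.approx(0.25, abs=0.02)
        assert res.ci95["c_prime"][0] < 0 < res.ci95["c_prime"][1]
        assert res.p_values["indirect"] < 0.01

    def test_null_indirect_not_rejected_excessively(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 60
        for _ in range(reps):
            X = rng.standard_normal(40)
            M = rng.standard_normal(40)
            Y = rng.standard_normal(40)
            res = ast.mediate(X, M, Y, n_boot=199, seed=int(rng.integers(2**31)))
            hits += res.p_values["indirect"] < 0.05
        # nominal alpha with binomial slack
        assert hits / reps < 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ast.mediate(np.ones(20), np.arange(20.0), np.arange(20.0))
        with pytest.raises(ValueError):
            ast.mediate(np.arange(5.0), np.arange(5.0), np.arange(5.0))
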