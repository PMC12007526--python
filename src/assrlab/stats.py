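"""Group-level statistics for the per-participant measures table.

Covers the inferential toolkit of the study design: mixed-design ANOVA
(two within-participant factors, one between-group factor) with
generalized eta squared, OLS linear models with confidence bands, two-
sample (Welch) and paired t contrasts, the logistic psychometric fit that
yields SNR_50 and speech-in-noise loss, and single-mediator path analysis
with case-resampling bootstrap inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
import statsmodels.api as sm

__all__ = ["LinearModelResult", "AnovaResult", "PsychometricFit",
           "MediationResult", "ContrastResult", "fit_snr50", "mixed_anova",
           "fit_linear", "group_contrast", "paired_contrast", "mediate"]


@dataclass
class LinearModelResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    slope_ci95: tuple[float, float]
    n: int


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, F, df1, df2, p, ges

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


@dataclass
class PsychometricFit:
    snr50_db: float
    slope: float
    sin_loss_db: float  # SNR_50 relative to the -2 dB QuickSIN norm


@dataclass
class ContrastResult:
    mean_a: float
    mean_b: float
    diff: float
    ci95: tuple[float, float]
    t_stat: float
    df: float
    p_value: float


@dataclass
class MediationResult:
    a: float          # X -> M
    b: float          # M -> Y | X
    c: float          # total X -> Y
    c_prime: float    # direct X -> Y | M
    indirect: float   # a*b
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0


def fit_snr50(snr_levels_db: np.ndarray, proportion_correct: np.ndarray
              ) -> PsychometricFit:
    """Two-parameter logistic fit of a word-recognition psychometric curve.

    Maximizes the Bernoulli likelihood of ``proportion_correct`` under
    p(x) = 1/(1 + exp(-(x - loc)/scale)). SNR_50 is the location; SIN loss
    is SNR_50 minus the -2 dB normative threshold.
    """
    x = np.asarray(snr_levels_db, float)
    y = np.asarray(proportion_correct, float)
    if len(x) < 4:
        raise ValueError("need at least four SNR levels")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.all(y <= 0.0) or np.all(y >= 1.0):
        raise ValueError("degenerate psychometric data (no crossing)")

    def nll(theta: np.ndarray) -> float:
        loc, log_scale = theta
        p = sps.logistic.cdf(x, loc=loc, scale=np.exp(log_scale))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

    # note: the curve rises with SNR; QuickSIN scores fall with SNR, so
    # callers pass proportion correct, not errors
    x0 = np.array([float(np.interp(0.5, np.sort(y), x[np.argsort(y)])), 0.0])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    loc, log_scale = res.x
    return PsychometricFit(snr50_db=float(loc),
                           slope=float(1.0 / np.exp(log_scale)),
                           sin_loss_db=float(loc) + 2.0)


def fit_linear(x: np.ndarray, y: np.ndarray) -> LinearModelResult:
    """Simple OLS regression with R², F, p and the 95% CI of the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return LinearModelResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), f_stat=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])), n=len(x))


def _ss(cell_means: np.ndarray, weights: float) -> float:
    grand = cell_means.mean()
    return float(weights * np.sum((cell_means - grand) ** 2))


def mixed_anova(table: pd.DataFrame, dv: str, subject: str,
                within: list[str], between: str) -> AnovaResult:
    """Mixed-design ANOVA: two within factors crossed with one between factor.

    Requires a balanced long-format table (one row per subject x within-
    cell, complete cases). Sums of squares follow the textbook univariate
    decomposition for split-plot designs; each within effect is tested
    against its subject-interaction error term. Effect size is generalized
    eta squared: SS_effect / (SS_effect + sum of all subject-error SS).
    """
    df = table[[subject, between, dv, *within]].dropna()
    w1, w2 = within
    cells = df.groupby([subject, w1, w2], observed=True)[dv]
    counts = cells.count()
    n_expected = (df[subject].nunique() * df[w1].nunique()
                  * df[w2].nunique())
    if len(counts) != n_expected or counts.nunique() != 1:
        raise ValueError("design has missing or unbalanced cells")
    flat = cells.mean().reset_index()
    groups = df.groupby(subject, observed=True)[between].first()
    flat[between] = flat[subject].map(groups)

    n_subj = flat[subject].nunique()
    lv1 = sorted(flat[w1].unique())
    lv2 = sorted(flat[w2].unique())
    a, b = len(lv1), len(lv2)
    grand = flat[dv].mean()

    def ss_of(cols: list[str]) -> float:
        m = flat.groupby(cols, observed=True)[dv].mean()
        cnt = flat.groupby(cols, observed=True)[dv].count()
        return float(np.sum(cnt * (m - grand) ** 2))

    ss_total = float(np.sum((flat[dv] - grand) ** 2))
    ss_between_cells = ss_of([between])
    ss_subj = ss_of([subject])                       # subjects (incl. group)
    ss_s_within = ss_subj - ss_between_cells         # subjects within groups
    ss_w1 = ss_of([w1])
    ss_w2 = ss_of([w2])
    ss_bw1 = ss_of([between, w1]) - ss_between_cells - ss_w1
    ss_bw2 = ss_of([between, w2]) - ss_between_cells - ss_w2
    ss_w1w2 = ss_of([w1, w2]) - ss_w1 - ss_w2
    ss_bw1w2 = (ss_of([between, w1, w2]) - ss_between_cells - ss_w1 - ss_w2
                - ss_bw1 - ss_bw2 - ss_w1w2)
    ss_sw1 = ss_of([subject, w1]) - ss_subj - ss_w1 - ss_bw1
    ss_sw2 = ss_of([subject, w2]) - ss_subj - ss_w2 - ss_bw2
    ss_sw1w2 = (ss_total - ss_subj - ss_w1 - ss_w2 - ss_w1w2 - ss_bw1
                - ss_bw2 - ss_bw1w2 - ss_sw1 - ss_sw2)

    n_groups = flat[between].nunique()
    df_s = n_subj - n_groups
    ss_err_all = ss_s_within + ss_sw1 + ss_sw2 + ss_sw1w2
    rows = []

    def add(effect: str, ss_eff: float, df_eff: int, ss_err: float,
            df_err: int) -> None:
        if df_eff <= 0:  # e.g. a single between-group level
            return
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(f, df_eff, df_err)) if ms_err > 0 else 1.0
        ges = ss_eff / (ss_eff + ss_err_all) if (ss_eff + ss_err_all) > 0 else 0.0
        rows.append({"effect": effect, "F": f, "df1": df_eff, "df2": df_err,
                     "p": p, "ges": ges})

    add(between, ss_between_cells, n_groups - 1, ss_s_within, df_s)
    add(w1, ss_w1, a - 1, ss_sw1, df_s * (a - 1))
    add(f"{between}*{w1}", ss_bw1, (n_groups - 1) * (a - 1), ss_sw1,
        df_s * (a - 1))
    add(w2, ss_w2, b - 1, ss_sw2, df_s * (b - 1))
    add(f"{between}*{w2}", ss_bw2, (n_groups - 1) * (b - 1), ss_sw2,
        df_s * (b - 1))
    add(f"{w1}*{w2}", ss_w1w2, (a - 1) * (b - 1), ss_sw1w2,
        df_s * (a - 1) * (b - 1))
    add(f"{between}*{w1}*{w2}", ss_bw1w2, (n_groups - 1) * (a - 1) * (b - 1),
        ss_sw1w2, df_s * (a - 1) * (b - 1))
    return AnovaResult(table=pd.DataFrame(rows))


def group_contrast(a: np.ndarray, b: np.ndarray,
                   equal_var: bool = False) -> ContrastResult:
    """Two-sample contrast (Welch by default) with a 95% CI on the difference."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return ContrastResult(float(np.mean(a)), float(np.mean(b)), 0.0,
                              (0.0, 0.0), 0.0, len(a) + len(b) - 2, 1.0)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se = np.sqrt(va / len(a) + vb / len(b))
    if equal_var:
        dof = len(a) + len(b) - 2
    else:
        dof = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1)
            + (vb / len(b)) ** 2 / (len(b) - 1))
    diff = float(np.mean(a) - np.mean(b))
    half = sps.t.ppf(0.975, dof) * se
    return ContrastResult(float(np.mean(a)), float(np.mean(b)), diff,
                          (diff - half, diff + half), float(t), float(dof),
                          float(p))


def paired_contrast(a: np.ndarray, b: np.ndarray) -> ContrastResult:
    """Paired contrast with a 95% CI on the mean difference."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired samples require equal n >= 2")
    d = a - b
    if np.var(d) == 0 and np.mean(d) == 0:
        return ContrastResult(float(np.mean(a)), float(np.mean(b)), 0.0,
                              (0.0, 0.0), 0.0, len(a) - 1, 1.0)
    t, p = sps.ttest_rel(a, b)
    se = np.std(d, ddof=1) / np.sqrt(len(d))
    half = sps.t.ppf(0.975, len(d) - 1) * se
    diff = float(np.mean(d))
    return ContrastResult(float(np.mean(a)), float(np.mean(b)), diff,
                          (diff - half, diff + half), float(t), len(d) - 1,
                          float(p))


def _ols_paths(X: np.ndarray, M: np.ndarray, Y: np.ndarray
               ) -> tuple[float, float, float, float]:
    # closed-form OLS (normal equations); kept dependency-free because the
    # bootstrap calls this thousands of times
    ones = np.ones_like(X)
    GX = np.column_stack([ones, X])
    a = np.linalg.lstsq(GX, M, rcond=None)[0][1]
    c = np.linalg.lstsq(GX, Y, rcond=None)[0][1]
    coef = np.linalg.lstsq(np.column_stack([ones, X, M]), Y, rcond=None)[0]
    return float(a), float(coef[2]), float(c), float(coef[1])


def mediate(X: np.ndarray, M: np.ndarray, Y: np.ndarray,
            n_boot: int = 1000, seed: int = 0) -> MediationResult:
    """Single-mediator path analysis with percentile-bootstrap inference.

    Paths: a (X→M), b (M→Y given X), c (total X→Y), c′ (direct), indirect
    effect a·b; on any data c = c′ + a·b holds exactly for OLS. Cases are
    resampled with replacement; CIs are percentile and p-values are
    two-sided sign-crossing probabilities with the add-one rule.
    """
    X = np.asarray(X, float)
    M = np.asarray(M, float)
    Y = np.asarray(Y, float)
    mask = np.isfinite(X) & np.isfinite(M) & np.isfinite(Y)
    X, M, Y = X[mask], M[mask], Y[mask]
    n = len(X)
    if n < 10:
        raise ValueError("mediation needs at least 10 complete cases")
    if np.var(X) == 0:
        raise ValueError("constant predictor")
    a, b, c, c_prime = _ols_paths(X, M, Y)
    rng = np.random.default_rng(seed)
    draws = {k: np.empty(n_boot) for k in ("a", "b", "c", "c_prime",
                                           "indirect")}
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            ai, bi, ci, cpi = _ols_paths(X[idx], M[idx], Y[idx])
        except Exception:
            ai = bi = ci = cpi = np.nan
        draws["a"][i], draws["b"][i] = ai, bi
        draws["c"][i], draws["c_prime"][i] = ci, cpi
        draws["indirect"][i] = ai * bi
    ci95, pvals = {}, {}
    for k, v in draws.items():
        v = v[np.isfinite(v)]
        ci95[k] = (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        n_lo = np.sum(v <= 0)
        n_hi = np.sum(v >= 0)
        pvals[k] = float(min(1.0, 2.0 * (1 + min(n_lo, n_hi)) / (len(v) + 1)))
    return MediationResult(a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
                           ci95=ci95, p_values=pvals, n_boot=n_boot,
                           seed=seed)
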