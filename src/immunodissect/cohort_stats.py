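"""Cohort-level statistics: contingency tests, ANOVA + LSD, rank tests,
Kaplan-Meier / log-rank survival and propensity-score matching.

Clinical covariates keep "Unknown" as a genuine category by default (the
tests of class association include it as a level; a drop-unknown option is
provided). The chi-square test is Pearson's without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
import statsmodels.api as sm


def contingency_from_clinical(
    clinical: pd.DataFrame,
    covariate: str,
    class_col: str = "class",
    drop_unknown: bool = False,
) -> pd.DataFrame:
    """Covariate-level x class count table, keeping Unknown unless dropped."""
    tab = pd.crosstab(clinical[covariate], clinical[class_col])
    if drop_unknown and "Unknown" in tab.index:
        tab = tab.drop(index="Unknown")
    return tab


def chi_square_test(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table; no continuity correction.

    All-zero rows or columns are dropped with a warning-free trim (they carry
    no information); a table reduced below 2 x 2 is an error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    arr = arr[arr.sum(axis=1) > 0, :]
    arr = arr[:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("degenerate contingency table (needs >= 2 rows and columns)")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2 x 2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2 x 2 table")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class AnovaLsdResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, t, p


def anova_lsd(values: pd.Series, groups: pd.Series) -> AnovaLsdResult:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    LSD uses the pooled within-group mean square with N - g degrees of
    freedom and reports unadjusted two-sided p-values, as is conventional
    for the procedure.
    """
    g = groups.reindex(values.index)
    data = {lv: values[g == lv].to_numpy(float) for lv in pd.unique(g.dropna())}
    if len(data) < 2 or any(len(v) < 2 for v in data.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*data.values())
    n_total = sum(len(v) for v in data.values())
    n_groups = len(data)
    msw = sum((len(v) - 1) * v.var(ddof=1) for v in data.values()) / (
        n_total - n_groups
    )
    if msw == 0:
        raise ValueError("zero within-group variance; LSD undefined")
    dfw = n_total - n_groups
    rows = []
    levels = list(data)
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            diff = data[a].mean() - data[b].mean()
            se = np.sqrt(msw * (1 / len(data[a]) + 1 / len(data[b])))
            t = diff / se
            rows.append(
                {"group_a": a, "group_b": b, "mean_diff": diff,
                 "t": t, "p_value": 2 * stats.t.sf(abs(t), dfw)}
            )
    return AnovaLsdResult(
        f_statistic=float(f),
        df_between=n_groups - 1,
        df_within=dfw,
        p_value=float(p),
        pairwise=pd.DataFrame(rows),
    )


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; exact enumeration for small tie-free inputs.

    Exact when n_x + n_y <= 12 and no ties are present, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class KaplanMeierResult:
    curves: dict[str, pd.DataFrame]  # group -> time, survival, variance
    medians: dict[str, float]  # NaN where the median is never reached


def kaplan_meier(
    times: pd.Series, events: pd.Series, groups: pd.Series | None = None
) -> KaplanMeierResult:
    """Product-limit survival curves with Greenwood variance per group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    if groups is None:
        groups = pd.Series("all", index=times.index)
    curves, medians = {}, {}
    for lv in pd.unique(groups):
        sel = (groups == lv).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        surv = kmf.survival_function_.iloc[:, 0]
        tab = pd.DataFrame(
            {
                "time": surv.index.to_numpy(),
                "survival": surv.to_numpy(),
            }
        )
        tab["greenwood_variance"] = _greenwood(t[sel], e[sel], tab["time"].to_numpy())
        curves[str(lv)] = tab
        med = kmf.median_survival_time_
        medians[str(lv)] = float(med) if np.isfinite(med) else float("nan")
    return KaplanMeierResult(curves=curves, medians=medians)


def _greenwood(t: np.ndarray, e: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Greenwood variance of the product-limit estimate on a time grid."""
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    s = 1.0
    acc = 0.0
    out = np.zeros_like(grid, dtype=float)
    pieces = []
    for et in event_times:
        n_at_risk = (t >= et).sum()
        d = ((t == et) & (e == 1)).sum()
        s *= 1 - d / n_at_risk
        if n_at_risk > d:
            acc += d / (n_at_risk * (n_at_risk - d))
        pieces.append((et, s * s * acc))
    for i, g in enumerate(grid):
        v = 0.0
        for et, val in pieces:
            if et <= g:
                v = val
        out[i] = v
    return out


def logrank_test(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups; df = number of groups - 1."""
    lv = pd.unique(groups)
    if len(lv) < 2:
        raise ValueError("need >= 2 groups")
    if any((groups == g).sum() == 0 for g in lv):
        raise ValueError("empty group")
    if int(np.asarray(events).sum()) == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(
        np.asarray(times, float), np.asarray(groups), np.asarray(events, int)
    )
    return float(res.test_statistic), len(lv) - 1, float(res.p_value)


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # treated, control, distance
    propensity: pd.Series
    smd_before: pd.Series
    smd_after: pd.Series
    n_treated: int
    n_matched: int


def standardized_mean_differences(
    covariates: pd.DataFrame, treated: pd.Series
) -> pd.Series:
    """|mean_t - mean_c| / sqrt((var_t + var_c)/2) per (numeric) covariate."""
    t = covariates[treated.astype(bool)]
    c = covariates[~treated.astype(bool)]
    num = (t.mean() - c.mean()).abs()
    den = np.sqrt((t.var(ddof=1) + c.var(ddof=1)) / 2)
    smd = num / den.replace(0.0, np.nan)
    return smd.fillna(0.0)


def _one_hot(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode object/category columns, Unknown as its own level."""
    out = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return out


def propensity_match(
    covariates: pd.DataFrame,
    treatment: pd.Series,
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> MatchResult:
    """1:1 greedy nearest-neighbour matching on the logit propensity score.

    The propensity model is a logistic regression fitted by IRLS
    (statsmodels); matching is without replacement within a caliper of
    ``caliper_sd`` times the standard deviation of the logit propensity
    score. Treated units are visited in seeded random order. Standardized
    mean differences before and after matching are reported on the encoded
    covariates.
    """
    X = _one_hot(covariates)
    # zero-variance columns carry no information and break the fit
    X = X.loc[:, X.std(ddof=0) > 0]
    y = treatment.astype(int).reindex(X.index)
    if set(y.unique()) != {0, 1}:
        raise ValueError("treatment must be binary with both levels present")
    if X.shape[1] == 0:
        ps = pd.Series(y.mean(), index=X.index)
    else:
        import warnings as _warnings

        design = sm.add_constant(X.to_numpy(dtype=float))
        model = sm.Logit(y.to_numpy(), design)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            try:
                fit = model.fit(disp=0, maxiter=100)
            except Exception:
                # near-collinear dummies can make the Newton step singular;
                # a quasi-Newton fit usually still converges
                try:
                    fit = model.fit(disp=0, maxiter=500, method="lbfgs")
                except Exception as exc:
                    raise ValueError(
                        f"logistic propensity fit failed: {exc}"
                    ) from exc
        ps_arr = fit.predict(design)
        degenerate = (ps_arr < 1e-8) | (ps_arr > 1 - 1e-8)
        if not np.all(np.isfinite(fit.params)) or degenerate.all():
            worst = X.columns[np.abs(fit.params[1:]).argmax()]
            raise ValueError(
                f"separation in logistic propensity fit (covariate {worst!r})"
            )
        ps = pd.Series(ps_arr, index=X.index)

    eps = 1e-9
    logit = np.log(np.clip(ps, eps, 1 - eps) / np.clip(1 - ps, eps, 1 - eps))
    sd = float(np.std(logit, ddof=1)) if len(logit) > 1 else 0.0
    caliper = caliper_sd * sd

    rng = np.random.default_rng(seed)
    treated_ids = list(X.index[y == 1])
    control_ids = list(X.index[y == 0])
    rng.shuffle(treated_ids)
    available = dict.fromkeys(control_ids, True)
    pairs = []
    for tid in treated_ids:
        best, best_d = None, np.inf
        for cid, free in available.items():
            if not free:
                continue
            d = abs(logit[tid] - logit[cid])
            if d < best_d:
                best, best_d = cid, d
        if best is not None and best_d <= caliper + 1e-12:
            available[best] = False
            pairs.append({"treated": tid, "control": best, "distance": best_d})

    pairs_df = pd.DataFrame(pairs, columns=["treated", "control", "distance"])
    matched_ids = pd.Index(
        list(pairs_df["treated"]) + list(pairs_df["control"])
    )
    smd_before = standardized_mean_differences(X, y.astype(bool))
    if len(pairs_df):
        smd_after = standardized_mean_differences(
            X.loc[matched_ids], y.loc[matched_ids].astype(bool)
        )
    else:
        smd_after = pd.Series(np.nan, index=X.columns)
    return MatchResult(
        pairs=pairs_df,
        propensity=ps,
        smd_before=smd_before,
        smd_after=smd_after,
        n_treated=len(treated_ids),
        n_matched=len(pairs_df),
    )
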