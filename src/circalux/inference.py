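"""Seasonal comparisons, the phase-timing regression, and AICc selection.

The final model regresses each participant-season's mean maximum
wrist-temperature timing (decimal observation hours after 17.00) on mean
standardized night-time (21.00-02.00) and morning (04.00-11.59) light AUC
(log10lux-minutes), plus season indicators with winter as the reference,
by ordinary least squares. Candidate term sets are ranked by AICc with the
small-sample correction 2k(k+1)/(n-k-1), k counting the coefficients plus
the error variance (the R MuMIn convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, InsufficientDataError

SEASON_ORDER = ("winter", "autumn", "spring", "summer")  # winter = reference
SEASON_DUMMIES = ("autumn", "spring", "summer")

#: Human-readable term labels for rendered model tables.
TERM_LABELS = {
    "const": "(intercept)",
    "mean_night_auc": "mean night-time light",
    "mean_morning_auc": "mean morning light",
    "season_autumn": "autumn",
    "season_spring": "spring",
    "season_summer": "summer",
}


# ---------------------------------------------------------------- Tukey HSD

def seasonal_comparison(values_by_group: dict) -> pd.DataFrame:
    """Tukey's HSD (Tukey-Kramer for unbalanced groups) across groups.

    Parameters
    ----------
    values_by_group : dict
        Group label -> 1-d array of daily AUC values.

    Returns
    -------
    DataFrame with one row per unordered pair: mean difference, 95%
    family-wise confidence interval, and adjusted p-value from the exact
    studentized-range distribution.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    if len(groups) < 2:
        raise InsufficientDataError("Tukey needs at least two groups")
    for k, v in groups.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than two values")
    names = list(groups)
    res = stats.tukey_hsd(*groups.values())
    ci = res.confidence_interval(0.95)
    rows = []
    for i, j in combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(res.statistic[i, j]),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------- participant-season means

def participant_season_means(exposures: pd.DataFrame, phases: pd.DataFrame) -> pd.DataFrame:
    """One row per participant-season: mean night/morning AUC and mean timing.

    ``exposures`` is the tidy per-day window table (needs windows
    ``std_night_2100_0200`` and ``morning_0400_1159``); ``phases`` the
    per-day phase table. Only days present in both contribute, and
    participants with no retained days in a season are absent.
    """
    keys = ["source_id", "season", "day_index"]
    wide = (
        exposures[exposures["window"].isin(["std_night_2100_0200", "morning_0400_1159"])]
        .pivot_table(index=keys, columns="window", values="auc_log10lux_min")
        .reset_index()
        .rename(
            columns={
                "std_night_2100_0200": "night_auc",
                "morning_0400_1159": "morning_auc",
            }
        )
    )
    merged = wide.merge(phases[keys + ["max_timing_h"]], on=keys, how="inner")
    merged = merged.dropna(subset=["night_auc", "morning_auc", "max_timing_h"])
    out = (
        merged.groupby(["source_id", "season"], as_index=False)
        .agg(
            mean_night_auc=("night_auc", "mean"),
            mean_morning_auc=("morning_auc", "mean"),
            mean_max_timing=("max_timing_h", "mean"),
            n_days=("max_timing_h", "size"),
        )
    )
    return out


# ----------------------------------------------------------------- OLS fit

@dataclass
class ModelFit:
    """Summary of one candidate OLS fit."""

    terms: list  # (name, estimate, std_error, t_value, p_value)
    n: int
    residual_df: int
    residual_se: float
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_df: tuple
    f_pvalue: float
    aicc: float
    loglik: float
    rss: float
    conf_int: dict = field(default_factory=dict)  # name -> (low, high)

    @property
    def coef(self) -> dict:
        return {t[0]: t[1] for t in self.terms}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.terms, columns=["term", "estimate", "s.e.", "t-value", "Pr(>|t|)"]
        )
        df["label"] = [TERM_LABELS.get(t, t) for t in df["term"]]
        return df


def _design_matrix(rows: pd.DataFrame, terms) -> tuple:
    cols = {"const": np.ones(len(rows))}
    for t in terms:
        if t == "season":
            present = set(rows["season"])
            for s in SEASON_DUMMIES:  # winter is the reference level
                if s in present:
                    cols[f"season_{s}"] = (rows["season"] == s).to_numpy(dtype=float)
        elif t == "night":
            cols["mean_night_auc"] = rows["mean_night_auc"].to_numpy(dtype=float)
        elif t == "morning":
            cols["mean_morning_auc"] = rows["mean_morning_auc"].to_numpy(dtype=float)
        else:
            cols[t] = rows[t].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names


def _aicc_from_rss(rss: float, n: int, n_coef: int) -> tuple:
    """Gaussian log-likelihood AIC/AICc; k counts coefficients + sigma^2."""
    llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    k = n_coef + 1
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        raise InsufficientDataError(
            f"AICc undefined: n={n} too small for k={k} parameters"
        )
    return llf, aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_phase_model(rows: pd.DataFrame, terms=("night", "morning", "season")) -> ModelFit:
    """OLS of mean maximum timing on the requested terms, with intercept.

    ``terms`` is any subset of {"night", "morning", "season"} (or explicit
    column names). Season enters as three indicators with winter as the
    reference level.
    """
    y = rows["mean_max_timing"].to_numpy(dtype=float)
    X, names = _design_matrix(rows, terms)
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n={n} rows cannot identify {p} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the culprits: columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise CollinearityError(f"rank-deficient design; involved terms: {bad}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p_pred = p - 1  # predictors excluding the intercept
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p_pred - 1) if p_pred else r2
    if p_pred:
        if r2 >= 1.0 - 1e-14:  # exact interpolation
            f_stat, f_p = np.inf, 0.0
        else:
            f_stat = (r2 / p_pred) / ((1.0 - r2) / df_resid)
            f_p = float(stats.f.sf(f_stat, p_pred, df_resid))
    else:
        f_stat, f_p = np.nan, np.nan
    llf, aicc = _aicc_from_rss(rss, n, p)

    tcrit = stats.t.ppf(0.975, df_resid)
    conf = {nm: (b - tcrit * s, b + tcrit * s) for nm, b, s in zip(names, beta, se)}
    terms_out = [
        (nm, float(b), float(s), float(tv), float(pv))
        for nm, b, s, tv, pv in zip(names, beta, se, tvals, pvals)
    ]
    return ModelFit(
        terms=terms_out,
        n=n,
        residual_df=df_resid,
        residual_se=float(np.sqrt(sigma2)),
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        f_statistic=float(f_stat),
        f_df=(p_pred, df_resid),
        f_pvalue=f_p,
        aicc=float(aicc),
        loglik=float(llf),
        rss=rss,
        conf_int=conf,
    )


#: Default candidate set: all subsets of {morning, night, season}.
def default_candidates():
    base = ["night", "morning", "season"]
    cands = []
    for r in range(len(base) + 1):
        for combo in combinations(base, r):
            cands.append(tuple(combo))
    return cands


def aicc_select(rows: pd.DataFrame, candidates=None) -> pd.DataFrame:
    """Fit each candidate term set and rank ascending by AICc.

    Returns a DataFrame (model, aicc, delta_aicc, r_squared, n_coef) sorted
    by AICc; ties keep declaration order. The fitted objects ride along in
    the ``fit`` column.
    """
    if candidates is None:
        candidates = default_candidates()
    recs = []
    for i, cand in enumerate(candidates):
        fit = fit_phase_model(rows, cand)
        recs.append(
            {
                "model": "+".join(cand) if cand else "intercept-only",
                "terms": cand,
                "aicc": fit.aicc,
                "r_squared": fit.r_squared,
                "n_coef": len(fit.terms),
                "order": i,
                "fit": fit,
            }
        )
    out = pd.DataFrame(recs).sort_values(["aicc", "order"], kind="stable")
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    return out.drop(columns="order").reset_index(drop=True)


def predict_shift(fit: ModelFit, delta_morning_auc: float = 0.0,
                  delta_night_auc: float = 0.0) -> float:
    """Predicted change in maximum timing (hours; negative = earlier).

    ``shift = beta_night * delta_night + beta_morning * delta_morning``
    for changes in window AUC expressed in log10lux-minutes.
    """
    coef = fit.coef
    if "mean_night_auc" not in coef or "mean_morning_auc" not in coef:
        raise ValueError("fit must contain night and morning terms")
    return float(
        coef["mean_night_auc"] * delta_night_auc
        + coef["mean_morning_auc"] * delta_morning_auc
    )


# ----------------------------------------------- printed-fit arithmetic

def adjusted_r_squared(r_squared: float, n: int, n_predictors: int) -> float:
    """adj R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - n_predictors - 1)


def f_from_r_squared(r_squared: float, n: int, n_predictors: int) -> float:
    """F = (R^2/p) / ((1 - R^2)/(n - p - 1))."""
    return (r_squared / n_predictors) / ((1.0 - r_squared) / (n - n_predictors - 1))


def residual_df(n: int, n_coefficients: int) -> int:
    return n - n_coefficients
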