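"""Statistical layer: within-cell regressions, Holm correction, population
one-sample tests, per-cell threshold models with post-burst prediction and
overshoot detection, pooled burst-size / burst-frequency models with
sequential (type-I) ANOVA comparison, and the JZS Bayes factor.

Conventions: two-sided tests; the 95% CI of a mean is 1.96 x SEM; effect
size for one-sample tests is Cohen's d (mean / SD).  Rows with missing
features are dropped case-wise and the dropped counts reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import integrate, stats as sps

__all__ = [
    "WithinCellFit",
    "PopulationSummary",
    "ThresholdModel",
    "BurstModelResult",
    "within_cell_fit",
    "holm_correction",
    "population_summary",
    "fit_threshold_model",
    "predict_threshold_after_burst",
    "detect_overshoot",
    "fit_burst_models",
    "jzs_bayes_factor",
]


# ---------------------------------------------------------------------------
# Within-cell fits and population summaries
# ---------------------------------------------------------------------------


@dataclass
class WithinCellFit:
    cell_id: str
    slope: float
    intercept: float
    r: float
    p_raw: float
    n_points: int
    p_holm: float = float("nan")
    flagged: bool = False
    reason: str = ""


def within_cell_fit(
    x: Sequence[float], y: Sequence[float], cell_id: str = ""
) -> WithinCellFit:
    """OLS slope/intercept plus Pearson r and its two-sided p for one cell.

    Pairs with a non-finite member are dropped; fewer than 3 complete pairs
    or zero variance in x flags the fit as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return WithinCellFit(
            cell_id, np.nan, np.nan, np.nan, np.nan, int(x.size),
            flagged=True, reason="fewer than 3 complete pairs",
        )
    if np.ptp(x) == 0:
        return WithinCellFit(
            cell_id, np.nan, np.nan, np.nan, np.nan, int(x.size),
            flagged=True, reason="zero variance in x",
        )
    res = sps.linregress(x, y)
    return WithinCellFit(
        cell_id,
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
        int(x.size),
    )


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment.

    Sorted ascending, p_(i) is multiplied by (m - i), successive maxima are
    enforced (monotonicity) and the result is capped at 1; values are
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running = max(running, val)
        adj_sorted[rank] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class PopulationSummary:
    mean: float
    ci95: float  # 1.96 x SEM
    es: float  # Cohen's d = mean / SD
    t: float
    p: float
    n_cells: int
    flagged: bool = False
    reason: str = ""


def population_summary(per_cell_values: Sequence[float]) -> PopulationSummary:
    """One-sample t test of per-cell values against zero with the reporting
    conventions used throughout (ci95 = 1.96 x SEM, es = mean / SD)."""
    v = np.asarray(per_cell_values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError("population summary needs at least 2 finite values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0:
        return PopulationSummary(
            mean, 0.0, np.nan, np.nan, np.nan, n,
            flagged=True, reason="zero variance",
        )
    sem = sd / math.sqrt(n)
    t, p = sps.ttest_1samp(v, 0.0)
    return PopulationSummary(mean, 1.96 * sem, mean / sd, float(t), float(p), n)


# ---------------------------------------------------------------------------
# Per-cell threshold model
# ---------------------------------------------------------------------------

THRESHOLD_PREDICTORS = ["ahp_amplitude", "ahp_slope", "ahp_duration", "v_rest"]


@dataclass
class ThresholdModel:
    cell_id: str
    params: Dict[str, float]  # includes "Intercept"
    r_squared: float
    n: int
    bic: float
    bic_interactions: float
    n_dropped: int = 0


def fit_threshold_model(
    per_ap: pd.DataFrame, cell_id: Optional[str] = None, min_rows: int = 10
) -> ThresholdModel:
    """Per-cell OLS of the intraburst AP threshold on the preceding AHP
    amplitude/slope/duration and the burst resting potential.

    Only intraburst APs are used (the first AP of each burst is excluded);
    the AHP predictors describe the AHP *preceding* each AP, i.e. the
    features attached to the previous AP of the same burst.  The
    interaction-augmented variant is also fitted and both BICs reported.
    """
    df = per_ap
    if cell_id is not None:
        df = df[df["cell_id"] == cell_id]
    rows = _intraburst_design(df)
    n0 = len(rows)
    rows = rows.dropna(subset=["threshold"] + THRESHOLD_PREDICTORS)
    if len(rows) < min_rows:
        raise ValueError(
            f"threshold model needs >= {min_rows} complete intraburst APs, "
            f"got {len(rows)}"
        )
    base = smf.ols(
        "threshold ~ ahp_amplitude + ahp_slope + ahp_duration + v_rest", data=rows
    ).fit()
    inter = smf.ols(
        "threshold ~ (ahp_amplitude + ahp_slope + ahp_duration + v_rest) ** 2",
        data=rows,
    ).fit()
    if np.linalg.matrix_rank(base.model.exog) < base.model.exog.shape[1]:
        bad = [
            name
            for name, col in zip(base.model.exog_names, base.model.exog.T)
            if np.ptp(col) == 0 and name != "Intercept"
        ]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    return ThresholdModel(
        cell_id=cell_id or (df["cell_id"].iloc[0] if len(df) else ""),
        params={k: float(v) for k, v in base.params.items()},
        r_squared=float(base.rsquared),
        n=int(base.nobs),
        bic=float(base.bic),
        bic_interactions=float(inter.bic),
        n_dropped=n0 - len(rows),
    )


def _intraburst_design(per_ap: pd.DataFrame) -> pd.DataFrame:
    """Rows for intraburst APs with the *preceding* AHP's features."""
    out = []
    for (_cell, _burst), grp in per_ap.groupby(["cell_id", "burst"], sort=False):
        grp = grp.sort_values("index_in_burst")
        for prev_row, row in zip(grp.iloc[:-1].itertuples(), grp.iloc[1:].itertuples()):
            out.append(
                {
                    "threshold": row.threshold,
                    "ahp_amplitude": prev_row.ahp_amplitude,
                    "ahp_slope": prev_row.ahp_slope,
                    "ahp_duration": prev_row.ahp_duration,
                    "v_rest": row.v_rest,
                }
            )
    return pd.DataFrame(out)


def predict_threshold_after_burst(
    model: ThresholdModel,
    last_ahp_amplitude: float,
    last_ahp_slope: float,
    v_rest: float,
    t_elapsed: np.ndarray,
) -> np.ndarray:
    """Predicted AP threshold as a function of the time elapsed since the
    last AHP trough (which plays the role of the AHP-duration predictor,
    all other predictors held constant).  Warns beyond 1 s."""
    t_elapsed = np.asarray(t_elapsed, dtype=float)
    if t_elapsed.size and t_elapsed.max() > 1000.0:
        import warnings

        warnings.warn("extrapolating the threshold model beyond 1 s", stacklevel=2)
    p = model.params
    return (
        p["Intercept"]
        + p["ahp_amplitude"] * last_ahp_amplitude
        + p["ahp_slope"] * last_ahp_slope
        + p["v_rest"] * v_rest
        + p["ahp_duration"] * t_elapsed
    )


@dataclass
class OvershootResult:
    overshoot: bool
    t_cross: float = float("nan")  # ms after the AHP trough
    margin: float = float("nan")  # max(Vm - prediction) over the segment


def detect_overshoot(
    t_after_peak: np.ndarray, vm: np.ndarray, predicted: np.ndarray
) -> OvershootResult:
    """Does the post-burst membrane potential exceed the predicted threshold
    curve (without spiking)?  Inputs are aligned arrays over the post-AHP
    segment, up to (and excluding) any next AP."""
    t_after_peak = np.asarray(t_after_peak, dtype=float)
    vm = np.asarray(vm, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    diff = vm - predicted
    margin = float(np.nanmax(diff)) if diff.size else float("nan")
    above = np.nonzero(diff > 0)[0]
    if above.size == 0:
        return OvershootResult(False, margin=margin)
    return OvershootResult(True, float(t_after_peak[above[0]]), margin)


# ---------------------------------------------------------------------------
# Pooled burst-size / burst-frequency models
# ---------------------------------------------------------------------------


@dataclass
class BurstModelResult:
    endog: str
    formula: str
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    bic: float
    params: Dict[str, float]
    n: int
    n_dropped: int


@dataclass
class BurstModelComparison:
    f: float
    p: float
    df_diff: int
    f_squared: float  # Cohen's f2 between nested models


def _loglog(x: np.ndarray) -> np.ndarray:
    return np.log(np.log(x))


def fit_burst_models(
    bursts: pd.DataFrame,
    include_slow_tau: bool = False,
    min_size: int = 4,
) -> Dict[str, object]:
    """Pooled OLS models of burst size and intraburst frequency.

    Endogenous transforms: log(log(size)) and log(frequency).  Exogenous:
    resting potential, first-AHP amplitude and first-AHP slope with all
    interactions; optionally the per-cell slow-AHP time constant and its
    pairwise interactions, in which case the augmented models are compared
    with the base ones by sequential (type-I) nested ANOVA and Cohen's f2.

    Only bursts with more than three APs enter (so log(log(size)) is always
    defined).  Required columns: size, intraburst_freq, v_rest,
    first_ahp_amplitude, first_ahp_slope (+ slow_tau when requested).
    """
    needed = ["size", "intraburst_freq", "v_rest", "first_ahp_amplitude",
              "first_ahp_slope"]
    if include_slow_tau:
        needed.append("slow_tau")
    df = bursts.copy()
    n0 = len(df)
    df = df[df["size"] >= min_size]
    df = df.dropna(subset=needed)
    df = df[np.isfinite(df["intraburst_freq"]) & (df["intraburst_freq"] > 0)]
    n_dropped = n0 - len(df)
    if len(df) < 10:
        raise ValueError("too few qualifying bursts (need >= 10)")
    df = df.assign(
        loglog_size=_loglog(df["size"].to_numpy(dtype=float)),
        log_freq=np.log(df["intraburst_freq"].to_numpy(dtype=float)),
    )
    base_rhs = "v_rest * first_ahp_amplitude * first_ahp_slope"
    out: Dict[str, object] = {}
    for endog, label in (("loglog_size", "size"), ("log_freq", "frequency")):
        base = smf.ols(f"{endog} ~ {base_rhs}", data=df).fit()
        result = BurstModelResult(
            endog=endog,
            formula=f"{endog} ~ {base_rhs}",
            r_squared=float(base.rsquared),
            f_stat=float(base.fvalue),
            df_model=int(base.df_model),
            df_resid=int(base.df_resid),
            bic=float(base.bic),
            params={k: float(v) for k, v in base.params.items()},
            n=int(base.nobs),
            n_dropped=n_dropped,
        )
        out[label] = result
        if include_slow_tau:
            full_rhs = (
                f"{base_rhs} + slow_tau + slow_tau:v_rest "
                "+ slow_tau:first_ahp_amplitude + slow_tau:first_ahp_slope"
            )
            full = smf.ols(f"{endog} ~ {full_rhs}", data=df).fit()
            anova = sm.stats.anova_lm(base, full)
            f2 = (full.rsquared - base.rsquared) / (1.0 - full.rsquared)
            out[f"{label}_with_tau"] = BurstModelResult(
                endog=endog,
                formula=f"{endog} ~ {full_rhs}",
                r_squared=float(full.rsquared),
                f_stat=float(full.fvalue),
                df_model=int(full.df_model),
                df_resid=int(full.df_resid),
                bic=float(full.bic),
                params={k: float(v) for k, v in full.params.items()},
                n=int(full.nobs),
                n_dropped=n_dropped,
            )
            out[f"{label}_comparison"] = BurstModelComparison(
                f=float(anova["F"].iloc[1]),
                p=float(anova["Pr(>F)"].iloc[1]),
                df_diff=int(anova["df_diff"].iloc[1]),
                f_squared=float(f2),
            )
    return out


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------


def jzs_bayes_factor(t: float, n: int, r_scale: float = 0.707) -> float:
    """One-sample Jeffreys-Zellner-Siow Bayes factor (BF10).

    Cauchy(0, r_scale) prior on the standardized effect size; the marginal
    likelihood under H1 integrates the noncentral-t likelihood over the
    prior via the standard g-representation (inverse-gamma mixture):

        BF10 = [ int_0^inf (1+N g)^{-1/2}
                 (1 + t^2 / ((1+N g) v))^{-(v+1)/2} pi(g) dg ]
               / (1 + t^2/v)^{-(v+1)/2}

    with v = n - 1 and pi(g) the InverseGamma(1/2, r^2/2) density.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("n must be >= 2")
    v = n - 1

    def integrand(g: float) -> float:
        if g <= 0:
            return 0.0
        one_ng = 1.0 + n * g
        like = one_ng ** -0.5 * (1.0 + t * t / (one_ng * v)) ** (-(v + 1) / 2.0)
        prior = (
            (r_scale / math.sqrt(2.0 * math.pi))
            * g ** -1.5
            * math.exp(-r_scale * r_scale / (2.0 * g))
        )
        return like * prior

    num, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    den = (1.0 + t * t / v) ** (-(v + 1) / 2.0)
    return num / den
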