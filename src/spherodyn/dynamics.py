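"""Temporal modeling and statistical comparison of feature series.

Three growth models are fitted to each feature's time course by least
squares:

    linear       y = a*t + b
    quadratic    y = a*t^2 + b*t + c
    exponential  y = a*exp(b*t)

Linear and quadratic fits are closed-form ordinary least squares; the
exponential is true nonlinear least squares (Levenberg-Marquardt),
initialized from a log-linear fit on the positive values — fitting
log y directly would reweight the errors and change the objective.

Goodness of fit is the adjusted R^2,

    adj R^2 = 1 - (SS_res / SS_tot) * (n - 1) / (n - k - 1),

with k the number of non-constant coefficients (linear 1, quadratic 2,
exponential 2 — the exponential's ``a`` is a multiplicative scale, not an
additive intercept, so it counts).

For each feature the best model is the one with the highest mean adjusted
R^2 across all replicates of all conditions; ties go to the simpler model.
Condition comparisons test per-replicate model parameters with a
two-sample Student's t-test (two conditions) or a one-way ANOVA F-test
(two or more).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

MODEL_KINDS = ("linear", "quadratic", "exponential")

#: non-constant coefficient count k used in the adjusted R^2 penalty.
MODEL_K = {"linear": 1, "quadratic": 2, "exponential": 2}

#: tie-break preference: fewer coefficients first, then fixed order.
_TIE_ORDER = {"linear": 0, "exponential": 1, "quadratic": 2}

#: model parameters submitted to statistical testing.
TESTED_PARAMETERS = {
    "linear": ("a",),
    "quadratic": ("a", "b"),
    "exponential": ("a", "b"),
}


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class ModelFit:
    model: str
    a: float
    b: float
    c: Optional[float]  # quadratic only
    adj_r2: float
    r2: float
    n_points: int
    feature: str = ""
    origin: str = ""

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        if self.model == "linear":
            return self.a * t + self.b
        if self.model == "quadratic":
            return self.a * t * t + self.b * t + self.c
        return self.a * np.exp(self.b * t)


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    model: str
    parameter: str
    test: str
    statistic: float
    p_value: float
    group_sizes: Tuple[int, ...]
    p_adjusted: Optional[float] = None


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def adjusted_r2(ss_res: float, ss_tot: float, n: int, k: int) -> float:
    """1 - (ss_res/ss_tot)(n-1)/(n-k-1); NaN (with a warning) when the
    series is constant (ss_tot = 0) or the fit is saturated (n <= k+1)."""
    if ss_tot <= 0:
        log.warning("constant series: adjusted R^2 undefined")
        return float("nan")
    if n <= k + 1:
        return float("nan")
    return 1.0 - (ss_res / ss_tot) * (n - 1) / (n - k - 1)


def fit_model(
    time_hours: Sequence[float],
    values: Sequence[float],
    model: str,
    feature: str = "",
    origin: str = "",
) -> ModelFit:
    """Least-squares fit of one model kind to a feature time series.

    Pairs with non-finite values (e.g. invalid frames) are dropped.
    """
    if model not in MODEL_KINDS:
        raise FitError(f"unknown model {model!r}; valid: {MODEL_KINDS}")
    t = np.asarray(time_hours, float)
    y = np.asarray(values, float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    ncoef = 3 if model == "quadratic" else 2
    if t.size < ncoef + 1:
        raise FitError(
            f"{model} fit of {feature or 'series'} needs >= {ncoef + 1} "
            f"finite points, got {t.size}"
        )

    if model == "linear":
        a, b = np.polyfit(t, y, 1)
        c = None
        pred = a * t + b
    elif model == "quadratic":
        a, b, c = np.polyfit(t, y, 2)
        pred = a * t * t + b * t + c
    else:
        pos = y > 0
        if pos.sum() < 2:
            raise FitError(
                f"exponential fit of {feature or 'series'}: "
                "needs >= 2 positive values for initialization"
            )
        b0, loga0 = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(loga0)), float(b0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            try:
                (a, b), _ = optimize.curve_fit(
                    lambda tt, aa, bb: aa * np.exp(bb * tt),
                    t,
                    y,
                    p0=p0,
                    maxfev=10000,
                )
            except RuntimeError as exc:
                raise FitError(
                    f"exponential fit of {feature or 'series'} did not converge"
                ) from exc
        c = None
        pred = a * np.exp(b * t)

    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    adj = adjusted_r2(ss_res, ss_tot, t.size, MODEL_K[model])
    return ModelFit(
        model=model,
        a=float(a),
        b=float(b),
        c=None if c is None else float(c),
        adj_r2=adj,
        r2=r2,
        n_points=int(t.size),
        feature=feature,
        origin=origin,
    )


def fit_all_models(
    time_hours: Sequence[float],
    values: Sequence[float],
    models: Sequence[str] = MODEL_KINDS,
    feature: str = "",
    origin: str = "",
) -> List[ModelFit]:
    fits = []
    for m in models:
        try:
            fits.append(fit_model(time_hours, values, m, feature, origin))
        except FitError as exc:
            log.warning("skipping %s fit: %s", m, exc)
    return fits


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def select_best_model(fits: Sequence[ModelFit]) -> Optional[str]:
    """Model kind with the highest mean adjusted R^2 across replicates.

    Ties break toward the simpler model (linear before exponential before
    quadratic). Returns None (flagged) if any replicate misses a model
    kind, so selection never compares unequal replicate sets.
    """
    if not fits:
        return None
    by_model: Dict[str, List[float]] = {}
    origins = set()
    for f in fits:
        by_model.setdefault(f.model, []).append(f.adj_r2)
        origins.add(f.origin)
    kinds = sorted(by_model)
    n_expected = len(origins)
    if any(len(v) != n_expected for v in by_model.values()):
        log.warning("missing fits for some replicates; no model selected")
        return None
    means = {m: float(np.nanmean(v)) for m, v in by_model.items()}
    return min(kinds, key=lambda m: (-means[m], _TIE_ORDER[m]))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def compare_conditions(
    fits_by_condition: Dict[str, Sequence[ModelFit]],
    parameter: str,
    welch: bool = False,
) -> ComparisonResult:
    """Test one model parameter across conditions.

    Exactly two conditions: two-sample Student's t-test (equal variance
    unless ``welch``). Two or more: one-way ANOVA F-test. All fits must be
    of the same model kind and feature.
    """
    groups = {}
    model = feature = None
    for cond, fits in fits_by_condition.items():
        vals = [getattr(f, parameter) for f in fits]
        for f in fits:
            model, feature = f.model, f.feature
        if len(vals) >= 2:
            groups[cond] = np.asarray(vals, float)
        else:
            log.warning(
                "condition %r has < 2 replicates; skipped in comparison", cond
            )
    if len(groups) < 2:
        raise FitError("need >= 2 conditions with >= 2 replicates each")
    samples = [groups[c] for c in sorted(groups)]
    if len(samples) == 2:
        stat, p = stats.ttest_ind(*samples, equal_var=not welch)
        test = "t_test"
    else:
        stat, p = stats.f_oneway(*samples)
        test = "anova"
    return ComparisonResult(
        feature=feature or "",
        model=model or "",
        parameter=parameter,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_sizes=tuple(len(s) for s in samples),
    )


def compare_all(
    fits_df: pd.DataFrame,
    best_models: Dict[str, str],
    welch: bool = False,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Comparison table over every feature's selected model.

    ``fits_df`` columns: condition, replicate, feature, model, a, b, c,
    adj_r2. Parameters tested follow the model kind (a for linear; a and b
    for quadratic and exponential). Raw p-values are reported; a
    Benjamini-Hochberg adjusted column is appended when requested.
    """
    results: List[ComparisonResult] = []
    for feature, model in sorted(best_models.items()):
        if model is None:
            continue
        sub = fits_df[(fits_df.feature == feature) & (fits_df.model == model)]
        by_cond: Dict[str, List[ModelFit]] = {}
        for _, row in sub.iterrows():
            by_cond.setdefault(row.condition, []).append(
                ModelFit(
                    model=row.model,
                    a=row.a,
                    b=row.b,
                    c=row.get("c"),
                    adj_r2=row.adj_r2,
                    r2=row.get("r2", float("nan")),
                    n_points=int(row.get("n_points", 0)),
                    feature=feature,
                    origin=str(row.replicate),
                )
            )
        for parameter in TESTED_PARAMETERS[model]:
            try:
                results.append(compare_conditions(by_cond, parameter, welch))
            except FitError as exc:
                log.warning("comparison skipped for %s/%s: %s", feature, parameter, exc)
    df = pd.DataFrame(
        [
            {
                "feature": r.feature,
                "model": r.model,
                "parameter": r.parameter,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
    if bh_correction and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------


def aggregate_replicates(
    series: Sequence[pd.DataFrame],
    feature: str,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-frame mean and t-based confidence band across replicates.

    For m >= 2 valid replicates at a frame the band is
    mean +/- t_(1-(1-ci)/2, m-1) * sd / sqrt(m); for m = 1 it collapses to
    the mean. Frames with no valid replicate are dropped.
    """
    if not series:
        raise FitError("aggregate_replicates needs >= 1 replicate")
    frames = []
    for df in series:
        frames.append(df[["frame", "time_hours", feature]].set_index("frame"))
    wide = pd.concat(
        [f[feature].rename(i) for i, f in enumerate(frames)], axis=1
    )
    time = frames[0]["time_hours"]
    m = wide.notna().sum(axis=1)
    mean = wide.mean(axis=1, skipna=True)
    sd = wide.std(axis=1, ddof=1, skipna=True)
    alpha = 1.0 - ci_level
    half = pd.Series(0.0, index=wide.index)
    multi = m >= 2
    if multi.any():
        tq = stats.t.ppf(1 - alpha / 2.0, (m[multi] - 1).to_numpy())
        half[multi] = tq * (sd[multi] / np.sqrt(m[multi])).to_numpy()
    out = pd.DataFrame(
        {
            "frame": wide.index,
            "time_hours": time.reindex(wide.index),
            "mean": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "n": m,
        }
    )
    return out[out["n"] > 0].reset_index(drop=True)
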