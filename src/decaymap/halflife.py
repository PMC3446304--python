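"""Per-gene half-life estimation from normalized RPK time courses.

First-order decay N(t) = N0 * exp(-k t) is fitted by ordinary least squares
of ln(rpk_norm) on t; t_half = ln2 / k. Genes are excluded when the t0
expression is below 50 RPK, when the log-linear fit has R^2 < 0.8, or when
more than one post-arrest time point is missing (zero RPK counts as
missing). Fitted half-lives above 15 min, and non-decaying series
(k <= 0), are reported as 15 min with the ``capped`` flag — observations
beyond that horizon are outside the resolution of a 10-minute chase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    STATUS_LOW_RPK,
    STATUS_MISSING,
    STATUS_OK,
    STATUS_POOR_FIT,
    HalfLifeRecord,
)

LN2 = math.log(2.0)


@dataclass
class DecayFit:
    k: float  # 1/min
    half_life: float  # minutes; inf when k <= 0
    r_squared: float  # on the log scale (the filter default)
    r_squared_linear: float
    n_points: int


def _linear_r2(v: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    ss_res = float(np.sum((v - pred) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-24 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_decay(times, values, method: str = "ols") -> DecayFit | None:
    """Fit an exponentially falling series.

    ``method='ols'`` (default): ordinary least squares of ln(value) on t.
    ``method='nls'``: nonlinear least squares of N0 * exp(-k t) on the
    linear scale, seeded from the OLS solution — a sensitivity alternative
    that weights early (abundant) points more heavily.

    Zero values are treated as missing. Returns None when fewer than three
    positive points remain or t0 is absent. A series with zero residual
    variance on the log scale (e.g. perfectly constant) is a perfect fit of
    the log-linear model, so its R^2 is 1.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = values > 0
    t, v = times[ok], values[ok]
    if len(t) < 3 or 0.0 not in t:
        return None
    logv = np.log(v)
    fit = stats.linregress(t, logv)
    slope, intercept = fit.slope, fit.intercept
    if method == "nls":
        from scipy.optimize import curve_fit
        try:
            popt, _ = curve_fit(lambda t, n0, k: n0 * np.exp(-k * t), t, v,
                                p0=(math.exp(intercept), -slope), maxfev=2000)
            slope, intercept = -popt[1], math.log(max(popt[0], 1e-300))
        except RuntimeError:
            pass  # keep the OLS solution
    elif method != "ols":
        raise ValueError(f"unknown fit method {method!r}")
    k = -slope
    log_pred = intercept + slope * t
    if np.ptp(logv - slope * t) < 1e-12:  # exact fit, incl. constant series
        r2 = 1.0
    else:
        r2 = _linear_r2(logv, log_pred)
    r2_lin = _linear_r2(v, np.exp(log_pred))
    half_life = LN2 / k if k > 0 else math.inf
    return DecayFit(k=float(k), half_life=float(half_life),
                    r_squared=float(r2), r_squared_linear=float(r2_lin),
                    n_points=len(t))


def filter_and_cap(gene_id: str, fit: DecayFit | None, rpk0: float,
                   n_missing_after_t0: int = 0, cap: float = 15.0,
                   r2_min: float = 0.8, rpk_min: float = 50.0,
                   max_missing_after_t0: int = 1) -> HalfLifeRecord:
    """Apply the exclusion filters and the reporting cap to one fit.

    Filter order: t0 expression floor (strict ``< rpk_min`` excludes), then
    missing-data rule (more than ``max_missing_after_t0`` zero/absent
    post-arrest points excludes, as does an unfittable series), then the
    fit-quality rule (strict ``< r2_min`` excludes). Surviving fits with
    k <= 0 or t_half > cap are reported at the cap with ``capped=True``.
    """
    if rpk0 < rpk_min:
        return HalfLifeRecord(gene_id=gene_id, status=STATUS_LOW_RPK)
    if n_missing_after_t0 > max_missing_after_t0 or fit is None:
        return HalfLifeRecord(gene_id=gene_id, status=STATUS_MISSING)
    if fit.r_squared < r2_min:
        return HalfLifeRecord(gene_id=gene_id, status=STATUS_POOR_FIT,
                              r_squared=fit.r_squared, n_points_used=fit.n_points)
    if not math.isfinite(fit.half_life) or fit.half_life > cap:
        return HalfLifeRecord(gene_id=gene_id, status=STATUS_OK, half_life=cap,
                              capped=True, r_squared=fit.r_squared,
                              n_points_used=fit.n_points)
    return HalfLifeRecord(gene_id=gene_id, status=STATUS_OK,
                          half_life=fit.half_life, capped=False,
                          r_squared=fit.r_squared, n_points_used=fit.n_points)


def estimate_halflife(gene_id: str, times, values, **filter_kwargs) -> HalfLifeRecord:
    """Fit one normalized series and apply the filters in one step."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    at0 = times == 0.0
    rpk0 = float(values[at0][0]) if at0.any() else 0.0
    n_missing = int(np.sum((times > 0) & (values <= 0)))
    fit = fit_decay(times, values)
    return filter_and_cap(gene_id, fit, rpk0, n_missing, **filter_kwargs)


def estimate_all(expression: pd.DataFrame, **filter_kwargs) -> list[HalfLifeRecord]:
    """Per-gene half-life records from a tidy normalized expression table.

    Expects columns gene_id, time_min, rpk_norm; replicate rows are averaged
    per (gene, time) before fitting.
    """
    mean = (expression.groupby(["gene_id", "time_min"])["rpk_norm"].mean()
            .reset_index())
    records = []
    for gene_id, sub in mean.groupby("gene_id"):
        records.append(estimate_halflife(
            str(gene_id), sub["time_min"].to_numpy(), sub["rpk_norm"].to_numpy(),
            **filter_kwargs))
    return records


def records_to_frame(records: list[HalfLifeRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"gene_id": r.gene_id, "half_life_min": r.half_life,
         "capped": r.capped, "r_squared": r.r_squared,
         "n_points": r.n_points_used, "status": r.status}
        for r in records
    ])


def summarize(records: list[HalfLifeRecord]) -> dict:
    """Distribution summary over genes with a fitted half-life.

    Capped values enter the order statistics at the cap value.
    """
    values = np.array([r.half_life for r in records if r.status == STATUS_OK])
    if len(values) == 0:
        raise ValueError("no fitted half-lives to summarize")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(len(values)),
        "median": float(med),
        "mean": float(values.mean()),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(values.min()),
        "n_capped": int(sum(r.capped for r in records if r.status == STATUS_OK)),
    }
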