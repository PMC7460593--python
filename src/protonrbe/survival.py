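"""Clonogenic survival processing, linear-quadratic fitting and RBE.

The linear-quadratic (LQ) model describes the clonogenic surviving
fraction after an absorbed dose D (Gy) as

    S(D) = exp(-alpha*D - beta*D**2),    alpha [Gy^-1], beta [Gy^-2] >= 0.

Fitting is by weighted least squares on the log-survival scale, where the
model is linear in (alpha, beta); inverse-variance weights come from the
replicate standard deviations. The relative biological effectiveness at a
survival level S is the ratio of isoeffective doses,

    RBE_S = D_ref(S) / D_test(S),

with the reference conventionally a Co-60 gamma beam and D(S) the positive
root of alpha*D + beta*D**2 = ln(1/S). Standard errors of RBE are
propagated from the fit covariances by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, nnls

from .design import condition_label

__all__ = [
    "SurvivalCurveFit",
    "RBEEstimate",
    "surviving_fractions",
    "fit_lq",
    "isoeffect_dose",
    "compute_rbe",
    "lq_survival",
]


def lq_survival(dose, alpha: float, beta: float):
    """LQ surviving fraction exp(-alpha*D - beta*D^2)."""
    d = np.asarray(dose, dtype=float)
    return np.exp(-alpha * d - beta * d * d)


@dataclass(frozen=True)
class SurvivalCurveFit:
    """LQ fit result: parameters, uncertainties and goodness of fit.

    ``r_squared`` is defined on the scale the curve was fitted on
    (log-survival by default).
    """

    alpha: float  # Gy^-1
    beta: float  # Gy^-2
    se_alpha: float = 0.0
    se_beta: float = 0.0
    cov_alpha_beta: float = 0.0
    r_squared: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.se_alpha < 0 or self.se_beta < 0:
            raise ValueError("standard errors must be non-negative")

    @property
    def covariance(self) -> np.ndarray:
        return np.array(
            [
                [self.se_alpha**2, self.cov_alpha_beta],
                [self.cov_alpha_beta, self.se_beta**2],
            ]
        )

    def survival(self, dose):
        return lq_survival(dose, self.alpha, self.beta)


@dataclass(frozen=True)
class RBEEstimate:
    """RBE at a fixed survival level with its propagated standard error."""

    rbe: float
    se: float
    survival_level: float
    reference: str
    test: str
    iso_dose_ref: float  # Gy
    iso_dose_test: float  # Gy


def surviving_fractions(
    colony_counts: pd.DataFrame, pooling: str = "wells"
) -> pd.DataFrame:
    """Reduce per-well colony counts to per-condition survival observations.

    The plating efficiency of each (mode, position, run) is estimated from
    that run's 0 Gy control wells, so SF(0 Gy) averages to 1 per run by
    construction; each well's surviving fraction is then
    (colonies / seeded) / PE_run.

    Parameters
    ----------
    colony_counts : DataFrame
        Columns ``mode, position, dose_gy, run, well, seeded, colonies``.
    pooling : {"wells", "runs"}
        "wells": mean/SD across all wells of a condition pooled over runs
        (n = total wells). "runs": mean/SD across the run means (n = runs).

    Returns
    -------
    DataFrame with columns ``label, mode, position, dose_gy, mean_sf,
    sd_sf, n`` sorted by condition and dose.
    """
    if pooling not in ("wells", "runs"):
        raise ValueError("pooling must be 'wells' or 'runs'")
    df = colony_counts.copy()
    required = {"mode", "position", "dose_gy", "run", "seeded", "colonies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"colony table missing columns: {sorted(missing)}")

    out = []
    for (mode, position), grp in df.groupby(["mode", "position"], sort=True):
        for run, rgrp in grp.groupby("run"):
            ctrl = rgrp[rgrp["dose_gy"] == 0]
            if ctrl.empty:
                raise ValueError(
                    f"run {run} of {mode}/{position} has no 0 Gy controls"
                )
            pe = ctrl["colonies"].sum() / ctrl["seeded"].sum()
            if pe <= 0:
                raise ValueError(
                    f"run {run} of {mode}/{position}: zero control colonies"
                )
            sf = rgrp["colonies"] / rgrp["seeded"] / pe
            df.loc[rgrp.index, "sf"] = sf
        label = condition_label(mode, position)
        cond = df.loc[grp.index]
        ctrl_total = int(cond.loc[cond["dose_gy"] == 0, "colonies"].sum())
        for dose, dgrp in cond.groupby("dose_gy"):
            if pooling == "wells":
                vals = dgrp["sf"].to_numpy()
            else:
                vals = dgrp.groupby("run")["sf"].mean().to_numpy()
            out.append(
                {
                    "label": label,
                    "mode": mode,
                    "position": position,
                    "dose_gy": float(dose),
                    "mean_sf": float(np.mean(vals)),
                    "sd_sf": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                    "total_colonies": int(dgrp["colonies"].sum()),
                    "control_colonies": ctrl_total,
                }
            )
    return pd.DataFrame(out).sort_values(["label", "dose_gy"]).reset_index(drop=True)


def _obs_arrays(observations) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(observations, pd.DataFrame):
        d = observations["dose_gy"].to_numpy(float)
        m = observations["mean_sf"].to_numpy(float)
        s = observations["sd_sf"].to_numpy(float)
        n = observations["n"].to_numpy(float)
    else:  # sequence of (dose, mean, sd, n)
        arr = np.asarray(list(observations), dtype=float)
        d, m, s, n = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    return d, m, s, n


def fit_lq(
    observations,
    scale: str = "log",
    weighting: str = "auto",
    label: str = "",
) -> SurvivalCurveFit:
    """Fit the LQ model to per-condition survival observations.

    Parameters
    ----------
    observations : DataFrame (``dose_gy, mean_sf, sd_sf, n``, optionally
        ``total_colonies, control_colonies``) or sequence of
        (dose, mean_sf, sd_sf, n) tuples. At least 3 distinct dose levels,
        at least one above 0 Gy.
    scale : {"log", "linear"}
        "log" (default): weighted linear least squares of -ln(mean SF) on
        (D, D^2). "linear": nonlinear least squares of mean SF on
        exp(-aD-bD^2) with sigma = SD/sqrt(n).
    weighting : {"auto", "poisson", "replicate"}
        Variance model for the log-scale observations. "poisson" uses
        counting statistics, var = 1/(total colonies) + 1/(control
        colonies) — the dosed 0 Gy rows are then excluded since their
        log-SF is 0 by construction against the very same controls.
        "replicate" uses the delta-method variance of the log of a mean,
        (SD / (mean * sqrt(n)))^2, from the replicate SDs — appropriate
        when only summary means are available (e.g. digitized curves), but
        with few dose points the noisy variance estimates make the
        resulting SEs anti-conservative. "auto" (default) picks "poisson"
        when colony totals are present.

    Both estimators constrain alpha, beta >= 0. Log-scale standard errors
    are the weighted-least-squares covariance (X' W X)^-1 with W the
    inverse observation variances; when a parameter sits at the zero
    boundary its SE is from the unconstrained curvature and should be
    read as approximate.
    """
    d, m, s, n = _obs_arrays(observations)
    if len(np.unique(d)) < 3:
        raise ValueError("need at least 3 distinct dose levels")
    if not np.any(d > 0):
        raise ValueError("need dose levels above 0 Gy")
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    if weighting not in ("auto", "poisson", "replicate"):
        raise ValueError("weighting must be 'auto', 'poisson' or 'replicate'")

    totals = ctrl = None
    if isinstance(observations, pd.DataFrame) and {
        "total_colonies",
        "control_colonies",
    } <= set(observations.columns):
        totals = observations["total_colonies"].to_numpy(float)
        ctrl = observations["control_colonies"].to_numpy(float)
    if weighting == "auto":
        weighting = "poisson" if totals is not None else "replicate"
    if weighting == "poisson" and totals is None:
        raise ValueError(
            "poisson weighting needs total_colonies/control_colonies columns"
        )

    pos = m > 0
    if weighting == "poisson":
        pos &= d > 0  # 0 Gy rows carry no information beyond the controls
    if not np.all(pos):
        n_drop = np.count_nonzero(~pos & (m <= 0))
        if n_drop:
            warnings.warn(f"dropping {n_drop} observation(s) with mean SF <= 0")
        d, m, s, n = d[pos], m[pos], s[pos], n[pos]
        if totals is not None:
            totals, ctrl = totals[pos], ctrl[pos]

    if weighting == "poisson":
        if np.any(totals <= 0) or np.any(ctrl <= 0):
            raise ValueError("poisson weighting needs positive colony totals")
        var_y = 1.0 / totals + 1.0 / ctrl
    else:
        # delta-method variance of ln(mean SF); fall back to the median
        # weight where a replicate SD is missing or zero
        var_y = (s / (m * np.sqrt(n))) ** 2
        bad = ~np.isfinite(var_y) | (var_y <= 0)
        if np.all(bad):
            var_y = np.ones_like(var_y)
        elif np.any(bad):
            var_y[bad] = np.median(var_y[~bad])

    X = np.column_stack([d, d * d])
    y = -np.log(m)
    w = 1.0 / var_y
    sw = np.sqrt(w)
    theta, _ = nnls(X * sw[:, None], y * sw)
    alpha, beta = float(theta[0]), float(theta[1])

    if scale == "linear":
        sd_mean = s / np.sqrt(n)
        bad_s = ~np.isfinite(sd_mean) | (sd_mean <= 0)
        if np.all(bad_s):
            sd_mean = None
        elif np.any(bad_s):
            sd_mean = sd_mean.copy()
            sd_mean[bad_s] = np.median(sd_mean[~bad_s])
        try:
            popt, pcov = curve_fit(
                lq_survival,
                d,
                m,
                p0=[max(alpha, 1e-6), max(beta, 1e-6)],
                sigma=sd_mean,
                bounds=(0.0, np.inf),
                maxfev=10000,
            )
        except RuntimeError as err:  # pragma: no cover - pathological input
            raise RuntimeError(f"LQ fit did not converge: {err}") from err
        alpha, beta = float(popt[0]), float(popt[1])
        resid = m - lq_survival(d, alpha, beta)
        ww = 1.0 if sd_mean is None else 1.0 / sd_mean**2
        rss = float(np.sum(ww * resid**2))
        tss = float(np.sum(ww * (m - np.average(m, weights=np.broadcast_to(ww, m.shape))) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        return SurvivalCurveFit(
            alpha,
            beta,
            float(np.sqrt(pcov[0, 0])),
            float(np.sqrt(pcov[1, 1])),
            float(pcov[0, 1]),
            r2,
            label,
        )

    resid = y - X @ theta
    rss = float(np.sum(w * resid**2))
    xtwx = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"singular design in LQ fit: {err}") from err
    ybar = np.average(y, weights=w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return SurvivalCurveFit(
        alpha,
        beta,
        float(np.sqrt(max(cov[0, 0], 0.0))),
        float(np.sqrt(max(cov[1, 1], 0.0))),
        float(cov[0, 1]),
        r2,
        label,
    )


def _iso_dose(alpha: float, beta: float, survival_level: float) -> float:
    ln_inv_s = np.log(1.0 / survival_level)
    if alpha < 0 or beta < 0 or (alpha == 0 and beta == 0):
        raise ValueError("need alpha > 0 or beta > 0, both non-negative")
    # stable form of the positive quadratic root (no cancellation as b -> 0)
    return 2.0 * ln_inv_s / (alpha + np.sqrt(alpha * alpha + 4.0 * beta * ln_inv_s))


def isoeffect_dose(fit: SurvivalCurveFit, survival_level: float) -> float:
    """Dose (Gy) at which the fitted LQ curve reaches `survival_level`.

    Solves alpha*D + beta*D^2 = ln(1/S) for the positive root; reduces to
    ln(1/S)/alpha in the pure-linear case.
    """
    if not 0 < survival_level < 1:
        raise ValueError("survival_level must be in (0, 1)")
    return float(_iso_dose(fit.alpha, fit.beta, survival_level))


def _iso_dose_gradient(alpha: float, beta: float, level: float) -> np.ndarray:
    """Central-difference gradient of the isoeffect dose w.r.t. (alpha, beta)."""
    grad = np.empty(2)
    for i, p in enumerate((alpha, beta)):
        h = 1e-6 * max(abs(p), 1e-3)
        lo = [alpha, beta]
        hi = [alpha, beta]
        hi[i] = p + h
        lo[i] = max(p - h, 0.0)
        grad[i] = (_iso_dose(hi[0], hi[1], level) - _iso_dose(lo[0], lo[1], level)) / (
            (hi[i] - lo[i])
        )
    return grad


def compute_rbe(
    reference: SurvivalCurveFit,
    test: SurvivalCurveFit,
    survival_level: float = 0.5,
) -> RBEEstimate:
    """RBE of `test` relative to `reference` at a fixed survival level.

    RBE = D_ref(S) / D_test(S). The standard error propagates each fit's
    (alpha, beta) covariance through the isoeffect dose by the delta
    method, treating the two fits as independent:

        (se/RBE)^2 = var(D_ref)/D_ref^2 + var(D_test)/D_test^2,
        var(D) = g' Sigma g,  g = d D / d(alpha, beta).
    """
    if not 0 < survival_level < 1:
        raise ValueError("survival_level must be in (0, 1)")
    d_ref = isoeffect_dose(reference, survival_level)
    d_test = isoeffect_dose(test, survival_level)
    rbe = d_ref / d_test

    def var_d(fit: SurvivalCurveFit, d: float) -> float:
        g = _iso_dose_gradient(fit.alpha, fit.beta, survival_level)
        return float(g @ fit.covariance @ g)

    rel_var = var_d(reference, d_ref) / d_ref**2 + var_d(test, d_test) / d_test**2
    se = rbe * np.sqrt(max(rel_var, 0.0))
    return RBEEstimate(
        rbe=float(rbe),
        se=float(se),
        survival_level=survival_level,
        reference=reference.label or "reference",
        test=test.label or "test",
        iso_dose_ref=float(d_ref),
        iso_dose_test=float(d_test),
    )
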