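"""Orientation tuning, selectivity, and receptive-field analyses for visual units.

Tuning curves are per-condition trial-mean firing rates (with SEM),
normalized by the most active orientation.  Selectivity is summarized by the
orientation selectivity index OSI = (Rpref - Rorth) / (Rpref + Rorth), with
units above 0.3 conventionally called orientation selective; a
circular-variance variant is available.  Receptive fields are mapped from
responses to stimuli flashed on a location grid (fixation at (0,0) visual
degrees), fit with a 2D elliptical Gaussian; RF size is twice the geometric
mean of the fitted sigmas, and eccentricity is the distance of the fitted
center from fixation.  The RF-size-vs-depth trend is tested with a linear
mixed model with a random intercept and random slope per shank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TuningCurve",
    "RFResult",
    "trial_rates",
    "orientation_curve",
    "osi",
    "preferred_orientation",
    "rf_map",
    "rf_fit",
    "rf_depth_model",
]


@dataclass
class TuningCurve:
    conditions_deg: np.ndarray
    mean_rate_hz: np.ndarray
    sem_hz: np.ndarray
    normalized: np.ndarray
    n_trials: np.ndarray


@dataclass
class RFResult:
    center_deg: tuple[float, float]
    size_deg: float
    eccentricity_deg: float
    fit_ok: bool
    response_grid: pd.DataFrame


def trial_rates(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float] = (0.0, None),
    align: str = "onset_s",
) -> np.ndarray:
    """Firing rate per trial inside ``window`` relative to the alignment event.

    ``window=(start, end)`` in seconds; ``end=None`` uses each trial's offset.
    """
    t = np.asarray(spike_times, dtype=float)
    start_rel, end_rel = window
    rates = np.empty(len(trials))
    for i, row in enumerate(trials.itertuples(index=False)):
        t0 = getattr(row, align) + start_rel
        t1 = row.offset_s if end_rel is None else getattr(row, align) + end_rel
        if t1 <= t0:
            raise ValueError("window must have positive length within the trial")
        n = np.searchsorted(t, t1, side="left") - np.searchsorted(t, t0, side="left")
        rates[i] = n / (t1 - t0)
    return rates


def orientation_curve(rates: np.ndarray, orientations: np.ndarray) -> TuningCurve:
    """Per-orientation mean rate, SEM, and max-normalized curve."""
    orientations = np.asarray(orientations, dtype=float)
    rates = np.asarray(rates, dtype=float)
    conds = np.unique(orientations)
    if conds.size < 2:
        raise ValueError("need >= 2 orientations")
    mean = np.empty(conds.size)
    sem = np.empty(conds.size)
    n = np.empty(conds.size, dtype=int)
    for i, c in enumerate(conds):
        r = rates[orientations == c]
        mean[i] = r.mean()
        n[i] = r.size
        if r.size < 2:
            warnings.warn(f"single trial at orientation {c}; SEM reported as 0")
            sem[i] = 0.0
        else:
            sem[i] = r.std(ddof=1) / np.sqrt(r.size)
    peak = mean.max()
    normalized = mean / peak if peak > 0 else np.zeros_like(mean)
    return TuningCurve(conds, mean, sem, normalized, n)


def osi(curve: TuningCurve, method: str = "pref_orth") -> float:
    """Orientation selectivity index in [0, 1].

    ``pref_orth``: (Rpref - Rorth)/(Rpref + Rorth) with Rpref the max
    condition mean and Rorth the mean at the grid condition nearest 90 deg
    away.  ``circular_variance``: one minus the circular variance, i.e. the
    resultant length |sum R exp(2i theta)| / sum R (0 = flat, 1 = one-hot).
    """
    r = np.clip(curve.mean_rate_hz, 0.0, None)
    if method == "circular_variance":
        tot = r.sum()
        if tot == 0:
            return 0.0
        z = np.sum(r * np.exp(2j * np.deg2rad(curve.conditions_deg)))
        return float(np.abs(z) / tot)
    if method != "pref_orth":
        raise ValueError(f"unknown OSI method {method!r}")
    i_pref = int(np.argmax(r))
    target = np.mod(curve.conditions_deg[i_pref] + 90.0, 180.0)
    d = np.abs(np.mod(curve.conditions_deg - target + 90.0, 180.0) - 90.0)
    i_orth = int(np.argmin(d))
    rp, ro = r[i_pref], r[i_orth]
    if rp + ro == 0:
        return 0.0
    return float((rp - ro) / (rp + ro))


def preferred_orientation(curve: TuningCurve, tol: float = 1e-9) -> float:
    """Vector-sum preferred orientation on [0, 180) deg; NaN when undefined.

    Half-angle of the doubled-angle resultant:
    0.5 * atan2(sum R sin 2theta, sum R cos 2theta).  A flat or symmetric
    curve yields a zero resultant and the NaN sentinel.
    """
    r = np.clip(curve.mean_rate_hz, 0.0, None)
    ang = 2.0 * np.deg2rad(curve.conditions_deg)
    y, x = np.sum(r * np.sin(ang)), np.sum(r * np.cos(ang))
    if np.hypot(x, y) <= tol * max(r.sum(), 1e-300):
        return float("nan")
    return float(np.mod(np.rad2deg(0.5 * np.arctan2(y, x)), 180.0))


def rf_map(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    baseline_window_s: float | None = None,
) -> pd.DataFrame:
    """Mean baseline-subtracted evoked rate per stimulus grid location.

    The baseline is each trial's rate in an equal-length window immediately
    before stimulus onset (length capped by ``baseline_window_s``).
    Returns a DataFrame with columns x_deg, y_deg, rate_hz.
    """
    need = {"grid_x_deg", "grid_y_deg"}
    if not need <= set(trials.columns):
        raise ValueError("trial table lacks grid_x_deg / grid_y_deg columns")
    t = np.asarray(spike_times, dtype=float)
    evoked = trial_rates(t, trials)
    base = np.empty(len(trials))
    for i, row in enumerate(trials.itertuples(index=False)):
        L = row.offset_s - row.onset_s
        if baseline_window_s is not None:
            L = min(L, baseline_window_s)
        t0, t1 = row.onset_s - L, row.onset_s
        n = np.searchsorted(t, t1, side="left") - np.searchsorted(t, t0, side="left")
        base[i] = n / L
    df = trials.copy()
    df["evoked_hz"] = evoked - base
    grid = (
        df.groupby(["grid_x_deg", "grid_y_deg"], as_index=False)["evoked_hz"]
        .mean()
        .rename(columns={"grid_x_deg": "x_deg", "grid_y_deg": "y_deg", "evoked_hz": "rate_hz"})
    )
    return grid


def _gauss2d(xy, amp, x0, y0, sx, sy, off):
    x, y = xy
    return off + amp * np.exp(-0.5 * (((x - x0) / sx) ** 2 + ((y - y0) / sy) ** 2))


def rf_fit(response_grid: pd.DataFrame, min_peak_snr: float = 2.0) -> RFResult:
    """2D elliptical Gaussian fit of a response grid by least squares.

    size = 2 * sqrt(sigma_x * sigma_y) (geometric-mean diameter at 1 sigma,
    doubled); eccentricity = distance of the fitted center from fixation.
    ``fit_ok`` is False when the peak does not clear ``min_peak_snr`` times
    the grid noise (robust SD of the grid values) or the fit diverges.
    """
    x = response_grid["x_deg"].to_numpy(dtype=float)
    y = response_grid["y_deg"].to_numpy(dtype=float)
    r = response_grid["rate_hz"].to_numpy(dtype=float)
    noise = 1.4826 * np.median(np.abs(r - np.median(r)))
    peak = r.max()
    bad = RFResult((np.nan, np.nan), np.nan, np.nan, False, response_grid)
    if peak <= 0 or (noise > 0 and peak < min_peak_snr * noise):
        return bad
    i0 = int(np.argmax(r))
    span = max(x.max() - x.min(), y.max() - y.min(), 1.0)
    p0 = [peak, x[i0], y[i0], span / 6, span / 6, float(np.median(r))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss2d,
                (x, y),
                r,
                p0=p0,
                bounds=(
                    [0, x.min() - span, y.min() - span, 1e-3, 1e-3, -np.inf],
                    [np.inf, x.max() + span, y.max() + span, 2 * span, 2 * span, np.inf],
                ),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return bad
    amp, x0, y0, sx, sy, _ = popt
    size = 2.0 * np.sqrt(sx * sy)
    ecc = float(np.hypot(x0, y0))
    return RFResult((float(x0), float(y0)), float(size), ecc, True, response_grid)


def rf_depth_model(
    rf_sizes: np.ndarray,
    depths: np.ndarray,
    shank_ids: np.ndarray,
) -> dict:
    """Linear mixed model: RF size ~ depth with random intercept+slope per shank.

    ``depths`` are in micrometre below the pia; the model is fit on depth in
    millimetre (keeps the random-slope variance well scaled) and the returned
    slope is in degrees of visual angle per mm of depth.  Returns the fixed
    slope, its 95% CI and p-value, and whether the random-slope fit converged
    (``random_slope_ok``); on a singular or non-converging fit the model
    falls back to random intercepts only.
    """
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"rf_size": np.asarray(rf_sizes, float),
         "depth": np.asarray(depths, float) / 1000.0,
         "shank": np.asarray(shank_ids)}
    )
    if df["shank"].nunique() < 2:
        raise ValueError("need >= 2 shanks")
    if df.groupby("shank").size().min() < 3:
        raise ValueError("need >= 3 units per shank")

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("rf_size ~ depth", df, groups=df["shank"], re_formula=re_formula)
            return model.fit(reml=True)

    random_slope_ok = True
    try:
        res = _fit("~depth")
        if (
            not res.converged
            or not np.isfinite(res.bse["depth"])
            or res.bse["depth"] == 0.0
        ):
            raise ValueError("random-slope fit did not converge")
    except (ValueError, np.linalg.LinAlgError):
        random_slope_ok = False
        res = _fit("1")

    # few shanks make z-based Wald intervals anti-conservative; use t with
    # df = n_shanks - 1 for the CI and p-value instead
    from scipy import stats as _st

    slope = float(res.params["depth"])
    se = float(res.bse["depth"])
    dof = df["shank"].nunique() - 1
    tcrit = float(_st.t.ppf(0.975, dof))
    pval = 2.0 * float(_st.t.sf(abs(slope / se), dof)) if se > 0 else 0.0
    return {
        "slope": slope,
        "se": se,
        "ci95": (slope - tcrit * se, slope + tcrit * se),
        "p": pval,
        "random_slope_ok": random_slope_ok,
        "n": len(df),
    }
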