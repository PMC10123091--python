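"""Nonlinear curve fits and derived quantities.

Covers the three fits used downstream of the assay: one-phase association
kinetics E(t) = Emax(1 - exp(-k t)) for single-turnover editing time
courses, the four-parameter logistic for dose-response potency (EC50), and
ordinary least squares for the editing-vs-fluorescence correlation.  Rate
constants are reported in the reciprocal of whatever time unit the input
uses; the fitter never converts units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP

import numpy as np
from scipy import optimize, stats

from .simulate import DoseSeries, KineticSeries, four_pl, one_phase_association

__all__ = [
    "FitError",
    "DegenerateSeriesError",
    "OnePhaseFit",
    "FourPLFit",
    "LinearFit",
    "fit_one_phase",
    "fit_4pl",
    "linear_fit",
    "fold_change",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; the message carries diagnostics."""


class DegenerateSeriesError(ValueError):
    """The series carries no signal to fit (e.g. flat response)."""


@dataclass
class OnePhaseFit:
    emax: float
    k: float
    emax_sd: float
    k_sd: float
    per_replicate: list[tuple[float, float]] = field(default_factory=list)
    rms_residual: float = 0.0


@dataclass
class FourPLFit:
    bottom: float
    top: float
    hill: float
    ec50: float
    se: dict = field(default_factory=dict)
    rms_residual: float = 0.0


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


def _one_phase_init(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Emax0 = max observed; k0 = ln2 / first half-rise time, fallback 1/median(t)."""
    emax0 = float(values.max())
    pos = times[times > 0]
    fallback = 1.0 / float(np.median(pos)) if pos.size else 1.0
    k0 = fallback
    half = emax0 / 2.0
    for t, v in zip(times, values):
        if t > 0 and v >= half:
            k0 = np.log(2.0) / t
            break
    return emax0, k0


def _fit_one_phase_single(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    if np.ptp(values) < 1e-12:
        raise DegenerateSeriesError("flat series: no rise to fit")
    emax0, k0 = _one_phase_init(times, values)
    pos = times[times > 0]
    k_hi = 1e3 / float(np.median(pos)) if pos.size else 1e3
    try:
        popt, _ = optimize.curve_fit(
            one_phase_association,
            times,
            values,
            p0=[max(emax0, 1e-6), min(k0, k_hi * 0.99)],
            bounds=([1e-9, 1e-9], [1.2, k_hi]),
            maxfev=10000,
        )
    except RuntimeError as e:  # pragma: no cover - scipy message passthrough
        raise FitError(f"one-phase fit did not converge: {e}") from e
    return float(popt[0]), float(popt[1])


def fit_one_phase(series: KineticSeries, pooled: bool = False) -> OnePhaseFit:
    """Fit E = Emax(1 - exp(-k t)).

    By default each replicate is fitted independently and parameters are
    reported as mean +/- SD across replicates (the "rate constant +/- SD"
    convention); ``pooled`` instead fits all replicate points jointly and
    reports covariance-based SEs.
    """
    t = series.times
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if t.min() > 0.2 * t.max():
        raise ValueError("need a time point near zero to anchor the rise")
    if pooled or series.n_reps == 1:
        tt = np.tile(t, series.n_reps)
        vv = series.values.ravel()
        emax, k = _fit_one_phase_single(tt, vv)
        resid = vv - one_phase_association(tt, emax, k)
        # SEs from a final unconstrained covariance evaluation
        try:
            _, pcov = optimize.curve_fit(
                one_phase_association, tt, vv, p0=[emax, k], maxfev=10000
            )
            ses = np.sqrt(np.diag(pcov))
        except RuntimeError:
            ses = np.array([np.nan, np.nan])
        return OnePhaseFit(
            emax, k, float(ses[0]), float(ses[1]),
            per_replicate=[(emax, k)],
            rms_residual=float(np.sqrt(np.mean(resid**2))),
        )
    fits = [_fit_one_phase_single(t, series.values[i]) for i in range(series.n_reps)]
    emaxs = np.array([f[0] for f in fits])
    ks = np.array([f[1] for f in fits])
    resid = np.concatenate(
        [
            series.values[i] - one_phase_association(t, *fits[i])
            for i in range(series.n_reps)
        ]
    )
    return OnePhaseFit(
        float(emaxs.mean()),
        float(ks.mean()),
        float(emaxs.std(ddof=1)),
        float(ks.std(ddof=1)),
        per_replicate=[(float(e), float(k)) for e, k in fits],
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def fit_4pl(series: DoseSeries) -> FourPLFit:
    """Least-squares four-parameter logistic fit; EC50 in the dose units."""
    d = series.doses
    if d.size < 4:
        raise ValueError("need at least 4 doses")
    dd = np.tile(d, series.n_reps)
    vv = series.values.ravel()
    span = float(np.ptp(vv))
    if span < 1e-12:
        raise DegenerateSeriesError("constant response: 4PL is unidentifiable")
    lo, hi = float(vv.min()), float(vv.max())
    p0 = [lo, hi, 1.0, float(np.exp(np.mean(np.log(d))))]
    bounds = (
        [lo - span, lo - span, 0.1, d.min() / 100.0],
        [hi + span, hi + span, 10.0, d.max() * 100.0],
    )
    try:
        popt, pcov = optimize.curve_fit(
            four_pl, dd, vv, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as e:
        raise FitError(f"4PL fit did not converge: {e}") from e
    bottom, top, hill, ec50 = (float(x) for x in popt)
    if top < bottom:  # reparameterize to the ascending convention
        bottom, top, hill = top, bottom, -hill
    resid = vv - four_pl(dd, *popt)
    ses = np.sqrt(np.diag(pcov))
    return FourPLFit(
        bottom,
        top,
        hill,
        ec50,
        se={k: float(s) for k, s in zip(("bottom", "top", "hill", "ec50"), ses)},
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares y ~ x with r^2 (the editing-vs-GFP regression)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


def fold_change(
    k_test: float, k_ref: float, decimals: int = 1, mode: str = "round"
) -> float:
    """Rate-constant ratio rendered at fixed precision.

    ``mode='round'`` rounds half up (0.221/0.049 -> 4.5, 28.7/16.4 -> 1.8);
    ``mode='truncate'`` drops digits instead.  Both exist because published
    ratios mix the two conventions.
    """
    if k_ref <= 0:
        raise ValueError("reference rate constant must be positive")
    if decimals < 0:
        raise ValueError("decimals must be non-negative")
    if mode not in ("round", "truncate"):
        raise ValueError("mode must be 'round' or 'truncate'")
    ratio = Decimal(str(k_test)) / Decimal(str(k_ref))
    quant = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "round" else ROUND_DOWN
    return float(ratio.quantize(quant, rounding=rounding))
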