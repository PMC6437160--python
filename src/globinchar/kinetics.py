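"""Rate-constant estimators.

Single-exponential fits (k_obs per stopped-flow trace, hemin-loss k-H),
weighted linear regression of k_obs versus [O2] (k_on from the slope, k_off
from the intercept, K_D = k_off/k_on), and autoxidation k_ox from
state-fraction time courses.

All rates carry a declared time unit; estimators never convert units
silently -- a trace in the wrong unit is a rejected input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectra import BasisSet, decompose


class UnitError(ValueError):
    """Raised when a trace's declared time unit does not match the estimator."""


@dataclass(frozen=True)
class KineticTrace:
    """One time-resolved absorbance record.

    ``time`` must be strictly increasing with at least 8 samples, in the
    declared ``time_unit`` ("s", "min" or "h").
    """

    time: np.ndarray
    signal: np.ndarray
    time_unit: str = "s"
    wavelength_nm: float | None = None
    temperature_C: float | None = None
    ligand_conc_M: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if self.time_unit not in ("s", "min", "h"):
            raise UnitError(f"undeclared or unknown time unit {self.time_unit!r}")
        if t.ndim != 1 or t.size < 8:
            raise ValueError("trace needs at least 8 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if y.shape != t.shape:
            raise ValueError("signal/time shape mismatch")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting offset + amplitude * exp(-rate * t)."""

    rate: float
    amplitude: float
    offset: float
    rate_se: float
    rmse: float
    converged: bool
    unit: str = "s"
    flags: tuple[str, ...] = ()

    @property
    def half_life(self) -> float:
        return np.log(2.0) / self.rate if self.rate > 0 else np.inf


def _noise_estimate(y: np.ndarray) -> float:
    # robust sigma from lag-1 differences; insensitive to the decay itself
    d = np.diff(y)
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def _exp_model(t, offset, amplitude, rate):
    return offset + amplitude * np.exp(-rate * t)


def _exp_jac(t, offset, amplitude, rate):
    e = np.exp(-rate * t)
    return np.column_stack([np.ones_like(t), e, -amplitude * t * e])


def fit_single_exponential(trace: KineticTrace) -> ExponentialFit:
    """Least-squares single-exponential fit of a kinetic trace.

    Initialization: the offset is seeded from the tail mean and the rate from
    a log-linear regression of |signal - tail mean|; the refinement is a
    damped (Levenberg-Marquardt) least-squares with analytic Jacobian.
    An amplitude below 3x the noise estimate is reported as non-converged
    ("degenerate amplitude"); a fit with rmse above 5x the noise estimate is
    flagged but still returned.
    """
    t = trace.time - trace.time[0]
    y = trace.signal
    noise = _noise_estimate(y)
    n_tail = max(3, y.size // 10)
    tail = float(np.mean(y[-n_tail:]))
    amp0 = float(y[0] - tail)

    if abs(amp0) < 3.0 * noise:
        return ExponentialFit(
            rate=0.0, amplitude=0.0, offset=float(np.mean(y)), rate_se=np.nan,
            rmse=float(np.std(y)), converged=False, unit=trace.time_unit,
            flags=("degenerate amplitude",),
        )

    resid = np.abs(y - tail)
    mask = resid > max(noise, 1e-3 * abs(amp0))
    # log-linear slope over the informative early part of the decay
    if mask.sum() >= 3:
        tm, rm = t[mask], np.log(resid[mask])
        slope = np.polyfit(tm, rm, 1)[0]
        rate0 = max(-slope, 1e-12)
    else:
        rate0 = 1.0 / max(t[-1], 1e-12)

    popt, pcov = curve_fit(
        _exp_model, t, y, p0=[tail, amp0, rate0], jac=_exp_jac,
        method="lm", maxfev=10000,
    )
    offset, amplitude, rate = popt
    fitted = _exp_model(t, *popt)
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    rate_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.nan
    flags: list[str] = []
    if noise > 0 and rmse > 5.0 * noise:
        flags.append("high rmse")
    converged = rate >= 0
    return ExponentialFit(
        rate=float(rate), amplitude=float(amplitude), offset=float(offset),
        rate_se=rate_se, rmse=rmse, converged=converged,
        unit=trace.time_unit, flags=tuple(flags),
    )


@dataclass(frozen=True)
class BindingKinetics:
    """O2 binding parameters from the k_obs vs concentration line."""

    k_on: float            # M^-1 s^-1, slope
    k_off: float           # s^-1, intercept (raw, may be negative -> flagged)
    K_D: float             # M, k_off / k_on; nan when not determined
    k_on_se: float
    k_off_se: float
    K_D_se: float
    r_squared: float
    flags: tuple[str, ...] = ()


def fit_kobs_vs_conc(
    points: list[tuple[float, float, float | None]] | list[tuple[float, float]],
) -> BindingKinetics:
    """Linear regression of pseudo-first-order rates on ligand concentration.

    ``points`` are (conc_M, k_obs_s, se) tuples; when SEs are supplied the
    regression is weighted by 1/se^2, otherwise ordinary least squares.
    k_on is the slope, k_off the intercept; a negative intercept is reported
    raw with a flag and K_D marked not determined.  K_D standard error
    combines slope and intercept SEs by the delta method (covariance
    included).
    """
    pts = [tuple(p) + (None,) * (3 - len(p)) for p in points]
    conc = np.array([p[0] for p in pts], dtype=float)
    kobs = np.array([p[1] for p in pts], dtype=float)
    ses = [p[2] for p in pts]
    if conc.size < 3:
        raise ValueError("need at least 3 concentration points")
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(conc) <= 0:
        raise ValueError("zero concentration spread")

    if all(s is not None and s > 0 for s in ses):
        w = 1.0 / np.array(ses, dtype=float) ** 2
    else:
        w = np.ones_like(conc)

    # closed-form weighted least squares for y = a + b x
    X = np.column_stack([np.ones_like(conc), conc])
    WX = X * w[:, None]
    cov_unscaled = np.linalg.inv(X.T @ WX)
    beta = cov_unscaled @ (WX.T @ kobs)
    intercept, slope = beta
    resid = kobs - X @ beta
    dof = conc.size - 2
    s2 = float((w * resid**2).sum() / dof) if dof > 0 else np.nan
    cov = cov_unscaled * s2
    intercept_se = float(np.sqrt(cov[0, 0]))
    slope_se = float(np.sqrt(cov[1, 1]))

    ybar = float((w * kobs).sum() / w.sum())
    ss_tot = float((w * (kobs - ybar) ** 2).sum())
    r2 = 1.0 - float((w * resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0

    flags: list[str] = []
    if slope <= 0 or (np.isfinite(slope_se) and slope <= 2.0 * slope_se):
        flags.append("slope not determined; K_D not determined")
        kd = np.nan
        kd_se = np.nan
    else:
        kd = intercept / slope
        if intercept < 0:
            flags.append("negative intercept; K_D not determined")
            kd = np.nan
            kd_se = np.nan
        else:
            # delta method: var(a/b) = (a/b)^2 [va/a^2 + vb/b^2 - 2 cov/(a b)]
            va, vb, vab = cov[0, 0], cov[1, 1], cov[0, 1]
            kd_se = abs(kd) * np.sqrt(
                max(va / intercept**2 + vb / slope**2 - 2 * vab / (intercept * slope), 0.0)
            ) if intercept != 0 else np.nan
    return BindingKinetics(
        k_on=float(slope), k_off=float(intercept), K_D=float(kd),
        k_on_se=slope_se, k_off_se=intercept_se, K_D_se=float(kd_se),
        r_squared=float(r2), flags=tuple(flags),
    )


def fit_binding_panel(traces) -> BindingKinetics:
    """Fit each trace's k_obs then regress on the [O2] metadata."""
    points = []
    for tr in traces:
        if tr.ligand_conc_M is None:
            raise ValueError("trace missing ligand concentration metadata")
        if tr.time_unit != "s":
            raise UnitError("binding traces must be in seconds")
        fit = fit_single_exponential(tr)
        if not fit.converged:
            raise ValueError("trace fit did not converge")
        points.append((tr.ligand_conc_M, fit.rate, fit.rate_se))
    return fit_kobs_vs_conc(points)


def fit_hemin_loss(trace: KineticTrace) -> ExponentialFit:
    """Hemin dissociation rate (h^-1) from a 410 nm decay.

    The trace must declare hours as its unit.  A duration shorter than two
    recovered half-lives is flagged ("short duration").
    """
    if trace.time_unit != "h":
        raise UnitError("hemin-loss traces must declare time in hours")
    fit = fit_single_exponential(trace)
    flags = list(fit.flags)
    duration = trace.time[-1] - trace.time[0]
    if fit.converged and fit.rate > 0 and duration < 2.0 * np.log(2.0) / fit.rate:
        flags.append("short duration")
    return ExponentialFit(
        rate=fit.rate, amplitude=fit.amplitude, offset=fit.offset,
        rate_se=fit.rate_se, rmse=fit.rmse, converged=fit.converged,
        unit="h", flags=tuple(flags),
    )


def _growth_model(t, rate):
    return 1.0 - np.exp(-rate * t)


def fit_autoxidation(series, basis: BasisSet) -> ExponentialFit:
    """Autoxidation rate (min^-1) from an oxy->met spectrum series.

    Each spectrum is decomposed into state fractions; the met fraction is
    fitted to 1 - exp(-k t).  A series whose met fraction does not increase
    overall is flagged.
    """
    if series.time_unit != "min":
        raise UnitError("autoxidation series must declare time in minutes")
    t = np.asarray(series.times, dtype=float)
    f_met = np.array([
        decompose(series.spectra[:, i], basis).fractions.f_met
        for i in range(t.size)
    ])
    flags: list[str] = []
    if f_met[-1] <= f_met[0]:
        flags.append("met fraction non-increasing")
    k0 = 1.0 / max(t[-1] / 3.0, 1e-12)
    half = np.argmin(np.abs(f_met - 0.5))
    if 0 < t[half] and 0.2 < f_met[half] < 0.8:
        k0 = np.log(2.0) / t[half]
    popt, pcov = curve_fit(_growth_model, t, f_met, p0=[k0], maxfev=10000)
    rate = float(popt[0])
    resid = f_met - _growth_model(t, rate)
    rmse = float(np.sqrt(np.mean(resid**2)))
    rate_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    return ExponentialFit(
        rate=rate, amplitude=1.0, offset=0.0, rate_se=rate_se, rmse=rmse,
        converged=rate >= 0, unit="min", flags=tuple(flags),
    )


def trace_to_csv(trace: KineticTrace) -> str:
    """CSV dialect: time_s (or time_min/time_h) and absorbance columns."""
    header = f"time_{trace.time_unit},absorbance"
    rows = [f"{t:.9g},{a:.9g}" for t, a in zip(trace.time, trace.signal)]
    return "\n".join([header, *rows]) + "\n"


def trace_from_csv(text: str, **metadata) -> KineticTrace:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    unit = lines[0].split(",")[0].split("_", 1)[1]
    data = np.array([[float(x) for x in ln.split(",")[:2]] for ln in lines[1:]])
    return KineticTrace(time=data[:, 0], signal=data[:, 1], time_unit=unit, **metadata)
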