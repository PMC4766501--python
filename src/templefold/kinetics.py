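"""Stopped-flow binding kinetics: exponential trace fits and
pseudo-first-order regression k_obs = k_on*[L] + k_off.

Association traces under pseudo-first-order conditions (ligand in large
excess over the probe) decay single-exponentially with observed rate
k_obs = k_on*[L] + k_off; k_on is the slope and k_off the intercept of a
linear regression of k_obs on ligand concentration.  k_off is always taken
from that intercept (linear extrapolation), never from displacement
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class InsufficientDataError(ValueError):
    """Not enough points/concentrations for the requested fit."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient (e.g. all concentrations equal)."""


class PseudoFirstOrderWarning(UserWarning):
    """Ligand excess below the 10x pseudo-first-order comfort zone."""


class UnderSampledWarning(UserWarning):
    """Fewer than 5 points beyond 3/k_obs: tail poorly constrained."""


class NegativeInterceptWarning(UserWarning):
    """Regression intercept (k_off) came out negative."""


@dataclass
class BindingTrace:
    """One stopped-flow fluorescence trace at fixed ligand concentration.

    time in seconds (strictly increasing, >= 10 points), signal in arbitrary
    fluorescence units, concentrations in uM.
    """

    time: np.ndarray
    signal: np.ndarray
    ligand_conc: float
    probe_conc: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 10:
            raise ValueError("trace needs >= 10 time points")
        if len(self.time) != len(self.signal):
            raise ValueError("time/signal length mismatch")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.ligand_conc <= 0 or self.probe_conc <= 0:
            raise ValueError("concentrations must be positive")
        excess = self.ligand_conc / self.probe_conc
        if excess < 2.0:
            raise ValueError(
                f"ligand excess {excess:.2f}x < 2x: pseudo-first-order analysis refused"
            )
        if excess < 10.0:
            warnings.warn(
                f"ligand excess {excess:.2f}x below 10x; pseudo-first-order "
                "approximation may be degraded",
                PseudoFirstOrderWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ObservedRate:
    """Observed rate at one ligand concentration (uM, s^-1)."""

    ligand_conc: float
    k_obs: float
    k_obs_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_obs <= 0:
            raise ValueError("k_obs must be positive")


@dataclass
class RateConstants:
    """Association/dissociation rate constants for one variant pair."""

    k_on: float  # uM^-1 s^-1
    k_off: float  # s^-1
    k_on_sd: float = float("nan")
    k_off_sd: float = float("nan")
    temperature: float = 283.15  # K
    variant_receptor: str = "WT"
    variant_ligand: str = "WT"
    negative_intercept: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        # A zero (or numerically tiny negative) slope is tolerated so the
        # degenerate zero-slope fit can be reported; anything needing K_D or
        # ddG values requires k_on > 0 and raises there.
        if self.k_on < -1e-9:
            raise ValueError("k_on must be non-negative")
        if self.k_off < 0:
            self.negative_intercept = True
            warnings.warn(
                f"negative intercept k_off = {self.k_off:.4g} s^-1 reported as-is",
                NegativeInterceptWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a single-exponential fit; check ``success`` before use."""

    k_obs: float
    amplitude: float
    offset: float
    k_obs_sd: float
    success: bool
    residual_norm: float
    message: str = ""


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting point: offset/amplitude from the endpoints,
    rate from the log-linearised early decay."""
    offset = float(y[-1])
    amplitude = float(y[0] - y[-1])
    z = (y - offset) / amplitude if amplitude != 0 else np.zeros_like(y)
    early = (z > 0.05) & (t > t[0])
    if early.sum() >= 2:
        k0 = max(1e-9, -np.polyfit(t[early], np.log(z[early]), 1)[0])
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)
    return float(k0), amplitude, offset


def fit_single_exponential(trace: BindingTrace) -> ExponentialFit:
    """Least-squares fit of signal(t) = offset + amplitude*exp(-k_obs*t).

    Non-convergence or degenerate input yields a fit-failure result carrying
    the residual norm rather than an exception.  Emits
    :class:`UnderSampledWarning` when fewer than 5 points lie past 3/k_obs.
    """
    t, y = trace.time, trace.signal
    if np.ptp(y) == 0:
        return ExponentialFit(
            np.nan, 0.0, float(y[0]), np.nan, False,
            0.0, "constant signal: no decay to fit",
        )
    k0, a0, c0 = _initial_guess(t, y)

    def model(tt, k, a, c):
        return c + a * np.exp(-k * tt)

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=(k0, a0, c0),
            bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        resid = float(np.linalg.norm(y - model(t, k0, a0, c0)))
        return ExponentialFit(np.nan, np.nan, np.nan, np.nan, False, resid, str(exc))

    k, a, c = popt
    resid = float(np.linalg.norm(y - model(t, *popt)))
    k_sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    if np.sum(t > 3.0 / k) < 5:
        warnings.warn(
            "fewer than 5 points past 3/k_obs: decay under-sampled",
            UnderSampledWarning,
            stacklevel=2,
        )
    return ExponentialFit(float(k), float(a), float(c), k_sd, True, resid)


def bootstrap_k_obs_sd(
    trace: BindingTrace, fit: ExponentialFit, n_boot: int = 200, seed: int = 0
) -> float:
    """Residual-resampling bootstrap standard error of k_obs (cross-check of
    the Jacobian covariance estimate)."""
    if not fit.success:
        raise ValueError("cannot bootstrap a failed fit")
    rng = np.random.default_rng(seed)
    t = trace.time
    yhat = fit.offset + fit.amplitude * np.exp(-fit.k_obs * t)
    resid = trace.signal - yhat
    ks = []
    for _ in range(n_boot):
        y_star = yhat + rng.choice(resid, size=len(resid), replace=True)
        f = fit_single_exponential(
            BindingTrace(t, y_star, trace.ligand_conc, trace.probe_conc)
        )
        if f.success:
            ks.append(f.k_obs)
    return float(np.std(ks, ddof=1))


def fit_pseudo_first_order(
    series, weighted: bool = True, absolute_sigma: bool = True, **variant_labels
) -> RateConstants:
    """Linear regression of k_obs on ligand concentration.

    slope = k_on, intercept = k_off.  Weighted by 1/sd^2 when all standard
    deviations are present and ``weighted`` is True, else ordinary least
    squares.  When the sds are genuine measurement uncertainties the
    parameter covariance is taken directly from the weighted normal
    equations (``absolute_sigma``); otherwise it is rescaled by the reduced
    chi-square.  A negative intercept is reported but flagged.
    """
    series = list(series)
    concs = np.array([o.ligand_conc for o in series], dtype=float)
    if len(set(concs)) < 3:
        if len(np.unique(concs)) == 1 and len(concs) >= 3:
            raise RankDeficiencyError("all ligand concentrations equal")
        raise InsufficientDataError(">= 3 distinct ligand concentrations required")
    kobs = np.array([o.k_obs for o in series], dtype=float)
    sds = np.array([o.k_obs_sd for o in series], dtype=float)

    have_sds = bool(np.all(np.isfinite(sds)) and np.all(sds > 0))
    w = 1.0 / sds**2 if (weighted and have_sds) else np.ones_like(kobs)

    # weighted normal equations with parameter covariance
    X = np.column_stack((concs, np.ones_like(concs)))
    WX = X * w[:, None]
    XtWX = X.T @ WX
    beta = np.linalg.solve(XtWX, WX.T @ kobs)
    resid = kobs - X @ beta
    dof = len(kobs) - 2
    if weighted and have_sds and absolute_sigma:
        s2 = 1.0
    elif dof > 0:
        s2 = float(resid @ (w * resid)) / dof
    else:
        s2 = 0.0
    cov = s2 * np.linalg.inv(XtWX)
    slope, intercept = beta
    return RateConstants(
        k_on=float(slope),
        k_off=float(intercept),
        k_on_sd=float(np.sqrt(cov[0, 0])),
        k_off_sd=float(np.sqrt(cov[1, 1])),
        **variant_labels,
    )


def dissociation_constant(rc: RateConstants) -> tuple[float, float]:
    """K_D = k_off/k_on (uM) with first-order error propagation."""
    if rc.k_on <= 0:
        raise ValueError("k_on must be positive")
    kd = rc.k_off / rc.k_on
    rel2 = 0.0
    if np.isfinite(rc.k_on_sd):
        rel2 += (rc.k_on_sd / rc.k_on) ** 2
    if np.isfinite(rc.k_off_sd) and rc.k_off != 0:
        rel2 += (rc.k_off_sd / rc.k_off) ** 2
    return float(kd), float(abs(kd) * np.sqrt(rel2))


def fit_trace_series(traces_by_conc: dict[float, list[BindingTrace]], **variant_labels) -> RateConstants:
    """Fit every trace, pool replicates per concentration, regress.

    Replicate spread (ddof=1 standard deviation) is used as the k_obs sd when
    >= 2 replicates exist; otherwise the single fit's standard error.
    """
    observed = []
    for conc in sorted(traces_by_conc):
        ks, ses = [], []
        for tr in traces_by_conc[conc]:
            f = fit_single_exponential(tr)
            if f.success:
                ks.append(f.k_obs)
                ses.append(f.k_obs_sd)
        if not ks:
            continue
        sd = float(np.std(ks, ddof=1)) if len(ks) > 1 else float(ses[0])
        observed.append(ObservedRate(conc, float(np.mean(ks)), sd))
    return fit_pseudo_first_order(observed, **variant_labels)
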