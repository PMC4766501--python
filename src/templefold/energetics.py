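"""Mutational free energies, Phi values and LFER (Bronsted alpha) fits.

Conventions: kcal/mol throughout, natural logarithms, destabilising
mutations positive on both axes, so the LFER slope alpha runs from 0
(reactant-like transition state) to 1 (product-like).

ddG_eq  = R*T*ln(K_D_mut / K_D_wt)          (equilibrium destabilisation)
ddG_ts  = R*T*ln(k_on_wt / k_on_mut)        (transition-state destabilisation,
                                             association side)
Phi     = ddG_ts / ddG_eq, reported only when |ddG_eq| >= 0.4 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kinetics import RateConstants, dissociation_constant

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: Variants with |ddG_eq| below this (kcal/mol) get no Phi value.
PHI_EXCLUSION_THRESHOLD = 0.4


class TemperatureMismatchError(ValueError):
    pass


@dataclass
class EnergeticRecord:
    """ddG_eq, ddG_ts and (optionally) Phi for one ligand variant."""

    ligand_variant: str
    ddg_eq: float
    ddg_ts: float
    ddg_eq_sd: float = float("nan")
    ddg_ts_sd: float = float("nan")
    phi: Optional[float] = None
    phi_sd: Optional[float] = None
    included_in_phi: bool = False


@dataclass(frozen=True)
class LFERResult:
    """Bronsted alpha = OLS slope of ddG_ts on ddG_eq, bootstrap errors."""

    alpha: float
    intercept: float
    alpha_sd: float
    intercept_sd: float
    n_points: int
    bootstrap_samples: int
    seed: int


def _check_comparable(wt: RateConstants, mut: RateConstants) -> float:
    if wt.variant_receptor != mut.variant_receptor:
        raise ValueError(
            f"receptor variants differ: {wt.variant_receptor!r} vs {mut.variant_receptor!r}"
        )
    if abs(wt.temperature - mut.temperature) > 1e-9:
        raise TemperatureMismatchError(
            f"temperatures differ: {wt.temperature} K vs {mut.temperature} K"
        )
    return wt.temperature


def ddG_eq(wt: RateConstants, mut: RateConstants) -> tuple[float, float]:
    """Equilibrium ddG (kcal/mol) from the K_D ratio, with propagated sd."""
    T = _check_comparable(wt, mut)
    kd_wt, kd_wt_sd = dissociation_constant(wt)
    kd_mut, kd_mut_sd = dissociation_constant(mut)
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("nonpositive K_D: ddG_eq undefined")
    val = R_KCAL * T * np.log(kd_mut / kd_wt)
    sd = R_KCAL * T * np.sqrt(
        (kd_wt_sd / kd_wt) ** 2 + (kd_mut_sd / kd_mut) ** 2
    )
    return float(val), float(sd)


def ddG_ts(wt: RateConstants, mut: RateConstants) -> tuple[float, float]:
    """Transition-state ddG (kcal/mol) from association rates, with sd."""
    T = _check_comparable(wt, mut)
    val = R_KCAL * T * np.log(wt.k_on / mut.k_on)
    rel2 = 0.0
    if np.isfinite(wt.k_on_sd):
        rel2 += (wt.k_on_sd / wt.k_on) ** 2
    if np.isfinite(mut.k_on_sd):
        rel2 += (mut.k_on_sd / mut.k_on) ** 2
    return float(val), float(R_KCAL * T * np.sqrt(rel2))


def phi_value(
    rec: EnergeticRecord, threshold: float = PHI_EXCLUSION_THRESHOLD
) -> EnergeticRecord:
    """Fill in Phi = ddG_ts/ddG_eq, or exclude when |ddG_eq| < threshold.

    Exclusion is the graceful path: the record comes back with ``phi=None``
    and ``included_in_phi=False`` (small denominators make the ratio
    meaningless, so such variants are excluded by rule).
    """
    if abs(rec.ddg_eq) < threshold:
        rec.phi = None
        rec.phi_sd = None
        rec.included_in_phi = False
        return rec
    phi = rec.ddg_ts / rec.ddg_eq
    rel2 = 0.0
    if np.isfinite(rec.ddg_ts_sd) and rec.ddg_ts != 0:
        rel2 += (rec.ddg_ts_sd / rec.ddg_ts) ** 2
    if np.isfinite(rec.ddg_eq_sd):
        rel2 += (rec.ddg_eq_sd / rec.ddg_eq) ** 2
    rec.phi = float(phi)
    rec.phi_sd = float(abs(phi) * np.sqrt(rel2)) if rel2 else None
    rec.included_in_phi = True
    return rec


def energetic_record(
    wt: RateConstants,
    mut: RateConstants,
    threshold: float = PHI_EXCLUSION_THRESHOLD,
) -> EnergeticRecord:
    """ddG_eq + ddG_ts + Phi for one mutant against its wild type."""
    eq, eq_sd = ddG_eq(wt, mut)
    ts, ts_sd = ddG_ts(wt, mut)
    rec = EnergeticRecord(mut.variant_ligand, eq, ts, eq_sd, ts_sd)
    return phi_value(rec, threshold)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise np.linalg.LinAlgError("rank-deficient LFER: all ddG_eq equal")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    return slope, float(ym - slope * xm)


def _bootstrap_lines(
    x: np.ndarray, y: np.ndarray, bootstrap: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Case-resampling bootstrap slopes/intercepts (vectorised; replicates
    with fewer than 3 distinct abscissae are redrawn)."""
    rng = np.random.default_rng(seed)
    n = len(x)
    slopes = np.empty(bootstrap)
    intercepts = np.empty(bootstrap)
    filled = 0
    while filled < bootstrap:
        todo = bootstrap - filled
        idx = rng.integers(0, n, size=(todo, n))
        xs = x[idx]
        ys = y[idx]
        distinct = (np.sort(xs, axis=1)[:, 1:] != np.sort(xs, axis=1)[:, :-1]).sum(axis=1) + 1
        ok = distinct >= 3
        xs, ys = xs[ok], ys[ok]
        xm = xs.mean(axis=1, keepdims=True)
        ym = ys.mean(axis=1, keepdims=True)
        sxx = ((xs - xm) ** 2).sum(axis=1)
        sxy = ((xs - xm) * (ys - ym)).sum(axis=1)
        s = sxy / sxx
        k = len(s)
        slopes[filled:filled + k] = s
        intercepts[filled:filled + k] = ym[:, 0] - s * xm[:, 0]
        filled += k
    return slopes, intercepts


def lfer_fit(
    records: Sequence[EnergeticRecord],
    bootstrap: int = 1000,
    seed: int = 0,
    exclude_below_threshold: bool = False,
) -> LFERResult:
    """Ordinary least squares of ddG_ts on ddG_eq; alpha = slope.

    Errors are the standard deviations of slope/intercept over ``bootstrap``
    case-resampling replicates (replicates with < 3 distinct abscissae are
    redrawn).  By default all records enter the fit — the 0.4 kcal/mol Phi
    exclusion removes Phi values, not LFER points; pass
    ``exclude_below_threshold=True`` for the stricter variant.
    """
    recs = [r for r in records if np.isfinite(r.ddg_eq) and np.isfinite(r.ddg_ts)]
    if exclude_below_threshold:
        recs = [r for r in recs if abs(r.ddg_eq) >= PHI_EXCLUSION_THRESHOLD]
    if len(recs) < 3:
        raise ValueError("LFER fit needs >= 3 records with both ddG values")
    x = np.array([r.ddg_eq for r in recs])
    y = np.array([r.ddg_ts for r in recs])
    slope, intercept = _ols(x, y)

    if bootstrap < 200:
        raise ValueError("report sds from >= 200 bootstrap replicates")
    n = len(x)
    slopes, intercepts = _bootstrap_lines(x, y, bootstrap, seed)
    return LFERResult(
        alpha=slope,
        intercept=intercept,
        alpha_sd=float(slopes.std(ddof=1)),
        intercept_sd=float(intercepts.std(ddof=1)),
        n_points=n,
        bootstrap_samples=bootstrap,
        seed=seed,
    )


def lfer_confidence_interval(
    records: Sequence[EnergeticRecord],
    bootstrap: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for alpha (same resampling as lfer_fit)."""
    recs = [r for r in records if np.isfinite(r.ddg_eq) and np.isfinite(r.ddg_ts)]
    x = np.array([r.ddg_eq for r in recs])
    y = np.array([r.ddg_ts for r in recs])
    slopes, _ = _bootstrap_lines(x, y, bootstrap, seed)
    lo, hi = np.quantile(slopes, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
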