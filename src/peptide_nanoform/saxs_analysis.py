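"""Interpretation chain for dilute-fibre SAXS curves.

Three classical readings of a 1-D scattering curve, in increasing order of
model commitment:

* low-q power-law exponents (q⁻¹ rods, q⁻²/q⁻⁵/³ flat or swollen ribbons)
  by log–log linear regression;
* cross-section Guinier analysis: for long rod-like particles
  ln(qI) vs q² is linear with slope −R_σ²/2, giving the cross-section
  radius of gyration R_σ (valid roughly while q·R_σ ≲ 1.3);
* full nonlinear least-squares fitting of the elliptical-cylinder form
  factor (Levenberg–Marquardt via lmfit), with any subset of parameters
  held fixed.

Because q·L ≫ 1 across the experimental window for fibres hundreds of nm
long, the length is weakly identified; fits typically fix length (and
scale) and determine the cross-section parameters plus background.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .saxs_models import (
    EllipticalCylinderParams,
    ScatteringCurve,
    elliptical_cylinder_intensity,
)

__all__ = [
    "DEFAULT_LOW_Q_WINDOW",
    "PowerLawFit",
    "GuinierCrossSectionFit",
    "FitResult",
    "power_law_fit",
    "guinier_cross_section",
    "fit_elliptical_cylinder",
    "regime_report",
]


#: Default window (nm⁻¹) for reading the low-q power-law exponent: the
#: bottom of the experimental q range, below the cross-section features
#: (q ≲ 2π/ribbon width for the fibre geometries considered here).
DEFAULT_LOW_Q_WINDOW = (0.086, 0.12)


@dataclass(frozen=True)
class PowerLawFit:
    """I ≈ c·q^exponent over a q window, fitted in log–log space."""

    exponent: float
    log_prefactor: float
    q_window: tuple[float, float]
    r_squared: float
    n_points: int


def power_law_fit(
    curve: ScatteringCurve,
    q_window: tuple[float, float],
    background: float = 0.0,
) -> PowerLawFit:
    """Ordinary least squares of log(I − background) on log q.

    Requires at least 5 points and strictly positive background-subtracted
    intensities inside the window.
    """
    qmin, qmax = q_window
    m = (curve.q >= qmin) & (curve.q <= qmax)
    if m.sum() < 5:
        raise ValueError(f"window [{qmin}, {qmax}] contains fewer than 5 points")
    q = curve.q[m]
    i = curve.i[m] - background
    if np.any(i <= 0):
        raise ValueError("non-positive intensities in window after background subtraction")
    x, y = np.log(q), np.log(i)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return PowerLawFit(
        exponent=float(slope),
        log_prefactor=float(intercept),
        q_window=(float(qmin), float(qmax)),
        r_squared=r2,
        n_points=int(m.sum()),
    )


@dataclass(frozen=True)
class GuinierCrossSectionFit:
    """Cross-section Guinier fit: ln(qI) vs q² linear regression.

    ``r_sigma`` is None when the fitted slope is non-negative (no Guinier
    decay in the window — the fit is flagged invalid rather than reporting
    a spurious radius).  ``valid`` additionally requires q·R_σ ≤ 1.3 at the
    top of the window.
    """

    slope: float
    intercept: float
    q_window: tuple[float, float]
    r_sigma: float | None
    valid: bool
    max_q_rsigma: float | None


def guinier_cross_section(
    curve: ScatteringCurve, q_window: tuple[float, float], qr_limit: float = 1.3
) -> GuinierCrossSectionFit:
    """Fit ln(q·I) against q²; R_σ = sqrt(−2·slope)."""
    qmin, qmax = q_window
    m = (curve.q >= qmin) & (curve.q <= qmax)
    if m.sum() < 3:
        raise ValueError(f"window [{qmin}, {qmax}] contains fewer than 3 points")
    q = curve.q[m]
    i = curve.i[m]
    if np.any(i <= 0):
        raise ValueError("non-positive intensities in Guinier window")
    slope, intercept = np.polyfit(q**2, np.log(q * i), 1)
    if slope >= 0:
        return GuinierCrossSectionFit(
            slope=float(slope),
            intercept=float(intercept),
            q_window=(float(qmin), float(qmax)),
            r_sigma=None,
            valid=False,
            max_q_rsigma=None,
        )
    r_sigma = float(np.sqrt(-2.0 * slope))
    max_qr = float(q[-1] * r_sigma)
    return GuinierCrossSectionFit(
        slope=float(slope),
        intercept=float(intercept),
        q_window=(float(qmin), float(qmax)),
        r_sigma=r_sigma,
        valid=max_qr <= qr_limit,
        max_q_rsigma=max_qr,
    )


@dataclass(frozen=True)
class FitResult:
    """Outcome of an elliptical-cylinder least-squares fit."""

    params: EllipticalCylinderParams
    uncertainties: dict
    reduced_chi2: float
    status: str  # converged | max-iter | failed
    fixed: tuple[str, ...]
    warnings: tuple[str, ...] = ()


_PARAM_NAMES = ("r_minor", "axis_ratio", "length", "scale", "background")


def fit_elliptical_cylinder(
    curve: ScatteringCurve,
    init: EllipticalCylinderParams,
    bounds: dict | None = None,
    fixed: tuple[str, ...] = (),
    q_range: tuple[float, float] = (0.1, 7.0),
    n_points: int | None = None,
) -> FitResult:
    """Levenberg–Marquardt fit of the elliptical-cylinder model.

    Minimizes Σ((I_obs − I_model)/σ)² over the curve restricted to
    ``q_range`` (σ = 1 where absent).  ``fixed`` names parameters held at
    their ``init`` values; ``bounds`` maps names to (lo, hi) pairs.
    Deterministic given identical inputs and init.
    """
    unknown = set(fixed) - set(_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter(s) in fixed mask: {sorted(unknown)}")
    data = curve.restrict(*q_range)
    if data.q.size < 8:
        raise ValueError("too few points in fitting q-range")
    weights = 1.0 / data.sigma if data.sigma is not None else None

    default_bounds = {
        "r_minor": (1e-3, np.inf),
        "axis_ratio": (1.0, np.inf),
        "length": (1e-3, np.inf),
        "scale": (0.0, np.inf),
        "background": (0.0, np.inf),
    }
    if bounds:
        default_bounds.update(bounds)

    pars = lmfit.Parameters()
    init_d = init.as_dict()
    for name in _PARAM_NAMES:
        lo, hi = default_bounds[name]
        pars.add(name, value=init_d[name], min=lo, max=hi, vary=name not in fixed)

    kwargs = {} if n_points is None else {"n_points": n_points}

    def residual(p):
        model = elliptical_cylinder_intensity(
            data.q,
            EllipticalCylinderParams(
                r_minor=p["r_minor"].value,
                axis_ratio=p["axis_ratio"].value,
                length=p["length"].value,
                scale=p["scale"].value,
                background=p["background"].value,
            ),
            **kwargs,
        )
        r = data.i - model.i
        return r * weights if weights is not None else r

    warnings_: list[str] = []
    try:
        out = lmfit.minimize(residual, pars, method="leastsq")
    except Exception as exc:  # noqa: BLE001 - fit failure is a reported status
        return FitResult(
            params=init,
            uncertainties={},
            reduced_chi2=float("nan"),
            status="failed",
            fixed=tuple(fixed),
            warnings=(str(exc),),
        )

    if out.success:
        status = "converged"
    elif "max" in (out.message or "").lower():
        status = "max-iter"
    else:
        status = "failed"
    if not out.errorbars and any(n not in fixed for n in _PARAM_NAMES):
        warnings_.append("covariance unavailable (degenerate Jacobian?)")

    best = EllipticalCylinderParams(
        **{n: float(out.params[n].value) for n in _PARAM_NAMES}
    )
    unc = {
        n: (float(out.params[n].stderr) if out.params[n].stderr is not None else None)
        for n in _PARAM_NAMES
        if n not in fixed
    }
    return FitResult(
        params=best,
        uncertainties=unc,
        reduced_chi2=float(out.redchi),
        status=status,
        fixed=tuple(fixed),
        warnings=tuple(warnings_),
    )


def regime_report(
    curve: ScatteringCurve,
    window_points: int = 15,
    slope_change_threshold: float = 0.25,
) -> list[tuple[tuple[float, float], float]]:
    """Descriptive list of (q-window, exponent) power-law regimes.

    Sliding-window log–log slopes are segmented wherever the local slope
    moves by more than ``slope_change_threshold`` from the running segment
    mean; each segment is then refitted as a single power law.
    """
    if curve.q.size < 30:
        raise ValueError("need at least 30 points for regime segmentation")
    x, y = np.log(curve.q), np.log(np.maximum(curve.i, 1e-300))
    half = window_points // 2
    centers = np.arange(half, curve.q.size - half)
    slopes = np.array(
        [
            np.polyfit(x[c - half : c + half + 1], y[c - half : c + half + 1], 1)[0]
            for c in centers
        ]
    )
    # greedy change-point segmentation on the local-slope sequence
    segments: list[list[int]] = [[0]]
    seg_mean = slopes[0]
    for k in range(1, slopes.size):
        if abs(slopes[k] - seg_mean) > slope_change_threshold:
            segments.append([k])
            seg_mean = slopes[k]
        else:
            segments[-1].append(k)
            seg_mean = np.mean(slopes[segments[-1]])
    report = []
    for seg in segments:
        if len(seg) < 3:
            continue
        i0 = int(centers[seg[0]] - half)
        i1 = int(centers[seg[-1]] + half)
        window = (float(curve.q[i0]), float(curve.q[i1]))
        fit = np.polyfit(x[i0 : i1 + 1], y[i0 : i1 + 1], 1)
        report.append((window, float(fit[0])))
    return report
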