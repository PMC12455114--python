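"""Simplified McGhee-von Hippel binding analysis for YOYO-1 titrations.

The model relates total ligand ``L_T`` to free ligand ``L_f`` for a lattice
of binding sites (DNA, measured in basepairs ``S_T``) with apparent binding
constant ``K_a`` and binding-site size ``n_site`` (bp occluded per bound
dye)::

    L_T = L_f + K_a * L_f / (1 + K_a * L_f) * (S_T / n_site)

Because free YOYO-1 is essentially non-fluorescent, the fluorescence signal
of a titration point is proportional to the bound concentration
``L_T - L_f``.  Clearing the denominator turns the isotherm into a quadratic
in ``L_f`` with exactly one non-negative root, which is what
:func:`solve_free_ligand` returns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "HillScatchardResult",
    "solve_free_ligand",
    "predict_signal",
    "fit_mvh",
    "hill_scatchard",
]


@dataclass
class TitrationSeries:
    """A fluorescence titration at fixed DNA concentration.

    Parameters
    ----------
    s_total : float
        DNA concentration in molar basepairs (constant over the series).
    l_total : ndarray
        Total dye concentration grid, M, strictly increasing.
    signal : ndarray
        Fluorescence signal, arbitrary units, same length as ``l_total``.
    condition : dict
        Free-form condition metadata (e.g. ``{"mg_mM": 1.0, "atp_mM": 0.0}``).
    """

    s_total: float
    l_total: np.ndarray
    signal: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.l_total = np.asarray(self.l_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.s_total <= 0:
            raise ValueError("s_total must be positive")
        if self.l_total.ndim != 1 or self.l_total.size != self.signal.size:
            raise ValueError("l_total and signal must be 1-D and equal length")
        if np.any(np.diff(self.l_total) <= 0):
            raise ValueError("l_total must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")


@dataclass
class BindingFit:
    """Fitted isotherm parameters with uncertainties."""

    ka: float                     # apparent binding constant, 1/M
    n_site: float                 # bp per bound dye
    scale: float                  # signal per M bound dye
    offset: float = 0.0           # signal baseline
    ka_err: float = np.nan
    n_site_err: float = np.nan
    scale_err: float = np.nan
    offset_err: float = np.nan
    residual_sd: float = np.nan
    r_squared: float = np.nan
    converged: bool = True
    flags: list = field(default_factory=list)


@dataclass
class HillScatchardResult:
    """Linearizing companion analyses of a fitted titration.

    Hill: log(theta/(1-theta)) regressed on log(L_f); slope ~ 1 for the
    non-cooperative single-site form.  Scatchard: r/L_f regressed on r
    (r = bound dye per bp); x-intercept estimates 1/n_site.
    """

    hill_slope: float
    hill_intercept: float
    hill_x: np.ndarray
    hill_y: np.ndarray
    scatchard_slope: float
    scatchard_intercept: float
    scatchard_x: np.ndarray
    scatchard_y: np.ndarray

    @property
    def scatchard_x_intercept(self) -> float:
        return -self.scatchard_intercept / self.scatchard_slope


def solve_free_ligand(l_total, s_total: float, ka: float, n_site: float):
    """Free ligand concentration solving the simplified MvH isotherm.

    Returns the unique non-negative root of

        K_a*L_f^2 + (1 + K_a*S_T/n - K_a*L_T)*L_f - L_T = 0

    using the numerically stable quadratic form (the ``q``-formulation that
    avoids catastrophic cancellation when the linear coefficient dominates).
    Accepts scalars or arrays in ``l_total``.
    """
    l_total = np.asarray(l_total, dtype=float)
    scalar = l_total.ndim == 0
    lt = np.atleast_1d(l_total)
    if np.any(lt < 0) or s_total < 0 or ka < 0 or n_site <= 0:
        raise ValueError("concentrations and ka must be >= 0, n_site > 0")
    if ka == 0:
        lf = lt.copy()
        return float(lf[0]) if scalar else lf
    a = ka
    b = 1.0 + ka * s_total / n_site - ka * lt
    c = -lt
    disc = np.sqrt(b * b - 4.0 * a * c)
    # stable root pair: q = -(b + sign(b)*sqrt(disc))/2; roots q/a and c/q
    q = -0.5 * (b + np.sign(b) * disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = q / a
        r2 = np.where(q != 0, c / q, 0.0)
    lf = np.where(r1 >= 0, r1, r2)
    lf = np.clip(lf, 0.0, lt)  # physical: 0 <= L_f <= L_T
    return float(lf[0]) if scalar else lf


def predict_signal(params: BindingFit, l_total, s_total: float):
    """Predicted fluorescence on a total-dye grid: scale*(L_T - L_f) + offset."""
    lf = solve_free_ligand(l_total, s_total, params.ka, params.n_site)
    return params.scale * (np.asarray(l_total, float) - lf) + params.offset


def _model(theta, lt, s_total, fit_offset):
    log10_ka, n_site, scale = theta[:3]
    offset = theta[3] if fit_offset else 0.0
    lf = solve_free_ligand(lt, s_total, 10.0 ** log10_ka, n_site)
    return scale * (lt - lf) + offset


def fit_mvh(
    series: TitrationSeries,
    fit_offset: bool = False,
    normalize: bool = False,
    weights: Sequence[float] | None = None,
) -> BindingFit:
    """Fit (K_a, n_site, scale[, offset]) to a titration by weighted NLLS.

    K_a is searched in log10-space.  The optimizer is started from a 3x3
    grid of (K_a, n_site) initials spanning 1e6-1e10 1/M and 1-4 bp and the
    best of all converged starts is reported.  ``normalize`` rescales the
    signal to a unit plateau before fitting (for display parity only; the
    default fits raw signal with a free scale so the error weighting is not
    distorted).

    Weighting defaults to relative (1 / signal, floored at 5% of the
    maximum), matching the multiplicative noise of fluorescence plate
    readers; pass explicit ``weights`` to override.
    """
    lt = series.l_total
    y = series.signal.astype(float)
    if lt.size < 5:
        raise ValueError("need at least 5 titration points to fit")
    if normalize:
        y = y / y.max()
    s_total = series.s_total
    if weights is None:
        w = 1.0 / np.clip(y, 0.05 * max(y.max(), 1e-300), None)
    else:
        w = np.asarray(weights, dtype=float)

    span = y.max() - y.min()
    if span <= 0:
        raise ValueError("flat titration signal; nothing to fit")

    # crude scale initial: plateau over S_T/n at the n initial
    def residuals(theta):
        return w * (_model(theta, lt, s_total, fit_offset) - y)

    best = None
    n_params = 4 if fit_offset else 3
    lower = [5.0, 0.5, 0.0] + ([-np.inf] if fit_offset else [])
    upper = [11.0, 10.0, np.inf] + ([np.inf] if fit_offset else [])
    for log_ka0 in (6.5, 8.0, 9.5):
        for n0 in (1.5, 2.5, 3.5):
            scale0 = y.max() / (s_total / n0)
            theta0 = [log_ka0, n0, scale0] + ([0.0] if fit_offset else [])
            try:
                sol = least_squares(
                    residuals, theta0, bounds=(lower, upper), method="trf",
                    xtol=1e-12, ftol=1e-12,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise RuntimeError("MvH fit failed to converge from all starts")

    theta = best.x
    resid = best.fun / np.where(w == 0, 1, w)
    dof = max(y.size - n_params, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan

    # covariance from the Jacobian at the optimum
    errs = np.full(n_params, np.nan)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * residual_sd**2
        errs = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        pass

    ka = 10.0 ** theta[0]
    flags = []
    if abs(theta[1] - lower[1]) < 1e-6 or abs(theta[1] - upper[1]) < 1e-6:
        flags.append("n_site_at_bound")
    # identifiability: does the design reach the plateau?
    plateau = theta[2] * s_total / theta[1]
    if y.max() < 0.8 * plateau:
        flags.append("below_plateau_identifiability_warning")
        warnings.warn(
            "titration does not reach 80% of the fitted plateau; "
            "K_a is weakly identified", stacklevel=2,
        )

    return BindingFit(
        ka=ka,
        n_site=float(theta[1]),
        scale=float(theta[2]),
        offset=float(theta[3]) if fit_offset else 0.0,
        ka_err=float(errs[0] * ka * np.log(10)),  # delta method, log10 -> linear
        n_site_err=float(errs[1]),
        scale_err=float(errs[2]),
        offset_err=float(errs[3]) if fit_offset else 0.0,
        residual_sd=residual_sd,
        r_squared=r2,
        converged=bool(best.success),
        flags=flags,
    )


def hill_scatchard(
    series: TitrationSeries,
    fit: BindingFit,
    occupancy_range: tuple[float, float] = (0.05, 0.95),
) -> HillScatchardResult:
    """Hill and Scatchard companion plots from a fitted titration.

    Occupancy theta = (signal - offset) / (scale * S_T / n_site); L_f is
    computed from the fitted isotherm.  Points with occupancy outside
    ``occupancy_range`` are excluded (the transforms diverge at 0 and 1).
    """
    s_total = series.s_total
    bound = (series.signal - fit.offset) / fit.scale
    theta = bound / (s_total / fit.n_site)
    lf = solve_free_ligand(series.l_total, s_total, fit.ka, fit.n_site)
    lo, hi = occupancy_range
    keep = (theta > lo) & (theta < hi) & (lf > 0)
    if keep.sum() < 3:
        raise ValueError(
            "fewer than 3 titration points with occupancy strictly inside "
            f"({lo}, {hi}); Hill/Scatchard analysis undefined"
        )
    th, lff, bnd = theta[keep], lf[keep], bound[keep]

    hx = np.log10(lff)
    hy = np.log10(th / (1.0 - th))
    hill = linregress(hx, hy)

    r = bnd / s_total          # bound dye per bp
    sx = r
    sy = r / lff
    scat = linregress(sx, sy)

    return HillScatchardResult(
        hill_slope=float(hill.slope),
        hill_intercept=float(hill.intercept),
        hill_x=hx,
        hill_y=hy,
        scatchard_slope=float(scat.slope),
        scatchard_intercept=float(scat.intercept),
        scatchard_x=sx,
        scatchard_y=sy,
    )
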