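"""Photobleaching, photo-fragmentation, and gel densitometry analysis.

Covers the photokinetic observables of dye-labeled DNA under illumination:
exponential decay of the total emission (per-dye bleaching), detection of
double-strand-break events in kymographs (a molecule splitting into two
separating segments), power-law kinetics of the fragmented population with
the half-fragmentation time t50, and densitometric quantification of gel
lanes into intact-band and fragment-smear fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .kymo import Kymograph, _column_edges

__all__ = [
    "BleachTrace",
    "DecayFit",
    "FragSeries",
    "PowerLawFit",
    "GelLaneProfile",
    "bleach_trace_from_kymograph",
    "fit_bleach_decay",
    "detect_fragmentation_event",
    "fit_fragmentation_power_law",
    "quantify_lane",
]


@dataclass
class BleachTrace:
    """Total background-subtracted intensity of one molecule vs time."""

    time_s: np.ndarray
    intensity: np.ndarray
    molecule_id: int = 0


@dataclass
class DecayFit:
    """Parameters of A*exp(-alpha*t) + B."""

    amplitude: float
    alpha: float              # 1/s
    offset: float
    amplitude_err: float = np.nan
    alpha_err: float = np.nan
    offset_err: float = np.nan
    residual_sd: float = np.nan
    degenerate: bool = False  # flat trace: alpha pinned to 0, A folded into B


@dataclass
class FragSeries:
    """Intact/fragment fraction vs light exposure time."""

    exposure_s: np.ndarray
    intact_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_s = np.asarray(self.exposure_s, dtype=float)
        self.intact_fraction = np.asarray(self.intact_fraction, dtype=float)
        if np.any((self.intact_fraction < 0) | (self.intact_fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def fragment_fraction(self) -> np.ndarray:
        return 1.0 - self.intact_fraction

    def isotonic(self) -> "FragSeries":
        """Intact fraction forced monotone non-increasing (pool-adjacent)."""
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
        cleaned = iso.fit_transform(self.exposure_s, self.intact_fraction)
        return FragSeries(self.exposure_s.copy(), cleaned)


@dataclass
class PowerLawFit:
    """Fragment fraction y = r * t**n_exp; t50 = (0.5/r)**(1/n_exp).

    ``n_exp`` is the kinetic exponent; it is deliberately named apart
    from the binding-site size ``n_site`` of the isotherm module, since
    both are conventionally written as a bare "n".
    """

    r: float
    n_exp: float
    t50: float
    covariance: np.ndarray = field(default_factory=lambda: np.full((2, 2), np.nan))


@dataclass
class GelLaneProfile:
    """Densitometry profile along one gel lane.

    ``position`` increases with migration distance, so smaller (faster)
    fragments appear at larger positions than the intact band.
    """

    position: np.ndarray
    intensity: np.ndarray
    band_window: tuple | None = None   # (lo, hi) positions of the intact band
    lane_id: int = 0


def bleach_trace_from_kymograph(kymo: Kymograph, flank_px: int = 6,
                                molecule_id: int = 0) -> BleachTrace:
    """Total background-subtracted intensity per frame of a kymograph."""
    T = kymo.n_frames
    vals = np.empty(T)
    for t in range(T):
        profile = kymo.matrix[:, t]
        n = profile.size
        flank = np.concatenate([profile[:flank_px], profile[-flank_px:]]) \
            if flank_px > 0 and 2 * flank_px < n else profile
        vals[t] = float(np.sum(profile - np.median(flank)))
    time = np.arange(T) * kymo.frame_interval
    return BleachTrace(time_s=time, intensity=vals, molecule_id=molecule_id)


def fit_bleach_decay(traces: list[BleachTrace] | BleachTrace,
                     average_first: bool = True) -> DecayFit | list[DecayFit]:
    """Fit A*exp(-alpha*t) + B to bleach traces.

    Default fits the mean trace of the batch (all traces must share the
    time grid); ``average_first=False`` fits each trace separately and
    returns a list.  Initials: A = first - last, B = last, alpha from a
    log-linear regression of (trace - B).  A flat trace returns alpha = 0
    with A folded into B and the degeneracy flag set.
    """
    if isinstance(traces, BleachTrace):
        traces = [traces]
    if not average_first:
        return [fit_bleach_decay([tr], average_first=True) for tr in traces]
    t0 = traces[0].time_s
    for tr in traces[1:]:
        if tr.time_s.shape != t0.shape or not np.allclose(tr.time_s, t0):
            raise ValueError("traces must share one time grid for averaging")
    y = np.mean([tr.intensity for tr in traces], axis=0)
    t = t0
    if t.size < 5:
        raise ValueError("need >= 5 time points to fit a decay")

    span = y.max() - y.min()
    scale = max(abs(y).max(), 1e-30)
    if span < 1e-9 * scale:
        return DecayFit(amplitude=0.0, alpha=0.0, offset=float(np.mean(y)),
                        degenerate=True)

    a0 = y[0] - y[-1]
    b0 = y[-1]
    pos = y - b0
    mask = pos > 0.05 * max(pos.max(), 1e-30)
    if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
        sl = linregress(t[mask], np.log(pos[mask])).slope
        alpha0 = max(-sl, 1e-6)
    else:
        alpha0 = 1.0 / max(t[-1], 1e-9)

    def model(tt, a, alpha, b):
        return a * np.exp(-alpha * tt) + b

    try:
        popt, pcov = curve_fit(model, t, y, p0=[max(a0, 1e-12 * scale), alpha0, b0],
                               bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError:
        return DecayFit(amplitude=0.0, alpha=0.0, offset=float(np.mean(y)),
                        degenerate=True)
    resid = y - model(t, *popt)
    errs = np.sqrt(np.diag(pcov))
    return DecayFit(
        amplitude=float(popt[0]), alpha=float(popt[1]), offset=float(popt[2]),
        amplitude_err=float(errs[0]), alpha_err=float(errs[1]),
        offset_err=float(errs[2]),
        residual_sd=float(np.std(resid)),
    )


def detect_fragmentation_event(
    kymo: Kymograph,
    threshold_fraction: float = 0.5,
    flank_px: int = 6,
    min_gap_px: int = 2,
    persist_frames: int = 3,
) -> float | None:
    """Time (s) of the first persistent molecule split, or None.

    Per column, above-threshold segments separated by >= ``min_gap_px``
    pixels are counted; the fragmentation time is the start of the
    earliest run of >= ``persist_frames`` consecutive columns with >= 2
    segments.  Columns without signal count as not-split.
    """
    T = kymo.n_frames
    is_split = np.zeros(T, dtype=bool)
    for t in range(T):
        res = _column_edges(kymo.matrix[:, t], threshold_fraction,
                            flank_px, min_gap_px)
        if res is not None:
            is_split[t] = res[2] >= 2
    run = 0
    for t in range(T):
        run = run + 1 if is_split[t] else 0
        if run >= persist_frames:
            return float((t - persist_frames + 1) * kymo.frame_interval)
    return None


def fit_fragmentation_power_law(series: FragSeries,
                                isotonic_cleanup: bool = True) -> PowerLawFit:
    """Fit fragment fraction y = r * t**n_exp and extrapolate t50.

    A log-log ordinary least squares on the interior points initializes a
    nonlinear fit on the linear scale.  t50 = (0.5 / r)**(1 / n_exp) is
    the exposure at which half the DNA is fragmented.
    """
    if isotonic_cleanup:
        series = series.isotonic()
    t = series.exposure_s
    y = series.fragment_fraction
    interior = (y > 0) & (y < 1) & (t > 0)
    if interior.sum() < 3:
        if np.all(series.fragment_fraction == 0):
            raise ValueError("no fragmentation observed; t50 undefined")
        raise ValueError("need >= 3 points with fragment fraction in (0, 1)")
    ols = linregress(np.log(t[interior]), np.log(y[interior]))
    n0 = max(ols.slope, 1e-3)
    r0 = float(np.exp(ols.intercept))

    def model(tt, r, n):
        return r * tt**n

    fit_mask = t > 0
    popt, pcov = curve_fit(model, t[fit_mask], y[fit_mask], p0=[r0, n0],
                           bounds=([1e-30, 1e-3], [np.inf, np.inf]),
                           maxfev=20000)
    r, n_exp = float(popt[0]), float(popt[1])
    t50 = float((0.5 / r) ** (1.0 / n_exp))
    return PowerLawFit(r=r, n_exp=n_exp, t50=t50, covariance=pcov)


def quantify_lane(
    lane: GelLaneProfile,
    band_window: tuple | None = None,
    baseline_window_px: int | None = None,
) -> tuple[float, float]:
    """(intact, fragment) fractions of a gel lane by densitometry.

    Baseline: rolling minimum (smoothed) subtracted from the profile; the
    default window spans the whole lane, reducing to a constant-offset
    subtraction — pass a narrower window for sloped baselines (it must
    stay wide relative to the smear, which is itself a broad feature).
    Intact = integral over the band window; fragment = integral over all
    positions of higher mobility (beyond the band window).  Fractions are
    normalized to their sum, so they are invariant to exposure scale and
    baseline offset.
    """
    win = band_window or lane.band_window
    pos, inten = lane.position, lane.intensity.astype(float)
    if win is None:
        # dominant peak defines the band; window at +-4 local half-widths
        i_pk = int(np.argmax(inten))
        half = inten[i_pk] / 2
        lo = i_pk
        while lo > 0 and inten[lo] > half:
            lo -= 1
        hi = i_pk
        while hi < inten.size - 1 and inten[hi] > half:
            hi += 1
        hw = max(hi - i_pk, i_pk - lo, 1)
        win = (pos[max(i_pk - 4 * hw, 0)], pos[min(i_pk + 4 * hw, pos.size - 1)])
    size = baseline_window_px or inten.size
    baseline = minimum_filter1d(inten, size=size, mode="nearest")
    baseline = uniform_filter1d(baseline, size=size, mode="nearest")
    net = np.clip(inten - baseline, 0.0, None)
    in_band = (pos >= win[0]) & (pos <= win[1])
    beyond = pos > win[1]
    intact = float(np.trapezoid(net[in_band], pos[in_band]))
    fragment = float(np.trapezoid(net[beyond], pos[beyond]))
    total = intact + fragment
    if total <= 0:
        raise ValueError("zero total signal in lane")
    return intact / total, fragment / total
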