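"""Circular-dichroism analysis for G-quadruplex samples.

Covers Savitzky-Golay smoothing, rule-based topology classification from
the canonical G4 CD band signatures, mono-/bi-exponential fits to
in-situ folding kinetics, and Boltzmann sigmoid fits to thermal melting
curves.

CD band conventions for G4 topologies: a parallel fold shows a positive
band near 264 nm and a negative band near 240 nm; an antiparallel fold
shows positive bands near 295 and 240 nm with a negative band near
260 nm; a hybrid fold (or a parallel/antiparallel mixture) shows positive
bands at both ~264 and ~290 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from lmfit import Model
from scipy import stats
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "CDSpectrum",
    "CDKineticTrace",
    "MeltingCurve",
    "ExponentialFit",
    "MeltingFit",
    "TopologyCall",
    "mono_exponential",
    "bi_exponential",
    "boltzmann_sigmoid",
    "smooth_spectrum",
    "classify_topology",
    "fit_exponential",
    "fit_melting",
    "TOPOLOGY_WINDOWS",
]


@dataclass
class CDSpectrum:
    """CD spectrum: ellipticity (mdeg) on a strictly increasing nm grid."""

    wavelength: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.wavelength.shape != self.signal.shape:
            raise ValueError("wavelength and signal must have equal length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength must be strictly increasing")


@dataclass
class CDKineticTrace:
    """CD signal at one wavelength versus time during in-situ mixing."""

    time: np.ndarray
    signal: np.ndarray
    time_unit: str = "min"
    wavelength_nm: float = 295.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class MeltingCurve:
    """CD melting curve: ellipticity versus temperature (deg C)."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")


def mono_exponential(t, a, b):
    """Saturating mono-exponential f(t) = a*(1 - exp(-b*t))."""
    return a * (1.0 - np.exp(-b * np.asarray(t, dtype=float)))


def bi_exponential(t, a, b, c, d):
    """Two-phase saturating form f(t) = a*(1-exp(-b*t)) + c*(1-exp(-d*t))."""
    t = np.asarray(t, dtype=float)
    return a * (1.0 - np.exp(-b * t)) + c * (1.0 - np.exp(-d * t))


def boltzmann_sigmoid(t, theta_folded, theta_unfolded, tm, width):
    """Two-state melting sigmoid with midpoint tm and transition width (deg C)."""
    t = np.asarray(t, dtype=float)
    return theta_folded + (theta_unfolded - theta_folded) / (1.0 + np.exp((tm - t) / width))


def smooth_spectrum(
    spec: CDSpectrum, window_points: int = 11, poly_order: int = 3
) -> CDSpectrum:
    """Savitzky-Golay smoothing with polynomial end-point handling."""
    if window_points % 2 == 0 or window_points <= poly_order:
        raise ValueError("window must be odd and greater than poly_order")
    if window_points >= len(spec.signal):
        raise ValueError("window must be shorter than the spectrum")
    smoothed = savgol_filter(spec.signal, window_points, poly_order, mode="interp")
    return CDSpectrum(wavelength=spec.wavelength.copy(), signal=smoothed)


# wavelength windows (nm) bracketing the canonical G4 CD landmarks
TOPOLOGY_WINDOWS = {
    "parallel_max": (255.0, 270.0),
    "parallel_min": (235.0, 248.0),
    "antiparallel_max": (285.0, 300.0),
    "antiparallel_min": (255.0, 270.0),
}


@dataclass
class TopologyCall:
    """Rule-based topology classification with its spectral evidence."""

    label: Literal["parallel", "antiparallel", "hybrid_or_mixture", "undetermined"]
    extrema: list[tuple[float, float]] = field(default_factory=list)  # (nm, mdeg)
    ratio_295_265: float = float("nan")
    noise_floor: float = float("nan")


def _band_extremum(
    wl: np.ndarray, y: np.ndarray, window: tuple[float, float], sign: int, floor: float
) -> tuple[float, float] | None:
    """Strongest genuine local extremum of the requested sign in a window.

    Peaks are located on the full spectrum first so a band tail leaking
    into a neighboring window is never mistaken for a band of its own.
    """
    yy = sign * y
    peaks, _ = find_peaks(yy, height=floor)
    inside = peaks[(wl[peaks] >= window[0]) & (wl[peaks] <= window[1])]
    if inside.size == 0:
        return None
    best = inside[np.argmax(yy[inside])]
    return float(wl[best]), float(y[best])


def classify_topology(
    spec: CDSpectrum, smooth: bool = True, window_points: int = 11
) -> TopologyCall:
    """Classify a G4 CD spectrum as parallel / antiparallel / hybrid.

    Decision rules on the smoothed spectrum:

    - parallel: positive maximum in 255-270 nm and negative minimum in
      235-248 nm, with no positive band at/above 285 nm;
    - antiparallel: positive maximum in 285-300 nm with negative signal
      in 255-270 nm;
    - hybrid_or_mixture: positive bands in both 255-270 and 285-300 nm;
    - undetermined: no band rises above the noise floor (5x the robust SD
      of the smoothing residual).

    The call is scale-invariant: multiplying the spectrum by a positive
    constant rescales bands and noise floor together.
    """
    if spec.wavelength[0] > 230.0 or spec.wavelength[-1] < 310.0:
        raise ValueError("spectrum must cover at least 230-310 nm")
    if smooth:
        sm = smooth_spectrum(spec, window_points=window_points)
        resid = spec.signal - sm.signal
        mad = np.median(np.abs(resid - np.median(resid)))
        floor = max(5.0 * 1.4826 * mad, 1e-9)
    else:
        sm = spec
        floor = 1e-9
    wl, y = sm.wavelength, sm.signal

    pos_264 = _band_extremum(wl, y, TOPOLOGY_WINDOWS["parallel_max"], +1, floor)
    neg_240 = _band_extremum(wl, y, TOPOLOGY_WINDOWS["parallel_min"], -1, floor)
    pos_290 = _band_extremum(wl, y, TOPOLOGY_WINDOWS["antiparallel_max"], +1, floor)
    neg_260 = _band_extremum(wl, y, TOPOLOGY_WINDOWS["antiparallel_min"], -1, floor)

    evidence = [e for e in (pos_264, neg_240, pos_290, neg_260) if e is not None]
    s265 = float(np.interp(265.0, wl, y))
    s295 = float(np.interp(295.0, wl, y))
    ratio = s295 / s265 if abs(s265) > 1e-12 else float("nan")

    if pos_264 and pos_290:
        label = "hybrid_or_mixture"
    elif pos_290 and neg_260:
        label = "antiparallel"
    elif pos_264 and neg_240 and not pos_290:
        label = "parallel"
    else:
        label = "undetermined"
    return TopologyCall(label=label, extrema=evidence, ratio_295_265=ratio, noise_floor=floor)


@dataclass
class ExponentialFit:
    """Mono- or bi-exponential kinetic fit; for bi, b >= d (fast phase first)."""

    model: Literal["mono", "bi"]
    a: float
    b: float  # 1/time-unit of the trace
    c: float | None = None
    d: float | None = None
    a_se: float = float("nan")
    b_se: float = float("nan")
    c_se: float | None = None
    d_se: float | None = None
    residual_norm: float = float("nan")
    converged: bool = True
    time_unit: str = "min"

    def __post_init__(self) -> None:
        if self.b <= 0 or (self.d is not None and self.d <= 0):
            raise ValueError("rates must be > 0")
        if self.model == "bi" and (self.c is None or self.d is None):
            raise ValueError("bi model requires c and d")
        if self.model == "bi" and self.b < self.d:
            self.a, self.c = self.c, self.a
            self.b, self.d = self.d, self.b
            self.a_se, self.c_se = self.c_se, self.a_se
            self.b_se, self.d_se = self.d_se, self.b_se

    def rate_per_min(self) -> float:
        """Fast-phase rate converted to 1/min."""
        return self.b * 60.0 if self.time_unit == "s" else self.b


def _fit_mono(t: np.ndarray, y: np.ndarray):
    model = Model(mono_exponential)
    a0 = float(y[-1]) if abs(y[-1]) > 1e-12 else float(np.max(np.abs(y)) or 1.0)
    # crude rate guess from the time to reach ~63% of the plateau
    frac = y / a0 if a0 != 0 else y
    above = np.flatnonzero(frac >= 0.632)
    b0 = 1.0 / t[above[0]] if above.size and t[above[0]] > 0 else 1.0 / max(t[-1], 1e-9)
    params = model.make_params(a=a0, b=b0)
    params["b"].set(min=1e-12)
    return model.fit(y, params, t=t)


def _fit_bi(t: np.ndarray, y: np.ndarray, mono_result):
    model = Model(bi_exponential)
    a0 = mono_result.params["a"].value
    b0 = mono_result.params["b"].value
    params = model.make_params(a=0.7 * a0, b=3.0 * b0, c=0.3 * a0, d=0.3 * b0)
    for k in ("b", "d"):
        params[k].set(min=1e-12)
    return model.fit(y, params, t=t)


def fit_exponential(
    trace: CDKineticTrace,
    model: Literal["auto", "mono", "bi"] = "auto",
    alpha: float = 0.01,
    min_rate_ratio: float = 3.0,
) -> ExponentialFit:
    """Fit f(t) = a*(1-exp(-b*t)) [+ c*(1-exp(-d*t))] to a kinetic trace.

    ``model='auto'`` prefers the bi-exponential only when the nested-model
    F-test is significant at ``alpha`` and the two rates differ by at
    least ``min_rate_ratio`` (the two-phase form is unidentifiable as the
    rates coincide).
    """
    t, y = trace.time, trace.signal
    if len(t) < 10:
        raise ValueError("need at least 10 points")
    res_mono = _fit_mono(t, y)
    chosen = None
    if model in ("auto", "bi"):
        res_bi = _fit_bi(t, y, res_mono)
        if model == "bi":
            chosen = ("bi", res_bi)
        else:
            rss1 = float(np.sum(res_mono.residual**2))
            rss2 = float(np.sum(res_bi.residual**2))
            df2 = len(t) - 4
            b_, d_ = res_bi.params["b"].value, res_bi.params["d"].value
            ratio = max(b_, d_) / max(min(b_, d_), 1e-300)
            if rss2 > 0 and df2 > 0:
                f = ((rss1 - rss2) / 2.0) / (rss2 / df2)
                p = stats.f.sf(f, 2, df2)
            else:
                p = 0.0
            chosen = ("bi", res_bi) if (p < alpha and ratio >= min_rate_ratio) else ("mono", res_mono)
    if chosen is None:
        chosen = ("mono", res_mono)
    name, res = chosen
    rnorm = float(np.sqrt(np.sum(res.residual**2)))
    if name == "mono":
        return ExponentialFit(
            model="mono",
            a=res.params["a"].value,
            b=res.params["b"].value,
            a_se=res.params["a"].stderr or float("nan"),
            b_se=res.params["b"].stderr or float("nan"),
            residual_norm=rnorm,
            converged=bool(res.success),
            time_unit=trace.time_unit,
        )
    return ExponentialFit(
        model="bi",
        a=res.params["a"].value,
        b=res.params["b"].value,
        c=res.params["c"].value,
        d=res.params["d"].value,
        a_se=res.params["a"].stderr or float("nan"),
        b_se=res.params["b"].stderr or float("nan"),
        c_se=res.params["c"].stderr,
        d_se=res.params["d"].stderr,
        residual_norm=rnorm,
        converged=bool(res.success),
        time_unit=trace.time_unit,
    )


@dataclass
class MeltingFit:
    """Boltzmann melting fit: baselines, midpoint T_m and width."""

    theta_folded: float
    theta_unfolded: float
    tm: float  # deg C
    width: float  # deg C
    tm_se: float = float("nan")
    residual_norm: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")


def fit_melting(curve: MeltingCurve) -> MeltingFit:
    """Fit the Boltzmann sigmoid to a melting curve and report T_m.

    Initial T_m is the temperature at which the signal crosses the
    midpoint of its extreme values. A flat curve yields a non-converged
    fit flag rather than an exception.
    """
    t = np.asarray(curve.temperature, dtype=float)
    y = np.asarray(curve.signal, dtype=float)
    if len(t) < 20:
        raise ValueError("need at least 20 points spanning both baselines")
    order = np.argsort(t)
    t, y = t[order], y[order]

    y0, y1 = float(np.mean(y[:5])), float(np.mean(y[-5:]))
    mid = 0.5 * (y0 + y1)
    crossing = np.flatnonzero(np.diff(np.sign(y - mid)) != 0)
    tm0 = float(t[crossing[0]]) if crossing.size else float(np.median(t))

    model = Model(boltzmann_sigmoid)
    params = model.make_params(theta_folded=y0, theta_unfolded=y1, tm=tm0, width=4.0)
    params["width"].set(min=1e-3)
    params["tm"].set(min=t[0], max=t[-1])
    result = model.fit(y, params, t=t)
    rnorm = float(np.sqrt(np.sum(result.residual**2)))
    converged = bool(result.success)
    span = abs(result.params["theta_unfolded"].value - result.params["theta_folded"].value)
    if span < 3.0 * np.std(result.residual):
        converged = False  # no resolvable transition
    return MeltingFit(
        theta_folded=result.params["theta_folded"].value,
        theta_unfolded=result.params["theta_unfolded"].value,
        tm=result.params["tm"].value,
        width=result.params["width"].value,
        tm_se=result.params["tm"].stderr or float("nan"),
        residual_norm=rnorm,
        converged=converged,
    )
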