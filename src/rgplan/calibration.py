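"""Receiver-gain calibration curves.

A calibration curve records, for one nucleus/field/sample at fixed reference
conditions (flip angle ``alpha_ref``, polarization ``p_ref``, spin
concentration ``c_ref``), how the spectral peak integral, noise RMS and
maximum FID amplitude behave across a sweep of receiver-gain (RG) settings.
Two calibrated channels are carried throughout: the *integral* channel,
whose ratio to the noise RMS is the reference SNR the planner rescales, and
the *FID-max* channel, which is the quantity the ADC ceiling actually
limits.  The two scales differ and are deliberately never derived from one
another.

The signal model is ``signal = A * f(RG) * sin(alpha) * P * C`` with no
intercept, so slope fits go through the origin.  Because the receiver's
internal gain staging ("level plan") can switch abruptly — producing the
characteristic SNR dip near RG ~ 20 on some spectrometers — interpolation
of the SNR channel never bridges a detected discontinuity: queries inside a
flagged segment snap to the nearer measured knot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateCurveError,
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
    OutOfRangeError,
)
from .physics import Nucleus

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "SlopeFit",
    "build_calibration",
    "fit_slope",
    "signal_deviation",
    "interpolate_snr",
    "interpolate_fid_max",
    "detect_discontinuity",
    "rg_from_db",
    "rg_to_db",
    "DEFAULT_DROP_THRESHOLD",
]

#: Relative SNR drop between adjacent knots treated as a level-plan switch.
DEFAULT_DROP_THRESHOLD = 0.1


def rg_from_db(rg_db) -> np.ndarray | float:
    """Convert a dB-valued receiver gain to the linear (amplitude) convention.

    Benchtop consoles quote RG in dB; ``rg_linear = 10**(dB/20)``.
    """
    return 10.0 ** (np.asarray(rg_db, dtype=float) / 20.0)


def rg_to_db(rg_linear) -> np.ndarray | float:
    """Inverse of :func:`rg_from_db`."""
    return 20.0 * np.log10(np.asarray(rg_linear, dtype=float))


@dataclass(frozen=True)
class CalibrationPoint:
    """One RG setting of a calibration sweep (a.u. throughout)."""

    rg: float
    signal_integral: float
    noise_rms: float
    fid_max: float = 0.0
    n_averages: int = 1

    def __post_init__(self):
        if self.rg <= 0:
            raise InvalidInputError("rg must be > 0")
        if self.noise_rms <= 0:
            raise InvalidInputError("noise_rms must be > 0")
        if self.signal_integral < 0:
            raise InvalidInputError("signal_integral must be >= 0")
        if self.fid_max < 0:
            raise InvalidInputError("fid_max must be >= 0")
        if self.n_averages < 1:
            raise InvalidInputError("n_averages must be >= 1")

    @property
    def snr(self) -> float:
        return self.signal_integral / self.noise_rms


@dataclass
class SlopeFit:
    """Through-origin least-squares slope with diagnostics."""

    slope: float
    stderr: float
    residuals: np.ndarray


@dataclass
class CalibrationCurve:
    """SNR_ref(RG) and FID-max(RG) at fixed reference conditions.

    ``slope_integral`` and ``slope_fid`` are the fitted hardware
    coefficients in a.u./(RG·M) for the two channels (the coefficient ``A``
    of the linear signal model, evaluated at ``alpha_ref`` and ``p_ref``).
    """

    points: list[CalibrationPoint]
    alpha_ref: float = 90.0
    p_ref: float = 1.0
    c_ref: float = 1.0
    nucleus: Nucleus | None = None
    field: float | None = None
    temperature: float | None = None
    rg_units: str = "linear"
    slope_integral: float | None = None
    slope_fid: float | None = None

    def __post_init__(self):
        if self.c_ref <= 0:
            raise InvalidInputError("c_ref must be > 0 M")
        if not 0 < self.p_ref <= 1:
            raise InvalidInputError("p_ref must be in (0, 1]")
        if not 0 < self.alpha_ref <= 90:
            raise InvalidInputError("alpha_ref must be in (0, 90] degrees")
        rgs = [p.rg for p in self.points]
        if rgs != sorted(rgs) or len(set(rgs)) != len(rgs):
            raise InvalidInputError(
                "points must be strictly increasing in rg with no duplicates"
            )

    @property
    def rgs(self) -> np.ndarray:
        return np.array([p.rg for p in self.points])

    @property
    def signals(self) -> np.ndarray:
        return np.array([p.signal_integral for p in self.points])

    @property
    def noises(self) -> np.ndarray:
        return np.array([p.noise_rms for p in self.points])

    @property
    def fid_maxes(self) -> np.ndarray:
        return np.array([p.fid_max for p in self.points])

    @property
    def snr(self) -> np.ndarray:
        return self.signals / self.noises

    @property
    def rg_min(self) -> float:
        return self.points[0].rg

    @property
    def rg_max(self) -> float:
        return self.points[-1].rg


def build_calibration(
    points: Sequence[CalibrationPoint],
    *,
    alpha_ref: float = 90.0,
    p_ref: float = 1.0,
    c_ref: float = 1.0,
    nucleus: Nucleus | None = None,
    field: float | None = None,
    temperature: float | None = None,
    rg_units: str = "linear",
    normalize_averages: bool = True,
) -> CalibrationCurve:
    """Assemble a :class:`CalibrationCurve` from sweep measurements.

    Points are sorted by ascending rg; duplicate rg values are rejected.
    With ``normalize_averages`` (default) the stored signal integral and
    FID maximum are divided by ``n_averages`` so sweeps recorded with
    different averaging share one per-scan scale.  Both channel slopes are
    fitted through the origin.
    """
    if len(points) < 2:
        raise InsufficientDataError("need at least 2 calibration points")
    pts = sorted(points, key=lambda p: p.rg)
    if len({p.rg for p in pts}) != len(pts):
        raise InvalidInputError("duplicate rg values in calibration points")
    if normalize_averages:
        pts = [
            replace(
                p,
                signal_integral=p.signal_integral / p.n_averages,
                fid_max=p.fid_max / p.n_averages,
                n_averages=1,
            )
            for p in pts
        ]
    curve = CalibrationCurve(
        points=list(pts),
        alpha_ref=alpha_ref,
        p_ref=p_ref,
        c_ref=c_ref,
        nucleus=nucleus,
        field=field,
        temperature=temperature,
        rg_units=rg_units,
    )
    curve.slope_integral = fit_slope(curve, "integral").slope
    if np.any(curve.fid_maxes > 0):
        curve.slope_fid = fit_slope(curve, "fid_max").slope
    return curve


def fit_slope(curve: CalibrationCurve, channel: str = "integral") -> SlopeFit:
    """Least-squares line through the origin of (rg, value / c_ref).

    Returns the slope in a.u./(RG·M) with its standard error and residuals.
    The zero-intercept form follows from the linear signal model (zero
    signal at zero gain).
    """
    if channel == "integral":
        y = curve.signals / curve.c_ref
    elif channel == "fid_max":
        y = curve.fid_maxes / curve.c_ref
    else:
        raise InvalidInputError("channel must be 'integral' or 'fid_max'")
    if len(curve.points) < 2:
        raise InsufficientDataError("need at least 2 points for a slope fit")
    if np.all(y == 0):
        raise DegenerateFitError(f"all {channel} values are zero")
    x = curve.rgs
    slope = float(np.dot(x, y) / np.dot(x, x))
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    stderr = float(np.sqrt(np.dot(resid, resid) / dof / np.dot(x, x)))
    return SlopeFit(slope, stderr, resid)


def signal_deviation(curve: CalibrationCurve) -> np.ndarray:
    """Fractional deviation of signal/RG from its value at the maximal RG.

    ``deviation(rg) = (signal(rg)/rg) * (rg_max/signal(rg_max)) - 1``;
    identically zero for a perfectly linear receiver, and exactly zero at
    the maximum-RG point by construction.
    """
    s_max = curve.points[-1].signal_integral
    if s_max == 0:
        raise DegenerateCurveError("zero signal at the maximum-RG point")
    return (curve.signals / curve.rgs) * (curve.rg_max / s_max) - 1.0


def detect_discontinuity(
    curve: CalibrationCurve, rel_drop_threshold: float = DEFAULT_DROP_THRESHOLD
) -> list[float]:
    """RG positions followed by an abrupt relative SNR drop.

    Returns each ``rg_i`` with ``SNR(rg_{i+1}) < (1 - threshold) * SNR(rg_i)``
    — the level-plan switch signature.  Empty for monotone-nondecreasing
    curves.
    """
    if not 0 < rel_drop_threshold < 1:
        raise InvalidInputError("rel_drop_threshold must be in (0, 1)")
    snr = curve.snr
    drops = snr[1:] < (1.0 - rel_drop_threshold) * snr[:-1]
    return [float(rg) for rg in curve.rgs[:-1][drops]]


def _interp_channel(
    curve: CalibrationCurve,
    rg,
    values: np.ndarray,
    snap_segments: list[int],
):
    rg_arr = np.atleast_1d(np.asarray(rg, dtype=float))
    x = curve.rgs
    eps = 1e-9 * (x[-1] - x[0])
    if np.any(rg_arr < x[0] - eps) or np.any(rg_arr > x[-1] + eps):
        raise OutOfRangeError(
            f"rg outside calibrated range [{x[0]:.6g}, {x[-1]:.6g}] "
            "(no extrapolation)"
        )
    rg_arr = np.clip(rg_arr, x[0], x[-1])
    out = np.interp(rg_arr, x, values)
    for seg in snap_segments:
        inside = (rg_arr > x[seg]) & (rg_arr < x[seg + 1])
        if inside.any():
            nearer_hi = (rg_arr[inside] - x[seg]) > (x[seg + 1] - rg_arr[inside])
            out[inside] = np.where(nearer_hi, values[seg + 1], values[seg])
    return out if np.ndim(rg) else float(out[0])


def interpolate_snr(
    curve: CalibrationCurve,
    rg,
    rel_drop_threshold: float = DEFAULT_DROP_THRESHOLD,
):
    """Reference SNR at arbitrary rg inside the calibrated range.

    Piecewise-linear between measured knots and exact at them.  Segments
    flagged by :func:`detect_discontinuity` are hardware switches, not
    smooth features, so queries inside one snap to the nearer knot instead
    of interpolating across it.  Accepts a scalar or an array.
    """
    flagged_rgs = set(detect_discontinuity(curve, rel_drop_threshold))
    segs = [i for i, rgv in enumerate(curve.rgs[:-1]) if float(rgv) in flagged_rgs]
    return _interp_channel(curve, rg, curve.snr, segs)


def interpolate_fid_max(curve: CalibrationCurve, rg):
    """Reference FID maximum at arbitrary rg (piecewise-linear, no snapping:
    the signal channel is continuous even across a level-plan switch)."""
    return _interp_channel(curve, rg, curve.fid_maxes, [])
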