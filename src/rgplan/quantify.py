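"""FID processing and quantification.

Turns complex free induction decays into spectra and extracts the
measurables that calibration and planning consume: peak integrals, the RMS
of a signal-free spectral region, their ratio (SNR), per-channel ADC
clipping reports, and the receiver range threshold (RRT, the ADC ceiling)
from clipped FIDs.

Processing follows the minimal recipe appropriate for receiver
characterization: plain discrete Fourier transform without apodization,
optional zero filling (integral-normalized so results do not depend on it),
zero/first-order phase correction, and baseline handling limited to a
constant offset for integrals and a linear detrend inside the noise window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    InvalidInputError,
    NoNoiseRegionError,
    NotClippedError,
    UndefinedSNRError,
)

__all__ = [
    "FIDRecord",
    "SpectrumRecord",
    "ClippingReport",
    "to_spectrum",
    "phase_correct",
    "integrate_peak",
    "estimate_noise",
    "snr_of",
    "detect_clipping",
    "estimate_rrt",
]

MIN_FID_SAMPLES = 16


@dataclass
class FIDRecord:
    """A complex time-domain acquisition.

    Attributes
    ----------
    samples : ndarray of complex
        Quadrature-detected time-domain points, in a.u.
    dwell : float
        Seconds per point.
    rg : float
        Receiver gain (linear convention) the FID was recorded with.
    alpha : float
        Excitation flip angle in degrees.
    clipped : bool
        True iff any quadrature channel touched the recorded ceiling
        (maintained by :func:`detect_clipping` / the simulator).
    meta : dict
        Free-form acquisition annotations.
    """

    samples: np.ndarray
    dwell: float
    rg: float = 1.0
    alpha: float = 90.0
    clipped: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size < MIN_FID_SAMPLES:
            raise InvalidInputError(
                f"FID needs >= {MIN_FID_SAMPLES} samples in a 1-D array"
            )
        if self.dwell <= 0:
            raise InvalidInputError("dwell must be > 0 s")


@dataclass
class SpectrumRecord:
    """A 1-D spectrum on an ascending Hz axis (offsets from the carrier)."""

    freq_axis: np.ndarray
    values: np.ndarray
    phase0: float = 0.0  # accumulated zero-order phase, degrees
    phase1: float = 0.0  # accumulated first-order phase, degrees across sweep

    def __post_init__(self):
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.values = np.asarray(self.values)
        if self.freq_axis.shape != self.values.shape:
            raise InvalidInputError("freq_axis and values must have equal length")
        if self.freq_axis.size < 2 or np.any(np.diff(self.freq_axis) <= 0):
            raise InvalidInputError("freq_axis must be strictly increasing")

    @property
    def sweep(self) -> float:
        return self.freq_axis[-1] - self.freq_axis[0]


def to_spectrum(fid: FIDRecord, zero_fill_factor: int = 1) -> SpectrumRecord:
    """Fourier transform a FID into a spectrum.

    The transform is scaled by the dwell time so that it approximates the
    continuous Fourier transform: spectral values have units a.u./Hz, peak
    integrals over a fixed Hz window are invariant under zero filling, and
    Parseval's identity holds between ``sum |fid|^2 * dwell`` and
    ``sum |spectrum|^2 * df``.
    """
    if int(zero_fill_factor) != zero_fill_factor or zero_fill_factor < 1:
        raise InvalidInputError("zero_fill_factor must be an integer >= 1")
    n = fid.samples.size * int(zero_fill_factor)
    values = np.fft.fftshift(np.fft.fft(fid.samples, n=n)) * fid.dwell
    freq = np.fft.fftshift(np.fft.fftfreq(n, d=fid.dwell))
    return SpectrumRecord(freq, values)


def phase_correct(
    spectrum: SpectrumRecord, phi0: float, phi1: float, pivot: float = 0.0
) -> SpectrumRecord:
    """Apply zero- and first-order phase correction (degrees).

    The first-order term varies linearly across the sweep width relative to
    ``pivot`` (Hz).  The magnitude spectrum is unchanged.
    """
    f = spectrum.freq_axis
    phase = np.deg2rad(phi0) + np.deg2rad(phi1) * (f - pivot) / spectrum.sweep
    return SpectrumRecord(
        f.copy(),
        spectrum.values * np.exp(1j * phase),
        phase0=spectrum.phase0 + phi0,
        phase1=spectrum.phase1 + phi1,
    )


def _region_mask(spectrum: SpectrumRecord, region: Sequence[float]) -> np.ndarray:
    lo, hi = float(region[0]), float(region[1])
    if not lo < hi:
        raise InvalidInputError(f"empty or inverted region ({lo}, {hi}) Hz")
    f = spectrum.freq_axis
    if lo < f[0] or hi > f[-1]:
        raise InvalidInputError(
            f"region ({lo}, {hi}) Hz outside spectral range ({f[0]:.6g}, {f[-1]:.6g})"
        )
    return (f >= lo) & (f <= hi)


def integrate_peak(
    spectrum: SpectrumRecord,
    region: Sequence[float],
    baseline: bool = True,
) -> float:
    """Trapezoidal integral of the real part over ``region`` (Hz).

    With ``baseline=True`` a zero-order offset equal to half the full-axis
    mean of the real part is subtracted first.  Rectangle-rule sampling of a
    one-sided decay adds a flat pedestal of ``s(0) * dwell / 2`` to the
    spectrum, and the full-axis mean equals ``s(0) * dwell`` exactly (DFT
    identity), so this removes the pedestal; being linear in the data, the
    correction cannot be biased by noise.  The integral is in a.u.·Hz
    (per-Hz spectral values times the bin width), hence zero-fill invariant.
    """
    mask = _region_mask(spectrum, region)
    if mask.sum() < 2:
        raise InvalidInputError("region contains fewer than 2 spectral points")
    y = np.real(spectrum.values)
    offset = 0.5 * float(np.mean(y)) if baseline else 0.0
    return float(np.trapezoid(y[mask] - offset, spectrum.freq_axis[mask]))


def _detrended_rms(y: np.ndarray) -> float:
    """RMS of ``y`` after removing a least-squares linear baseline."""
    x = np.arange(y.size, dtype=float)
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    return float(np.sqrt(np.mean(resid**2)))


def estimate_noise(
    spectrum: SpectrumRecord,
    region: Sequence[float] | None = None,
    peak_regions: Sequence[Sequence[float]] = (),
    window_frac: float = 0.1,
    return_region: bool = False,
):
    """Noise RMS of a signal-free spectral region.

    If ``region`` is given, the RMS of its real part is returned after
    removing a linear baseline fit.  In automatic mode the contiguous window
    of ``window_frac`` of the points with minimal standard deviation, among
    candidate windows disjoint from every ``peak_regions`` interval, is
    selected.
    """
    y = np.real(spectrum.values).astype(float)
    f = spectrum.freq_axis
    if region is not None:
        mask = _region_mask(spectrum, region)
        for peak in peak_regions:
            plo, phi = float(peak[0]), float(peak[1])
            if not (region[1] <= plo or region[0] >= phi):
                raise InvalidInputError(
                    "noise region overlaps a declared peak region"
                )
        if mask.sum() < 8:
            raise InvalidInputError("noise region contains fewer than 8 points")
        rms = _detrended_rms(y[mask])
        return (rms, (float(region[0]), float(region[1]))) if return_region else rms

    n = y.size
    w = max(8, int(round(window_frac * n)))
    if w > n:
        raise NoNoiseRegionError("window wider than the spectrum")
    step = max(1, w // 8)
    best = None
    for start in range(0, n - w + 1, step):
        lo_hz, hi_hz = f[start], f[start + w - 1]
        if any(
            not (hi_hz < float(p[0]) or lo_hz > float(p[1])) for p in peak_regions
        ):
            continue
        rms = _detrended_rms(y[start : start + w])
        if best is None or rms < best[0]:
            best = (rms, (float(lo_hz), float(hi_hz)))
    if best is None:
        raise NoNoiseRegionError(
            "no contiguous window disjoint from the peak regions"
        )
    return best if return_region else best[0]


def snr_of(
    spectrum: SpectrumRecord,
    peak_region: Sequence[float],
    noise_region: Sequence[float] | None = None,
    convention: str = "integral",
    window_frac: float = 0.1,
) -> float:
    """SNR = peak quantifier / noise RMS.

    ``convention="integral"`` (default) uses the trapezoidal peak integral;
    ``"amplitude"`` uses the maximum real value within the peak region.
    """
    if convention not in ("integral", "amplitude"):
        raise InvalidInputError("convention must be 'integral' or 'amplitude'")
    noise = estimate_noise(
        spectrum,
        region=noise_region,
        peak_regions=(peak_region,),
        window_frac=window_frac,
    )
    if noise == 0:
        raise UndefinedSNRError("noise RMS is zero; SNR is undefined")
    if convention == "integral":
        signal = integrate_peak(spectrum, peak_region)
    else:
        mask = _region_mask(spectrum, peak_region)
        signal = float(np.max(np.real(spectrum.values)[mask]))
    return signal / noise


@dataclass
class ClippingReport:
    """Result of per-channel clipping detection."""

    clipped: bool
    indices: np.ndarray
    fraction: float


def detect_clipping(
    fid: FIDRecord, rrt: float, near_fraction: float = 0.999
) -> ClippingReport:
    """Flag samples whose real or imaginary channel reaches the ADC ceiling.

    A sample counts as clipped when ``|real| >= near_fraction * rrt`` or
    ``|imag| >= near_fraction * rrt`` (the boundary itself counts: the
    allowed region is signal strictly matching ``<= S_m``).  Updates
    ``fid.clipped`` in place and returns the report.
    """
    if rrt <= 0:
        raise InvalidInputError("rrt must be > 0")
    level = near_fraction * rrt
    hit = (np.abs(fid.samples.real) >= level) | (np.abs(fid.samples.imag) >= level)
    indices = np.flatnonzero(hit)
    fid.clipped = bool(indices.size)
    return ClippingReport(fid.clipped, indices, indices.size / fid.samples.size)


def _plateau_levels(channel: np.ndarray, min_run: int, tol: float) -> list[float]:
    """Absolute levels of runs of >= min_run samples at the channel max."""
    mag = np.abs(channel)
    peak = mag.max()
    if peak == 0:
        return []
    near = mag >= (1.0 - tol) * peak
    levels: list[float] = []
    run_start = None
    for i, flag in enumerate(np.append(near, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_run:
                levels.append(float(np.median(mag[run_start:i])))
            run_start = None
    return levels


def estimate_rrt(
    fids: Sequence[FIDRecord] | FIDRecord,
    min_run: int = 4,
    tol: float = 1e-3,
) -> float:
    """Estimate the ADC ceiling from the flat-topped plateau of clipped FIDs.

    Scans the real and imaginary channel of every FID for runs of at least
    ``min_run`` consecutive samples within ``tol`` (relative) of that
    channel's maximum magnitude and returns the median plateau level.
    Unclipped records contribute no plateau and are ignored; if none of the
    FIDs shows a plateau a :class:`NotClippedError` is raised.
    """
    if isinstance(fids, FIDRecord):
        fids = [fids]
    levels: list[float] = []
    for fid in fids:
        levels += _plateau_levels(fid.samples.real, min_run, tol)
        levels += _plateau_levels(fid.samples.imag, min_run, tol)
    if not levels:
        raise NotClippedError(
            "no flat-topped plateau found; RRT cannot be estimated from "
            "unclipped data"
        )
    return float(np.median(levels))
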