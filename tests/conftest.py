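"""Shared fixtures: analytic calibration curves and random-curve factories."""

import numpy as np
import pytest

from rgplan import (
    CalibrationPoint,
    build_calibration,
    noise_preset,
    noise_sigma,
)

DEFAULT_RGS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0, 14.0, 18.0, 20.2, 25.4, 32.0, 50.8, 72.0, 101.0)


def make_linear_curve(
    slope_integral=5.0,
    slope_fid=50.0,
    rgs=(1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
    c_ref=2.0,
    p_ref=0.5,
    alpha_ref=90.0,
    noise_rms=1.0,
):
    """A perfectly linear receiver: signal = slope * rg * c_ref, flat noise."""
    points = [
        CalibrationPoint(
            rg=rg,
            signal_integral=slope_integral * rg * c_ref,
            noise_rms=noise_rms,
            fid_max=slope_fid * rg * c_ref,
        )
        for rg in rgs
    ]
    return build_calibration(
        points, alpha_ref=alpha_ref, p_ref=p_ref, c_ref=c_ref
    )


def make_dip_curve(scale=100.0, rgs=DEFAULT_RGS, c_ref=1.0, p_ref=1e-5):
    """Linear signal channel with the dip preset's analytic noise curve."""
    model = noise_preset("dip")
    points = [
        CalibrationPoint(
            rg=rg,
            signal_integral=scale * rg,
            noise_rms=float(noise_sigma(model, rg)),
            fid_max=scale * rg,
        )
        for rg in rgs
    ]
    return build_calibration(points, alpha_ref=90.0, p_ref=p_ref, c_ref=c_ref)


def make_random_curve(rng):
    """A random but valid calibration curve (positive SNR, linear FID channel)."""
    n_knots = int(rng.integers(5, 12))
    rgs = np.sort(rng.uniform(0.25, 101.0, n_knots))
    while np.any(np.diff(rgs) < 1e-3):
        rgs = np.sort(rng.uniform(0.25, 101.0, n_knots))
    signals = rng.lognormal(mean=3.0, sigma=1.0, size=n_knots) * rgs
    noises = rng.lognormal(mean=0.0, sigma=0.5, size=n_knots)
    fid_slope = rng.lognormal(mean=2.0, sigma=1.0)
    points = [
        CalibrationPoint(
            rg=float(rg),
            signal_integral=float(s),
            noise_rms=float(nz),
            fid_max=float(fid_slope * rg),
        )
        for rg, s, nz in zip(rgs, signals, noises)
    ]
    return build_calibration(
        points,
        alpha_ref=90.0,
        p_ref=float(rng.uniform(1e-6, 1.0)),
        c_ref=float(rng.uniform(0.1, 2.0)),
    )


@pytest.fixture
def linear_curve():
    return make_linear_curve()


@pytest.fixture
def dip_curve():
    return make_dip_curve()
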