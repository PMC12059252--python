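"""Receiver-chain simulator: noise model, FIDs, sweeps, hyperpolarized series."""

import math

import numpy as np
import pytest

from rgplan import (
    CalibrationPoint,
    ConstraintSpec,
    InvalidInputError,
    NoiseModel,
    OutOfRangeError,
    ReceiverModel,
    SampleSpec,
    build_calibration,
    detect_discontinuity,
    hyper_series,
    noise_preset,
    noise_sigma,
    normalize_series,
    optimize,
    rg_sweep,
    synth_fid,
)
from rgplan.simulate import _dip_parameters

from conftest import DEFAULT_RGS


def _analytic_snr(model, rg):
    return rg / noise_sigma(model, rg)


def test_noise_sigma_limiting_regimes():
    input_only = NoiseModel(sigma_input=2.0, sigma_output=0.0)
    rgs = np.array([1.0, 4.0, 16.0])
    # SNR flat: noise proportional to gain
    assert np.allclose(noise_sigma(input_only, rgs), 2.0 * rgs)
    snr = rgs / noise_sigma(input_only, rgs)
    assert np.allclose(snr, snr[0])

    output_only = NoiseModel(sigma_input=0.0, sigma_output=3.0)
    # SNR strictly linear in rg
    assert np.allclose(noise_sigma(output_only, rgs), 3.0)
    assert np.allclose(rgs / noise_sigma(output_only, rgs), rgs / 3.0)


def test_noise_model_validation():
    with pytest.raises(InvalidInputError):
        NoiseModel(sigma_input=-1.0)
    with pytest.raises(InvalidInputError):
        NoiseModel(switch_penalty=0.5)
    with pytest.raises(InvalidInputError):
        noise_preset("nope")
    with pytest.raises(InvalidInputError):
        noise_sigma(NoiseModel(), 0.0)


def test_dip_preset_reproduces_design_ratios_in_closed_form():
    """The dip preset is solved so that SNR(18)/SNR(0.25) = 4.8 and the
    switch costs 40% of SNR between RG 18 and 20.2."""
    model = noise_preset("dip")
    assert model.rg_switch == 18.0
    assert _analytic_snr(model, 18.0) / _analytic_snr(model, 0.25) == pytest.approx(
        4.8, rel=1e-9
    )
    assert 1 - _analytic_snr(model, 20.2) / _analytic_snr(model, 18.0) == pytest.approx(
        0.40, rel=1e-9
    )
    r, penalty = _dip_parameters()
    assert model.sigma_output == pytest.approx(r)
    assert model.switch_penalty == pytest.approx(penalty)


def test_preset_families_have_their_qualitative_shapes():
    rgs = np.geomspace(0.25, 101, 60)
    sat = _analytic_snr(noise_preset("saturating"), rgs)
    assert np.all(np.diff(sat) > 0)  # monotone rise...
    assert sat[-1] / sat[np.searchsorted(rgs, 30.0)] < 1.05  # ...plateaued > 30
    mono = _analytic_snr(noise_preset("monotone"), rgs)
    assert np.all(np.diff(mono) > 0)
    assert mono[-1] / mono[np.searchsorted(rgs, 30.0)] > 1.5  # still climbing


def test_synth_fid_determinism_and_validation():
    a = synth_fid(10.0, rg=4.0, noise=noise_preset("dip"), seed=123)
    b = synth_fid(10.0, rg=4.0, noise=noise_preset("dip"), seed=123)
    c = synth_fid(10.0, rg=4.0, noise=noise_preset("dip"), seed=124)
    assert np.array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)
    with pytest.raises(InvalidInputError):
        synth_fid(1.0, t2_star=0.0)
    with pytest.raises(InvalidInputError):
        synth_fid(1.0, n_points=8)


def test_synth_fid_clipping_ceiling_conservation():
    rrt = 1.24e9
    # noiseless, below ceiling: pure unclipped decay
    clean = synth_fid(1.0e8, rg=2.0, noise=None, rrt=rrt)
    assert not clean.clipped
    assert np.max(np.abs(clean.samples)) == pytest.approx(2.0e8)

    # driven past the ceiling: clipped flag set, channels never exceed rrt
    hot = synth_fid(
        1.2 * rrt, rg=1.0, noise=noise_preset("dip", 1e6), rrt=rrt, seed=5
    )
    assert hot.clipped
    assert np.max(np.abs(hot.samples.real)) <= rrt
    assert np.max(np.abs(hot.samples.imag)) <= rrt


def test_noiseless_linear_sweep_recovers_slopes_exactly():
    sweep = rg_sweep(1e4, [1.0, 2.0, 4.0, 8.0], noise=None, c_ref=2.0)
    curve = build_calibration(sweep.points, c_ref=2.0)
    # the FID-max channel is exact: first sample magnitude = gain * amplitude
    assert curve.slope_fid == pytest.approx(sweep.truth["slope_fid"], rel=1e-12)
    # the integral channel is exactly linear in rg (fit residuals vanish)...
    assert np.allclose(
        curve.signals / curve.rgs, curve.signals[0] / curve.rgs[0], rtol=1e-9
    )
    # ...and matches the analytic absorption-integral slope to ~1%
    assert curve.slope_integral == pytest.approx(
        sweep.truth["slope_integral"], rel=0.02
    )


def test_sweep_determinism_and_seed_independence_of_slope():
    kwargs = dict(
        rg_list=[0.5, 2.0, 8.0, 32.0],
        noise=NoiseModel(sigma_input=50.0, sigma_output=60.0),
        replicates=2,
        c_ref=1.0,
        noise_region=(-1900.0, -300.0),
    )
    a = rg_sweep(1e4, seed=7, **kwargs)
    b = rg_sweep(1e4, seed=7, **kwargs)
    assert a.table.equals(b.table)

    c = rg_sweep(1e4, seed=8, **kwargs)
    fit_a = build_calibration(a.points).slope_integral
    fit_c = build_calibration(c.points).slope_integral
    # different noise realizations, statistically compatible slopes
    assert abs(fit_a - fit_c) / fit_a < 0.05


def test_dip_sweep_measured_optimum_matches_analytic_optimum():
    """Quantified SNR across a dip-preset sweep peaks at the pre-switch
    gain the noise model predicts (RG 18)."""
    model = noise_preset("dip", sigma_input=2000.0)
    sweep = rg_sweep(
        1e5,
        list(DEFAULT_RGS),
        noise=model,
        replicates=32,
        seed=11,
        n_points=4096,
        noise_region=(-1900.0, -300.0),
    )
    curve = build_calibration(sweep.points)
    measured_best = curve.rgs[np.argmax(curve.snr)]
    analytic = np.asarray(DEFAULT_RGS)
    analytic_best = analytic[np.argmax(_analytic_snr(model, analytic))]
    assert analytic_best == 18.0
    assert measured_best == analytic_best
    assert detect_discontinuity(curve) == [18.0]


def test_end_to_end_sweep_to_plan_lands_in_plateau():
    """sweep -> calibrate -> optimize finds the pre-switch plateau (RG in
    [10, 18]) for a low-flip-angle hyperpolarized plan, on every seed."""
    for seed in range(10):
        sweep = rg_sweep(
            1e5,
            list(DEFAULT_RGS),
            noise=noise_preset("dip", sigma_input=2000.0),
            replicates=8,
            seed=seed,
            noise_region=(-1900.0, -300.0),
        )
        curve = build_calibration(sweep.points, p_ref=8.1e-6, c_ref=1.308)
        sample = SampleSpec(concentration=0.09, polarization=0.35)
        receiver = ReceiverModel(rrt=1.24e9, allowed_rg=list(DEFAULT_RGS))
        plan = optimize(curve, sample, receiver, ConstraintSpec(alpha_max=5.0))
        assert 10.0 <= plan.rg_opt <= 18.0
        assert plan.fid_max_pred <= receiver.s_m


def test_hyper_series_polarization_bookkeeping():
    # a 90-degree shot consumes everything: the next integral is exactly 0
    series = hyper_series(
        1.0, 50.0, [90.0, 90.0], [1.0, 1.0], tr=np.array([1.0, 2.0]), noise=None
    )
    assert series.integrals[1] == pytest.approx(0.0, abs=1e-15)

    # constant flip angle and TR: exact closed-form decay with cos losses
    n, alpha, tr_s, t1 = 12, 5.0, 8.0, 55.0
    times = tr_s * np.arange(1, n + 1)
    series = hyper_series(
        0.3, t1, [alpha] * n, [18.0] * n, tr=times, concentration=0.1, noise=None
    )
    cosa = math.cos(math.radians(alpha))
    expected = (
        18.0
        * math.sin(math.radians(alpha))
        * 0.3
        * 0.1
        * np.exp(-times / t1)
        * cosa ** np.arange(n)
    )
    assert np.allclose(series.integrals, expected, rtol=1e-12)


def test_alternating_rg_scales_raw_integrals_by_gain_ratio():
    n = 6
    times = 8.0 * np.arange(1, n + 1)
    rgs = [0.25 if i % 2 == 0 else 18.0 for i in range(n)]
    series = hyper_series(0.3, 55.0, [5.0] * n, rgs, tr=times, noise=None)
    pol = 0.3 * np.exp(-times / 55.0) * math.cos(math.radians(5.0)) ** np.arange(n)
    ratio = (series.integrals[1] / pol[1]) / (series.integrals[0] / pol[0])
    assert ratio == pytest.approx(18.0 / 0.25, rel=1e-12)  # = 72


def _linear_curve_for_norm(noise_model, rgs=(0.25, 1.0, 4.0, 10.0, 18.0)):
    return build_calibration(
        [
            CalibrationPoint(
                rg=rg,
                signal_integral=100.0 * rg,
                noise_rms=float(noise_sigma(noise_model, rg)),
                fid_max=100.0 * rg,
            )
            for rg in rgs
        ]
    )


def test_normalize_constant_rg_series_is_identity_scaling():
    model = noise_preset("dip")
    curve = _linear_curve_for_norm(model)
    n = 10
    times = 8.0 * np.arange(1, n + 1)
    series = hyper_series(0.3, 55.0, [5.0] * n, [18.0] * n, tr=times, noise=None)
    fit = normalize_series(series, curve)
    assert np.allclose(fit.factors, 1.0)
    # effective decay: T1 relaxation plus cos(alpha) loss per TR
    rate = 1 / 55.0 - math.log(math.cos(math.radians(5.0))) / 8.0
    assert fit.decay_time == pytest.approx(1 / rate, rel=1e-6)


def test_normalize_alternating_series_recovers_effective_decay():
    """20 stochastic replicates: the normalized alternating-RG series fits
    a mono-exponential whose decay matches the closed form within 2%."""
    model = noise_preset("dip")
    curve = _linear_curve_for_norm(model)
    n, alpha, tr_s, t1 = 40, 5.0, 8.0, 55.0
    times = tr_s * np.arange(1, n + 1)
    rate = 1 / t1 - math.log(math.cos(math.radians(alpha))) / tr_s
    rgs = [0.25 if i % 2 == 0 else 18.0 for i in range(n)]
    for seed in range(20):
        series = hyper_series(
            0.33,
            t1,
            [alpha] * n,
            rgs,
            tr=times,
            concentration=0.1,
            signal_scale=1.2e5,
            noise=model,
            seed=seed,
        )
        fit = normalize_series(series, curve)
        assert fit.decay_time == pytest.approx(1 / rate, rel=0.02)


def test_normalize_with_nonlinear_gain_removes_alternation():
    """A series generated with a nonlinear gain curve and normalized with
    that same measured curve shows <1% residual alternation."""
    gain = lambda rg: np.asarray(rg, dtype=float) ** 1.15
    rgs_cal = (0.25, 1.0, 4.0, 10.0, 18.0)
    curve = build_calibration(
        [
            CalibrationPoint(
                rg=rg, signal_integral=float(100.0 * gain(rg)), noise_rms=1.0
            )
            for rg in rgs_cal
        ]
    )
    n = 12
    times = 8.0 * np.arange(1, n + 1)
    series = hyper_series(
        0.3,
        55.0,
        [5.0] * n,
        [0.25 if i % 2 == 0 else 18.0 for i in range(n)],
        tr=times,
        noise=None,
        gain_function=gain,
    )
    fit = normalize_series(series, curve)
    pol = 0.3 * np.exp(-times / 55.0) * math.cos(math.radians(5.0)) ** np.arange(n)
    flat = fit.normalized / pol
    assert (flat.max() - flat.min()) / flat.mean() < 0.01


def test_normalize_series_range_check():
    curve = _linear_curve_for_norm(noise_preset("dip"))
    series = hyper_series(
        0.3, 55.0, [5.0] * 4, [0.25, 18.0, 50.0, 18.0], tr=8.0 * np.arange(1, 5),
        noise=None,
    )
    with pytest.raises(OutOfRangeError):
        normalize_series(series, curve)
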