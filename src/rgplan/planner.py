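"""SNR-optimal (receiver gain, flip angle) planning under the ADC ceiling.

The core method: a reference SNR(RG) curve measured once at known
conditions (alpha_ref, P_ref, C_ref) predicts the SNR of *any* sample via

    SNR(RG) = SNR_ref(RG) * sin(alpha)/sin(alpha_ref) * P/P_ref * C/C_ref

while the FID-amplitude channel of the same calibration predicts whether a
given (RG, alpha) overflows the digitizer (predicted FID max <= S_m, where
S_m = safety_factor * RRT).  Maximizing the first quantity subject to the
second and to a flip-angle cap alpha_m is a two-variable constrained
problem, solved here on a dense grid: build the signal and SNR maps, mask
the overflow region, take the arg-max.  This matters most for
hyperpolarized experiments, where the transient signal rules out automatic
gain adjustment and a wrong RG either clips the FID or throws away SNR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .calibration import CalibrationCurve, interpolate_fid_max, interpolate_snr
from .errors import InfeasiblePlanError, InvalidInputError
from .physics import Nucleus

logger = logging.getLogger("rgplan.planner")

__all__ = [
    "SampleSpec",
    "ReceiverModel",
    "ConstraintSpec",
    "PlanResult",
    "scale_snr",
    "predict_fid_max",
    "clipping_product",
    "flip_angle_limit",
    "optimize",
    "averaging_acceleration",
    "avance_neo_rg_ladder",
]

#: Float tolerance used when collecting SNR ties for the arg-max tie-break.
_TIE_RTOL = 1e-12


def avance_neo_rg_ladder(
    rg_min: float = 0.25, rg_max: float = 101.0, step_ratio: float = 2 ** (1 / 6)
) -> np.ndarray:
    """Discrete RG settings of a research console: a geometric ladder.

    High-field consoles expose gains on an approximately geometric grid
    (ratio ~2^(1/6) ~ 1.12, e.g. ... 18, 20.2, 22.6 ...) from 0.25 to 101.
    Synthetic stand-in for hardware gain tables, descending from ``rg_max``.
    """
    vals = [rg_max]
    while vals[-1] / step_ratio >= rg_min * (1 - 1e-9):
        vals.append(vals[-1] / step_ratio)
    return np.array(sorted(round(v, 3) for v in vals))


@dataclass
class SampleSpec:
    """The sample the plan is for.

    ``concentration`` is the *spin* concentration in M (molecular
    concentration times spins per molecule); ``polarization`` a fraction in
    (0, 1], either given directly (hyperpolarized) or computed from
    :func:`rgplan.physics.thermal_polarization`.
    """

    concentration: float
    polarization: float
    nucleus: Nucleus | None = None

    def __post_init__(self):
        if self.concentration <= 0:
            raise InvalidInputError("concentration must be > 0 M")
        if not 0 < self.polarization <= 1:
            raise InvalidInputError("polarization must be in (0, 1]")


@dataclass
class ReceiverModel:
    """Receiver-chain description: gain range, ADC ceiling, safety factor."""

    rrt: float
    rg_min: float = 0.25
    rg_max: float = 101.0
    allowed_rg: Sequence[float] | None = None
    gain_function: Callable[[np.ndarray], np.ndarray] | None = None
    safety_factor: float = 1.0

    def __post_init__(self):
        if self.rrt <= 0:
            raise InvalidInputError("rrt must be > 0")
        if not 0 < self.rg_min < self.rg_max:
            raise InvalidInputError("require 0 < rg_min < rg_max")
        if not 0 < self.safety_factor <= 1:
            raise InvalidInputError("safety_factor must be in (0, 1]")

    @property
    def s_m(self) -> float:
        """Maximum allowed signal: safety_factor * RRT."""
        return self.safety_factor * self.rrt


@dataclass
class ConstraintSpec:
    """Optimization constraints: flip-angle cap and optional S_m override."""

    alpha_max: float = 90.0
    s_m_override: float | None = None

    def __post_init__(self):
        if not 0 < self.alpha_max <= 90:
            raise InvalidInputError("alpha_max must be in (0, 90] degrees")
        if self.s_m_override is not None and self.s_m_override <= 0:
            raise InvalidInputError("s_m_override must be > 0")


@dataclass
class PlanResult:
    """Optimal settings plus the full maps they were selected from."""

    rg_opt: float
    alpha_opt: float
    snr_pred: float
    fid_max_pred: float
    clip_margin: float  # fraction of S_m the predicted FID max uses
    rg_grid: np.ndarray = field(repr=False)
    alpha_grid: np.ndarray = field(repr=False)
    snr_map: np.ndarray = field(repr=False)  # shape (n_alpha, n_rg)
    signal_map: np.ndarray = field(repr=False)
    feasible: np.ndarray = field(repr=False)


def _condition_ratio(curve: CalibrationCurve, sample: SampleSpec) -> float:
    return (sample.polarization / curve.p_ref) * (sample.concentration / curve.c_ref)


def scale_snr(
    curve: CalibrationCurve, sample: SampleSpec, alpha: float, rg
):
    """Predicted SNR at target conditions.

    ``SNR_ref(rg) * sin(alpha)/sin(alpha_ref) * P/P_ref * C/C_ref``.
    """
    if not 0 < alpha <= 90:
        raise InvalidInputError("alpha must be in (0, 90] degrees")
    sin_ratio = math.sin(math.radians(alpha)) / math.sin(math.radians(curve.alpha_ref))
    return interpolate_snr(curve, rg) * sin_ratio * _condition_ratio(curve, sample)


def predict_fid_max(
    curve: CalibrationCurve, sample: SampleSpec, alpha: float, rg
):
    """Predicted maximum FID amplitude (the quantity the ADC ceiling limits).

    The reference FID maximum is interpolated from the calibration's
    FID-amplitude channel and rescaled with the same sin(alpha), P and C
    ratios as the SNR.
    """
    if not 0 < alpha <= 90:
        raise InvalidInputError("alpha must be in (0, 90] degrees")
    sin_ratio = math.sin(math.radians(alpha)) / math.sin(math.radians(curve.alpha_ref))
    return (
        interpolate_fid_max(curve, rg) * sin_ratio * _condition_ratio(curve, sample)
    )


def clipping_product(
    curve: CalibrationCurve, sample: SampleSpec, receiver: ReceiverModel
) -> float:
    """Maximum ``sin(alpha) * RG`` product that stays at or below S_m.

    Closed form for a linear FID channel: the predicted FID maximum is
    ``slope_fid * C * (P/p_ref) * sin(alpha) * rg / sin(alpha_ref)``, so the
    product saturating S_m is

        k = S_m * sin(alpha_ref) * p_ref / (slope_fid * C * P).

    Scales inversely with P·C: halving the concentration doubles k (and with
    it the clipping-free flip angle at any fixed RG).
    """
    if sample.polarization * sample.concentration <= 0:
        raise InvalidInputError("P * C must be positive")
    if curve.slope_fid is None or curve.slope_fid <= 0:
        raise InvalidInputError(
            "curve has no calibrated FID-amplitude channel (slope_fid)"
        )
    s_m = receiver.s_m
    return (
        s_m
        * math.sin(math.radians(curve.alpha_ref))
        * curve.p_ref
        / (curve.slope_fid * sample.concentration * sample.polarization)
    )


def flip_angle_limit(k: float, rg: float) -> float:
    """Largest clipping-free flip angle (degrees) at receiver gain ``rg``.

    ``arcsin(min(1, k/rg))`` — saturates at 90 deg once ``k >= rg``.
    """
    if k <= 0 or rg <= 0:
        raise InvalidInputError("k and rg must be > 0")
    return math.degrees(math.asin(min(1.0, k / rg)))


def averaging_acceleration(snr_ratio: float) -> float:
    """Fold reduction in the number of averages from an SNR improvement.

    Averaging gains SNR with the square root of the scan count, so an SNR
    ratio r shortens averaging by r**2 (1.5x SNR -> 2.25x fewer scans).
    """
    if snr_ratio <= 0:
        raise InvalidInputError("snr_ratio must be > 0")
    return snr_ratio**2


def _default_alpha_grid(alpha_max: float, step: float = 0.1) -> np.ndarray:
    if alpha_max <= step:
        return np.array([alpha_max])
    grid = np.arange(step, alpha_max + step / 2, step)
    if abs(grid[-1] - alpha_max) > 1e-9:
        grid = np.append(grid, alpha_max)
    return grid


def _default_rg_grid(
    curve: CalibrationCurve, receiver: ReceiverModel, n_rg: int
) -> np.ndarray:
    lo = max(receiver.rg_min, curve.rg_min)
    hi = min(receiver.rg_max, curve.rg_max)
    if lo >= hi and receiver.allowed_rg is None:
        raise InvalidInputError(
            "receiver RG bounds and calibrated range do not overlap"
        )
    if receiver.allowed_rg is not None:
        grid = np.asarray(sorted(receiver.allowed_rg), dtype=float)
        grid = grid[(grid >= lo) & (grid <= hi)]
        if grid.size == 0:
            raise InvalidInputError(
                "no allowed RG setting inside the calibrated range"
            )
        return grid
    # include the measured knots so plans land on calibrated gains (matters
    # around a flagged level-plan switch, where interior points snap)
    knots = curve.rgs[(curve.rgs >= lo) & (curve.rgs <= hi)]
    return np.unique(np.concatenate([np.geomspace(lo, hi, n_rg), knots]))


def optimize(
    curve: CalibrationCurve,
    sample: SampleSpec,
    receiver: ReceiverModel,
    constraints: ConstraintSpec | None = None,
    alpha_step: float = 0.1,
    n_rg: int = 400,
    rg_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
) -> PlanResult:
    """Maximize predicted SNR over (RG, alpha) under the overflow constraint.

    Five steps: interpolate the reference SNR and FID-max channels onto the
    RG grid, rescale both to the sample's conditions across the alpha grid,
    mask every cell whose predicted FID maximum exceeds S_m, and return the
    arg-max of the masked SNR map.  Ties (within float tolerance) break
    toward lower RG — less clipping risk at identical sensitivity — then
    lower alpha.

    The RG grid defaults to the receiver's discrete ``allowed_rg`` list
    restricted to the calibrated range, else ``n_rg`` log-spaced points;
    alpha runs from ``alpha_step`` to ``alpha_max`` in ``alpha_step`` steps.
    Raises :class:`InfeasiblePlanError` (reporting the minimal-violation
    cell) when no cell satisfies the constraint.
    """
    constraints = constraints or ConstraintSpec()
    s_m = (
        constraints.s_m_override
        if constraints.s_m_override is not None
        else receiver.s_m
    )
    if rg_grid is None:
        rg_grid = _default_rg_grid(curve, receiver, n_rg)
    else:
        rg_grid = np.asarray(rg_grid, dtype=float)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid(constraints.alpha_max, alpha_step)
    else:
        alpha_grid = np.asarray(alpha_grid, dtype=float)

    snr_ref = np.atleast_1d(interpolate_snr(curve, rg_grid))
    fid_ref = np.atleast_1d(interpolate_fid_max(curve, rg_grid))
    ratio = _condition_ratio(curve, sample)
    sin_ratio = np.sin(np.radians(alpha_grid)) / math.sin(
        math.radians(curve.alpha_ref)
    )

    snr_map = np.outer(sin_ratio, snr_ref) * ratio
    signal_map = np.outer(sin_ratio, fid_ref) * ratio
    feasible = signal_map <= s_m

    if not feasible.any():
        i, j = np.unravel_index(np.argmin(signal_map), signal_map.shape)
        cell = (float(rg_grid[j]), float(alpha_grid[i]), float(signal_map[i, j]))
        raise InfeasiblePlanError(
            f"no feasible (RG, alpha) cell: minimal predicted FID max "
            f"{cell[2]:.4g} a.u. at RG={cell[0]:.4g}, alpha={cell[1]:.3g} deg "
            f"still exceeds S_m={s_m:.4g} a.u.",
            cell=cell,
        )
    n_masked = int((~feasible).sum())
    if n_masked:
        logger.info(
            "overflow mask removed %d of %d grid cells (S_m=%.4g a.u.)",
            n_masked,
            feasible.size,
            s_m,
        )

    masked = np.where(feasible, snr_map, -np.inf)
    best = masked.max()
    ties = np.argwhere(masked >= best * (1.0 - _TIE_RTOL))
    # lowest RG first, then lowest alpha
    order = np.lexsort((alpha_grid[ties[:, 0]], rg_grid[ties[:, 1]]))
    i, j = ties[order[0]]

    return PlanResult(
        rg_opt=float(rg_grid[j]),
        alpha_opt=float(alpha_grid[i]),
        snr_pred=float(snr_map[i, j]),
        fid_max_pred=float(signal_map[i, j]),
        clip_margin=float(signal_map[i, j] / s_m),
        rg_grid=rg_grid,
        alpha_grid=alpha_grid,
        snr_map=snr_map,
        signal_map=signal_map,
        feasible=feasible,
    )
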