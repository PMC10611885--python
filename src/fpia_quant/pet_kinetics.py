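"""Kinetic quantification of tissue time-activity curves.

Implements the irreversible two-tissue compartment (2TC) forward model,
Patlak graphical analysis, weighted nonlinear compartmental fitting and
spectral analysis by non-negative least squares.

Model
-----
For an irreversible 2TC configuration (k4 = 0) the tissue impulse response
is

    h(t) = K1 * [ k3/(k2+k3) + k2/(k2+k3) * exp(-(k2+k3) t) ]

and the measured concentration is

    CT(t) = (1 - vb) * (h (*) Cp)(t) + vb * Cb(t)

with Cp the parent-plasma input, Cb whole blood and vb the blood volume
fraction.  The net irreversible influx rate constant is
Ki = K1 k3 / (k2 + k3).  Convolution is carried out on a fine (1 s) grid
and frame values are interval averages, matching how a scanner integrates
counts over a frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .blood import InputFunction
from .core_io import FrameSchedule, TissueTAC, ValidationError

__all__ = [
    "CompartmentParams",
    "PatlakResult",
    "Spectrum",
    "tissue_response",
    "patlak_fit",
    "fit_2tc",
    "spectral_analysis",
]

FINE_DT_MIN = 1.0 / 60.0  # 1-s convolution grid


@dataclass
class CompartmentParams:
    """Two-tissue compartment rate constants.

    K1 in mL/cm^3/min; k2, k3, k4 in /min; vb the fractional blood volume.
    ``Ki = K1*k3/(k2+k3)`` is the derived net influx rate; ``vt`` (total
    volume of distribution, mL/cm^3) exists only for a reversible
    configuration (k4 > 0).
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.0
    converged: bool = True
    residual: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValidationError(f"rate constant {name} must be nonnegative")
        if not 0.0 <= self.vb <= 1.0:
            raise ValidationError("vb must lie in [0, 1]")

    @property
    def Ki(self) -> float:
        denom = self.k2 + self.k3
        if denom == 0.0:
            # k2 = k3 = 0: everything delivered is trapped only if k3 > 0
            return 0.0
        return self.K1 * self.k3 / denom

    @property
    def vt(self) -> float:
        """Total volume of distribution; finite only when k4 > 0."""
        if self.k4 <= 0 or self.k2 <= 0:
            return float("inf") if self.K1 > 0 and self.k3 > 0 else (
                self.K1 / self.k2 if self.k2 > 0 else float("nan")
            )
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)


@dataclass
class PatlakResult:
    """Patlak graphical-analysis estimate over frames with mid-time >= t*."""

    Ki: float
    V0: float
    t_star_min: float
    r_squared: float
    n_points: int


@dataclass
class Spectrum:
    """Spectral-analysis decomposition of a TAC.

    ``betas`` is the decay-rate grid (per minute) including 0; ``alphas``
    the nonnegative weights.  The weight at beta = 0 measures irreversible
    trapping (``Ki_trap``); the reversible components integrate to
    ``VT_rev = sum(alpha/beta, beta > 0)``.
    """

    betas: np.ndarray
    alphas: np.ndarray
    blood_weight: float = 0.0
    residual: float = float("nan")

    @property
    def Ki_trap(self) -> float:
        zero = np.isclose(self.betas, 0.0)
        return float(self.alphas[zero].sum())

    @property
    def VT_rev(self) -> float:
        pos = self.betas > 0
        return float(np.sum(self.alphas[pos] / self.betas[pos]))


def _fine_grid(t_end_min: float, dt_min: float = FINE_DT_MIN) -> np.ndarray:
    n = int(np.ceil(t_end_min / dt_min)) + 1
    return np.linspace(0.0, n * dt_min, n + 1)


def _convolve_exp(cp: np.ndarray, theta: float, dt: float) -> np.ndarray:
    """(Cp (*) exp(-theta t)) on a uniform grid, via an exact recursion.

    Uses the trapezoid-consistent recursion
    y[i] = y[i-1]*e^{-theta dt} + dt/2 * (cp[i] + cp[i-1] e^{-theta dt}),
    which is O(n) and accurate for theta*dt << 1.
    """
    if theta == 0.0:
        out = np.concatenate([[0.0], np.cumsum((cp[1:] + cp[:-1]) * dt / 2.0)])
        return out
    e = float(np.exp(-theta * dt))
    add = dt / 2.0 * (cp[1:] + cp[:-1] * e)
    # y[i] = e*y[i-1] + add[i] is a first-order IIR filter
    tail = signal.lfilter([1.0], [1.0, -e], add)
    return np.concatenate([[0.0], tail])


def _frame_average(fine_t: np.ndarray, fine_y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval (trapezoid)."""
    cumint = np.concatenate(
        [[0.0], np.cumsum((fine_y[1:] + fine_y[:-1]) * np.diff(fine_t) / 2.0)]
    )
    start_min = schedule.frame_start_s / 60.0
    end_min = schedule.frame_end_s / 60.0
    int_start = np.interp(start_min, fine_t, cumint)
    int_end = np.interp(end_min, fine_t, cumint)
    return (int_end - int_start) / (end_min - start_min)


def _model_fine(
    params: CompartmentParams, cp: np.ndarray, cb: np.ndarray, dt: float
) -> np.ndarray:
    """Noiseless tissue curve on the fine grid for a (k4 = 0) 2TC model."""
    K1, k2, k3, vb = params.K1, params.k2, params.k3, params.vb
    theta = k2 + k3
    if K1 == 0.0:
        tissue = np.zeros_like(cp)
    elif theta == 0.0:
        # limit k2 -> 0, k3 -> 0: h(t) = K1, pure trapping of delivery
        tissue = K1 * _convolve_exp(cp, 0.0, dt)
    else:
        trap = k3 / theta
        rev = k2 / theta
        tissue = K1 * (trap * _convolve_exp(cp, 0.0, dt) + rev * _convolve_exp(cp, theta, dt))
    return (1.0 - vb) * tissue + vb * cb


def tissue_response(
    params: CompartmentParams,
    input_fn: InputFunction,
    blood_fn: InputFunction | None,
    schedule: FrameSchedule,
) -> TissueTAC:
    """Forward-model a frame-averaged tissue TAC from 2TC parameters.

    ``blood_fn`` supplies the whole-blood curve for the vb term; when absent
    the parent-plasma input is used in its place.
    """
    t_end = schedule.total_duration_s / 60.0
    fine_t = _fine_grid(t_end)
    dt = float(fine_t[1] - fine_t[0])
    cp = input_fn(fine_t)
    cb = blood_fn(fine_t) if blood_fn is not None else cp
    fine_y = _model_fine(params, cp, cb, dt)
    vals = _frame_average(fine_t, fine_y, schedule)
    return TissueTAC(schedule.mid_times_min, vals, statistic="mean", region="model")


def patlak_fit(
    tac: TissueTAC, input_fn: InputFunction, t_star_min: float = 15.0
) -> PatlakResult:
    """Patlak graphical analysis: OLS of CT/Cp vs. normalised plasma integral.

    Only frames with mid-time >= ``t_star_min`` enter the regression; the
    slope is the net influx constant Ki and the intercept the initial
    distribution volume V0.  Linearity of the retained points is summarised
    by r^2.
    """
    t = tac.mid_time_min
    use = t >= t_star_min
    if np.count_nonzero(use) < 3:
        raise ValidationError("Patlak fit needs at least 3 frames after t*")
    cp = input_fn(t[use])
    if np.any(cp <= 0):
        raise ValidationError("input function must be positive at all Patlak frames")
    # normalised time: integral of Cp from 0 to t over Cp(t)
    grid = input_fn.time_min
    vals = input_fn.parent_plasma_kBq_mL
    cumint = np.concatenate([[0.0], np.cumsum((vals[1:] + vals[:-1]) * np.diff(grid) / 2.0)])
    x = np.interp(t[use], grid, cumint) / cp
    y = tac.value_kBq_mL[use] / cp
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PatlakResult(
        Ki=float(slope),
        V0=float(intercept),
        t_star_min=float(t_star_min),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=int(np.count_nonzero(use)),
    )


_FIT_BOUNDS = {"K1": (0.0, 2.0), "k2": (0.0, 5.0), "k3": (0.0, 5.0), "vb": (0.0, 0.2)}


def fit_2tc(
    tac: TissueTAC,
    input_fn: InputFunction,
    blood_fn: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
    fix_k4_zero: bool = True,
    fit_vb: bool = True,
    multistart: int = 10,
    seed: int | None = 0,
) -> CompartmentParams:
    """Weighted nonlinear least-squares fit of the irreversible 2TC model.

    Weights are proportional to sqrt(frame duration) (longer frames carry
    less noise); the best of ``multistart`` seeded starting points by
    residual is returned.  Non-convergence of every start is flagged on the
    result rather than raised.
    """
    if not fix_k4_zero:
        raise NotImplementedError("only the irreversible (k4 = 0) configuration is fitted")
    if schedule is None:
        raise ValidationError("fit_2tc requires the frame schedule for frame averaging")
    t_end = schedule.total_duration_s / 60.0
    fine_t = _fine_grid(t_end)
    dt = float(fine_t[1] - fine_t[0])
    cp = input_fn(fine_t)
    cb = blood_fn(fine_t) if blood_fn is not None else cp
    w = np.sqrt(schedule.frame_duration_s / schedule.frame_duration_s.max())
    y_obs = tac.value_kBq_mL

    def residuals(x: np.ndarray) -> np.ndarray:
        K1, k2, k3 = x[0], x[1], x[2]
        vb = x[3] if fit_vb else 0.0
        p = CompartmentParams(K1=K1, k2=k2, k3=k3, vb=vb)
        fine_y = _model_fine(p, cp, cb, dt)
        return w * (_frame_average(fine_t, fine_y, schedule) - y_obs)

    lb = [_FIT_BOUNDS["K1"][0], _FIT_BOUNDS["k2"][0], _FIT_BOUNDS["k3"][0]]
    ub = [_FIT_BOUNDS["K1"][1], _FIT_BOUNDS["k2"][1], _FIT_BOUNDS["k3"][1]]
    if fit_vb:
        lb.append(_FIT_BOUNDS["vb"][0])
        ub.append(_FIT_BOUNDS["vb"][1])
    rng = np.random.default_rng(seed)
    starts = [np.array([0.1, 0.3, 0.05, 0.03][: len(lb)])]
    for _ in range(max(0, multistart - 1)):
        starts.append(
            np.array(
                [
                    rng.uniform(0.01, 0.5),
                    rng.uniform(0.05, 1.0),
                    rng.uniform(0.005, 0.5),
                    rng.uniform(0.0, 0.1),
                ][: len(lb)]
            )
        )
    best = None
    any_converged = False
    for x0 in starts:
        sol = optimize.least_squares(
            residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        any_converged = any_converged or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    x = best.x
    return CompartmentParams(
        K1=float(x[0]),
        k2=float(x[1]),
        k3=float(x[2]),
        vb=float(x[3]) if fit_vb else 0.0,
        converged=bool(any_converged),
        residual=float(np.sqrt(2.0 * best.cost)),
    )


def spectral_analysis(
    tac: TissueTAC,
    input_fn: InputFunction,
    blood_fn: InputFunction | None = None,
    schedule: FrameSchedule | None = None,
    n_betas: int = 100,
    beta_min: float = 0.001,
    beta_max: float = 10.0,
    include_blood: bool = True,
) -> Spectrum:
    """Non-negative least-squares spectral decomposition of a TAC.

    The basis is the input function convolved with exponentials on a
    log-spaced beta grid, augmented with beta = 0 (the trapping component)
    and optionally a whole-blood column.  The nonnegativity constraint makes
    the recovered spectrum sparse.
    """
    betas = np.concatenate([[0.0], np.geomspace(beta_min, beta_max, n_betas)])
    if np.unique(betas).size != betas.size:
        raise ValidationError("spectral basis contains duplicate betas")
    if schedule is None:
        raise ValidationError("spectral_analysis requires the frame schedule")
    t_end = schedule.total_duration_s / 60.0
    fine_t = _fine_grid(t_end)
    dt = float(fine_t[1] - fine_t[0])
    cp = input_fn(fine_t)
    if np.all(cp <= 0):
        raise ValidationError("input function is nonpositive everywhere")
    cols = []
    for beta in betas:
        fine_y = _convolve_exp(cp, float(beta), dt)
        cols.append(_frame_average(fine_t, fine_y, schedule))
    A = np.stack(cols, axis=1)
    if include_blood:
        cb = blood_fn(fine_t) if blood_fn is not None else cp
        A = np.column_stack([A, _frame_average(fine_t, cb, schedule)])
    y = tac.value_kBq_mL
    coef, rnorm = optimize.nnls(A, y)
    blood_weight = float(coef[-1]) if include_blood else 0.0
    alphas = coef[: betas.size]
    return Spectrum(betas=betas, alphas=alphas, blood_weight=blood_weight, residual=float(rnorm))
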