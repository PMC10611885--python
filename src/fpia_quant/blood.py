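"""Arterial blood processing: cross-calibration, metabolite correction,
continuous/discrete merging and population-average input functions.

The sampling protocol this module targets is continuous arterial counting
over the first 10 min plus discrete arterial samples at 2.5, 15, 30, 45 and
60 min post-injection, each discrete sample assayed for whole-blood and
plasma activity and for the parent (unmetabolised) fraction.  Fluoropivalate
is essentially non-metabolised, so the parent fraction is close to one; the
machinery still supports a declining parent fraction for tracers that need
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, optimize

from .core_io import PatientMeta, ValidationError

__all__ = [
    "BloodSeries",
    "InputFunction",
    "cross_calibrate",
    "metabolite_correct",
    "merge_input_function",
    "PopulationInputFunction",
    "population_input_function",
]

DISCRETE_SAMPLE_TIMES_MIN = (2.5, 15.0, 30.0, 45.0, 60.0)


@dataclass
class BloodSeries:
    """Raw blood measurements for one patient.

    ``continuous_*`` covers roughly the first 10 minutes at high temporal
    resolution (whole blood only); the discrete samples carry whole blood,
    plasma and parent fraction.
    """

    continuous_time_min: np.ndarray
    continuous_wb_kBq_mL: np.ndarray
    discrete_time_min: np.ndarray
    discrete_wb_kBq_mL: np.ndarray
    discrete_plasma_kBq_mL: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "continuous_time_min",
            "continuous_wb_kBq_mL",
            "discrete_time_min",
            "discrete_wb_kBq_mL",
            "discrete_plasma_kBq_mL",
            "parent_fraction",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.continuous_time_min) <= 0) or np.any(
            np.diff(self.discrete_time_min) <= 0
        ):
            raise ValidationError("blood sample times must be strictly increasing")
        for arr in (self.continuous_wb_kBq_mL, self.discrete_wb_kBq_mL, self.discrete_plasma_kBq_mL):
            if np.any(arr < 0):
                raise ValidationError("blood activities must be nonnegative")
        if np.any((self.parent_fraction < 0) | (self.parent_fraction > 1)):
            raise ValidationError("parent fraction must lie in [0, 1]")

    def continuous_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.continuous_time_min * 60.0, "kBq_mL": self.continuous_wb_kBq_mL}
        )

    def discrete_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.discrete_time_min,
                "wb_kBq_mL": self.discrete_wb_kBq_mL,
                "plasma_kBq_mL": self.discrete_plasma_kBq_mL,
                "parent_fraction": self.parent_fraction,
            }
        )

    @classmethod
    def from_frames(cls, continuous: pd.DataFrame, discrete: pd.DataFrame) -> "BloodSeries":
        return cls(
            continuous_time_min=np.asarray(continuous["time_s"], dtype=float) / 60.0,
            continuous_wb_kBq_mL=np.asarray(continuous["kBq_mL"], dtype=float),
            discrete_time_min=np.asarray(discrete["time_min"], dtype=float),
            discrete_wb_kBq_mL=np.asarray(discrete["wb_kBq_mL"], dtype=float),
            discrete_plasma_kBq_mL=np.asarray(discrete["plasma_kBq_mL"], dtype=float),
            parent_fraction=np.asarray(discrete["parent_fraction"], dtype=float),
        )


@dataclass
class InputFunction:
    """Metabolite-corrected parent-plasma concentration on a dense grid."""

    time_min: np.ndarray
    parent_plasma_kBq_mL: np.ndarray
    provenance: str = "measured"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.parent_plasma_kBq_mL = np.asarray(self.parent_plasma_kBq_mL, dtype=float)
        if self.time_min.shape != self.parent_plasma_kBq_mL.shape:
            raise ValidationError("input-function arrays differ in length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValidationError("input-function times must be strictly increasing")
        if not np.all(np.isfinite(self.parent_plasma_kBq_mL)):
            raise ValidationError("input function contains non-finite values")
        if np.any(self.parent_plasma_kBq_mL < -1e-12):
            raise ValidationError("input function must be nonnegative")
        np.clip(self.parent_plasma_kBq_mL, 0.0, None, out=self.parent_plasma_kBq_mL)

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero before the grid, flat after it."""
        return np.interp(
            np.asarray(t_min, dtype=float),
            self.time_min,
            self.parent_plasma_kBq_mL,
            left=0.0,
            right=float(self.parent_plasma_kBq_mL[-1]),
        )

    def integral(self, t_min: float) -> float:
        """Trapezoid integral from 0 to ``t_min`` on a dense grid."""
        grid = np.linspace(0.0, float(t_min), 2049)
        return float(np.trapezoid(self(grid), grid))


def cross_calibrate(
    continuous_time_min: np.ndarray,
    continuous_wb: np.ndarray,
    discrete_time_min: np.ndarray,
    discrete_wb: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Scale the continuous detector onto the discrete whole-blood samples.

    Returns the scaled continuous series and the least-squares scale factor
    ``s`` minimising ``sum (s*c_i - d_i)^2`` over discrete samples inside the
    continuous window.
    """
    ct = np.asarray(continuous_time_min, dtype=float)
    cv = np.asarray(continuous_wb, dtype=float)
    dt = np.asarray(discrete_time_min, dtype=float)
    dv = np.asarray(discrete_wb, dtype=float)
    inside = (dt >= ct[0]) & (dt <= ct[-1])
    if not np.any(inside):
        raise ValidationError("no discrete sample falls inside the continuous window")
    c_at = np.interp(dt[inside], ct, cv)
    denom = float(np.dot(c_at, c_at))
    if denom == 0.0:
        raise ValidationError("continuous series is zero at every overlap point")
    scale = float(np.dot(c_at, dv[inside])) / denom
    return cv * scale, scale


def _fit_sigmoid_pf(t: np.ndarray, pf: np.ndarray) -> "interpolate.interp1d":
    """Fit a declining sigmoid pf(t) = 1 - a * t^n / (t^n + b) with pf(0)=1."""

    def model(tt, a, b, n):
        tt = np.maximum(tt, 0.0)
        return 1.0 - a * tt**n / (tt**n + b)

    p0 = (max(1e-3, 1.0 - float(pf[-1])), max(np.median(t), 1.0), 2.0)
    popt, _ = optimize.curve_fit(
        model, t, pf, p0=p0, bounds=([0.0, 1e-6, 0.5], [1.0, 1e4, 8.0]), maxfev=20000
    )
    return lambda tt: np.clip(model(np.asarray(tt, dtype=float), *popt), 0.0, 1.0)


def metabolite_correct(
    series: BloodSeries,
    pf_model: str = "interpolate",
    plasma_wb_ratio: float | None = None,
    grid_dt_s: float = 1.0,
    t_end_min: float = 66.5,
) -> InputFunction:
    """Build a parent-plasma input function from discrete samples.

    Parent plasma = plasma x parent fraction, with pf(0)=1 enforced and a
    monotone nonincreasing parent-fraction curve (piecewise-linear default,
    sigmoid fit optional).  Where plasma is missing the whole-blood values
    are multiplied by a constant plasma/whole-blood ratio fitted from the
    samples that have both (default 1.0).
    """
    t = series.discrete_time_min
    pf = series.parent_fraction
    plasma = series.discrete_plasma_kBq_mL.copy()
    have_plasma = plasma > 0
    if plasma_wb_ratio is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = plasma[have_plasma] / series.discrete_wb_kBq_mL[have_plasma]
        ratios = ratios[np.isfinite(ratios)]
        plasma_wb_ratio = float(np.mean(ratios)) if ratios.size else 1.0
    plasma[~have_plasma] = series.discrete_wb_kBq_mL[~have_plasma] * plasma_wb_ratio

    t_pf = np.concatenate([[0.0], t])
    pf_vals = np.concatenate([[1.0], pf])
    # enforce monotone nonincreasing parent fraction
    pf_vals = np.minimum.accumulate(pf_vals)
    if pf_model == "interpolate":
        pf_fn = lambda tt: np.interp(np.asarray(tt, dtype=float), t_pf, pf_vals)
    elif pf_model == "sigmoid":
        pf_fn = _fit_sigmoid_pf(t_pf, pf_vals)
    else:
        raise ValidationError(f"unknown parent-fraction model '{pf_model}'")

    grid = np.arange(0.0, t_end_min * 60.0 + grid_dt_s / 2, grid_dt_s) / 60.0
    plasma_on_grid = np.interp(grid, np.concatenate([[0.0], t]), np.concatenate([[0.0], plasma]))
    parent = plasma_on_grid * pf_fn(grid)
    out = InputFunction(grid, parent, provenance="measured")
    out.pf_fn = pf_fn  # attach for inspection / tests
    return out


def merge_input_function(
    continuous_time_min: np.ndarray,
    continuous_parent: np.ndarray,
    discrete_time_min: np.ndarray,
    discrete_parent: np.ndarray,
    t_end_min: float = 66.5,
    grid_dt_s: float = 1.0,
) -> InputFunction:
    """Join the early continuous segment with the late discrete samples.

    The continuous segment is kept verbatim up to its end (nominally 10 min);
    beyond it the curve interpolates linearly through the discrete points,
    anchored at the continuous end value so the merged curve is continuous.
    """
    ct = np.asarray(continuous_time_min, dtype=float)
    cv = np.asarray(continuous_parent, dtype=float)
    dt = np.asarray(discrete_time_min, dtype=float)
    dv = np.asarray(discrete_parent, dtype=float)
    t_join = float(ct[-1])
    late = dt > t_join
    tail_t = np.concatenate([[t_join], dt[late]])
    tail_v = np.concatenate([[cv[-1]], dv[late]])
    if tail_t.size > 1 and np.any(np.diff(tail_t) > 20.0):
        warnings.warn("gap of more than 20 min between blood samples in the merged input function")
    grid = np.arange(0.0, t_end_min * 60.0 + grid_dt_s / 2, grid_dt_s) / 60.0
    vals = np.empty_like(grid)
    early = grid <= t_join
    vals[early] = np.interp(grid[early], ct, cv, left=0.0)
    vals[~early] = np.interp(grid[~early], tail_t, tail_v, right=float(tail_v[-1]))
    return InputFunction(grid, vals, provenance="measured")


@dataclass
class PopulationInputFunction:
    """Dose/weight-normalised template averaged across measured curves.

    Each contributing curve is divided by the patient's injected activity
    per body weight (the SUV normaliser), so the template is unitless and can
    be rescaled to any new patient by their own dose/weight.
    """

    time_min: np.ndarray
    template: np.ndarray
    n_patients: int = 0

    def apply(self, meta: PatientMeta) -> InputFunction:
        scale = meta.injected_activity_MBq * 1000.0 / (meta.body_weight_kg * 1000.0)
        return InputFunction(self.time_min.copy(), self.template * scale, provenance="population")


def population_input_function(
    ifs: list[tuple[InputFunction, PatientMeta]]
) -> PopulationInputFunction:
    """Average dose/weight-normalised input functions on a common grid."""
    if not ifs:
        raise ValidationError("population input function needs at least one measured curve")
    ref_grid = ifs[0][0].time_min
    curves = []
    for input_fn, meta in ifs:
        scale = meta.injected_activity_MBq * 1000.0 / (meta.body_weight_kg * 1000.0)
        curves.append(input_fn(ref_grid) / scale)
    template = np.mean(np.stack(curves, axis=0), axis=0)
    return PopulationInputFunction(ref_grid.copy(), template, n_patients=len(ifs))
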