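"""MRI quantification: DCE (extended Tofts), DSC perfusion with leakage
correction and SVD deconvolution, pulsed-ASL CBF, DWI ADC, and
contralateral-white-matter normalisation.

All perfusion outputs are intended to be reported relative to contralateral
white matter (CWM), which removes arbitrary scanner scaling from DSC and
ASL maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import svd

from .core_io import ValidationError, VOIMask
from .pet_kinetics import _convolve_exp

__all__ = [
    "DCEParams",
    "DSCResult",
    "ASLResult",
    "ADCResult",
    "ASL_DEFAULTS",
    "spgr_signal",
    "dce_signal_to_concentration",
    "tofts_concentration",
    "fit_extended_tofts",
    "dsc_quantify",
    "asl_cbf",
    "asl_delta_m",
    "fit_adc",
    "normalize_to_cwm",
]


@dataclass
class DCEParams:
    """Extended-Tofts estimates: Ktrans (/min), kep (/min), vp, ve = Ktrans/kep."""

    Ktrans: float
    kep: float
    vp: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.Ktrans < 0 or self.kep < 0 or self.vp < 0:
            raise ValidationError("DCE parameters must be nonnegative")

    @property
    def ve(self) -> float:
        return self.Ktrans / self.kep if self.kep > 0 else 0.0


@dataclass
class DSCResult:
    """DSC perfusion summary (relative units before CWM normalisation)."""

    cbv: float
    cbv_lc: float
    cbf: float
    mtt_s: float
    ttp_s: float
    k_leak: float


@dataclass
class ASLResult:
    cbf_ml_100g_min: float
    constants: dict = field(default_factory=dict)


@dataclass
class ADCResult:
    adc_mm2_s: float
    s0: float
    n_bvalues: int


#: 3 T pulsed-ASL constants: blood-brain partition coefficient (mL/g),
#: inversion efficiency, blood T1 (s).
ASL_DEFAULTS = {"lambda_blood_partition": 0.9, "inversion_efficiency": 0.98, "T1_blood_s": 1.65}


# ---------------------------------------------------------------------------
# DCE


def spgr_signal(
    R1: np.ndarray, M0: float, TR_s: float, flip_deg: float
) -> np.ndarray:
    """Spoiled-gradient-echo signal S = M0 sin(a) (1-E1)/(1-E1 cos(a))."""
    a = np.deg2rad(flip_deg)
    E1 = np.exp(-TR_s * np.asarray(R1, dtype=float))
    return M0 * np.sin(a) * (1.0 - E1) / (1.0 - E1 * np.cos(a))


def dce_signal_to_concentration(
    signal_series: np.ndarray,
    T10_s: float,
    r1_per_mM_s: float,
    TR_s: float,
    flip_deg: float,
    baseline_frames: int,
    mode: str = "spgr",
) -> np.ndarray:
    """Convert a DCE signal series to gadolinium concentration (mM).

    ``spgr`` inverts the spoiled-gradient-echo signal equation:
    R1(t) is recovered from the signal relative to the pre-contrast
    baseline, and C(t) = (R1(t) - 1/T10) / r1.  ``linear`` uses the
    small-concentration approximation C proportional to dS/S_baseline.
    """
    s = np.asarray(signal_series, dtype=float)
    if np.any(s <= 0):
        raise ValidationError("DCE signal must be positive")
    if T10_s <= 0:
        raise ValidationError("T10 must be positive")
    s0 = float(s[:baseline_frames].mean())
    if mode == "linear":
        return (s - s0) / s0
    a = np.deg2rad(flip_deg)
    R10 = 1.0 / T10_s
    E10 = np.exp(-TR_s * R10)
    # infer M0 sin(a) from baseline signal and known T10
    m0sin = s0 * (1.0 - E10 * np.cos(a)) / (1.0 - E10)
    y = s / m0sin
    E1 = (1.0 - y) / (1.0 - y * np.cos(a))
    if np.any(E1 <= 0) or np.any(E1 >= 1):
        raise ValidationError("signal outside the invertible SPGR range")
    R1 = -np.log(E1) / TR_s
    return (R1 - R10) / r1_per_mM_s


def tofts_concentration(
    t_min: np.ndarray,
    cp: np.ndarray,
    Ktrans: float,
    kep: float,
    vp: float,
) -> np.ndarray:
    """Extended-Tofts forward model on a uniform time grid (minutes).

    Ct(t) = vp Cp(t) + Ktrans * int_0^t Cp(u) exp(-kep (t-u)) du.
    """
    t = np.asarray(t_min, dtype=float)
    dt = float(t[1] - t[0])
    return vp * cp + Ktrans * _convolve_exp(np.asarray(cp, dtype=float), kep, dt)


def fit_extended_tofts(
    t_min: np.ndarray, conc: np.ndarray, plasma_conc: np.ndarray
) -> DCEParams:
    """Least-squares extended-Tofts fit of a tissue concentration curve."""
    t = np.asarray(t_min, dtype=float)
    ct = np.asarray(conc, dtype=float)
    cp = np.asarray(plasma_conc, dtype=float)
    if t.size != ct.size or t.size != cp.size:
        raise ValidationError("time, tissue and plasma series must align")

    def residuals(x: np.ndarray) -> np.ndarray:
        return tofts_concentration(t, cp, x[0], x[1], x[2]) - ct

    best = None
    for x0 in ([0.05, 0.3, 0.02], [0.2, 1.0, 0.05], [0.01, 0.05, 0.01]):
        sol = optimize.least_squares(
            residuals,
            x0,
            bounds=([0.0, 1e-4, 0.0], [5.0, 20.0, 0.5]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    x = best.x
    ktrans = float(x[0])
    if ktrans < 1e-9:
        ktrans = 0.0
    return DCEParams(Ktrans=ktrans, kep=float(x[1]), vp=float(x[2]), converged=bool(best.success))


# ---------------------------------------------------------------------------
# DSC


def _delta_r2star(signal: np.ndarray, baseline_frames: int, TE_s: float) -> np.ndarray:
    s = np.asarray(signal, dtype=float)
    s0 = float(s[:baseline_frames].mean())
    if s0 <= 0 or np.any(s <= 0):
        raise ValidationError("DSC signal must be positive")
    return -np.log(s / s0) / TE_s


def dsc_quantify(
    tissue_signal: np.ndarray,
    aif_signal: np.ndarray,
    TE_s: float,
    baseline_frames: int,
    dt_s: float,
    reference_dr2: np.ndarray | None = None,
    svd_threshold: float = 0.2,
) -> DSCResult:
    """Quantify a DSC bolus passage for one tissue curve.

    ΔR2*(t) = -ln(S/S0)/TE for tissue and AIF.  CBV is the ratio of the
    time integrals.  Leakage is handled by a two-parameter linear fit of the
    tissue curve against a non-enhancing reference curve (typically the
    whole-brain or CWM average, which shares the tissue dispersion; the AIF
    does not) and its running integral; the leakage term is added back to
    form the corrected CBVlc.  Without a reference no correction is applied
    and CBVlc = CBV.  CBF comes from block-circulant SVD deconvolution of
    the tissue curve with the AIF (singular values below ``svd_threshold``
    of the maximum zeroed); MTT = CBV/CBF and TTP is the time of the ΔR2*
    maximum.
    """
    if TE_s <= 0:
        raise ValidationError("TE must be positive")
    if baseline_frames < 5:
        raise ValidationError("DSC needs at least 5 pre-bolus baseline frames")
    dr2_t = _delta_r2star(tissue_signal, baseline_frames, TE_s)
    dr2_a = _delta_r2star(aif_signal, baseline_frames, TE_s)
    int_aif = float(np.trapezoid(dr2_a, dx=dt_s))
    if abs(int_aif) < 1e-12:
        raise ValidationError("AIF integral is approximately zero")

    if reference_dr2 is None:
        k_leak = 0.0
        corrected = dr2_t
    else:
        # Boxerman-style fit: dr2_t ~ k1 * ref - K2 * int(ref); K2 captures
        # the T1/T2* leakage deviation from the non-enhancing reference
        ref = np.asarray(reference_dr2, dtype=float)
        ref_int = np.concatenate([[0.0], np.cumsum((ref[1:] + ref[:-1]) * dt_s / 2.0)])
        X = np.column_stack([ref, ref_int])
        coef, *_ = np.linalg.lstsq(X, dr2_t, rcond=None)
        k_leak = float(-coef[1])  # positive k_leak = T1-dominant leakage
        corrected = dr2_t + k_leak * ref_int

    cbv = float(np.trapezoid(dr2_t, dx=dt_s)) / int_aif
    cbv_lc = float(np.trapezoid(corrected, dx=dt_s)) / int_aif

    # block-circulant SVD deconvolution: aif (*) residue = tissue
    n = dr2_t.size
    m = 2 * n
    a_pad = np.concatenate([dr2_a, np.zeros(m - n)])
    c_pad = np.concatenate([corrected, np.zeros(m - n)])
    A = np.empty((m, m))
    for j in range(m):
        A[:, j] = np.roll(a_pad, j)
    A *= dt_s
    U, s, Vt = svd(A)
    s_inv = np.where(s >= svd_threshold * s.max(), 1.0 / np.where(s > 0, s, 1.0), 0.0)
    residue = Vt.T @ (s_inv * (U.T @ c_pad))
    # residue peak is flow in 1/s on the same relative scale as the
    # unitless cbv above, so mtt = cbv/cbf comes out in seconds
    cbf = float(np.max(residue[:n]))
    mtt_s = cbv / cbf if cbf > 0 else float("inf")
    ttp_s = float(np.argmax(dr2_t) * dt_s)
    return DSCResult(cbv=cbv, cbv_lc=cbv_lc, cbf=cbf, mtt_s=mtt_s, ttp_s=ttp_s, k_leak=k_leak)


# ---------------------------------------------------------------------------
# ASL


def asl_cbf(
    delta_M: float | np.ndarray,
    M0: float | np.ndarray,
    TI1_s: float,
    TI2_s: float,
    constants: dict | None = None,
) -> ASLResult:
    """QUIPSS-II pulsed-ASL perfusion quantification.

    CBF = 6000 * lambda * dM / (2 * alpha * M0 * TI1 * exp(-TI2/T1b)) in
    mL/100 g/min.
    """
    c = dict(ASL_DEFAULTS)
    if constants:
        c.update(constants)
    M0 = np.asarray(M0, dtype=float)
    if np.any(M0 <= 0):
        raise ValidationError("M0 must be positive")
    lam = c["lambda_blood_partition"]
    alpha = c["inversion_efficiency"]
    t1b = c["T1_blood_s"]
    cbf = 6000.0 * lam * np.asarray(delta_M, dtype=float) / (
        2.0 * alpha * M0 * TI1_s * np.exp(-TI2_s / t1b)
    )
    c.update({"TI1_s": TI1_s, "TI2_s": TI2_s})
    return ASLResult(cbf_ml_100g_min=cbf if cbf.ndim else float(cbf), constants=c)


def asl_delta_m(
    cbf_ml_100g_min: float | np.ndarray,
    M0: float | np.ndarray,
    TI1_s: float,
    TI2_s: float,
    constants: dict | None = None,
) -> np.ndarray:
    """Forward pulsed-ASL model: the label-control difference for a CBF."""
    c = dict(ASL_DEFAULTS)
    if constants:
        c.update(constants)
    return (
        np.asarray(cbf_ml_100g_min, dtype=float)
        * 2.0
        * c["inversion_efficiency"]
        * np.asarray(M0, dtype=float)
        * TI1_s
        * np.exp(-TI2_s / c["T1_blood_s"])
        / (6000.0 * c["lambda_blood_partition"])
    )


# ---------------------------------------------------------------------------
# DWI


def fit_adc(signals: np.ndarray, b_values_s_mm2: np.ndarray) -> ADCResult:
    """Log-linear least squares of ln(S) against b; ADC = -slope (mm^2/s)."""
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values_s_mm2, dtype=float)
    if np.unique(b).size < 2:
        raise ValidationError("ADC needs at least 2 distinct b-values")
    if np.any(s <= 0):
        raise ValidationError("DWI signals must be positive")
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return ADCResult(adc_mm2_s=float(-slope), s0=float(np.exp(intercept)), n_bvalues=int(b.size))


# ---------------------------------------------------------------------------
# normalisation


def normalize_to_cwm(
    map_values: np.ndarray,
    cwm_mask: "VOIMask | np.ndarray | None" = None,
    cwm_values: np.ndarray | None = None,
) -> np.ndarray:
    """Divide a parameter map (or region value) by the CWM mean.

    The reference is either the masked portion of ``map_values`` (pass
    ``cwm_mask``) or an explicit sample of CWM values (pass ``cwm_values``,
    useful for region-level tables).
    """
    vals = np.asarray(map_values, dtype=float)
    if cwm_values is not None:
        ref = np.asarray(cwm_values, dtype=float)
        if ref.size == 0:
            raise ValidationError("CWM reference values are empty")
        cwm_mean = float(ref.mean())
    else:
        if cwm_mask is None:
            raise ValidationError("provide cwm_mask or cwm_values")
        mask = (
            cwm_mask.voxels if isinstance(cwm_mask, VOIMask) else np.asarray(cwm_mask, dtype=bool)
        )
        if not np.any(mask):
            raise ValidationError("CWM mask is empty")
        if vals.shape != mask.shape:
            raise ValidationError("map and CWM mask shapes differ")
        cwm_mean = float(vals[mask].mean())
    if cwm_mean <= 0:
        raise ValidationError("CWM mean must be positive")
    return vals / cwm_mean
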