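"""Static PET quantification: SUV, blood-pool correction, tumour-to-brain
ratios, fractional-threshold masks and mask-overlap scores.

SUV normalises activity concentration by injected dose per body weight
(tissue density taken as 1 g/mL), so SUV = C[kBq/mL] / (dose[MBq] /
weight[kg]).  The blood-pool correction subtracts a normalised whole-blood
SUV measured in the superior sagittal sinus: SUVc = SUV - f_b * SUV_sinus,
where f_b is a nominal cerebral blood volume fraction (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import DynamicImage, PatientMeta, ValidationError, VOIMask

__all__ = [
    "SUVImage",
    "OverlapResult",
    "compute_suv",
    "static_window",
    "blood_correct",
    "tbr",
    "threshold_mask",
    "dice",
    "volume_variation",
]


@dataclass
class SUVImage:
    """Unitless 3-D SUV grid with window provenance."""

    voxels: np.ndarray
    affine: np.ndarray
    window: str = "static_frame"
    corrected: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("SUV image contains non-finite values")


@dataclass
class OverlapResult:
    """Mask agreement: DICE plus the signed percent volume variation."""

    dice: float
    volume_variation_percent: float
    volume_mri_mL: float
    volume_suv_mL: float


def compute_suv(
    frame_values_kBq_mL: np.ndarray,
    meta: PatientMeta,
    affine: np.ndarray | None = None,
    window: str = "static_frame",
) -> SUVImage:
    """SUV = C / (injected activity / body weight), density 1 g/mL.

    Dose in MBq over weight in kg gives kBq/g = kBq/mL, so the ratio is
    unitless.
    """
    if meta.injected_activity_MBq <= 0 or meta.body_weight_kg <= 0:
        raise ValidationError("dose and weight must be positive for SUV")
    norm = meta.injected_activity_MBq * 1000.0 / (meta.body_weight_kg * 1000.0)
    vox = np.asarray(frame_values_kBq_mL, dtype=float) / norm
    if affine is None:
        affine = np.eye(4)
    return SUVImage(vox, np.asarray(affine, dtype=float), window=window)


def static_window(image: DynamicImage, mode: str = "last5_mean") -> np.ndarray:
    """Collapse a dynamic image to the static analysis window.

    ``last5_mean`` is the duration-weighted mean of the final five frames
    (26 min for the clinical schedule); ``frame_nearest_60`` picks the
    single frame whose mid-time is closest to 60 min.  Note that on the
    clinical schedule no frame has mid-time exactly 60 min; the closest is
    the 55.5-60.5 min frame (mid-time 58 min).
    """
    mids = image.schedule.mid_times_min
    if mode == "last5_mean":
        if len(image.schedule) < 5:
            raise ValidationError("last5_mean needs at least 5 frames")
        dur = image.schedule.frame_duration_s[-5:]
        frames = image.voxels[..., -5:]
        return np.tensordot(frames, dur / dur.sum(), axes=([3], [0]))
    if mode == "frame_nearest_60":
        idx = int(np.argmin(np.abs(mids - 60.0)))
        return image.voxels[..., idx].copy()
    raise ValidationError(f"unknown static window mode '{mode}'")


def blood_correct(suv: SUVImage, sinus: VOIMask, blood_fraction: float = 0.05) -> SUVImage:
    """Subtract the normalised blood-pool SUV: SUVc = SUV - f_b * mean sinus SUV."""
    if sinus.n_voxels == 0:
        raise ValidationError("sinus mask is empty")
    if not 0.0 <= blood_fraction <= 1.0:
        raise ValidationError("blood_fraction must lie in [0, 1]")
    sinus_mean = float(suv.voxels[sinus.voxels].mean())
    out = suv.voxels - blood_fraction * sinus_mean
    return SUVImage(out, suv.affine, window=suv.window, corrected=True)


def tbr(suv: SUVImage, tumour: VOIMask, contralateral: VOIMask) -> dict[str, float]:
    """Tumour-to-brain ratios: tumour SUVmax (and SUVmean) over
    contralateral SUVmean."""
    if tumour.n_voxels == 0 or contralateral.n_voxels == 0:
        raise ValidationError("tumour and contralateral masks must be non-empty")
    contra_mean = float(suv.voxels[contralateral.voxels].mean())
    if contra_mean <= 0:
        raise ValidationError("contralateral mean SUV must be positive")
    tum = suv.voxels[tumour.voxels]
    return {
        "tbr_max": float(tum.max()) / contra_mean,
        "tbr_mean": float(tum.mean()) / contra_mean,
    }


def threshold_mask(suv: SUVImage, fraction: float, search: VOIMask) -> VOIMask:
    """Fractional-SUVmax threshold segmentation within a search region.

    Voxels at or above ``fraction * SUVmax`` (SUVmax taken within the search
    region) are kept, restricted to the 26-connected component containing
    the hottest voxel; without the connectivity restriction low-uptake scans
    would pick up disconnected background.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("threshold fraction must lie in (0, 1)")
    if search.n_voxels == 0:
        raise ValidationError("search region is empty")
    region_vals = suv.voxels[search.voxels]
    vmax = float(region_vals.max())
    if vmax <= 0:
        raise ValidationError("no positive SUV within the search region")
    above = (suv.voxels >= fraction * vmax) & search.voxels
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    # component containing the hottest voxel of the search region
    masked = np.where(search.voxels, suv.voxels, -np.inf)
    hot = np.unravel_index(int(np.argmax(masked)), suv.voxels.shape)
    keep = labels == labels[hot]
    role = f"suv{int(round(fraction * 100))}"
    return VOIMask(keep, search.affine, role=role)


def dice(a: VOIMask, b: VOIMask) -> float:
    """DICE overlap 2|A n B| / (|A| + |B|); symmetric in its arguments."""
    if a.voxels.shape != b.voxels.shape:
        raise ValidationError("masks must share a grid for DICE")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValidationError("DICE undefined for two empty masks")
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def volume_variation(mri: VOIMask, suv: VOIMask) -> float:
    """Signed percent volume variation ((V_mri - V_suv) / V_suv) * 100.

    Not symmetric: the MRI-defined volume is compared against the SUV
    threshold volume, matching the clinical reporting convention.
    """
    v_suv = suv.volume_mL()
    if v_suv <= 0:
        raise ValidationError("SUV mask is empty; volume variation undefined")
    v_mri = mri.volume_mL()
    return (v_mri - v_suv) / v_suv * 100.0


def overlap(mri: VOIMask, suv: VOIMask) -> OverlapResult:
    """DICE and volume variation for an MRI-vs-SUV mask pair."""
    return OverlapResult(
        dice=dice(mri, suv),
        volume_variation_percent=volume_variation(mri, suv),
        volume_mri_mL=mri.volume_mL(),
        volume_suv_mL=suv.volume_mL(),
    )
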