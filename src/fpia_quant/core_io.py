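"""Timed 4-D imaging containers, NIfTI/CSV study IO and TAC extraction.

Activity volumes are assumed decay-corrected to injection time by the
scanner reconstruction; no further decay handling is applied here.  The
frame schedule is stored in seconds; all kinetic fitting downstream works
in minutes, because rate constants in this field are reported per minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CLINICAL_FRAME_SPEC",
    "FrameSchedule",
    "DynamicImage",
    "VOIMask",
    "PatientMeta",
    "TissueTAC",
    "Study",
    "parse_frame_schedule",
    "frame_mid_times",
    "extract_tac",
    "resample_mask",
    "load_study",
    "save_study",
]

#: Clinical acquisition protocol: 10x15 s, 3x60 s, 5x120 s, 9x300 s, 1x360 s
#: for a 66.5 min dynamic scan.
CLINICAL_FRAME_SPEC: tuple[tuple[int, float], ...] = (
    (10, 15.0),
    (3, 60.0),
    (5, 120.0),
    (9, 300.0),
    (1, 360.0),
)

MASK_ROLES = frozenset(
    {"lesion_flair", "lesion_t1ce", "contralateral", "cwm", "sinus", "suv30", "suv40"}
)


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (seconds) of a dynamic acquisition."""

    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        dur = np.asarray(self.frame_duration_s, dtype=float)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise ValidationError("frame starts/durations must be 1-D, same length")
        if start.size == 0:
            raise ValidationError("empty frame schedule")
        if np.any(dur <= 0):
            raise ValidationError("frame durations must be strictly positive")
        if np.any(np.diff(start) < 0):
            raise ValidationError("frame starts must be nondecreasing")
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_duration_s", dur)

    def __len__(self) -> int:
        return int(self.frame_start_s.size)

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s

    @property
    def total_duration_s(self) -> float:
        return float(np.sum(self.frame_duration_s))

    @property
    def mid_times_min(self) -> np.ndarray:
        return frame_mid_times(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_start_s": self.frame_start_s, "frame_duration_s": self.frame_duration_s}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrameSchedule":
        return cls(
            np.asarray(df["frame_start_s"], dtype=float),
            np.asarray(df["frame_duration_s"], dtype=float),
        )


def parse_frame_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Expand a ``(count, duration_s)`` protocol into a contiguous schedule.

    The schedule starts at t=0 and frame ``i+1`` starts where frame ``i``
    ends, so the total duration is ``sum(count * duration)``.
    """
    durations: list[float] = []
    for count, dur in spec:
        if int(count) != count or count < 1:
            raise ValidationError(f"frame count must be a positive integer, got {count}")
        if dur <= 0:
            raise ValidationError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    dur_arr = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(dur_arr)[:-1]])
    return FrameSchedule(starts, dur_arr)


def frame_mid_times(schedule: FrameSchedule) -> np.ndarray:
    """Mid-frame times in minutes: (start + duration/2) / 60."""
    return (schedule.frame_start_s + schedule.frame_duration_s / 2.0) / 60.0


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError("affine must be 4x4")
    return affine


def _voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class DynamicImage:
    """4-D activity concentration (kBq/mL) with acquisition timing.

    ``voxels`` is (x, y, z, frame), decay-corrected to injection time.
    """

    voxels: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = _check_affine(self.affine)
        if self.voxels.ndim != 4:
            raise ValidationError("dynamic image must be 4-D (x, y, z, frame)")
        if self.voxels.shape[3] != len(self.schedule):
            raise ValidationError(
                f"frame axis length {self.voxels.shape[3]} does not match "
                f"schedule length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("dynamic image contains non-finite values")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return _voxel_size_from_affine(self.affine)

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class VOIMask:
    """Binary volume of interest on a reference grid."""

    voxels: np.ndarray
    affine: np.ndarray
    role: str = "lesion_flair"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.affine = _check_affine(self.affine)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return _voxel_size_from_affine(self.affine)

    def volume_mL(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class PatientMeta:
    """Injection and demographic data needed for SUV and grouping."""

    patient_id: str
    injected_activity_MBq: float
    body_weight_kg: float
    grade_label: str = "LGG"
    who_grade: int = 2

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0 or self.body_weight_kg <= 0:
            raise ValidationError("injected activity and body weight must be positive")
        if self.grade_label not in {"LGG", "HGG"}:
            raise ValidationError("grade_label must be LGG or HGG")
        if self.who_grade not in {2, 3, 4}:
            raise ValidationError("who_grade must be 2, 3 or 4")
        if not (50.0 <= self.injected_activity_MBq <= 1000.0):
            import warnings

            warnings.warn(
                f"injected activity {self.injected_activity_MBq} MBq outside the "
                "plausible 50-1000 MBq range",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "injected_activity_MBq": self.injected_activity_MBq,
            "body_weight_kg": self.body_weight_kg,
            "grade_label": self.grade_label,
            "who_grade": self.who_grade,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatientMeta":
        return cls(
            patient_id=str(d["patient_id"]),
            injected_activity_MBq=float(d["injected_activity_MBq"]),
            body_weight_kg=float(d["body_weight_kg"]),
            grade_label=str(d.get("grade_label", "LGG")),
            who_grade=int(d.get("who_grade", 2)),
        )


@dataclass
class TissueTAC:
    """Region time-activity curve at frame mid-times (minutes, kBq/mL)."""

    mid_time_min: np.ndarray
    value_kBq_mL: np.ndarray
    statistic: str = "mean"
    region: str = ""

    def __post_init__(self) -> None:
        self.mid_time_min = np.asarray(self.mid_time_min, dtype=float)
        self.value_kBq_mL = np.asarray(self.value_kBq_mL, dtype=float)
        if self.mid_time_min.shape != self.value_kBq_mL.shape:
            raise ValidationError("TAC time and value arrays differ in length")
        if np.any(np.diff(self.mid_time_min) <= 0):
            raise ValidationError("TAC mid-times must be strictly increasing")
        if self.statistic not in {"mean", "max"}:
            raise ValidationError("statistic must be 'mean' or 'max'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.mid_time_min, "value": self.value_kBq_mL})


def extract_tac(image: DynamicImage, mask: VOIMask, statistic: str = "mean") -> TissueTAC:
    """Per-frame mean or max of the masked voxels."""
    if mask.voxels.shape != image.shape3d:
        raise ValidationError(
            f"mask grid {mask.voxels.shape} does not match image grid {image.shape3d}"
        )
    if mask.n_voxels == 0:
        raise ValidationError(f"mask '{mask.role}' is empty")
    vals = image.voxels[mask.voxels]  # (n_voxels, n_frames)
    if statistic == "mean":
        curve = vals.mean(axis=0)
    elif statistic == "max":
        curve = vals.max(axis=0)
    else:
        raise ValidationError("statistic must be 'mean' or 'max'")
    return TissueTAC(image.schedule.mid_times_min, curve, statistic=statistic, region=mask.role)


def resample_mask(
    mask: VOIMask, target_affine: np.ndarray, target_shape: tuple[int, int, int]
) -> VOIMask:
    """Nearest-neighbour resampling of a mask onto a target grid.

    Resampling a mask onto its own grid is the identity.
    """
    target_affine = _check_affine(target_affine)
    if (
        mask.voxels.shape == tuple(target_shape)
        and np.allclose(mask.affine, target_affine, atol=1e-6)
    ):
        return VOIMask(mask.voxels.copy(), target_affine.copy(), role=mask.role)
    # target index -> world -> source index
    xform = np.linalg.inv(mask.affine) @ target_affine
    out = ndimage.affine_transform(
        mask.voxels.astype(np.float32),
        matrix=xform[:3, :3],
        offset=xform[:3, 3],
        output_shape=tuple(target_shape),
        order=0,
        mode="constant",
        cval=0.0,
    )
    return VOIMask(out > 0.5, target_affine.copy(), role=mask.role)


@dataclass
class Study:
    """All inputs for one patient, on the PET quantification grid."""

    pet: DynamicImage
    masks: dict[str, VOIMask]
    meta: PatientMeta
    blood: "object | None" = None  # BloodSeries, untyped to avoid a cycle
    mri: dict = field(default_factory=dict)
    truth: dict | None = None


def _save_nifti(arr: np.ndarray, affine: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine, dtype=float)


def save_study(study: Study, out_dir: str | Path) -> Path:
    """Write a study to a directory of NIfTI / CSV / JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save_nifti(study.pet.voxels, study.pet.affine, out / "pet_dynamic.nii.gz")
    study.pet.schedule.to_frame().to_csv(out / "schedule.csv", index=False)
    for role, mask in study.masks.items():
        _save_nifti(mask.voxels.astype(np.uint8), mask.affine, out / f"mask_{role}.nii.gz")
    (out / "meta.json").write_text(json.dumps(study.meta.to_dict(), indent=2))
    if study.blood is not None:
        study.blood.continuous_frame().to_csv(out / "blood_continuous.csv", index=False)
        study.blood.discrete_frame().to_csv(out / "blood_discrete.csv", index=False)
    if study.mri:
        params: dict = {}
        for name, series in study.mri.items():
            sdict = dict(series)
            for key in ("signal", "delta_m", "m0"):
                if key in sdict:
                    _save_nifti(sdict.pop(key), study.pet.affine, out / f"mri_{name}_{key}.nii.gz")
            params[name] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in sdict.items()
            }
        (out / "mri_params.json").write_text(json.dumps(params, indent=2))
    if study.truth is not None:
        (out / "truth.json").write_text(json.dumps(study.truth, indent=2, default=_jsonify))
    return out


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")


def load_study(study_dir: str | Path, affine_tol_mm: float = 1e-3) -> Study:
    """Load a study directory; masks are resampled onto the PET grid.

    Raises distinct errors for missing files, frame-count mismatches and
    affine mismatches beyond tolerance (masks are nearest-neighbour
    resampled when their grid differs from the PET grid).
    """
    from .blood import BloodSeries  # local import to avoid a cycle

    d = Path(study_dir)
    pet_path = d / "pet_dynamic.nii.gz"
    sched_path = d / "schedule.csv"
    meta_path = d / "meta.json"
    for p in (pet_path, sched_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"required study file missing: {p}")
    vox, affine = _load_nifti(pet_path)
    schedule = FrameSchedule.from_frame(pd.read_csv(sched_path))
    if vox.ndim != 4 or vox.shape[3] != len(schedule):
        raise ValidationError(
            f"PET frame count {vox.shape[-1] if vox.ndim == 4 else 'n/a'} does not "
            f"match schedule length {len(schedule)}"
        )
    pet = DynamicImage(vox, affine, schedule)
    masks: dict[str, VOIMask] = {}
    for p in sorted(d.glob("mask_*.nii.gz")):
        role = p.stem.replace(".nii", "").removeprefix("mask_")
        mvox, maff = _load_nifti(p)
        mask = VOIMask(mvox > 0.5, maff, role=role)
        if mask.voxels.shape != pet.shape3d or not np.allclose(
            maff, affine, atol=affine_tol_mm
        ):
            mask = resample_mask(mask, affine, pet.shape3d)
        masks[role] = mask
    meta = PatientMeta.from_dict(json.loads(meta_path.read_text()))
    blood = None
    if (d / "blood_continuous.csv").exists() and (d / "blood_discrete.csv").exists():
        blood = BloodSeries.from_frames(
            pd.read_csv(d / "blood_continuous.csv"), pd.read_csv(d / "blood_discrete.csv")
        )
    mri: dict = {}
    if (d / "mri_params.json").exists():
        params = json.loads((d / "mri_params.json").read_text())
        for name, sdict in params.items():
            series = {
                k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
                for k, v in sdict.items()
            }
            for key in ("signal", "delta_m", "m0"):
                p = d / f"mri_{name}_{key}.nii.gz"
                if p.exists():
                    series[key], _ = _load_nifti(p)
            mri[name] = series
    truth = None
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())
    return Study(pet=pet, masks=masks, meta=meta, blood=blood, mri=mri, truth=truth)
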