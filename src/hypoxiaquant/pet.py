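"""PET hypoxia quantification.

Converts activity-concentration volumes to standardized uptake values (SUV),
normalizes to the blood-pool background measured in an aortic VOI to obtain
tumor-to-background ratios (TBR), and summarizes a tumor VOI by TBRmax,
TBRpeak, hypoxic volume (HV) and a binary hypoxic classification.

Definitions
-----------
SUV      activity concentration / (injected dose / body weight); with
         concentration in kBq/mL, dose in kBq, weight in g and tissue density
         taken as 1 g/mL the quantity is dimensionless.
TBR      voxel SUV divided by the mean SUV over the aorta VOI.
TBRmax   maximum TBR over the tumor VOI.
TBRpeak  mean TBR over the TBRmax voxel and its 26-connected 3D neighbors,
         restricted to the tumor VOI.
HV       total volume (mL) of tumor voxels with TBR strictly above a
         threshold (default 1.4); tumors with HV strictly above 1 mL are
         classified hypoxic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ActivityVolume",
    "SUVVolume",
    "TBRVolume",
    "HypoxiaMetrics",
    "activity_to_suv",
    "compute_tbr",
    "compute_hypoxia_metrics",
]


@dataclass(frozen=True)
class ActivityVolume:
    """3D activity-concentration grid (kBq/mL) with acquisition scalars.

    ``injected_dose_kbq`` must already be decay-corrected to scan time;
    decay correction is the caller's responsibility.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    injected_dose_kbq: float
    patient_weight_g: float

    def __post_init__(self) -> None:
        _check_volume(self.values, self.spacing_mm)
        if self.injected_dose_kbq <= 0:
            raise ValidationError("injected dose must be positive")
        if self.patient_weight_g <= 0:
            raise ValidationError("patient weight must be positive")


@dataclass(frozen=True)
class SUVVolume:
    """Dimensionless SUV per voxel with physical voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        _check_volume(self.values, self.spacing_mm)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass(frozen=True)
class TBRVolume:
    """Per-voxel tumor-to-background ratio and the background SUV used."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    background_suv: float

    def __post_init__(self) -> None:
        _check_volume(self.values, self.spacing_mm)
        if self.background_suv <= 0:
            raise ValidationError("background SUV must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass(frozen=True)
class HypoxiaMetrics:
    tbr_max: float
    tbr_peak: float
    hv_ml: float
    is_hypoxic: bool
    n_hypoxic_voxels: int
    background_suv: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "tbr_max": self.tbr_max,
            "tbr_peak": self.tbr_peak,
            "hv_ml": self.hv_ml,
            "is_hypoxic": self.is_hypoxic,
            "n_hypoxic_voxels": self.n_hypoxic_voxels,
            "background_suv": self.background_suv,
        }


def _check_volume(values: np.ndarray, spacing_mm) -> None:
    if np.asarray(values).ndim != 3:
        raise ValidationError("volume must be 3-dimensional")
    if len(spacing_mm) != 3 or any(s <= 0 for s in spacing_mm):
        raise ValidationError("spacing must be three positive values (mm)")


def _check_mask(mask: np.ndarray, shape: tuple, name: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValidationError(f"{name} mask shape {mask.shape} != volume shape {shape}")
    if not mask.any():
        raise ValidationError(f"{name} mask is empty")
    return mask


def activity_to_suv(vol: ActivityVolume) -> SUVVolume:
    """Convert activity concentration to SUV.

    SUV = concentration / (injected_dose / patient_weight); with kBq/mL over
    kBq/g the units cancel at unit tissue density.
    """
    norm = vol.injected_dose_kbq / vol.patient_weight_g
    return SUVVolume(np.asarray(vol.values, dtype=float) / norm, tuple(vol.spacing_mm))


def compute_tbr(suv: SUVVolume, aorta: np.ndarray) -> TBRVolume:
    """Divide every voxel SUV by the mean SUV over the aorta VOI."""
    aorta = _check_mask(aorta, suv.values.shape, "aorta")
    background = float(np.mean(suv.values[aorta]))
    if background <= 0:
        raise ValidationError("mean aorta SUV must be positive")
    return TBRVolume(suv.values / background, tuple(suv.spacing_mm), background)


def _neighborhood_mean(tbr: np.ndarray, tumor: np.ndarray, idx: tuple[int, int, int]) -> float:
    """Mean TBR over a voxel and its 26-connected neighbors inside the VOI.

    Uses exact summation so the result does not depend on traversal order.
    """
    shape = tbr.shape
    members = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        j = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
        if all(0 <= j[k] < shape[k] for k in range(3)) and tumor[j]:
            members.append(tbr[j])
    return math.fsum(members) / len(members)


def compute_hypoxia_metrics(
    tbr: TBRVolume,
    tumor: np.ndarray,
    tbr_threshold: float = 1.4,
    hv_threshold_ml: float = 1.0,
) -> HypoxiaMetrics:
    """Summarize a tumor VOI of a TBR map.

    TBRpeak averages the TBRmax voxel with its in-VOI 26-neighborhood; when
    several voxels tie for TBRmax, every argmax neighborhood is evaluated and
    the largest mean is reported (deterministic, order-independent). Both the
    TBR and the HV thresholds are strict inequalities.
    """
    tumor = _check_mask(tumor, tbr.values.shape, "tumor")
    values = tbr.values
    in_voi = values[tumor]
    tbr_max = float(in_voi.max())

    argmax = np.argwhere(tumor & (values == tbr_max))
    tbr_peak = max(
        _neighborhood_mean(values, tumor, tuple(idx)) for idx in argmax
    )

    n_hypoxic = int(np.count_nonzero(tumor & (values > tbr_threshold)))
    hv_ml = n_hypoxic * tbr.voxel_volume_ml
    return HypoxiaMetrics(
        tbr_max=tbr_max,
        tbr_peak=float(tbr_peak),
        hv_ml=float(hv_ml),
        is_hypoxic=bool(hv_ml > hv_threshold_ml),
        n_hypoxic_voxels=n_hypoxic,
        background_suv=tbr.background_suv,
    )
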