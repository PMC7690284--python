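"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the raw data the quantification modules consume:

* :func:`generate_pet_phantom` — a 3D SUV volume containing a spherical
  tumor with a hotter hypoxic sub-sphere, over a uniform background, plus a
  disjoint spherical aorta VOI at the blood-pool SUV;
* :func:`generate_ihc_image` — an RGB brightfield image of elliptical
  hematoxylin- and DAB-stained nuclei mixed by Beer–Lambert optical density
  (I = I0·10^−OD), nuclei placed without overlap by rejection sampling;
* :func:`generate_survival_cohort` — a cohort whose hazard switches at a
  known biomarker cut-off, with exponential event times (closed-form group
  medians ln2/λ) and optional censoring;
* :func:`generate_array_table` — paired cytokine-array membranes (NPS/HPS)
  with replicate spots, shared positive/negative controls and programmed
  per-analyte fold inductions.

Every generator is a pure function of its spec: the same seed reproduces
bit-identical output. Ground-truth records carry enough information to
compute each downstream metric analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError, LayoutError
from .ihc import HDAB_STAIN_MATRIX
from .pet import SUVVolume

__all__ = [
    "PetPhantomSpec",
    "PetPhantom",
    "IhcPhantomSpec",
    "IhcPhantom",
    "CohortSpec",
    "SurvivalCohort",
    "ArrayLayout",
    "generate_pet_phantom",
    "generate_ihc_image",
    "generate_survival_cohort",
    "generate_array_table",
]


# --------------------------------------------------------------------------
# PET phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PetPhantomSpec:
    """Spherical-region PET phantom.

    Centers and radii are in mm in the grid's physical frame (voxel centers
    at (i + 0.5)·spacing). SUV levels are dimensionless; the defaults give a
    tumor at TBR 1.2 (below the 1.4 hypoxia threshold) with a hypoxic core
    at TBR 2.0 over an aorta blood pool at SUV 1.0.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_center_mm: tuple[float, float, float] = (64.0, 64.0, 64.0)
    tumor_radius_mm: float = 20.0
    hypoxic_center_mm: tuple[float, float, float] = (64.0, 64.0, 64.0)
    hypoxic_radius_mm: float = 9.0
    aorta_center_mm: tuple[float, float, float] = (20.0, 20.0, 64.0)
    aorta_radius_mm: float = 8.0
    background_suv: float = 0.5
    aorta_suv: float = 1.0
    tumor_suv: float = 1.2
    hypoxic_suv: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("grid shape and spacing must be positive")
        for name in ("tumor_radius_mm", "hypoxic_radius_mm", "aorta_radius_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.aorta_suv <= 0:
            raise ConfigurationError("aorta SUV must be positive")
        d_ht = math.dist(self.hypoxic_center_mm, self.tumor_center_mm)
        if d_ht + self.hypoxic_radius_mm > self.tumor_radius_mm:
            raise ConfigurationError("hypoxic sphere must lie inside the tumor sphere")
        d_at = math.dist(self.aorta_center_mm, self.tumor_center_mm)
        if d_at <= self.aorta_radius_mm + self.tumor_radius_mm:
            raise ConfigurationError("aorta sphere must be disjoint from the tumor sphere")


@dataclass(frozen=True)
class PetPhantom:
    suv: SUVVolume
    tumor_mask: np.ndarray
    aorta_mask: np.ndarray
    ground_truth: dict


def _sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    """Voxels whose *center* lies inside the analytic sphere (inclusive)."""
    axes = [
        (np.arange(n) + 0.5) * s - c
        for n, s, c in zip(shape, spacing, center_mm)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= radius_mm**2


def generate_pet_phantom(spec: PetPhantomSpec) -> PetPhantom:
    """Build the SUV volume, VOI masks and analytic ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm
    tumor = _sphere_mask(shape, spacing, spec.tumor_center_mm, spec.tumor_radius_mm)
    hypoxic = _sphere_mask(shape, spacing, spec.hypoxic_center_mm, spec.hypoxic_radius_mm)
    aorta = _sphere_mask(shape, spacing, spec.aorta_center_mm, spec.aorta_radius_mm)

    values = np.full(shape, spec.background_suv, dtype=float)
    values[aorta] = spec.aorta_suv
    values[tumor] = spec.tumor_suv
    values[hypoxic] = spec.hypoxic_suv
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)

    voxel_ml = float(np.prod(spacing)) / 1000.0
    n_hyp = int(hypoxic.sum())
    ground_truth = {
        "n_hypoxic_voxels": n_hyp,
        "hv_ml_voxel": n_hyp * voxel_ml,
        "hv_ml_analytic": (4.0 / 3.0) * math.pi * spec.hypoxic_radius_mm**3 / 1000.0,
        "tbr_background": spec.background_suv / spec.aorta_suv,
        "tbr_tumor": spec.tumor_suv / spec.aorta_suv,
        "tbr_hypoxic": spec.hypoxic_suv / spec.aorta_suv,
        "voxel_volume_ml": voxel_ml,
        "seed": spec.seed,
    }
    return PetPhantom(
        suv=SUVVolume(values, tuple(spacing)),
        tumor_mask=tumor,
        aorta_mask=aorta,
        ground_truth=ground_truth,
    )


# --------------------------------------------------------------------------
# IHC phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IhcPhantomSpec:
    """Brightfield H-DAB slide phantom.

    Nuclei are ellipses with semi-axes drawn uniformly from
    ``nucleus_axes_um`` and random orientation, placed without overlap.
    DAB-positive nuclei carry the DAB chromogen plus a reduced hematoxylin
    counterstain; negatives carry hematoxylin only. Pixel intensities follow
    I_c = I0·10^(−OD_c) per channel, then optional Gaussian noise, then
    8-bit quantization.
    """

    image_size_px: tuple[int, int] = (600, 600)
    pixel_size_um: float = 0.5
    n_nuclei: int = 100
    dab_positive_fraction: float = 0.3
    nucleus_axes_um: tuple[float, float] = (2.5, 4.5)
    hematoxylin_od: float = 0.6
    dab_od: float = 0.8
    stain_matrix: np.ndarray = field(default_factory=lambda: HDAB_STAIN_MATRIX.copy())
    background_intensity: float = 255.0
    noise_sd: float = 0.0
    seed: int = 0
    counterstain_fraction: float = 0.4  # hematoxylin carried by DAB+ nuclei
    max_placement_attempts: int = 200

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.image_size_px) or self.pixel_size_um <= 0:
            raise ConfigurationError("image size and pixel size must be positive")
        if not 0.0 <= self.dab_positive_fraction <= 1.0:
            raise ConfigurationError("dab_positive_fraction must be in [0, 1]")
        if self.n_nuclei < 0 or self.noise_sd < 0:
            raise ConfigurationError("n_nuclei and noise_sd must be non-negative")
        lo, hi = self.nucleus_axes_um
        if not 0 < lo <= hi:
            raise ConfigurationError("nucleus_axes_um must be an increasing positive range")
        m = np.asarray(self.stain_matrix, dtype=float)
        if m.shape != (3, 3) or not np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-6):
            raise ConfigurationError("stain matrix rows must be unit-norm OD vectors")


@dataclass(frozen=True)
class IhcPhantom:
    image: np.ndarray         # uint8 RGB
    roi_mask: np.ndarray      # bool, full frame
    ground_truth: dict


def generate_ihc_image(spec: IhcPhantomSpec) -> IhcPhantom:
    """Rasterize non-overlapping stained nuclei into an 8-bit RGB image."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    px = spec.pixel_size_um
    max_r_px = spec.nucleus_axes_um[1] / px
    margin_px = 2.0  # keep 8-connected components separated after rasterization

    centers: list[tuple[float, float]] = []
    params: list[tuple[float, float, float]] = []  # a_px, b_px, angle
    for _ in range(spec.n_nuclei):
        placed = False
        for _attempt in range(spec.max_placement_attempts):
            cy = rng.uniform(max_r_px, h - max_r_px)
            cx = rng.uniform(max_r_px, w - max_r_px)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= (2 * max_r_px + margin_px) ** 2
                for oy, ox in centers
            ):
                a = rng.uniform(*spec.nucleus_axes_um) / px
                b = rng.uniform(*spec.nucleus_axes_um) / px
                params.append((a, b, rng.uniform(0, math.pi)))
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei "
                f"in {h}x{w} px after {spec.max_placement_attempts} attempts each"
            )

    n_pos = int(round(spec.dab_positive_fraction * spec.n_nuclei))
    is_positive = np.zeros(spec.n_nuclei, dtype=bool)
    if spec.n_nuclei:
        is_positive[rng.choice(spec.n_nuclei, size=n_pos, replace=False)] = True

    m = np.asarray(spec.stain_matrix, dtype=float)
    hema_vec, dab_vec = m[0], m[1]
    od = np.zeros((h, w, 3), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), (a, b, ang), pos in zip(centers, params, is_positive):
        # evaluate only a local window around the nucleus
        r = int(math.ceil(max(a, b))) + 1
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        dy = (yy[y0:y1, x0:x1] + 0.5) - cy
        dx = (xx[y0:y1, x0:x1] + 0.5) - cx
        u = dy * math.cos(ang) + dx * math.sin(ang)
        v = -dy * math.sin(ang) + dx * math.cos(ang)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if pos:
            vec = spec.dab_od * dab_vec + spec.counterstain_fraction * spec.hematoxylin_od * hema_vec
        else:
            vec = spec.hematoxylin_od * hema_vec
        od[y0:y1, x0:x1][inside] += vec

    intensity = spec.background_intensity * np.power(10.0, -od)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    image = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    roi = np.ones((h, w), dtype=bool)
    roi_area_mm2 = roi.sum() * (px / 1000.0) ** 2
    ground_truth = {
        "n_nuclei": spec.n_nuclei,
        "n_dab_positive": int(is_positive.sum()),
        "roi_area_mm2": float(roi_area_mm2),
        "density_per_mm2": float(is_positive.sum() / roi_area_mm2),
        "dab_od": spec.dab_od,
        "seed": spec.seed,
    }
    return IhcPhantom(image=image, roi_mask=roi, ground_truth=ground_truth)


# --------------------------------------------------------------------------
# Survival cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort whose hazard jumps at a known biomarker cut-off.

    Event times are exponential with the group hazard (events/month), so the
    theoretical group median survival is ln2/λ. Defaults mirror a hypoxia-
    imaging cohort: biomarker ~ N(1.6, 0.3) (a TBRmax-like score), cut-off
    1.6, medians 21 vs 9 months, 20% random censoring, 60-month follow-up.
    """

    n_subjects: int = 150
    biomarker_distribution: tuple[str, tuple[float, ...]] = ("normal", (1.6, 0.3))
    true_cutoff: float = 1.6
    hazard_low: float = math.log(2) / 21.0
    hazard_high: float = math.log(2) / 9.0
    censoring_rate: float = 0.2
    max_followup_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if self.hazard_low <= 0 or self.hazard_high <= 0:
            raise ConfigurationError("hazards must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if self.max_followup_months <= 0:
            raise ConfigurationError("max follow-up must be positive")


@dataclass(frozen=True)
class SurvivalCohort:
    table: pd.DataFrame  # subject_id, time_months, event, biomarker
    ground_truth: dict


def _draw_biomarker(rng: np.random.Generator, dist: tuple[str, tuple[float, ...]], n: int):
    name, args = dist
    if name == "normal":
        return rng.normal(*args, size=n)
    if name == "uniform":
        return rng.uniform(*args, size=n)
    if name == "lognormal":
        return rng.lognormal(*args, size=n)
    if name == "levels":
        # noise-free ordinal biomarker: each subject sits exactly on one of
        # the given levels (e.g. a reading grid); used for cut-point recovery
        return rng.choice(np.asarray(args, dtype=float), size=n)
    raise ConfigurationError(f"unknown biomarker distribution {name!r}")


def generate_survival_cohort(spec: CohortSpec) -> SurvivalCohort:
    """Draw biomarkers, exponential event times and censoring."""
    rng = np.random.default_rng(spec.seed)
    biomarker = _draw_biomarker(rng, spec.biomarker_distribution, spec.n_subjects)
    high = biomarker > spec.true_cutoff
    hazard = np.where(high, spec.hazard_high, spec.hazard_low)
    t_event = rng.exponential(1.0 / hazard)

    dropout = rng.random(spec.n_subjects) < spec.censoring_rate
    t_drop = rng.uniform(0.0, t_event)  # dropout happens before the event
    time = np.where(dropout, t_drop, t_event)
    event = (~dropout).astype(int)
    over = time > spec.max_followup_months  # administrative end of study
    time = np.where(over, spec.max_followup_months, time)
    event = np.where(over, 0, event)
    time = np.maximum(time, 1e-9)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(spec.n_subjects)],
            "time_months": time,
            "event": event,
            "biomarker": biomarker,
        }
    )
    ground_truth = {
        "true_cutoff": spec.true_cutoff,
        "median_low_months": math.log(2) / spec.hazard_low,
        "median_high_months": math.log(2) / spec.hazard_high,
        "hazard_ratio": spec.hazard_high / spec.hazard_low,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "seed": spec.seed,
    }
    return SurvivalCohort(table=table, ground_truth=ground_truth)


# --------------------------------------------------------------------------
# Cytokine array membranes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayLayout:
    """Spot layout shared by the paired NPS/HPS membranes.

    ``base_intensity`` maps each analyte to its NPS spot mean (arbitrary
    densitometry units on top of the negative-control background).
    """

    base_intensity: dict[str, float]
    n_replicates: int = 2
    pos_ctrl_level: float = 1000.0
    neg_ctrl_level: float = 0.0
    n_pos_ctrl: int = 2
    n_neg_ctrl: int = 2

    def __post_init__(self) -> None:
        if self.n_pos_ctrl < 1 or self.n_neg_ctrl < 1:
            raise LayoutError("layout needs at least one positive and one negative control")
        if self.n_replicates < 2:
            raise LayoutError("layout needs at least 2 replicate spots per analyte")
        if self.pos_ctrl_level <= self.neg_ctrl_level:
            raise LayoutError("positive control level must exceed the negative control level")


def generate_array_table(
    layout: ArrayLayout,
    true_fold_map: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paired membranes with programmed HPS/NPS fold inductions.

    Before noise, the HPS spot mean of an analyte is fold × its NPS spot
    mean (measured above the negative-control background); control spots are
    identical across membranes. Returns one long table with a ``membrane``
    column in the CSV schema consumed by the array CLI.
    """
    missing = set(true_fold_map) - set(layout.base_intensity)
    if missing:
        raise LayoutError(f"fold map names analytes absent from the layout: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for membrane in ("NPS", "HPS"):
        for analyte, base in layout.base_intensity.items():
            fold = true_fold_map.get(analyte, 1.0) if membrane == "HPS" else 1.0
            # with the default zero negative-control level the control
            # normalization preserves the programmed fold exactly
            level = layout.neg_ctrl_level + fold * base
            for rep in range(layout.n_replicates):
                rows.append((membrane, analyte, rep, level, False, False))
        for rep in range(layout.n_pos_ctrl):
            rows.append((membrane, "POS", rep, layout.pos_ctrl_level, True, False))
        for rep in range(layout.n_neg_ctrl):
            rows.append((membrane, "NEG", rep, layout.neg_ctrl_level, False, True))
    table = pd.DataFrame(
        rows,
        columns=["membrane", "analyte", "replicate", "intensity", "is_pos_ctrl", "is_neg_ctrl"],
    )
    if noise_sd > 0:
        table["intensity"] = table["intensity"] + rng.normal(0.0, noise_sd, size=len(table))
    return table
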