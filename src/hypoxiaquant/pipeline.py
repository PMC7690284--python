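"""End-to-end orchestration: simulate → quantify → manifest.

A pipeline run executes the requested stages in dependency order and writes
a run manifest (parameters, seed, package version, SHA-256 of every input
and output file) next to the results, so that two runs with identical
configuration and seed are byte-comparable.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

from . import io, pet, phantoms
from .errors import ValidationError
from .ihc import quantify_dab_density

logger = logging.getLogger("hypoxiaquant")

__version__ = "0.1.0"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(out_dir: Path, stage: str, params: dict, files: list[Path], seed: int | None) -> dict:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "parameters": params,
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    io.write_json(out_dir / f"{stage}_manifest.json", manifest)
    return manifest


def simulate_pet_stage(out_dir: str | Path, spec: phantoms.PetPhantomSpec) -> dict:
    """Write a PET phantom (volume, masks, ground truth) and its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = phantoms.generate_pet_phantom(spec)
    io.write_nifti(out / "suv.nii.gz", phantom.suv.values, phantom.suv.spacing_mm)
    io.write_nifti(out / "tumor.nii.gz", phantom.tumor_mask.astype("uint8"), phantom.suv.spacing_mm)
    io.write_nifti(out / "aorta.nii.gz", phantom.aorta_mask.astype("uint8"), phantom.suv.spacing_mm)
    io.write_json(out / "ground_truth.json", phantom.ground_truth)
    files = [out / n for n in ("suv.nii.gz", "tumor.nii.gz", "aorta.nii.gz", "ground_truth.json")]
    logger.info("simulate-pet: wrote phantom with %d hypoxic voxels",
                phantom.ground_truth["n_hypoxic_voxels"])
    return _manifest(out, "simulate_pet", {"spec": str(spec)}, files, spec.seed)


def pet_stage(
    suv_path: str | Path,
    tumor_path: str | Path,
    aorta_path: str | Path,
    out_path: str | Path,
    tbr_threshold: float = 1.4,
    hv_threshold_ml: float = 1.0,
) -> pet.HypoxiaMetrics:
    """Quantify a SUV volume: TBRmax, TBRpeak, HV, hypoxic flag → JSON."""
    for p, stage in ((suv_path, "SUV volume"), (tumor_path, "tumor mask"), (aorta_path, "aorta mask")):
        if not Path(p).exists():
            raise ValidationError(f"pet stage: missing {stage} at {p}")
    suv = io.read_nifti_volume(suv_path)
    tumor = io.read_nifti_mask(tumor_path, like=suv)
    aorta = io.read_nifti_mask(aorta_path, like=suv)
    tbr = pet.compute_tbr(suv, aorta)
    metrics = pet.compute_hypoxia_metrics(
        tbr, tumor, tbr_threshold=tbr_threshold, hv_threshold_ml=hv_threshold_ml
    )
    io.write_json(Path(out_path), metrics.to_dict())
    logger.info("pet: TBRmax=%.3f TBRpeak=%.3f HV=%.3f mL hypoxic=%s",
                metrics.tbr_max, metrics.tbr_peak, metrics.hv_ml, metrics.is_hypoxic)
    return metrics


def simulate_ihc_stage(out_dir: str | Path, spec: phantoms.IhcPhantomSpec) -> dict:
    """Write an IHC phantom (RGB TIFF, ROI PNG, ground truth) and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = phantoms.generate_ihc_image(spec)
    io.write_rgb_tiff(out / "slide.tiff", phantom.image)
    io.write_mask_png(out / "roi.png", phantom.roi_mask)
    io.write_json(out / "ground_truth.json", phantom.ground_truth)
    files = [out / n for n in ("slide.tiff", "roi.png", "ground_truth.json")]
    logger.info("simulate-ihc: %d nuclei (%d DAB+)",
                phantom.ground_truth["n_nuclei"], phantom.ground_truth["n_dab_positive"])
    return _manifest(out, "simulate_ihc", {"spec": str(spec)}, files, spec.seed)


def ihc_stage(
    image_path: str | Path,
    roi_path: str | Path,
    pixel_size_um: float,
    out_path: str | Path,
    min_area_um2: float = 10.0,
    max_area_um2: float = 500.0,
):
    """Quantify DAB-positive nuclei density on a slide image → JSON."""
    for p, what in ((image_path, "slide image"), (roi_path, "ROI mask")):
        if not Path(p).exists():
            raise ValidationError(f"ihc stage: missing {what} at {p}")
    img = io.read_rgb_image(image_path)
    roi = io.read_mask_png(roi_path)
    result = quantify_dab_density(
        img, roi, pixel_size_um, min_area_um2=min_area_um2, max_area_um2=max_area_um2
    )
    io.write_json(Path(out_path), result.to_dict())
    logger.info("ihc: %d objects over %.4f mm² → %.1f /mm²",
                result.positive_object_count, result.roi_area_mm2, result.density_per_mm2)
    return result


def demo(out_dir: str | Path, seed: int = 0) -> dict:
    """Simulate-then-quantify round trip for PET and IHC in one directory."""
    out = Path(out_dir)
    pet_dir, ihc_dir = out / "pet", out / "ihc"
    simulate_pet_stage(pet_dir, phantoms.PetPhantomSpec(noise_sd=0.0, seed=seed))
    metrics = pet_stage(
        pet_dir / "suv.nii.gz", pet_dir / "tumor.nii.gz", pet_dir / "aorta.nii.gz",
        pet_dir / "metrics.json",
    )
    simulate_ihc_stage(ihc_dir, phantoms.IhcPhantomSpec(seed=seed))
    density = ihc_stage(
        ihc_dir / "slide.tiff", ihc_dir / "roi.png",
        phantoms.IhcPhantomSpec().pixel_size_um, ihc_dir / "density.json",
    )
    summary = {
        "pet_metrics": metrics.to_dict(),
        "ihc_density": density.to_dict(),
        "pet_ground_truth": io.read_json(pet_dir / "ground_truth.json"),
        "ihc_ground_truth": io.read_json(ihc_dir / "ground_truth.json"),
    }
    io.write_json(out / "demo_summary.json", summary)
    return summary
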