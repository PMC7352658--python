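"""File-format helpers: TIFF/PNG tiles, centroid CSVs, NIfTI volumes, cohort CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .ihc import StainedTile
from .mri import SegmentationCase
from .synthetic import TileGroundTruth


def save_tile(tile: StainedTile, path: str | Path) -> None:
    """8-bit RGB TIFF (or PNG by extension); float tiles are rounded."""
    path = Path(path)
    rgb = np.clip(np.round(np.asarray(tile.rgb, dtype=float)), 0, 255).astype(np.uint8)
    if path.suffix.lower() == ".png":
        Image.fromarray(rgb).save(path)
    else:
        tifffile.imwrite(path, rgb, photometric="rgb")


def load_tile(path: str | Path, pixel_size_um: float = 0.92) -> StainedTile:
    path = Path(path)
    if path.suffix.lower() == ".png":
        rgb = np.asarray(Image.open(path).convert("RGB"))
    else:
        rgb = tifffile.imread(path)
    return StainedTile(rgb=rgb, pixel_size_um=pixel_size_um)


def save_ground_truth(gt: TileGroundTruth, stem: str | Path) -> None:
    """Centroid CSV (<stem>.csv) plus a 16-bit label TIFF (<stem>_labels.tiff)."""
    stem = Path(stem)
    rows = [{"row": r, "col": c, "positive": False} for r, c in gt.centers_negative] + [
        {"row": r, "col": c, "positive": True} for r, c in gt.centers_positive
    ]
    pd.DataFrame(rows, columns=["row", "col", "positive"]).to_csv(
        stem.with_suffix(".csv"), index=False
    )
    tifffile.imwrite(stem.parent / (stem.name + "_labels.tiff"), gt.label_image.astype(np.uint16))


def save_segmentation_case(case: SegmentationCase, outdir: str | Path, stem: str = "case") -> None:
    """Compartment + atlas NIfTI volumes plus a JSON region/laterality map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(case.voxel_spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(case.compartments.astype(np.int16), affine),
             outdir / f"{stem}_seg.nii.gz")
    if case.atlas is not None:
        nib.save(nib.Nifti1Image(case.atlas.astype(np.int16), affine),
                 outdir / f"{stem}_atlas.nii.gz")
    with open(outdir / f"{stem}_regions.json", "w") as fh:
        json.dump(
            {
                "region_names": {str(k): v for k, v in case.region_names.items()},
                "laterality": {str(k): v for k, v in case.laterality.items()},
            },
            fh,
            indent=2,
        )


def load_segmentation_case(outdir: str | Path, stem: str = "case") -> SegmentationCase:
    outdir = Path(outdir)
    seg = nib.load(outdir / f"{stem}_seg.nii.gz")
    spacing = tuple(float(z) for z in seg.header.get_zooms()[:3])
    atlas_path = outdir / f"{stem}_atlas.nii.gz"
    atlas = np.asarray(nib.load(atlas_path).dataobj) if atlas_path.exists() else None
    regions_path = outdir / f"{stem}_regions.json"
    region_names, laterality = {}, {}
    if regions_path.exists():
        with open(regions_path) as fh:
            maps = json.load(fh)
        region_names = {int(k): v for k, v in maps.get("region_names", {}).items()}
        laterality = {int(k): v for k, v in maps.get("laterality", {}).items()}
    return SegmentationCase(
        compartments=np.asarray(seg.dataobj),
        voxel_spacing_mm=spacing,
        atlas=atlas,
        region_names=region_names,
        laterality=laterality,
    )
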