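"""MR-derived tumor features from co-registered segmentation and atlas volumes.

Works on manually segmented 3D label volumes (0 background, 1 enhancing
tumor, 2 necrosis, 3 edema/non-enhancing) together with an atlas label
volume already warped onto the same voxel grid.  Registration itself is
out of scope: inputs are asserted, not aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SegmentationCase",
    "MriFeatures",
    "COMPARTMENTS",
    "LOBES",
    "compartment_volumes",
    "count_foci",
    "location_percentages",
    "extract_features",
]

COMPARTMENTS = {"enhancing": 1, "necrosis": 2, "edema": 3}
LOBES = ("frontal", "parietal", "temporal", "occipital")
#: Deep brain = corpus callosum, periventricular regions, basal ganglia,
#: thalamus, brainstem and cerebellum; atlases collapse these to "deep".
REGION_CATEGORIES = LOBES + ("deep", "other")


@dataclass(frozen=True)
class SegmentationCase:
    """Tumor compartments + atlas on one voxel grid.

    ``region_names`` maps atlas codes to one of frontal / parietal /
    temporal / occipital / deep / other; ``laterality`` maps codes to
    left / right / midline.  When merged atlases would give a voxel both a
    lobar and a deep identity, the code map must already encode the deep
    code (deep wins — it is the prognostically targeted variable).
    """

    compartments: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    atlas: np.ndarray | None = None
    region_names: dict[int, str] = field(default_factory=dict)
    laterality: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        comp = np.asarray(self.compartments)
        if comp.ndim != 3:
            raise ValueError("compartments must be a 3D volume")
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(spacing) != 3 or min(spacing) <= 0:
            raise ValueError("voxel_spacing_mm must be three positive floats")
        if self.atlas is not None:
            atlas = np.asarray(self.atlas)
            if atlas.shape != comp.shape:
                raise ValueError("atlas and compartments must share one grid")
            object.__setattr__(self, "atlas", atlas)
        bad = {c for c in self.region_names.values()} - set(REGION_CATEGORIES)
        if bad:
            raise ValueError(f"unknown region categories: {sorted(bad)}")
        object.__setattr__(self, "compartments", comp)
        object.__setattr__(self, "voxel_spacing_mm", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm))


@dataclass(frozen=True)
class MriFeatures:
    enhancing_cm3: float
    necrotic_cm3: float
    edema_cm3: float
    n_foci: int
    pct_frontal: float = np.nan
    pct_parietal: float = np.nan
    pct_temporal: float = np.nan
    pct_occipital: float = np.nan
    pct_deep: float = np.nan
    pct_other: float = np.nan
    pct_left: float = np.nan


def compartment_volumes(case: SegmentationCase) -> tuple[float, float, float]:
    """(enhancing, necrotic, edema) volumes in cm^3 (voxel count x voxel volume)."""
    spacing = case.voxel_spacing_mm
    if max(spacing) / min(spacing) > 5:
        warnings.warn("highly anisotropic voxels (max/min spacing > 5)")
    vv = case.voxel_volume_mm3 / 1000.0  # mm^3 -> cm^3
    comp = case.compartments
    return (
        float((comp == COMPARTMENTS["enhancing"]).sum() * vv),
        float((comp == COMPARTMENTS["necrosis"]).sum() * vv),
        float((comp == COMPARTMENTS["edema"]).sum() * vv),
    )


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndi.generate_binary_structure(3, order)


def count_foci(case: SegmentationCase, connectivity: int = 26) -> int:
    """Number of connected groups of enhancing-tumor voxels (multifocality)."""
    enhancing = case.compartments == COMPARTMENTS["enhancing"]
    _, n = ndi.label(enhancing, structure=_structure(connectivity))
    return int(n)


def _mass_mask(case: SegmentationCase, mass_definition: str) -> np.ndarray:
    if mass_definition == "enhancing_plus_necrosis":
        return np.isin(case.compartments, (COMPARTMENTS["enhancing"], COMPARTMENTS["necrosis"]))
    if mass_definition == "enhancing_only":
        return case.compartments == COMPARTMENTS["enhancing"]
    raise ValueError("mass_definition must be 'enhancing_plus_necrosis' or 'enhancing_only'")


def location_percentages(
    case: SegmentationCase, mass_definition: str = "enhancing_plus_necrosis"
) -> dict[str, float]:
    """Percent of the main tumor mass per atlas region category, plus pct_left.

    The main tumor mass defaults to enhancing + necrosis (the tumor proper,
    excluding edema); ``enhancing_only`` is available.  Atlas codes not in
    ``region_names`` fall into ``other``.  An empty tumor mass raises.
    """
    if case.atlas is None:
        raise ValueError("case has no atlas volume")
    mass = _mass_mask(case, mass_definition)
    total = int(mass.sum())
    if total == 0:
        raise ValueError("empty tumor mass: location percentages undefined")
    codes = case.atlas[mass]
    out: dict[str, float] = {}
    for cat in REGION_CATEGORIES:
        cat_codes = [c for c, name in case.region_names.items() if name == cat]
        n = int(np.isin(codes, cat_codes).sum())
        if cat == "other":
            # codes absent from the map also count as "other"
            mapped = list(case.region_names)
            n += int((~np.isin(codes, mapped)).sum())
        out[f"pct_{cat}"] = 100.0 * n / total
    left_codes = [c for c, side in case.laterality.items() if side == "left"]
    out["pct_left"] = 100.0 * int(np.isin(codes, left_codes).sum()) / total
    return out


def extract_features(
    case: SegmentationCase,
    mass_definition: str = "enhancing_plus_necrosis",
    connectivity: int = 26,
) -> MriFeatures:
    """All MR features of one case in a single record."""
    enh, nec, ede = compartment_volumes(case)
    foci = count_foci(case, connectivity)
    loc = {}
    if case.atlas is not None and _mass_mask(case, mass_definition).any():
        loc = location_percentages(case, mass_definition)
    return MriFeatures(enhancing_cm3=enh, necrotic_cm3=nec, edema_cm3=ede, n_foci=foci, **loc)
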