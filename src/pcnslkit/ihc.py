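"""Immune-cell scoring of DAB / hematoxylin stained brightfield tiles.

The scoring pipeline mirrors standard digital-pathology practice for
tissue-microarray (TMA) cores: the RGB tile is converted to optical
density (Beer-Lambert), unmixed into hematoxylin (nuclear counterstain)
and DAB (positive chromogen) channels, each channel is thresholded both
locally (Phansalkar) and globally (Otsu), stray background pixels are
removed with a neighbor-count rule, touching nuclei are split by a
distance-transform watershed, and the immune score is reported as the
percentage of DAB+ cells among all detected cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = [
    "StainedTile",
    "StainMatrix",
    "SegmentationParams",
    "CellDetection",
    "ImmuneScore",
    "MARKERS",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve_stains",
    "segment_positive",
    "filter_background",
    "split_touching",
    "score_core",
]

MARKERS = ("CD3", "CD45ro", "CD68", "FoxP3")

#: Classical H-DAB optical-density vectors (per RGB channel), unit norm.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.269, 0.568, 0.778)


@dataclass(frozen=True)
class StainedTile:
    """One RGB brightfield tile with its physical pixel size.

    ``rgb`` is an (H, W, 3) array with values in [0, 255]; float arrays are
    accepted so that synthetic tiles can round-trip through deconvolution
    without quantization loss.
    """

    rgb: np.ndarray
    pixel_size_um: float = 0.92

    def __post_init__(self):
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")
        if rgb.shape[0] < 1 or rgb.shape[1] < 1:
            raise ValueError("tile dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "rgb", rgb)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass(frozen=True)
class StainMatrix:
    """Unit-norm hematoxylin and DAB OD vectors plus an orthogonal residual.

    The 3x3 unmixing matrix has the two stain vectors and their (normalized)
    cross product as rows; unmixing uses its pseudo-inverse.
    """

    hema_vector: tuple[float, float, float] = HEMATOXYLIN_OD
    dab_vector: tuple[float, float, float] = DAB_OD

    def __post_init__(self):
        h = np.asarray(self.hema_vector, dtype=float)
        d = np.asarray(self.dab_vector, dtype=float)
        hn, dn = np.linalg.norm(h), np.linalg.norm(d)
        if hn == 0 or dn == 0:
            raise ValueError("stain vectors must be nonzero")
        h, d = h / hn, d / dn
        cross = np.cross(h, d)
        if np.linalg.norm(cross) < 1e-6:
            raise np.linalg.LinAlgError("stain vectors are collinear")
        object.__setattr__(self, "hema_vector", tuple(h))
        object.__setattr__(self, "dab_vector", tuple(d))

    @property
    def matrix(self) -> np.ndarray:
        h = np.asarray(self.hema_vector)
        d = np.asarray(self.dab_vector)
        r = np.cross(h, d)
        r = r / np.linalg.norm(r)
        return np.stack([h, d, r])


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the threshold / filter / split stages.

    Phansalkar defaults are the values of the original publication
    (radius 15 px, k=0.25, p=2, q=10); ``min_cell_area_px`` of 20 px at
    0.92 um/px is ~17 um^2, below any real nucleus, so it removes debris
    without eating cells.
    """

    phansalkar_radius_px: int = 15
    phansalkar_k: float = 0.25
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    min_cell_area_px: int = 20
    neighbor_min: int = 2
    connectivity: int = 8
    watershed_h_fraction: float = 0.3
    min_od: float = 0.15  # absolute OD floor: below this a pixel is unstained

    def __post_init__(self):
        if self.phansalkar_radius_px < 1:
            raise ValueError("phansalkar_radius_px must be >= 1")
        if self.min_cell_area_px < 1:
            raise ValueError("min_cell_area_px must be >= 1")
        if not 0 <= self.neighbor_min <= 8:
            raise ValueError("neighbor_min must be in 0..8")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _structure(self) -> np.ndarray:
        return ndi.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


@dataclass(frozen=True)
class CellDetection:
    """Labelled cells of one stain channel."""

    label_image: np.ndarray
    centroids: np.ndarray  # (n, 2) of (row, col)
    count: int

    def __post_init__(self):
        n_labels = len(np.unique(self.label_image[self.label_image > 0]))
        if not (self.count == n_labels == len(self.centroids)):
            raise ValueError("count, labels and centroids disagree")


@dataclass(frozen=True)
class ImmuneScore:
    """Percent positively stained cells for one IHC marker.

    ``percent_positive`` = 100 * n_dab / (n_dab + n_hema), i.e. the DAB+
    fraction of all detected cells (hematoxylin counting the negative
    nuclei).  ``ratio_dab_to_hema`` is the alternative reading of a
    DAB-to-hematoxylin ratio, reported for transparency.  A tile with no
    detected cells yields an undefined (NaN, flagged) score, never 0.
    """

    marker: str
    n_dab: int
    n_hema: int

    @property
    def defined(self) -> bool:
        return (self.n_dab + self.n_hema) > 0

    @property
    def percent_positive(self) -> float:
        total = self.n_dab + self.n_hema
        return 100.0 * self.n_dab / total if total else math.nan

    @property
    def ratio_dab_to_hema(self) -> float:
        return self.n_dab / self.n_hema if self.n_hema else math.nan


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density per channel, OD = -log10((I + 1) / 256).

    The +1 offset keeps OD finite at I = 0; I0 = 256 makes a pure white
    pixel (255) map to exactly 0 OD.
    """
    return -np.log10((np.asarray(rgb, dtype=float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; result clipped to [0, 255] (float)."""
    return np.clip(256.0 * 10.0 ** (-np.asarray(od, dtype=float)) - 1.0, 0.0, 255.0)


def deconvolve_stains(
    tile: StainedTile, stains: StainMatrix | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix a tile into hematoxylin and DAB concentration (OD) maps.

    Per-pixel OD vectors are projected onto the stain basis via the
    pseudo-inverse of the stain matrix; negative concentrations are
    clipped to zero.
    """
    stains = stains or StainMatrix()
    od = rgb_to_od(tile.rgb).reshape(-1, 3)
    conc = od @ np.linalg.pinv(stains.matrix)
    conc = np.clip(conc, 0.0, None)
    h, w = tile.shape
    return conc[:, 0].reshape(h, w), conc[:, 1].reshape(h, w)


def _phansalkar_threshold(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Local Phansalkar threshold surface on an image normalized to [0, 1].

    t = m * (1 + p*exp(-q*m) + k*(s/R - 1)) with R = 0.5, computed over a
    square window of side 2*radius + 1.
    """
    w = 2 * params.phansalkar_radius_px + 1
    m = ndi.uniform_filter(img, size=w, mode="reflect")
    m2 = ndi.uniform_filter(img * img, size=w, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    return m * (
        1.0
        + params.phansalkar_p * np.exp(-params.phansalkar_q * m)
        + params.phansalkar_k * (s / 0.5 - 1.0)
    )


def segment_positive(od_map: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Binary mask of positively stained pixels.

    A pixel passes only if it clears BOTH the Phansalkar local threshold
    and the Otsu global threshold (AND combination: OR would reduce to the
    looser of the two thresholds and defeat dual thresholding), plus an
    absolute OD floor (``min_od``) so that blank channels containing only
    acquisition noise stay empty.  A constant map has no Otsu threshold
    and yields an empty mask with a warning.
    """
    params = params or SegmentationParams()
    od_map = np.asarray(od_map, dtype=float)
    if od_map.min() == od_map.max():
        warnings.warn("constant OD map: Otsu threshold undefined, returning empty mask")
        return np.zeros(od_map.shape, dtype=bool)
    if od_map.max() <= params.min_od:  # blank channel: noise only, no stain
        return np.zeros(od_map.shape, dtype=bool)
    global_mask = od_map > threshold_otsu(od_map)
    norm = od_map / od_map.max()
    local_mask = norm > _phansalkar_threshold(norm, params)
    return global_mask & local_mask & (od_map > params.min_od)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def filter_background(mask: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Drop positive pixels with fewer than ``neighbor_min`` positive 8-neighbors.

    Single pass over the input mask; the output is always a subset of the
    input (the rule only removes pixels).
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    neighbors = ndi.convolve(mask.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    return mask & (neighbors >= params.neighbor_min)


def split_touching(mask: np.ndarray, params: SegmentationParams | None = None) -> CellDetection:
    """Split touching cells by watershed on the negated distance transform.

    Seeds are the h-maxima of each connected object's Euclidean distance
    map with h = ``watershed_h_fraction`` * (object's max distance), so
    shallow necks between adjacent nuclei become watershed lines while
    single convex nuclei stay whole.  Objects below ``min_cell_area_px``
    are discarded.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    structure = params._structure
    out = np.zeros(mask.shape, dtype=np.int32)
    labels, n = ndi.label(mask, structure=structure)
    next_id = 1
    for i, sl in enumerate(ndi.find_objects(labels, n), start=1):
        if sl is None:
            continue
        region = labels[sl] == i
        dist = ndi.distance_transform_edt(np.pad(region, 1))[1:-1, 1:-1]
        h = params.watershed_h_fraction * dist.max()
        seeds, n_seeds = ndi.label(h_maxima(dist, h) if h > 0 else region, structure=structure)
        if n_seeds <= 1:
            parts = region.astype(np.int32)
            n_parts = 1
        else:
            parts = watershed(-dist, markers=seeds, mask=region, connectivity=structure)
            n_parts = n_seeds
        for j in range(1, n_parts + 1):
            part = parts == j
            area = int(part.sum())
            if area >= params.min_cell_area_px:
                out[sl][part] = next_id
                next_id += 1
    count = next_id - 1
    if count:
        centroids = np.asarray(ndi.center_of_mass(out > 0, out, range(1, count + 1)))
    else:
        centroids = np.empty((0, 2))
    return CellDetection(label_image=out, centroids=centroids, count=count)


def detect_cells(od_map: np.ndarray, params: SegmentationParams | None = None) -> CellDetection:
    """segment -> neighbor filter -> watershed split for one stain channel."""
    params = params or SegmentationParams()
    mask = filter_background(segment_positive(od_map, params), params)
    return split_touching(mask, params)


def score_core(
    tile: StainedTile,
    stains: StainMatrix | None = None,
    params: SegmentationParams | None = None,
    marker: str = "CD3",
) -> tuple[ImmuneScore, CellDetection, CellDetection]:
    """Score one TMA core: percent DAB+ cells plus both channel detections.

    The neighbor filter is applied to the pixel mask before labelling and
    watershed (the rule is defined on pixels, not objects).
    """
    params = params or SegmentationParams()
    hema_map, dab_map = deconvolve_stains(tile, stains)
    det_dab = detect_cells(dab_map, params)
    det_hema = detect_cells(hema_map, params)
    score = ImmuneScore(marker=marker, n_dab=det_dab.count, n_hema=det_hema.count)
    if not score.defined:
        warnings.warn("no cells detected: immune score undefined")
    return score, det_dab, det_hema
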