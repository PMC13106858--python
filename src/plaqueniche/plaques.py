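"""Plaque segmentation and the distance-to-nearest-plaque field.

The amyloid-stain image is min-max normalized, thresholded (Otsu by default),
and 8-connected components below a minimum area are discarded.  The exact
Euclidean distance transform of the background to the plaque set, scaled to
µm, then defines every neighborhood statistic downstream: distance is 0 on
plaque pixels and +inf when the mask is empty.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import PixelScale
from .io import StainImage

log = logging.getLogger("plaqueniche")

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class DegenerateImageError(ValueError):
    """Thresholding is undefined on the given image."""


@dataclasses.dataclass
class PlaqueField:
    """Labeled plaque mask plus the µm distance field.

    Attributes
    ----------
    label_mask:
        Integer grid; 0 is background, k > 0 is plaque k.  Labels are
        numbered 1..K in raster order of each component's first pixel.
    distance:
        Per-pixel Euclidean distance (µm) to the nearest plaque pixel;
        exactly 0 on plaque pixels, +inf everywhere when no plaque exists.
    nearest_label:
        Label of the nearest plaque pixel (0 when no plaque exists).
    plaque_table:
        One row per plaque: id, area_um2, centroid_x, centroid_y, border.
    """

    label_mask: np.ndarray
    scale: PixelScale
    distance: np.ndarray | None = None
    nearest_label: np.ndarray | None = None
    plaque_table: pd.DataFrame | None = None

    @property
    def n_plaques(self) -> int:
        return int(self.label_mask.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_mask.shape


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber components 1..K by raster order of their first pixel."""
    old = []
    seen = set()
    for v in labels.ravel():
        if v and v not in seen:
            seen.add(v)
            old.append(v)
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    for new, o in enumerate(old, start=1):
        lut[o] = new
    return lut[labels]


def segment_plaques(
    img: StainImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area: float = 10.0,
) -> PlaqueField:
    """Segment plaques from the amyloid stain by global thresholding.

    Parameters
    ----------
    img:
        Amyloid-stain image.
    method:
        ``"otsu"`` (threshold chosen on the normalized histogram) or
        ``"fixed"`` (``fixed_threshold`` on the normalized [0, 1] scale).
    min_area:
        Components smaller than this many µm² are removed as noise.

    Returns a :class:`PlaqueField` with the distance field already built.
    """
    norm = img.normalized()
    if method == "otsu":
        if norm.max() == norm.min():
            raise DegenerateImageError(
                "constant image: Otsu threshold is undefined; use method='fixed'"
            )
        thr = threshold_otsu(norm)
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    binary = norm > thr
    labels, _ = ndimage.label(binary, structure=EIGHT_CONNECTED)
    pixel_area = img.scale.pixel_area_um2
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes * pixel_area < min_area)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels = _relabel_raster_order(labels)
    if labels.max() == 0 and binary.any():
        log.warning("all components below min_area=%g µm²: empty plaque field", min_area)

    field = PlaqueField(label_mask=labels, scale=img.scale)
    field.plaque_table = _plaque_table(field)
    return distance_field(field)


def field_from_mask(mask: np.ndarray, scale: PixelScale | None = None) -> PlaqueField:
    """Build a PlaqueField directly from a boolean or label mask."""
    scale = scale or PixelScale()
    mask = np.asarray(mask)
    if mask.dtype == bool:
        labels, _ = ndimage.label(mask, structure=EIGHT_CONNECTED)
    else:
        labels = mask.astype(np.int32)
    field = PlaqueField(label_mask=labels, scale=scale)
    field.plaque_table = _plaque_table(field)
    return distance_field(field)


def _plaque_table(field: PlaqueField) -> pd.DataFrame:
    labels = field.label_mask
    k = int(labels.max())
    pixel_area = field.scale.pixel_area_um2
    mpp = field.scale.microns_per_pixel
    rows = []
    if k:
        sizes = np.bincount(labels.ravel(), minlength=k + 1)
        cy, cx = np.indices(labels.shape)
        sum_y = np.bincount(labels.ravel(), weights=cy.ravel(), minlength=k + 1)
        sum_x = np.bincount(labels.ravel(), weights=cx.ravel(), minlength=k + 1)
        border_labels = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :]))
        border_labels |= set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
        for pid in range(1, k + 1):
            rows.append(
                {
                    "id": pid,
                    "area_um2": sizes[pid] * pixel_area,
                    "centroid_x": sum_x[pid] / sizes[pid] * mpp,
                    "centroid_y": sum_y[pid] / sizes[pid] * mpp,
                    "border": pid in border_labels,
                }
            )
    return pd.DataFrame(
        rows, columns=["id", "area_um2", "centroid_x", "centroid_y", "border"]
    )


def distance_field(field: PlaqueField) -> PlaqueField:
    """Fill the exact Euclidean distance transform (µm) of a labeled field.

    Also records, per pixel, the label of the nearest plaque pixel so that
    points can later be attributed to their nearest plaque.  An empty mask
    yields an all-+inf distance field.
    """
    labels = field.label_mask
    if labels.max() == 0:
        field.distance = np.full(labels.shape, np.inf)
        field.nearest_label = np.zeros(labels.shape, dtype=np.int32)
        return field
    background = labels == 0
    dist_px, (iy, ix) = ndimage.distance_transform_edt(background, return_indices=True)
    field.distance = dist_px * field.scale.microns_per_pixel
    field.nearest_label = labels[iy, ix].astype(np.int32)
    return field


def query_distance(
    field: PlaqueField,
    x_um: np.ndarray,
    y_um: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance to nearest plaque for continuous µm points.

    Points are mapped to their nearest pixel center (coordinates are
    continuous and may fall between centers).  Returns ``(distance_um,
    nearest_plaque_id, in_bounds)`` aligned with input order; out-of-bounds
    points get distance NaN and a False flag.
    """
    if field.distance is None:
        distance_field(field)
    x_um = np.asarray(x_um, dtype=float)
    y_um = np.asarray(y_um, dtype=float)
    mpp = field.scale.microns_per_pixel
    col = np.rint(x_um / mpp).astype(int)
    row = np.rint(y_um / mpp).astype(int)
    h, w = field.shape
    in_bounds = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    if not in_bounds.all():
        log.warning("%d points out of image bounds", int((~in_bounds).sum()))
    d = np.full(x_um.shape, np.nan)
    pid = np.zeros(x_um.shape, dtype=np.int32)
    r, c = row[in_bounds], col[in_bounds]
    d[in_bounds] = field.distance[r, c]
    pid[in_bounds] = field.nearest_label[r, c]
    return d, pid, in_bounds
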