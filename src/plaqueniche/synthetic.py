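"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume and
nothing more: plaques are bright disks on a noisy background (the analyses
depend only on the mask and distances, not plaque morphology), transcripts
are inhomogeneous Poisson point processes whose intensity is a function of
the distance-to-plaque zone, cell count matrices are negative binomial with
planted marker structure, and immunofluorescence channels are Gaussian
nucleus blobs with a bright T-cell region over designated nuclei.  Identical
seeds give bitwise-identical outputs, and every generator returns a
machine-readable truth record sufficient to score downstream stages.

Synthetic images default to a 1 µm/px rendering so that a 512-px frame is a
512 µm window — large relative to the 69 µm zone radius, as real slides are.
The real-slide scale (0.138 µm/px) applies only when reading rendered data.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import DEFAULT_ZONE_RADIUS_UM, PixelScale
from .io import CellMatrix, StainImage
from .plaques import PlaqueField, field_from_mask

log = logging.getLogger("plaqueniche")


class PlacementError(RuntimeError):
    """Requested geometry could not be placed after bounded retries."""


@dataclasses.dataclass(frozen=True)
class EnrichmentSpec:
    """Planted spatial enrichment for one gene.

    ``baseline_intensity`` is points per µm² in the outside zone;
    ``fold_inside`` / ``fold_adjacent`` multiply it within the respective
    zones.  Both folds equal to 1 defines a spatially homogeneous (null)
    gene.
    """

    gene: str
    baseline_intensity: float
    fold_inside: float = 1.0
    fold_adjacent: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_intensity < 0:
            raise ValueError("baseline_intensity must be >= 0")
        if self.fold_inside < 0 or self.fold_adjacent < 0:
            raise ValueError("folds must be >= 0")


@dataclasses.dataclass(frozen=True)
class CellTypeSpec:
    """Planted cell type: marker genes with elevated negative-binomial mean.

    ``dispersion`` is the NB size parameter (variance = mean + mean²/size);
    ``spatial_rule`` places cells uniformly or within the plaque
    neighborhood (d <= zone radius).
    """

    type_name: str
    marker_genes: tuple[str, ...]
    marker_mean: float = 10.0
    background_mean: float = 0.5
    dispersion: float = 10.0
    spatial_rule: str = "uniform"

    def __post_init__(self) -> None:
        if len(self.marker_genes) == 0:
            raise ValueError(f"cell type {self.type_name!r} has no marker genes")
        if not self.marker_mean > self.background_mean:
            raise ValueError("marker_mean must exceed background_mean (planted separability)")
        if self.spatial_rule not in ("uniform", "plaque_adjacent"):
            raise ValueError(f"unknown spatial_rule {self.spatial_rule!r}")


# ---------------------------------------------------------------------------
# Plaque images


def _place_disks(rng, n, radius_range_px, image_size, max_tries):
    """Non-overlapping disks fully inside the frame, rejection-sampled."""
    h, w = image_size
    centers, radii = [], []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} non-overlapping plaques in a {h}x{w} frame "
                "after bounded retries; request fewer or smaller plaques"
            )
        tries += 1
        r = rng.uniform(*radius_range_px)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        if all(np.hypot(cy - y0, cx - x0) > r + r0 for (y0, x0), r0 in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def make_plaque_image(
    n_plaques: int,
    radius_range_um: tuple[float, float] = (5.0, 15.0),
    image_size: tuple[int, int] = (512, 512),
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    scale: PixelScale | None = None,
    foreground: float = 1.0,
    background: float = 0.1,
    blur_sigma_px: float = 0.0,
) -> tuple[StainImage, np.ndarray, dict]:
    """Amyloid-stain stand-in: bright disks on a dark noisy background.

    Returns ``(image, true_label_mask, truth)`` where truth records centers
    (px), radii (px) and the generator parameters.  Disks do not overlap and
    lie fully inside the frame; an unplaceable request raises
    :class:`PlacementError`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scale = scale or PixelScale(1.0)
    if n_plaques < 0:
        raise ValueError("n_plaques must be >= 0")
    r_px = (scale.to_px(radius_range_um[0]), scale.to_px(radius_range_um[1]))
    centers, radii = _place_disks(rng, n_plaques, r_px, image_size, max_tries=1000 * max(n_plaques, 1))

    img = np.full(image_size, background, dtype=float)
    mask = np.zeros(image_size, dtype=np.int32)
    yy, xx = np.indices(image_size)
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[disk] = foreground
        mask[disk] = k
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    img = img + rng.normal(0.0, noise_sd, image_size)
    truth = {
        "centers_px": [(float(cy), float(cx)) for cy, cx in centers],
        "radii_px": [float(r) for r in radii],
        "foreground": foreground,
        "background": background,
        "noise_sd": noise_sd,
    }
    return StainImage(data=img, scale=scale, channel="amyloid"), mask, truth


# ---------------------------------------------------------------------------
# Transcript point processes


def _zone_pixel_indices(field: PlaqueField, zone_radius: float):
    d = field.distance
    return {
        "inside": np.flatnonzero((d == 0).ravel()),
        "adjacent": np.flatnonzero(((d > 0) & (d <= zone_radius)).ravel()),
        "outside": np.flatnonzero((d > zone_radius).ravel()),
    }


def make_transcripts(
    field: PlaqueField,
    specs: list[EnrichmentSpec],
    zone_radius: float = DEFAULT_ZONE_RADIUS_UM,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene inhomogeneous Poisson transcripts over the field's window.

    The intensity is piecewise constant over the three zones of the
    pixel-resolved distance field: ``baseline * fold(zone)``.  Counts per
    zone are Poisson with mean intensity × zone area; positions are uniform
    within the zone (pixel drawn uniformly, jittered within the pixel).

    Returns ``(table, truth)``; truth holds the expected count and realized
    count per (gene, zone) plus zone areas.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mpp = field.scale.microns_per_pixel
    pixel_area = field.scale.pixel_area_um2
    zone_px = _zone_pixel_indices(field, zone_radius)
    w = field.shape[1]

    rows_x, rows_y, rows_g = [], [], []
    truth_rows = []
    any_intensity = False
    for spec in specs:
        folds = {"inside": spec.fold_inside, "adjacent": spec.fold_adjacent, "outside": 1.0}
        for zone, pix in zone_px.items():
            area = pix.size * pixel_area
            lam = spec.baseline_intensity * folds[zone] * area
            if lam > 0:
                any_intensity = True
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n > 0 and pix.size > 0:
                chosen = rng.integers(0, pix.size, size=n)
                flat = pix[chosen]
                py = flat // w
                px_ = flat % w
                jit = rng.uniform(-0.5, 0.5, size=(n, 2))
                rows_x.append((px_ + jit[:, 0]) * mpp)
                rows_y.append((py + jit[:, 1]) * mpp)
                rows_g.append(np.repeat(spec.gene, n))
            truth_rows.append(
                {
                    "gene": spec.gene,
                    "zone": zone,
                    "expected_count": lam,
                    "realized_count": n if pix.size > 0 else 0,
                    "zone_area_um2": area,
                }
            )
    if not any_intensity:
        log.warning("all intensities zero: empty transcript table")
    if rows_x:
        table = pd.DataFrame(
            {
                "x": np.concatenate(rows_x),
                "y": np.concatenate(rows_y),
                "gene": np.concatenate(rows_g),
            }
        )
    else:
        table = pd.DataFrame({"x": [], "y": [], "gene": []})
    truth = {
        "per_zone": pd.DataFrame(truth_rows),
        "zone_radius": zone_radius,
        "window_area_um2": field.label_mask.size * pixel_area,
    }
    return table, truth


def csr_points(
    intensity: float,
    window_um: tuple[float, float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Homogeneous Poisson (CSR) points in a rectangular µm window."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    wx, wy = window_um
    n = rng.poisson(intensity * wx * wy)
    return np.column_stack([rng.uniform(0, wx, n), rng.uniform(0, wy, n)])


# ---------------------------------------------------------------------------
# Cell matrices


def make_cells(
    types: list[CellTypeSpec],
    n_cells_per_type: int,
    panel: list[str],
    field: PlaqueField,
    zone_radius: float = DEFAULT_ZONE_RADIUS_UM,
    seed: int | np.random.Generator = 0,
) -> tuple[CellMatrix, np.ndarray]:
    """Negative-binomial cell × gene counts with planted marker structure.

    Each cell of a type draws marker-gene counts at ``marker_mean`` and all
    other panel genes at ``background_mean``.  Cells with
    ``spatial_rule="plaque_adjacent"`` are placed at distance <= zone_radius
    from a plaque; others uniformly over the window.  Returns the matrix
    (all entries observed) and the true type labels.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    panel = list(panel)
    for t in types:
        missing = set(t.marker_genes) - set(panel)
        if missing:
            raise ValueError(f"markers of {t.type_name!r} not in panel: {sorted(missing)}")
    n_total = n_cells_per_type * len(types)
    counts = np.zeros((n_total, len(panel)))
    labels = np.empty(n_total, dtype=object)
    xs = np.zeros(n_total)
    ys = np.zeros(n_total)

    mpp = field.scale.microns_per_pixel
    w = field.shape[1]
    zone_px = _zone_pixel_indices(field, zone_radius)
    near_px = np.concatenate([zone_px["inside"], zone_px["adjacent"]])
    all_px = np.arange(field.label_mask.size)

    def nb(mean, size, n):
        if mean <= 0:
            return np.zeros(n, dtype=int)
        p = size / (size + mean)
        return rng.negative_binomial(size, p, n)

    row = 0
    for t in types:
        marker_idx = [panel.index(g) for g in t.marker_genes]
        for _ in range(n_cells_per_type):
            counts[row, :] = nb(t.background_mean, t.dispersion, len(panel))
            counts[row, marker_idx] = nb(t.marker_mean, t.dispersion, len(marker_idx))
            labels[row] = t.type_name
            pool = near_px if t.spatial_rule == "plaque_adjacent" else all_px
            if pool.size == 0:
                raise PlacementError(
                    f"no pixels satisfy spatial_rule={t.spatial_rule!r} for {t.type_name!r}"
                )
            flat = pool[rng.integers(0, pool.size)]
            jit = rng.uniform(-0.5, 0.5, 2)
            xs[row] = (flat % w + jit[0]) * mpp
            ys[row] = (flat // w + jit[1]) * mpp
            row += 1

    cells = pd.DataFrame(
        {"cell_id": [f"cell_{i}" for i in range(n_total)], "x": xs, "y": ys}
    )
    cm = CellMatrix(counts=counts, genes=panel, cells=cells)
    return cm, labels


# ---------------------------------------------------------------------------
# Immunofluorescence image pairs


@dataclasses.dataclass(frozen=True)
class IFGeometry:
    """Layout of the synthetic nucleus / T-cell image pair (pixel units)."""

    image_size: tuple[int, int] = (256, 256)
    nucleus_radius_px: float = 4.0
    min_separation_px: float = 18.0
    margin_px: float = 10.0
    nucleus_amplitude: float = 100.0
    tcell_radius_px: float = 7.0
    tcell_amplitude: float = 100.0
    background: float = 5.0
    noise_sd: float = 1.0


def make_if_images(
    n_nuclei: int,
    n_tcells: int,
    geometry: IFGeometry | None = None,
    seed: int | np.random.Generator = 0,
    scale: PixelScale | None = None,
    gradient_amplitude: float = 0.0,
) -> tuple[StainImage, StainImage, dict]:
    """Paired DAPI / T-cell-channel images with known object counts.

    One bright blob per nucleus in the DAPI channel; a bright disk over each
    of the first ``n_tcells`` nuclei in the T-cell channel.  An optional
    linear intensity gradient (amplitude over the image width) emulates
    uneven illumination that rolling-ball background subtraction removes.
    """
    if n_tcells > n_nuclei:
        raise ValueError("n_tcells must be <= n_nuclei")
    geom = geometry or IFGeometry()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scale = scale or PixelScale(1.0)
    h, w = geom.image_size

    centers = []
    tries = 0
    max_tries = 2000 * max(n_nuclei, 1)
    m = geom.margin_px
    while len(centers) < n_nuclei:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_nuclei} nuclei with separation "
                f">= {geom.min_separation_px} px in a {h}x{w} frame"
            )
        tries += 1
        cy = rng.uniform(m, h - m)
        cx = rng.uniform(m, w - m)
        if all(np.hypot(cy - y0, cx - x0) >= geom.min_separation_px for y0, x0 in centers):
            centers.append((cy, cx))

    tcell_flags = np.zeros(n_nuclei, dtype=bool)
    tcell_flags[:n_tcells] = True

    yy, xx = np.indices((h, w))
    dapi = np.full((h, w), geom.background, dtype=float)
    tcell = np.full((h, w), geom.background, dtype=float)
    sig = geom.nucleus_radius_px / 1.5
    for (cy, cx) in centers:
        dapi += geom.nucleus_amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2)
        )
    for flag, (cy, cx) in zip(tcell_flags, centers):
        if flag:
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= geom.tcell_radius_px ** 2
            tcell[disk] += geom.tcell_amplitude
    if gradient_amplitude:
        ramp = gradient_amplitude * xx / max(w - 1, 1)
        dapi += ramp
        tcell += ramp
    dapi += rng.normal(0, geom.noise_sd, (h, w))
    tcell += rng.normal(0, geom.noise_sd, (h, w))

    truth = {
        "centers_px": [(float(cy), float(cx)) for cy, cx in centers],
        "tcell_flags": tcell_flags.tolist(),
        "n_nuclei": n_nuclei,
        "n_tcells": n_tcells,
    }
    return (
        StainImage(dapi, scale, channel="dapi"),
        StainImage(tcell, scale, channel="tcell"),
        truth,
    )


def simulate_field(
    n_plaques: int = 8,
    image_size: tuple[int, int] = (512, 512),
    seed: int | np.random.Generator = 0,
    scale: PixelScale | None = None,
    **kwargs,
) -> tuple[StainImage, PlaqueField, dict]:
    """Convenience: plaque image plus the ground-truth distance field."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    img, mask, truth = make_plaque_image(
        n_plaques, image_size=image_size, seed=rng, scale=scale, **kwargs
    )
    field = field_from_mask(mask, img.scale)
    return img, field, truth
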