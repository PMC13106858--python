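"""Immunofluorescence T-cell quantification chain.

Mirrors the classic ImageJ-style recipe: rolling-ball background
subtraction (radius 30 px), Gaussian blur, prominence-based maxima
detection on the DAPI channel (one point per nucleus), a threshold mask on
the T-cell channel, nucleus points inside the mask counted as T cells, and
per-plaque T-cell counts within a 90 px radius of each plaque center.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.morphology import h_maxima
from skimage.restoration import rolling_ball

from .io import StainImage

log = logging.getLogger("plaqueniche")


def subtract_background(img: StainImage, radius: int = 30) -> StainImage:
    """Rolling-ball background subtraction.

    The background is estimated by grayscale morphology with a ball
    structuring element of the given radius (the classic algorithm, not the
    sliding-paraboloid variant) and subtracted; the output is nonnegative.
    As in the classic implementation, the image is lightly smoothed (3x3
    mean) before the ball is rolled so the estimate does not ride under
    pixel noise; the subtraction itself uses the original intensities.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(img.shape):
        raise ValueError(
            f"radius {radius} >= smallest image dimension {min(img.shape)}"
        )
    data = img.data.astype(float)
    smoothed = ndimage.uniform_filter(data, size=3)
    background = np.minimum(rolling_ball(smoothed, radius=radius), data)
    out = np.clip(data - background, 0, None)
    return StainImage(out, img.scale, img.channel)


def detect_nuclei(
    dapi: StainImage,
    blur_radius: float = 5.0,
    prominence: float = 1.0,
    exclude_border: int = 1,
) -> np.ndarray:
    """Nucleus center points from the (background-subtracted) DAPI channel.

    Gaussian smoothing (sigma = blur_radius px) followed by detection of
    local maxima with prominence — height above the highest saddle to any
    higher maximum — of at least the threshold; sub-peaks below it merge
    into one point.  The prominence applies to the image's own intensity
    scale; :func:`run_counting_chain` feeds it display-scaled (8-bit-like)
    data so that the conventional threshold of 1 keeps its meaning.
    Maxima whose point lies within ``exclude_border`` pixels of the image
    edge are discarded (blur and background estimation are unreliable
    there, producing spurious edge ridges).  Returns (N, 2) pixel
    coordinates ``(x, y)`` ordered by raster position of each maximum
    (deterministic tie-break).
    """
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    blurred = ndimage.gaussian_filter(dapi.data.astype(float), blur_radius)
    if float(blurred.max() - blurred.min()) < prominence:
        return np.empty((0, 2))
    peaks = h_maxima(blurred, prominence)
    labels, n = ndimage.label(peaks)
    if n == 0:
        return np.empty((0, 2))
    centers = ndimage.center_of_mass(peaks, labels, range(1, n + 1))
    pts = np.array([(cx, cy) for cy, cx in centers], dtype=float)
    if exclude_border > 0:
        h, w = dapi.shape
        b = exclude_border
        keep = (
            (pts[:, 0] >= b) & (pts[:, 0] < w - b)
            & (pts[:, 1] >= b) & (pts[:, 1] < h - b)
        )
        pts = pts[keep]
    if len(pts) == 0:
        return np.empty((0, 2))
    order = np.lexsort((pts[:, 0], pts[:, 1]))  # raster order: y, then x
    return pts[order]


@dataclasses.dataclass
class CountResult:
    """Nucleus points with T-cell flags and chain parameters."""

    nucleus_points: np.ndarray  # (N, 2) px, (x, y)
    tcell_flags: np.ndarray  # bool per nucleus
    n_nuclei: int
    n_tcells: int
    parameters: dict

    @property
    def tcell_frequency(self) -> float:
        return self.n_tcells / self.n_nuclei if self.n_nuclei else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.nucleus_points[:, 0],
                "y": self.nucleus_points[:, 1],
                "is_tcell": self.tcell_flags,
            }
        )


def count_tcells(
    nucleus_points: np.ndarray,
    tcell_img: StainImage,
    channel_threshold: float,
    parameters: dict | None = None,
    mask: np.ndarray | None = None,
) -> CountResult:
    """Flag nuclei whose point falls in the thresholded T-cell channel.

    The threshold applies to the min-max normalized [0, 1] channel (or to a
    precomputed boolean ``mask``); every DAPI maximum inside the resulting
    mask counts as a T cell, all maxima count as total cells.
    """
    if not 0 <= channel_threshold <= 1:
        raise ValueError("channel_threshold must be within [0, 1]")
    nucleus_points = np.atleast_2d(np.asarray(nucleus_points, dtype=float))
    if nucleus_points.size == 0:
        nucleus_points = np.empty((0, 2))
    if mask is None:
        mask = tcell_img.normalized() > channel_threshold
    h, w = mask.shape
    flags = np.zeros(len(nucleus_points), dtype=bool)
    for i, (x, y) in enumerate(nucleus_points):
        r, c = int(round(y)), int(round(x))
        if 0 <= r < h and 0 <= c < w:
            flags[i] = mask[r, c]
    params = dict(parameters or {})
    params["channel_threshold"] = channel_threshold
    return CountResult(
        nucleus_points=nucleus_points,
        tcell_flags=flags,
        n_nuclei=len(nucleus_points),
        n_tcells=int(flags.sum()),
        parameters=params,
    )


def run_counting_chain(
    dapi: StainImage,
    tcell_img: StainImage,
    background_radius: int = 30,
    blur_radius: float = 5.0,
    prominence: float = 1.0,
    channel_threshold: float = 0.5,
) -> CountResult:
    """Full chain: background subtraction, blur + maxima, threshold count.

    The channel pair is first converted to a shared 8-bit-like display
    scale — min-max over both channels jointly, mapped to [0, 255] — as a
    single-acquisition pair would be.  Rolling-ball background estimation
    and the prominence threshold act on intensity units, so this fixed
    scale makes the whole chain invariant to multiplying the raw
    intensities by any positive constant; the shared range also keeps a
    signal-free T-cell channel dark instead of stretching its noise to
    full range.
    """
    lo = min(float(dapi.data.min()), float(tcell_img.data.min()))
    hi = max(float(dapi.data.max()), float(tcell_img.data.max()))
    span = (hi - lo) if hi > lo else 1.0

    def display(img: StainImage) -> StainImage:
        return StainImage((img.data - lo) / span * 255.0, img.scale, img.channel)

    dapi_bg = subtract_background(display(dapi), background_radius)
    tcell_bg = subtract_background(display(tcell_img), background_radius)
    pts = detect_nuclei(dapi_bg, blur_radius, prominence)
    # threshold on the shared display scale, not per-channel min-max
    mask = tcell_bg.data / 255.0 > channel_threshold
    return count_tcells(
        pts,
        tcell_bg,
        channel_threshold,
        parameters={
            "background_radius": background_radius,
            "blur_radius": blur_radius,
            "prominence": prominence,
        },
        mask=mask,
    )


def tcells_per_plaque(
    plaque_centers: np.ndarray,
    result: CountResult,
    radius: float = 90.0,
) -> pd.DataFrame:
    """Per-plaque T-cell counts within a fixed radius of each center.

    Each flagged T cell within the radius of at least one center is counted
    once, for the nearest center, preventing double counting.  Units are
    pixels, matching the counting chain.
    """
    plaque_centers = np.atleast_2d(np.asarray(plaque_centers, dtype=float))
    if plaque_centers.size == 0:
        raise ValueError("empty plaque-center list")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    counts = np.zeros(len(plaque_centers), dtype=int)
    tpts = result.nucleus_points[result.tcell_flags]
    for x, y in tpts:
        d = np.hypot(plaque_centers[:, 0] - x, plaque_centers[:, 1] - y)
        k = int(np.argmin(d))
        if d[k] <= radius:
            counts[k] += 1
    return pd.DataFrame(
        {
            "plaque_x": plaque_centers[:, 0],
            "plaque_y": plaque_centers[:, 1],
            "tcell_count": counts,
        }
    )


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std(ddof=0)
    ry = (ry - ry.mean()) / ry.std(ddof=0)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(rx, ry[list(perm)])) / n
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    exact_max_n: int = 9,
) -> dict:
    """Spearman correlation with a least-squares fit for plotting parity.

    Ties are midranked.  The p-value is an exact permutation value for
    n <= ``exact_max_n`` and the usual t-approximation otherwise.  The
    returned dict also carries the linear-regression line and the half-width
    parameters of its 95% confidence band.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman's rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    fit = stats.linregress(x, y)
    # 95% CI half-width of the mean prediction at x0:
    # t * s * sqrt(1/n + (x0 - xbar)^2 / Sxx)
    resid = y - (fit.intercept + fit.slope * x)
    s = math.sqrt(float((resid ** 2).sum()) / (n - 2)) if n > 2 else np.nan
    return {
        "rho": rho,
        "p": p,
        "n": n,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.rvalue ** 2,
        "ci_t": float(stats.t.ppf(0.975, n - 2)),
        "ci_s": s,
        "ci_xbar": float(x.mean()),
        "ci_sxx": float(((x - x.mean()) ** 2).sum()),
    }
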