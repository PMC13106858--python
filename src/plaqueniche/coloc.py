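"""Annulus-renormalized distance histograms (colocalization profiles).

For each reference ("marker 2") point, the histogram of distances to all
marker-1 points is computed; the per-reference histograms are averaged and
each bin is divided by its annulus area pi*w^2*(2b-1), converting the radial
histogram into a density that is flat under complete spatial randomness.
No window edge correction is applied.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .plaques import PlaqueField, query_distance

log = logging.getLogger("plaqueniche")


def annulus_areas(bin_width: float, n_bins: int) -> np.ndarray:
    """Ring areas pi*((b*w)^2 - ((b-1)*w)^2) = pi*w^2*(2b-1), b = 1..n."""
    b = np.arange(1, n_bins + 1)
    return np.pi * bin_width ** 2 * (2 * b - 1)


@dataclasses.dataclass
class DistanceProfile:
    """Radial distance histogram with annulus renormalization.

    ``normalized_density`` has relative units when built from a
    probability-density histogram (see ``density_normalized`` flag): the
    composition of density normalization with the annulus divide preserves
    shape, not absolute intensity.
    """

    bin_edges: np.ndarray  # length B+1, µm
    raw_count: np.ndarray  # mean count per reference point, length B
    annulus_area: np.ndarray  # µm², length B
    normalized_density: np.ndarray  # length B
    n_reference_points: int
    density_normalized: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self, **annot) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "raw": self.raw_count,
                "annulus_area": self.annulus_area,
                "density": self.normalized_density,
            }
        )
        for k, v in annot.items():
            df.insert(0, k, v)
        return df


def _check_bins(bin_width: float, max_range: float) -> int:
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = max_range / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("max_range must be a multiple of bin_width")
    return int(round(n_bins))


def distance_profile(
    marker1: np.ndarray,
    reference: np.ndarray,
    bin_width: float = 5.0,
    max_range: float = 200.0,
) -> DistanceProfile:
    """Average, annulus-renormalized distance histogram of marker 1 around
    reference points.

    Parameters
    ----------
    marker1, reference:
        (N, 2) µm coordinates.  ``reference`` plays the paper-2 role: one
        histogram per reference point, averaged over references (not
        pair-pooled).
    """
    marker1 = np.atleast_2d(np.asarray(marker1, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.size == 0:
        raise ValueError("empty reference point set")
    n_bins = _check_bins(bin_width, max_range)
    edges = np.arange(n_bins + 1) * bin_width
    areas = annulus_areas(bin_width, n_bins)
    if marker1.size == 0:
        log.warning("empty marker1 set: all-zero profile")
        zero = np.zeros(n_bins)
        return DistanceProfile(edges, zero, areas, zero.copy(), len(reference))

    counts = np.zeros(n_bins)
    # chunk references to bound the pairwise-distance matrix
    chunk = max(1, int(2e7) // max(len(marker1), 1))
    for i in range(0, len(reference), chunk):
        d = cdist(reference[i: i + chunk], marker1)
        h, _ = np.histogram(d, bins=edges)
        counts += h
    mean_counts = counts / len(reference)
    return DistanceProfile(
        bin_edges=edges,
        raw_count=mean_counts,
        annulus_area=areas,
        normalized_density=mean_counts / areas,
        n_reference_points=len(reference),
    )


def zone_filtered_references(
    reference: np.ndarray,
    field: PlaqueField,
    zone_radius: float,
) -> np.ndarray:
    """Keep only references in the inside + adjacent zones."""
    d, _, ok = query_distance(field, reference[:, 0], reference[:, 1])
    keep = ok & (d <= zone_radius)
    return reference[keep]


def marker_set_profile(
    table: pd.DataFrame,
    set_genes: list[str],
    reference: np.ndarray,
    bin_width: float = 5.0,
    max_range: float = 200.0,
) -> DistanceProfile:
    """Mean profile over a marker gene set (each gene as marker 1).

    Genes absent from the table are dropped with a warning; an empty
    intersection is an error.
    """
    present = [g for g in set_genes if (table["gene"] == g).any()]
    absent = sorted(set(set_genes) - set(present))
    if absent:
        log.warning("marker genes absent from table, dropped: %s", absent)
    if not present:
        raise ValueError("no marker-set gene present in the transcript table")
    profiles = []
    for g in present:
        pts = table.loc[table["gene"] == g, ["x", "y"]].to_numpy(float)
        profiles.append(distance_profile(pts, reference, bin_width, max_range))
    mean_raw = np.mean([p.raw_count for p in profiles], axis=0)
    mean_norm = np.mean([p.normalized_density for p in profiles], axis=0)
    ref0 = profiles[0]
    return DistanceProfile(
        bin_edges=ref0.bin_edges,
        raw_count=mean_raw,
        annulus_area=ref0.annulus_area,
        normalized_density=mean_norm,
        n_reference_points=ref0.n_reference_points,
    )


def plaque_distance_profile(
    points: np.ndarray,
    field: PlaqueField,
    bin_width: float = 5.0,
    max_range: float = 200.0,
    density: bool = True,
) -> DistanceProfile:
    """Annulus-renormalized histogram of point distance-to-plaque.

    Distances come from the pixel-resolution distance field, matching the
    field-based analysis; with ``density=True`` the histogram is first
    normalized to a probability density (resulting units are relative).
    """
    n_bins = _check_bins(bin_width, max_range)
    edges = np.arange(n_bins + 1) * bin_width
    areas = annulus_areas(bin_width, n_bins)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        nan = np.full(n_bins, np.nan)
        return DistanceProfile(edges, np.zeros(n_bins), areas, nan, 0, density)
    d, _, ok = query_distance(field, points[:, 0], points[:, 1])
    d = d[ok & np.isfinite(d)]
    h, _ = np.histogram(d, bins=edges, density=density)
    return DistanceProfile(
        bin_edges=edges,
        raw_count=np.histogram(d, bins=edges)[0].astype(float),
        annulus_area=areas,
        normalized_density=h / areas,
        n_reference_points=len(d),
        density_normalized=density,
    )


def relative_overrepresentation(
    table: pd.DataFrame,
    gene: str,
    field: PlaqueField,
    bin_width: float = 5.0,
    max_range: float = 200.0,
    low_count: int = 10,
) -> pd.DataFrame:
    """Per-bin ratio of a gene's plaque-distance density profile to the
    pooled all-genes baseline.

    Both profiles are probability-density histograms of transcript
    distance-to-plaque, annulus-renormalized; the ratio captures relative
    over-representation near plaques.  Genes with fewer than ``low_count``
    transcripts are emitted with a ``low_count`` flag.
    """
    gene_pts = table.loc[table["gene"] == gene, ["x", "y"]].to_numpy(float)
    all_pts = table[["x", "y"]].to_numpy(float)
    gp = plaque_distance_profile(gene_pts, field, bin_width, max_range)
    bp = plaque_distance_profile(all_pts, field, bin_width, max_range)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            bp.normalized_density > 0,
            gp.normalized_density / bp.normalized_density,
            np.nan,
        )
    out = gp.to_frame(gene=gene)
    out["baseline_density"] = bp.normalized_density
    out["ratio"] = ratio
    out["low_count"] = len(gene_pts) < low_count
    if len(gene_pts) < low_count:
        log.warning("gene %s has only %d transcripts (low-count flag)", gene, len(gene_pts))
    return out
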