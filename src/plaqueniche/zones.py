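"""Three-zone neighborhood assignment, area-normalized densities, and the
Kruskal–Wallis + Dunn zone tests.

Zones by distance d to the nearest plaque: ``inside`` (d = 0, i.e. on a
plaque pixel), ``adjacent`` (0 < d <= zone_radius) and ``outside``
(d > zone_radius).  The default radius is 69 µm.  Densities are transcript
counts divided by the pixel-counted zone area clipped to the imaged window.
"""
from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_ZONE_RADIUS_UM
from .plaques import PlaqueField, query_distance

log = logging.getLogger("plaqueniche")

ZONES = ("inside", "adjacent", "outside")


def classify_distance(d: np.ndarray, zone_radius: float = DEFAULT_ZONE_RADIUS_UM) -> np.ndarray:
    """Map distances (µm) to zone names; boundary d == radius is adjacent."""
    d = np.asarray(d, dtype=float)
    zone = np.where(d == 0, "inside", np.where(d <= zone_radius, "adjacent", "outside"))
    return zone.astype(object)


def assign_zones(
    field: PlaqueField,
    points: pd.DataFrame,
    zone_radius: float = DEFAULT_ZONE_RADIUS_UM,
) -> pd.DataFrame:
    """Assign each transcript point to a zone and its nearest plaque.

    Returns the input table with ``distance`` (µm), ``zone``,
    ``nearest_plaque_id`` and ``in_bounds`` columns appended; out-of-bounds
    points keep NaN distance and are excluded from all densities.
    """
    if zone_radius <= 0:
        raise ValueError("zone_radius must be > 0")
    if field.n_plaques == 0:
        log.warning("empty plaque set: all points assigned 'outside'")
    d, pid, ok = query_distance(field, points["x"].to_numpy(), points["y"].to_numpy())
    out = points.copy()
    out["distance"] = d
    out["zone"] = pd.array(
        np.where(ok, classify_distance(np.nan_to_num(d, nan=np.inf), zone_radius), "out_of_bounds"),
        dtype=object,
    )
    out["nearest_plaque_id"] = pid
    out["in_bounds"] = ok
    return out


def zone_areas(
    field: PlaqueField,
    zone_radius: float = DEFAULT_ZONE_RADIUS_UM,
) -> pd.Series:
    """Pixel-counted zone areas (µm²) clipped to the imaged window.

    The three areas always sum exactly to the window area (a partition).
    """
    d = field.distance
    pixel_area = field.scale.pixel_area_um2
    inside = int((d == 0).sum())
    adjacent = int(((d > 0) & (d <= zone_radius)).sum())
    outside = d.size - inside - adjacent
    return pd.Series(
        {z: n * pixel_area for z, n in zip(ZONES, (inside, adjacent, outside))},
        name="area_um2",
    )


def per_plaque_zone_areas(
    field: PlaqueField,
    zone_radius: float = DEFAULT_ZONE_RADIUS_UM,
) -> pd.DataFrame:
    """Zone areas partitioned by nearest plaque (ties to lower plaque id).

    Every pixel of the window belongs to exactly one (plaque, zone) cell,
    so the areas sum to the window area.
    """
    if field.n_plaques == 0:
        raise ValueError("per-plaque areas undefined without plaques")
    d = field.distance.ravel()
    pid = field.nearest_label.ravel()
    zone_idx = np.where(d == 0, 0, np.where(d <= zone_radius, 1, 2))
    pixel_area = field.scale.pixel_area_um2
    rows = []
    for p in range(1, field.n_plaques + 1):
        sel = pid == p
        for zi, z in enumerate(ZONES):
            rows.append(
                {
                    "plaque_id": p,
                    "zone": z,
                    "area_um2": int((sel & (zone_idx == zi)).sum()) * pixel_area,
                }
            )
    return pd.DataFrame(rows)


def zone_density(
    assignment: pd.DataFrame,
    areas: pd.Series | pd.DataFrame,
    genes: list[str] | None = None,
    per_plaque: bool = False,
) -> pd.DataFrame:
    """Per-gene per-zone transcript densities (count / µm²).

    With ``per_plaque=True``, ``areas`` must be the per-plaque partition from
    :func:`per_plaque_zone_areas` and counts are split by nearest plaque.
    Zero-area cells get NaN density and a ``degenerate`` flag.  Genes
    requested but absent from the table yield zero-count rows with a warning.
    """
    pts = assignment[assignment["in_bounds"]]
    if genes is None:
        genes = sorted(pts["gene"].unique())
    else:
        missing = set(genes) - set(pts["gene"].unique())
        if missing:
            log.warning("genes absent from transcript table: %s", sorted(missing))

    rows = []
    if per_plaque:
        if not isinstance(areas, pd.DataFrame):
            raise ValueError("per_plaque=True requires per-plaque areas")
        area_lut = areas.set_index(["plaque_id", "zone"])["area_um2"]
        grp = pts.groupby(["gene", "nearest_plaque_id", "zone"], observed=True).size()
        plaque_ids = sorted(areas["plaque_id"].unique())
        for g in genes:
            for p in plaque_ids:
                for z in ZONES:
                    n = int(grp.get((g, p, z), 0))
                    a = float(area_lut.get((p, z), 0.0))
                    rows.append(_density_row(g, z, n, a, plaque_id=p))
    else:
        grp = pts.groupby(["gene", "zone"], observed=True).size()
        for g in genes:
            for z in ZONES:
                n = int(grp.get((g, z), 0))
                a = float(areas[z])
                rows.append(_density_row(g, z, n, a))
    return pd.DataFrame(rows)


def _density_row(gene, zone, count, area, plaque_id=None):
    row = {
        "gene": gene,
        "zone": zone,
        "transcript_count": count,
        "zone_area_um2": area,
        "density": count / area if area > 0 else np.nan,
        "degenerate": area <= 0,
    }
    if plaque_id is not None:
        row["plaque_id"] = plaque_id
    return row


def scale_per_gene(density_table: pd.DataFrame) -> pd.DataFrame:
    """z-score densities across rows of each gene (display parity only)."""
    out = density_table.copy()

    def z(v):
        s = v.std(ddof=0)
        return (v - v.mean()) / s if s > 0 else v * 0.0

    out["density_scaled"] = out.groupby("gene")["density"].transform(z)
    return out


# ---------------------------------------------------------------------------
# Rank statistics


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    adjust: str = "holm",
    pairwise: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Kruskal–Wallis omnibus plus Dunn's pairwise post-hoc tests.

    Parameters
    ----------
    groups:
        Mapping group name -> 1-D observations (e.g. per-plaque densities
        per zone).  Ties are midranked with the standard tie correction.
    adjust:
        Multiplicity adjustment over all pairs: ``"holm"`` (default) or
        ``"bonferroni"``.
    pairwise:
        Skip the Dunn post-hoc table when False (omnibus only; cheap in
        Monte-Carlo loops).

    Returns
    -------
    omnibus:
        Series with ``H``, ``df``, ``p``.
    pairwise:
        DataFrame with one row per pair: ``z``, ``p_raw``, ``p_adj``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(np.asarray(v)) == 0:
            raise ValueError(f"group {name!r} has no observations")
    values = [np.asarray(groups[n], dtype=float) for n in names]

    if all(np.array_equal(v, values[0]) for v in values[1:]) and all(
        np.ptp(v) == 0 for v in values
    ):
        # All observations identical: H = 0 by convention, p = 1.
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values)

    omnibus = pd.Series({"H": h, "df": len(names) - 1, "p": p})
    if not pairwise:
        return omnibus, pd.DataFrame(
            columns=["comparison", "z", "p_raw", "p_adj", "method"]
        )

    pooled = np.concatenate(values)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    sizes = np.array([v.size for v in values])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(names))]
    )
    # Tie correction term for Dunn's z.
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n_total - 1))

    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append(
            {"comparison": f"{names[i]} vs {names[j]}", "z": z, "p_raw": p_raw}
        )
    pw = pd.DataFrame(rows)
    if len(pw):
        pw["p_adj"] = multipletests(pw["p_raw"], method=adjust)[1]
        pw["method"] = f"dunn-{adjust}"
    return omnibus, pw
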