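"""Readers and writers for the formats the pipeline touches.

Transcript tables are CSV/TSV with header columns ``x, y, gene``; stain
images are single-channel TIFF; segmented cell matrices are an MTX file plus
``genes.tsv`` and ``cells.tsv`` side-cars.  Coordinates are converted to µm
on read and all round-trips are lossless (bitwise for integers, <=1e-9
relative for floats).
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import tifffile

from .config import PixelScale

log = logging.getLogger("plaqueniche")


class FormatError(ValueError):
    """Input file does not match the expected layout."""


@dataclasses.dataclass
class StainImage:
    """2-D grayscale intensity grid with attached pixel scale.

    ``data[row, col]`` follows raster convention: row index is y, column
    index is x.  ``channel`` tags the source stain (e.g. ``"amyloid"``,
    ``"dapi"``, ``"tcell"``).
    """

    data: np.ndarray
    scale: PixelScale
    channel: str = "amyloid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError(f"expected 2-D image, got shape {self.data.shape}")
        if self.data.size == 0:
            raise FormatError("zero-size image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def normalized(self) -> np.ndarray:
        """Min-max normalized view on [0, 1].

        A constant image has no contrast to normalize; it is flagged in the
        log and an all-zeros view is returned.
        """
        lo = float(self.data.min())
        hi = float(self.data.max())
        if hi == lo:
            log.warning("constant image: min-max normalization degenerate, returning zeros")
            return np.zeros(self.data.shape, dtype=float)
        return (self.data.astype(float) - lo) / (hi - lo)


def read_stain_image(
    path: str | Path,
    scale: PixelScale | None = None,
    channel_index: int | None = None,
    channel: str = "amyloid",
) -> StainImage:
    """Read a single-channel 2-D TIFF (or one channel of a stack)."""
    scale = scale or PixelScale()
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        if channel_index is None:
            raise FormatError(
                f"{path}: 3-D stack of shape {data.shape} requires an explicit channel_index"
            )
        data = data[channel_index]
    if data.ndim != 2:
        raise FormatError(f"{path}: expected 2-D image, got shape {data.shape}")
    return StainImage(data=data, scale=scale, channel=channel)


def write_stain_image(path: str | Path, img: StainImage) -> None:
    tifffile.imwrite(str(path), img.data)


# ---------------------------------------------------------------------------
# Transcript tables


def read_transcripts(
    path: str | Path,
    unit: str = "px",
    scale: PixelScale | None = None,
) -> pd.DataFrame:
    """Read a transcript point table into a µm-coordinate DataFrame.

    Parameters
    ----------
    path:
        CSV or TSV file with header columns ``x``, ``y``, ``gene``
        (Molecular Cartography-style point export).
    unit:
        ``"px"`` or ``"um"``; pixel coordinates are converted through
        ``scale`` so the returned table is always in µm.
    scale:
        Pixel size; defaults to the rendered-slide scale (0.138 µm/px).

    Returns
    -------
    DataFrame with columns ``x``, ``y`` (float µm) and ``gene`` (str), input
    record order preserved.  Rows with an empty gene name or non-numeric
    coordinates are rejected and logged.
    """
    scale = scale or PixelScale()
    if unit not in ("px", "um", "µm"):
        raise ValueError(f"unit must be 'px' or 'um', got {unit!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype={"gene": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty transcript file") from None
    for col in ("x", "y", "gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: transcript table has no rows")

    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    gene = df["gene"].fillna("").astype(str)
    bad_coord = x.isna() | y.isna()
    for i in df.index[bad_coord]:
        log.warning("%s: row %d has non-numeric coordinate, dropped", path, i + 2)
    bad_gene = gene.str.len() == 0
    if bad_gene.any():
        log.warning("%s: %d rows with empty gene name dropped", path, int(bad_gene.sum()))
    keep = ~(bad_coord | bad_gene)
    out = pd.DataFrame({"x": x[keep], "y": y[keep], "gene": gene[keep]})
    out = out.reset_index(drop=True)
    if unit == "px":
        out["x"] = scale.to_um(out["x"].to_numpy(float))
        out["y"] = scale.to_um(out["y"].to_numpy(float))
    log.info("read %d transcripts (%d genes) from %s", len(out), out["gene"].nunique(), path)
    return out


def write_transcripts(path: str | Path, table: pd.DataFrame) -> None:
    """Write a µm transcript table as CSV (columns x, y, gene)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table[["x", "y", "gene"]].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Segmented cell matrices (MTX + genes.tsv + cells.tsv)


@dataclasses.dataclass
class CellMatrix:
    """Segmented cells: integer gene counts plus centroid coordinates.

    ``counts`` is a dense float array (cells × genes) in which NaN marks a
    *missing* measurement — distinct from an observed zero — so the
    marker-missingness filter can act before missing values are imputed to 0.
    """

    counts: np.ndarray
    genes: list[str]
    cells: pd.DataFrame  # columns: cell_id, x, y (µm)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise FormatError("counts must be 2-D (cells × genes)")
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.genes):
            raise FormatError(
                f"matrix has {n_genes} genes but metadata lists {len(self.genes)}"
            )
        if n_cells != len(self.cells):
            raise FormatError(
                f"matrix has {n_cells} cells but metadata lists {len(self.cells)}"
            )
        observed = self.counts[~np.isnan(self.counts)]
        if (observed < 0).any():
            raise FormatError("negative counts in cell matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.counts)

    def centroids(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(float)


def read_cell_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> CellMatrix:
    """Read an MTX sparse count matrix with gene and cell side-cars.

    Entries absent from the sparse file are recorded as *missing* (NaN),
    not zero: the export writes every measured entry explicitly, including
    measured zeros, so absence means the marker was not assayed for that
    cell.
    """
    m = scipy.io.mmread(str(matrix_path)).tocoo()
    genes = [ln.split("\t")[0] for ln in Path(genes_path).read_text().splitlines() if ln]
    cells = pd.read_csv(cells_path, sep="\t")
    for col in ("cell_id", "x", "y"):
        if col not in cells.columns:
            raise FormatError(f"{cells_path}: missing column {col!r}")
    counts = np.full((m.shape[0], m.shape[1]), np.nan)
    counts[m.row, m.col] = m.data
    return CellMatrix(counts=counts, genes=genes, cells=cells)


def write_cell_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    cm: CellMatrix,
) -> None:
    """Write the MTX trio; missing (NaN) entries are simply not stored."""
    obs = ~np.isnan(cm.counts)
    rows, cols = np.nonzero(obs)
    sp = scipy.sparse.coo_matrix(
        (cm.counts[rows, cols], (rows, cols)), shape=cm.counts.shape
    )
    # mmwrite drops explicit zeros from a COO only if eliminate_zeros is
    # called; keep them so measured zeros survive the round trip.
    _mmwrite_keep_zeros(matrix_path, sp)
    Path(genes_path).write_text("".join(f"{g}\n" for g in cm.genes))
    cm.cells.to_csv(cells_path, sep="\t", index=False)


def _mmwrite_keep_zeros(path: str | Path, m: scipy.sparse.coo_matrix) -> None:
    lines = [
        "%%MatrixMarket matrix coordinate real general\n",
        f"{m.shape[0]} {m.shape[1]} {m.nnz}\n",
    ]
    for r, c, v in zip(m.row, m.col, m.data):
        lines.append(f"{r + 1} {c + 1} {v:.17g}\n")
    Path(path).write_text("".join(lines))
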