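"""Tile-level data model and I/O for tiled whole-slide images.

A whole-slide image (WSI) is decomposed into a regular grid of square,
non-overlapping tiles (default 256x256 px).  Each tile carries a
*composition vector*: a point on the K-simplex giving the fraction of each
of K tissue/cell-type clusters among the tile's contents.  The grid is the
common currency of the package: clustering, ROI selection and evaluation
all operate on it.

Conventions
-----------
* Tiles are indexed ``(row, col)``, 0-based; the flat tile index is
  ``row * n_cols + col``.
* Pixel windows are half-open: tile ``(r, c)`` covers pixels
  ``[r*s, (r+1)*s) x [c*s, (c+1)*s)`` for tile size ``s``.
* Images whose dimensions are not multiples of the tile size lose their
  trailing partial tiles.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TileGrid",
    "build_grid_from_label_map",
    "assign_tile_annotation",
    "filter_background_tiles",
    "rescale_intensity_percentiles",
    "read_tile_table",
    "write_tile_table",
]

#: annotation value meaning "no annotated pixel in this tile"
NO_ANNOTATION = -1

_COMP_TOL = 1e-6


@dataclass
class TileGrid:
    """A tiled WSI with per-tile composition vectors.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape in tiles.
    tile_size_px : int
        Side of each square tile in pixels.
    compositions : ndarray, shape (n_tiles, K)
        Per-tile cluster composition; each *valid* tile's row sums to 1.
    labels : ndarray of int, shape (n_tiles,), optional
        Cluster id per tile; defaults to ``argmax`` of the composition.
    annotations : ndarray of int, shape (n_tiles,), optional
        Ground-truth annotation id per tile; ``-1`` marks tiles with no
        annotated pixel.
    valid : ndarray of bool, shape (n_tiles,), optional
        Tile validity mask; background-excluded tiles are invalid.
    embeddings : ndarray, shape (n_tiles, d), optional
        Per-tile feature vectors from any external encoder.
    """

    n_rows: int
    n_cols: int
    tile_size_px: int
    compositions: np.ndarray
    labels: np.ndarray | None = None
    annotations: np.ndarray | None = None
    valid: np.ndarray | None = None
    embeddings: np.ndarray | None = None

    def __post_init__(self):
        self.compositions = np.asarray(self.compositions, dtype=float)
        if self.compositions.ndim != 2:
            raise ValueError("compositions must be a 2-D (n_tiles, K) array")
        if self.compositions.shape[0] != self.n_tiles:
            raise ValueError(
                f"compositions has {self.compositions.shape[0]} rows, "
                f"expected n_rows*n_cols = {self.n_tiles}"
            )
        if self.valid is None:
            self.valid = np.ones(self.n_tiles, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.labels is None:
            self.labels = np.argmax(self.compositions, axis=1).astype(np.int64)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=np.int64)
        self._validate()

    def _validate(self):
        comp = self.compositions
        if np.any(comp < -_COMP_TOL) or np.any(comp > 1 + _COMP_TOL):
            raise ValueError("composition entries must lie in [0, 1]")
        sums = comp[self.valid].sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-4)
        if bad.size:
            idx = np.flatnonzero(self.valid)[bad]
            raise ValueError(
                f"valid-tile compositions must sum to 1; offending flat tile "
                f"indices: {idx[:10].tolist()}"
            )

    # -- geometry ---------------------------------------------------------

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_clusters(self) -> int:
        return self.compositions.shape[1]

    def flat_index(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    # -- derived quantities -----------------------------------------------

    def wsi_composition(self) -> np.ndarray:
        """Pooled composition ``b`` of all valid tiles — the slide-wide
        cluster fractions."""
        if not self.valid.any():
            raise ValueError("grid has no valid tiles")
        return self.compositions[self.valid].mean(axis=0)

    def copy(self) -> "TileGrid":
        return replace(
            self,
            compositions=self.compositions.copy(),
            labels=self.labels.copy(),
            annotations=None if self.annotations is None else self.annotations.copy(),
            valid=self.valid.copy(),
            embeddings=None if self.embeddings is None else self.embeddings.copy(),
        )


def _tile_windows(shape, tile_size_px):
    """Yield (row, col, row-slice, col-slice) of complete tiles; partial
    trailing tiles are dropped."""
    n_rows = shape[0] // tile_size_px
    n_cols = shape[1] // tile_size_px
    s = tile_size_px
    for r in range(n_rows):
        for c in range(n_cols):
            yield r, c, slice(r * s, (r + 1) * s), slice(c * s, (c + 1) * s)


def build_grid_from_label_map(label_map: np.ndarray, tile_size_px: int) -> TileGrid:
    """Build a :class:`TileGrid` from a pixel-level label map.

    ``label_map`` holds integer tissue/cell-type ids per pixel with 0
    meaning *unlabeled*.  ``composition[t, k]`` is the fraction of labeled
    pixels in tile ``t`` carrying id ``k+1``; tiles with no labeled pixel
    are marked invalid.
    """
    label_map = np.asarray(label_map)
    if label_map.ndim != 2 or label_map.size == 0:
        raise ValueError("label map must be a non-empty 2-D array")
    if tile_size_px < 1:
        raise ValueError("tile_size_px must be >= 1")
    if tile_size_px > min(label_map.shape):
        raise ValueError(
            f"tile size {tile_size_px} exceeds map extent {label_map.shape}"
        )
    if label_map.min() < 0:
        raise ValueError("pixel ids must be >= 0 (0 = unlabeled)")

    n_rows = label_map.shape[0] // tile_size_px
    n_cols = label_map.shape[1] // tile_size_px
    k_max = int(label_map.max())
    n_clusters = max(k_max, 1)
    comps = np.zeros((n_rows * n_cols, n_clusters))
    valid = np.zeros(n_rows * n_cols, dtype=bool)
    for r, c, rs, cs in _tile_windows(label_map.shape, tile_size_px):
        counts = np.bincount(label_map[rs, cs].ravel(), minlength=k_max + 1)
        labeled = counts[1:].sum()
        t = r * n_cols + c
        if labeled > 0:
            comps[t, : counts.size - 1] = counts[1:] / labeled
            valid[t] = True
    return TileGrid(n_rows, n_cols, tile_size_px, comps, valid=valid)


def assign_tile_annotation(label_map: np.ndarray, grid: TileGrid) -> TileGrid:
    """Assign each tile the annotation id with the largest pixel count
    inside the tile (ties broken toward the lowest id).

    Tiles with at least one annotated (non-zero) pixel receive that id;
    fully unlabeled tiles get :data:`NO_ANNOTATION` and are excluded from
    annotation-based analyses.
    """
    label_map = np.asarray(label_map)
    need = (grid.n_rows * grid.tile_size_px, grid.n_cols * grid.tile_size_px)
    if label_map.shape[0] < need[0] or label_map.shape[1] < need[1]:
        raise ValueError(
            f"annotation map {label_map.shape} does not cover the grid's "
            f"pixel extent {need}"
        )
    k_max = int(label_map.max())
    annotations = np.full(grid.n_tiles, NO_ANNOTATION, dtype=np.int64)
    for r, c, rs, cs in _tile_windows(need, grid.tile_size_px):
        counts = np.bincount(label_map[rs, cs].ravel(), minlength=k_max + 1)
        if counts[1:].sum() > 0:
            # argmax over ids >= 1; np.argmax takes the first (lowest id) on ties
            annotations[r * grid.n_cols + c] = int(np.argmax(counts[1:])) + 1
    out = grid.copy()
    out.annotations = annotations
    return out


def filter_background_tiles(
    rgb_tiles: np.ndarray,
    white_level: int = 210,
    area_fraction: float = 0.70,
) -> np.ndarray:
    """Mark background tiles of an 8-bit RGB tile stack.

    A tile is background iff the fraction of pixels whose three channels
    are *all* strictly above ``white_level`` (default 210) strictly exceeds
    ``area_fraction`` (default 0.70) — the standard white-slide exclusion
    rule for H&E tiles.

    Parameters
    ----------
    rgb_tiles : ndarray, shape (n_tiles, h, w, 3), integer dtype
        8-bit RGB pixel data per tile.

    Returns
    -------
    ndarray of bool, shape (n_tiles,)
        True where the tile is background.
    """
    rgb_tiles = np.asarray(rgb_tiles)
    if rgb_tiles.ndim != 4 or rgb_tiles.shape[-1] != 3:
        raise ValueError("expected an (n_tiles, h, w, 3) RGB stack")
    if not np.issubdtype(rgb_tiles.dtype, np.integer) or rgb_tiles.max(initial=0) > 255:
        raise ValueError(
            "background filtering expects 8-bit integer RGB values; rescale "
            "the input to 0..255 first"
        )
    white = np.all(rgb_tiles > white_level, axis=-1)
    frac = white.reshape(white.shape[0], -1).mean(axis=1)
    return frac > area_fraction


def rescale_intensity_percentiles(
    image: np.ndarray, lo_pct: float = 70.0, hi_pct: float = 99.99
) -> np.ndarray:
    """Min-max rescale a grayscale image to [0, 1] against the given
    intensity percentiles (defaults 70th and 99.99th, the usual contrast
    normalization for immunofluorescence channels).

    Values at or below the low percentile map to 0, at or above the high
    percentile to 1, linearly in between.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError("require 0 <= lo_pct < hi_pct <= 100")
    image = np.asarray(image, dtype=float)
    lo, hi = np.percentile(image, [lo_pct, hi_pct])
    if hi <= lo:
        warnings.warn(
            "intensity percentiles coincide (constant image?); returning zeros",
            stacklevel=2,
        )
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


# -- tabular I/O -----------------------------------------------------------

_REQUIRED_COLS = ("row", "col", "valid")


def write_tile_table(grid: TileGrid, path) -> None:
    """Write a grid to a CSV tile table (one row per tile)."""
    rows, cols = np.divmod(np.arange(grid.n_tiles), grid.n_cols)
    data = {"row": rows, "col": cols, "valid": grid.valid.astype(int)}
    data["label"] = grid.labels
    if grid.annotations is not None:
        data["annotation"] = grid.annotations
    for k in range(grid.n_clusters):
        data[f"composition_{k}"] = grid.compositions[:, k]
    if grid.embeddings is not None:
        for d in range(grid.embeddings.shape[1]):
            data[f"embedding_{d}"] = grid.embeddings[:, d]
    df = pd.DataFrame(data)
    header = (
        f"# roiselect tile table; n_rows={grid.n_rows} n_cols={grid.n_cols} "
        f"tile_size_px={grid.tile_size_px}\n"
    )
    if hasattr(path, "write"):
        path.write(header)
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.12g")


def read_tile_table(path, tile_size_px: int | None = None) -> TileGrid:
    """Read a CSV tile table into a :class:`TileGrid`.

    The table needs ``row``, ``col`` and ``valid`` columns plus either
    ``composition_0..K-1`` columns or a ``label`` column (from which
    one-hot compositions are synthesized).  A leading ``#`` comment line
    written by :func:`write_tile_table` carries the grid geometry;
    otherwise geometry is inferred from the row/col extents and
    ``tile_size_px`` must be supplied.
    """
    meta = {}
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    if text.startswith("#"):
        first, _, rest = text.partition("\n")
        for tok in first.lstrip("# ").split():
            if "=" in tok:
                key, _, val = tok.partition("=")
                try:
                    meta[key] = int(val)
                except ValueError:
                    pass
        text = rest
    df = pd.read_csv(io.StringIO(text))
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"tile table missing required columns: {missing}")

    n_rows = meta.get("n_rows", int(df["row"].max()) + 1)
    n_cols = meta.get("n_cols", int(df["col"].max()) + 1)
    tsize = meta.get("tile_size_px", tile_size_px)
    if tsize is None:
        raise ValueError("tile_size_px not in table header; pass it explicitly")
    if len(df) != n_rows * n_cols:
        raise ValueError(
            f"table has {len(df)} rows; expected {n_rows * n_cols} "
            f"({n_rows}x{n_cols} grid)"
        )
    order = np.lexsort((df["col"].to_numpy(), df["row"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)

    comp_cols = sorted(
        (c for c in df.columns if c.startswith("composition_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    valid = df["valid"].to_numpy().astype(bool)
    if comp_cols:
        comps = df[comp_cols].to_numpy(dtype=float)
        sums = comps[valid].sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-4)
        if bad.size:
            idx = np.flatnonzero(valid)[bad]
            raise ValueError(
                f"compositions must sum to 1; offending table rows "
                f"(0-based, sorted order): {idx[:10].tolist()}"
            )
    elif "label" in df.columns:
        labels = df["label"].to_numpy(dtype=np.int64)
        k = int(labels.max()) + 1
        comps = np.zeros((len(df), k))
        comps[np.arange(len(df)), labels] = 1.0
    else:
        raise ValueError("tile table needs composition_* columns or a label column")

    emb_cols = sorted(
        (c for c in df.columns if c.startswith("embedding_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    return TileGrid(
        n_rows,
        n_cols,
        tsize,
        comps,
        labels=df["label"].to_numpy(dtype=np.int64) if "label" in df.columns else None,
        annotations=(
            df["annotation"].to_numpy(dtype=np.int64)
            if "annotation" in df.columns
            else None
        ),
        valid=valid,
        embeddings=df[emb_cols].to_numpy(dtype=float) if emb_cols else None,
    )
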