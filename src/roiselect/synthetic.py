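"""Synthetic tissue generator with known ground truth.

Emulates the structure of a multiplexed-imaging WSI — a 2-D tissue made of
spatially contiguous regions of K tissue/cell-type clusters, tiled into
square tiles each carrying a cluster-composition vector — so that
clustering, ROI selection and evaluation can all be exercised against a
known answer without any real slide.

The label field is built by smoothing independent Gaussian white-noise
fields (one per cluster) and taking a per-pixel argmax after adding
per-cluster offsets; the offsets are tuned by coordinate-wise bisection so
the realized global cluster proportions land within +/-0.02 of the
requested target.  Smoothing length-scale controls region size: large
values give a few large contiguous blobs (histology-like), zero gives
i.i.d. pixel labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tilegrid import TileGrid, build_grid_from_label_map

__all__ = [
    "SyntheticSpec",
    "generate_label_field",
    "generate_tile_grid",
    "generate_paired_embeddings",
    "generate_mask_pair",
]

PROPORTION_TOL = 0.02


def _default_proportions():
    return None


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic tissue.

    Defaults mirror the study conditions the package targets: a 40x40 grid
    of 256-px tiles with K=7 clusters.
    """

    image_size_px: int = 40 * 256
    tile_size_px: int = 256
    n_clusters: int = 7
    target_proportions: np.ndarray | None = field(default_factory=_default_proportions)
    smoothness_px: float = 1024.0
    dirichlet_conc: float = np.inf
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.target_proportions is None:
            self.target_proportions = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.target_proportions = np.asarray(self.target_proportions, dtype=float)
        if self.target_proportions.size != self.n_clusters:
            raise ValueError("target_proportions must have length n_clusters")
        if abs(self.target_proportions.sum() - 1.0) > 1e-9 or np.any(
            self.target_proportions < 0
        ):
            raise ValueError("target_proportions must lie on the simplex")

    @property
    def grid_shape(self):
        n = self.image_size_px // self.tile_size_px
        return n, n


def _smooth_fields(n_clusters: int, size: int, sigma: float, rng: np.random.Generator):
    """K independent standardized smooth Gaussian fields of shape (size, size)."""
    fields = rng.standard_normal((n_clusters, size, size))
    if sigma > 0:
        fields = ndimage.gaussian_filter(fields, sigma=(0, sigma, sigma), mode="wrap")
    sd = fields.reshape(n_clusters, -1).std(axis=1)
    sd[sd == 0] = 1.0
    return fields / sd[:, None, None]


def _realized_proportions(fields, offsets):
    labels = np.argmax(fields + offsets[:, None, None], axis=0)
    counts = np.bincount(labels.ravel(), minlength=fields.shape[0])
    return counts / labels.size, labels


def _tune_offsets(fields, target, tol=PROPORTION_TOL, max_rounds=400):
    """Damped fixed-point search for per-cluster offsets so the argmax
    proportions match ``target`` within ``tol``.

    Raising a cluster's offset monotonically grows its share, so the
    update ``o_k += rate * (target_k - realized_k)`` converges for smooth
    fields; the step decays to polish the fit.
    """
    k = fields.shape[0]
    offsets = np.zeros(k)
    best = (np.inf, offsets.copy(), None, None)
    props, labels = _realized_proportions(fields, offsets)
    for i in range(max_rounds):
        err = props - target
        worst = np.abs(err).max()
        if worst < best[0]:
            best = (worst, offsets.copy(), props, labels)
        if worst <= tol * 0.25:
            break
        rate = 3.0 / (1.0 + i / 40.0)
        offsets = offsets - rate * err
        offsets -= offsets.mean()  # only offset differences matter
        props, labels = _realized_proportions(fields, offsets)
    else:
        _, offsets, props, labels = best
    return offsets, props, labels


def generate_label_field(spec: SyntheticSpec) -> np.ndarray:
    """Generate a pixel label map (ids 1..K, fully labeled) whose global
    cluster proportions match ``spec.target_proportions`` within +/-0.02.

    Deterministic for a fixed ``spec.seed``.  Raises if the offset search
    cannot reach the target at the requested smoothness, reporting the
    proportions actually achieved.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_clusters == 1:
        return np.ones((spec.image_size_px, spec.image_size_px), dtype=np.int32)

    # work on a coarser lattice when the field is smooth enough that the
    # fine structure is redundant (sigma stays >= 4 lattice units), then
    # upsample by nearest neighbour
    zoom = max(1, min(spec.tile_size_px // 8, int(spec.smoothness_px / 4)))
    work_size = -(-spec.image_size_px // zoom)
    fields = _smooth_fields(
        spec.n_clusters, work_size, spec.smoothness_px / zoom, rng
    )
    _, props, labels = _tune_offsets(fields, spec.target_proportions)
    if np.any(np.abs(props - spec.target_proportions) > PROPORTION_TOL):
        raise RuntimeError(
            "could not reach target proportions at this smoothness; achieved "
            f"{np.round(props, 4).tolist()} vs target "
            f"{np.round(spec.target_proportions, 4).tolist()}"
        )
    labels = (labels + 1).astype(np.int32)
    if zoom > 1:
        labels = np.repeat(np.repeat(labels, zoom, axis=0), zoom, axis=1)
        labels = labels[: spec.image_size_px, : spec.image_size_px]
    return labels


def generate_tile_grid(spec: SyntheticSpec, return_truth: bool = False):
    """Generate a :class:`TileGrid` from a synthetic label field.

    With finite ``spec.dirichlet_conc`` each tile's composition is
    resampled from a Dirichlet centered on the pixel-true composition with
    that concentration (measurement noise on cell-type calling); at
    ``inf`` compositions equal the pixel-true fractions exactly.

    Returns ``grid`` or ``(grid, truth)`` where ``truth`` is the
    ground-truth WSI composition (per-cluster pixel fractions).
    """
    label_map = generate_label_field(spec)
    grid = build_grid_from_label_map(label_map, spec.tile_size_px)
    counts = np.bincount(label_map.ravel(), minlength=spec.n_clusters + 1)[1:]
    truth = counts / counts.sum()
    if np.isfinite(spec.dirichlet_conc):
        rng = np.random.default_rng(spec.seed + 1)
        alpha0 = float(spec.dirichlet_conc)
        comps = grid.compositions
        noisy = np.empty_like(comps)
        for t in range(comps.shape[0]):
            alpha = comps[t] * alpha0 + 1e-3
            noisy[t] = rng.dirichlet(alpha)
        grid = TileGrid(
            grid.n_rows, grid.n_cols, grid.tile_size_px, noisy, valid=grid.valid
        )
    if return_truth:
        return grid, truth
    return grid


def generate_paired_embeddings(
    grid: TileGrid, dim: int = 16, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Per-tile embeddings standing in for an external encoder's latents.

    Each embedding is a fixed random linear map of the tile's composition
    plus isotropic Gaussian noise.  At ``noise_sd=0`` the embeddings are an
    exact linear function of composition, so the first K-1 canonical
    correlations against the compositions equal 1.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    mixing = rng.standard_normal((grid.n_clusters, dim))
    emb = grid.compositions @ mixing
    if noise_sd > 0:
        emb = emb + noise_sd * rng.standard_normal(emb.shape)
    return emb


def generate_mask_pair(
    shape: tuple[int, int], target_dice: float, seed: int = 0, tol: float = 0.05
):
    """Generate two binary nuclear masks with a prescribed Dice overlap.

    The first mask is a field of disk-like nuclei; the second is a
    morphological perturbation of it (random pixel flips at a rate found by
    bisection) whose realized Dice lands within ``tol`` of ``target_dice``.
    ``target_dice=1`` returns identical masks.
    """
    if not (0 < target_dice <= 1):
        raise ValueError("target_dice must be in (0, 1]")
    rng = np.random.default_rng(seed)
    base = np.zeros(shape, dtype=bool)
    n_nuclei = max(4, shape[0] * shape[1] // 400)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(n_nuclei):
        cy, cx = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        r = rng.integers(3, max(4, min(shape) // 16))
        base |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if target_dice >= 1.0:
        return base, base.copy()

    def _dice(a, b):
        denom = a.sum() + b.sum()
        return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom

    def _perturb(rate):
        flip = np.random.default_rng(seed + 1).random(shape) < rate
        return base ^ flip

    lo, hi = 0.0, 1.0
    other = base.copy()
    for _ in range(40):
        rate = 0.5 * (lo + hi)
        other = _perturb(rate)
        d = _dice(base, other)
        if abs(d - target_dice) <= tol * 0.5:
            break
        if d > target_dice:
            lo = rate
        else:
            hi = rate
    return base, other
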