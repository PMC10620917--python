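"""Composition metrics for evaluating a selected ROI set against the WSI.

Three metrics quantify how representative a set of regions is of the whole
slide: the mean squared error and the Jensen-Shannon divergence between
the pooled composition of the selected ROIs and the slide-wide
composition, and the mean Shannon entropy of the individual ROI
compositions (tissue heterogeneity).  MSE is sensitive to single
outlying clusters; JSD with the 0*log(0)=0 convention silently drops
empty clusters and can understate divergence — reporting both guards
against each one's blind spot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionReport",
    "composition_mse",
    "composition_jsd",
    "shannon_entropy",
    "mean_roi_entropy",
    "evaluate_selection",
]


def _check_simplex(p, name, tol=1e-6):
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a 1-D composition vector")
    if np.any(p < -tol):
        raise ValueError(f"{name} has negative entries")
    return np.clip(p, 0.0, None)


def composition_mse(r, w0) -> float:
    """Mean squared error between two composition vectors:
    ``MSE = (1/n) * sum_i (r_i - w0_i)^2`` over the n clusters."""
    r = np.asarray(r, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if r.shape != w0.shape or r.ndim != 1:
        raise ValueError("composition vectors must be 1-D and of equal length")
    return float(np.mean((r - w0) ** 2))


def composition_jsd(r, w, exact: bool = False) -> float:
    """Base-2 Jensen-Shannon divergence between composition vectors.

    The default follows the common convention that terms with a zero
    numerator contribute 0 (``0*log0 = 0``); clusters absent from one
    vector but not its mixture still contribute through the other term.
    ``exact=True`` computes the divergence through its mixture-KL form
    ``0.5*KL(r||m) + 0.5*KL(w||m)`` with ``m = (r+w)/2`` — mathematically
    identical, implemented independently, and used as a cross-check.

    Bounded by 1 (attained on disjoint supports).
    """
    r = _check_simplex(r, "R")
    w = _check_simplex(w, "W")
    if r.shape != w.shape:
        raise ValueError("composition vectors must have equal length")
    m = 0.5 * (r + w)
    if exact:
        def _kl(p, q):
            mask = p > 0
            return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))

        return 0.5 * _kl(r, m) + 0.5 * _kl(w, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        tr = np.where(r > 0, r * np.log2(np.where(r > 0, r, 1.0) / np.where(m > 0, m, 1.0)), 0.0)
        tw = np.where(w > 0, w * np.log2(np.where(w > 0, w, 1.0) / np.where(m > 0, m, 1.0)), 0.0)
    return float(0.5 * tr.sum() + 0.5 * tw.sum())


def shannon_entropy(p, base: float | None = None) -> float:
    """Shannon entropy ``H(p) = -sum_k p_k log p_k`` (natural log by
    default; pass ``base=2`` for bits)."""
    p = _check_simplex(p, "p")
    nz = p[p > 0]
    h = float(-np.sum(nz * np.log(nz)))
    if base is not None:
        h /= np.log(base)
    return h


def mean_roi_entropy(per_roi, base: float | None = None) -> float:
    """Mean Shannon entropy of the individual ROI compositions:
    ``(1/m) * sum_i H(r_i)``.  High values mean heterogeneous regions."""
    per_roi = list(per_roi)
    if len(per_roi) == 0:
        raise ValueError("need at least one ROI composition")
    return float(np.mean([shannon_entropy(r, base=base) for r in per_roi]))


@dataclass
class SelectionReport:
    """Evaluation of a selected ROI set against the whole slide.

    Attributes
    ----------
    combined : ndarray
        Pooled composition ``R`` over all tiles of all selected ROIs.
    wsi : ndarray
        Slide-wide composition ``W``.
    per_roi : ndarray, shape (m, K)
        Composition of each selected ROI.
    mse, jsd, mean_entropy : float
        The three evaluation metrics (JSD in base 2; entropy base set at
        construction, natural log by default).
    """

    combined: np.ndarray
    wsi: np.ndarray
    per_roi: np.ndarray
    mse: float
    jsd: float
    mean_entropy: float
    entropy_base: float | None = None

    def to_dict(self):
        return {
            "mse": self.mse,
            "jsd": self.jsd,
            "mean_entropy": self.mean_entropy,
            "entropy_base": self.entropy_base if self.entropy_base else "e",
            "combined_composition": np.asarray(self.combined).tolist(),
            "wsi_composition": np.asarray(self.wsi).tolist(),
            "per_roi_composition": np.asarray(self.per_roi).tolist(),
        }


def evaluate_selection(grid, windows, entropy_base: float | None = None) -> SelectionReport:
    """Pool the tiles of the given ROI windows and score the selection.

    Duplicate tiles (from overlapping or repeated windows) are pooled
    once, so the combined composition depends only on the set of distinct
    covered tiles.  Per-ROI entropies still use each window's own pooled
    composition.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("empty window set")
    covered = np.zeros(grid.n_tiles, dtype=bool)
    per_roi = []
    for w in windows:
        idx = w.tile_indices(grid)
        sel = idx[grid.valid[idx]]
        if sel.size == 0:
            raise ValueError(f"window {w} contains no valid tile")
        covered[sel] = True
        per_roi.append(grid.compositions[sel].mean(axis=0))
    combined = grid.compositions[covered].mean(axis=0)
    wsi = grid.wsi_composition()
    return SelectionReport(
        combined=combined,
        wsi=wsi,
        per_roi=np.asarray(per_roi),
        mse=composition_mse(combined, wsi),
        jsd=composition_jsd(combined, wsi),
        mean_entropy=mean_roi_entropy(per_roi, base=entropy_base),
        entropy_base=entropy_base,
    )
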