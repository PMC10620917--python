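"""Virtual-stain quality metrics on paired adjacent-section images.

A virtual stain is compared with the real stain by windowed SSIM, and the
score is compensated for section-to-section content drift by dividing by
the Dice overlap of the nuclear masks of the two adjacent sections: if
only 80% of nuclei physically coincide between sections, a perfect
virtual stain cannot exceed SSIM ~0.8, so SSIM/Dice restores a
like-for-like scale (values above 1 are possible and reported as-is).
Marker positivity ratios between real and virtual images are compared by
Pearson correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "dice",
    "windowed_ssim",
    "compensated_ssim",
    "positive_cell_ratio",
    "correlate_ratios",
    "stain_pair_report",
]


def dice(mask_a, mask_b) -> float:
    """Dice coefficient ``2|A n B| / (|A| + |B|)`` between binary masks.

    Two empty masks agree trivially and score 1.0.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def windowed_ssim(x, y, window_px: int = 11) -> float:
    """Mean structural similarity over an odd-sided sliding window
    (default 11 px) for images in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("images must have the same shape")
    if window_px % 2 == 0 or window_px < 3:
        raise ValueError("window_px must be odd and >= 3")
    if min(x.shape) < window_px:
        raise ValueError("image smaller than the SSIM window")
    return float(
        structural_similarity(x, y, win_size=window_px, data_range=1.0)
    )


def compensated_ssim(ssim_value: float, dice_value: float) -> float:
    """Dice-compensated SSIM: ``ssim / dice``, uncapped.

    Values above 1 indicate the virtual stain resembles the real one more
    than the sections' own nuclei overlap would predict; they are
    reported as-is.  A Dice of 0 leaves the quantity undefined (NaN with
    a warning).
    """
    if dice_value == 0:
        warnings.warn(
            "Dice is 0; compensated SSIM undefined (returning NaN)",
            stacklevel=2,
        )
        return float("nan")
    if dice_value < 0:
        raise ValueError("dice_value must be >= 0")
    return float(ssim_value / dice_value)


def stain_pair_report(real, virtual, mask_a, mask_b, window_px: int = 11) -> dict:
    """Convenience: Dice, SSIM and compensated SSIM for one ROI pair."""
    d = dice(mask_a, mask_b)
    s = windowed_ssim(real, virtual, window_px=window_px)
    c = compensated_ssim(s, d) if d > 0 else float("nan")
    return {"dice": d, "ssim": s, "compensated_ssim": c}


def positive_cell_ratio(cell_table, marker: str, gate_threshold: float) -> float:
    """Fraction of cells whose mean intensity for ``marker`` is strictly
    above ``gate_threshold``."""
    df = pd.DataFrame(cell_table)
    if len(df) == 0:
        raise ValueError("empty cell table")
    if marker not in df.columns:
        raise KeyError(f"marker {marker!r} not in cell table")
    return float((df[marker].to_numpy() > gate_threshold).mean())


def correlate_ratios(real_ratios, virtual_ratios):
    """Pearson correlation (and two-sided p-value) between per-ROI
    positivity ratios from real and virtual images.

    Returns ``(r, p)``; with zero variance on either side the
    correlation is undefined and ``(nan, nan)`` is returned with a
    warning.
    """
    r = np.asarray(real_ratios, dtype=float)
    v = np.asarray(virtual_ratios, dtype=float)
    if r.shape != v.shape or r.ndim != 1 or r.size < 3:
        raise ValueError("need two equal-length 1-D arrays with >= 3 entries")
    if np.ptp(r) == 0 or np.ptp(v) == 0:
        warnings.warn("zero variance; Pearson correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.pearsonr(r, v)
    return float(res.statistic), float(res.pvalue)
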