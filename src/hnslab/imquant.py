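"""Confocal z-stack intensity quantification and two-channel colocalisation.

Intensity quantification follows the sum-slices workflow: z-slices are
combined into a single wide-precision projection, a structure-specific
lower-limit threshold masks out background (strictly greater-than; masked
pixels are excluded from every statistic), and images are summarised by an
integer-binned intensity histogram and by the area/mean normalisation
(masked pixel count divided by masked mean intensity).

Colocalisation reports the Pearson product-moment coefficient (no
threshold) alongside thresholded Manders coefficients tM1/tM2, with
Costes-style automatic threshold estimation and rolling-ball background
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball

__all__ = [
    "STRUCTURE_THRESHOLDS",
    "MaskedProjection",
    "ColocResult",
    "sum_projection",
    "threshold_mask",
    "intensity_histogram",
    "normalized_area_metric",
    "group_compare",
    "rolling_ball_background",
    "pearson_coloc",
    "costes_thresholds",
    "manders_coloc",
]

#: Standardised lower-limit thresholds per brain structure (grey-scale units).
STRUCTURE_THRESHOLDS = {"son": 400.0, "pvn": 128.0, "pituitary": 10.0}


class EmptyMaskError(ValueError):
    """Raised when a statistic is requested on an empty mask."""


@dataclass(frozen=True)
class MaskedProjection:
    """Sum projection with its above-threshold mask."""

    values: np.ndarray
    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        m = np.asarray(self.mask, dtype=bool)
        if v.shape != m.shape:
            raise ValueError("values and mask must share a shape")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class ColocResult:
    """Pearson and thresholded-Manders colocalisation summary."""

    r_p: float
    tm1: float
    tm2: float
    threshold_ch1: float
    threshold_ch2: float
    roi_pixels: int


def sum_projection(stack) -> np.ndarray:
    """Pixelwise sum of all z-slices in a wide float representation."""
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("stack must be shaped (z, y, x)")
    if arr.shape[0] < 1:
        raise ValueError("stack must contain at least one slice")
    return arr.sum(axis=0)


def threshold_mask(projection, threshold: float) -> MaskedProjection:
    """Mask pixels strictly above the lower-limit threshold.

    Pixels with value <= threshold are excluded from all downstream
    statistics (the NaN-designation step of the workflow). An empty mask is
    allowed here and raises only when a statistic is computed.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    proj = np.asarray(projection, dtype=np.float64)
    mask = proj > threshold
    if not mask.any():
        warnings.warn("threshold leaves an empty mask", stacklevel=2)
    return MaskedProjection(proj, mask, float(threshold))


def intensity_histogram(masked: MaskedProjection, bin_width: float = 1.0):
    """Integer-aligned intensity histogram of masked pixels.

    Bins of the given width cover [floor(min), max]; counts sum to the mask
    size. Returns (bin_edges, counts).
    """
    vals = masked.masked_values
    if vals.size == 0:
        raise EmptyMaskError("cannot histogram an empty mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(vals.min() / bin_width) * bin_width
    n_bins = int(np.floor((vals.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return edges, counts


def normalized_area_metric(masked: MaskedProjection) -> float:
    """Total masked area (pixels) divided by the masked mean intensity."""
    vals = masked.masked_values
    if vals.size == 0:
        raise EmptyMaskError("cannot normalise an empty mask")
    return float(vals.size / vals.mean())


def group_compare(group1, group2, paired: bool = False, one_tailed: bool = True):
    """Student's t comparison of per-image metrics between two groups.

    Returns a dict with group means ± SEM, t, and the (optionally
    one-tailed) p-value. The default is an unpaired test; the paired mode
    matches the spreadsheet "type 1" convention but assumes the images are
    genuinely paired.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal group sizes")
        diffs = a - b
        if np.allclose(diffs, 0):
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
    if one_tailed:
        p /= 2.0
    return {
        "mean1": float(a.mean()), "sem1": float(stats.sem(a)),
        "mean2": float(b.mean()), "sem2": float(stats.sem(b)),
        "t": t, "p": p, "paired": paired, "one_tailed": one_tailed,
    }


def rolling_ball_background(image, radius_px: float):
    """Subtract a rolling-ball background estimate; output clamped at 0."""
    img = np.asarray(image, dtype=np.float64)
    if radius_px < 1:
        raise ValueError("radius must be at least 1 pixel")
    if radius_px > min(img.shape):
        raise ValueError("radius exceeds the smallest image dimension")
    background = rolling_ball(img, radius=radius_px)
    return np.clip(img - background, 0.0, None)


def _roi_pair(ch1, ch2, roi=None):
    a = np.asarray(ch1, dtype=np.float64)
    b = np.asarray(ch2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    if roi is not None:
        m = np.asarray(roi, dtype=bool)
        if m.shape != a.shape:
            raise ValueError("roi mask must match the channel shape")
        a, b = a[m], b[m]
    return a.ravel(), b.ravel()


def pearson_coloc(ch1, ch2, roi=None) -> float:
    """Pearson product-moment correlation of pixel intensities (no threshold)."""
    a, b = _roi_pair(ch1, ch2, roi)
    if a.size < 2:
        raise ValueError("need at least 2 ROI pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance channel; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def costes_thresholds(ch1, ch2, roi=None, n_steps: int = 256, min_pixels: int = 25,
                      r_stop: float = 0.02):
    """Costes-style automatic threshold pair for thresholded Manders.

    Walks candidate channel-1 thresholds down the orthogonal (major-axis)
    channel-1 vs channel-2 regression line and returns the largest pair
    below which the correlation of sub-threshold pixels is negligible
    (<= ``r_stop``; the small positive stop tolerance absorbs the shallow
    residual correlation a noise floor contributes). When the
    inter-channel covariance is non-positive (no positive association, the
    Costes construction is undefined) the method falls back to independent
    per-channel Otsu thresholds.
    """
    a, b = _roi_pair(ch1, ch2, roi)
    if a.size < 2:
        raise ValueError("need at least 2 ROI pixels")
    if a.max() == 0 or b.max() == 0:
        raise ValueError("all-zero channel; thresholds undefined")
    s_aa = a.var()
    s_bb = b.var()
    s_ab = float(np.cov(a, b)[0, 1])
    if s_ab <= 0 or s_aa == 0 or s_bb == 0:
        return float(threshold_otsu(a)), float(threshold_otsu(b))
    # major-axis (orthogonal) regression line b = slope*a + intercept
    diff = s_bb - s_aa
    slope = (diff + np.sqrt(diff**2 + 4 * s_ab**2)) / (2 * s_ab)
    intercept = float(b.mean() - slope * a.mean())
    # quantile-spaced candidates: dense where the pixel mass lives
    candidates = np.unique(np.quantile(a, np.linspace(1.0, 0.0, n_steps)))[::-1]
    evaluated: list[tuple[float, float]] = []  # (r_below, t1)
    t1_best = None
    for t1 in candidates:
        t2 = slope * t1 + intercept
        below = (a < t1) & (b < t2)
        if below.sum() < min_pixels:
            continue
        sa, sb = a[below], b[below]
        if sa.std() == 0 or sb.std() == 0:
            # sub-threshold signal exhausted: correlation has vanished
            t1_best = float(t1)
            break
        r = stats.pearsonr(sa, sb).statistic
        evaluated.append((float(r), float(t1)))
        if r <= r_stop:
            t1_best = float(t1)
            break
    if t1_best is None:
        if evaluated:
            # never crossed the stop level: take the threshold minimising the
            # sub-threshold correlation, smallest threshold on near-ties
            r_min = min(r for r, _ in evaluated)
            t1_best = min(t for r, t in evaluated if r <= r_min + 1e-3)
        else:
            t1_best = float(a.min())
    t2_best = slope * t1_best + intercept
    return t1_best, float(np.clip(t2_best, b.min(), b.max()))


def manders_coloc(ch1, ch2, roi=None, thresholds=None, auto_threshold: bool = True) -> ColocResult:
    """Thresholded Manders coefficients with Pearson correlation.

    tM1 is the fraction of channel-1 intensity found on pixels where
    channel 2 exceeds its threshold, and tM2 symmetrically. Thresholds come
    from Costes-style estimation unless supplied.
    """
    a, b = _roi_pair(ch1, ch2, roi)
    if a.size < 2:
        raise ValueError("need at least 2 ROI pixels")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero channel; Manders coefficients undefined")
    if thresholds is not None:
        t1, t2 = float(thresholds[0]), float(thresholds[1])
    elif auto_threshold:
        t1, t2 = costes_thresholds(ch1, ch2, roi)
    else:
        t1 = t2 = 0.0
    tm1 = float(a[b > t2].sum() / a.sum())
    tm2 = float(b[a > t1].sum() / b.sum())
    return ColocResult(
        r_p=pearson_coloc(ch1, ch2, roi),
        tm1=tm1,
        tm2=tm2,
        threshold_ch1=t1,
        threshold_ch2=t2,
        roi_pixels=a.size,
    )
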