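"""Number & brightness (N&B) moment analysis.

The apparent brightness of a pixel's intensity trace is

    B = (Var - sigma0^2) / (S * (mean - offset)) = 1 + epsilon,

where S, offset and sigma0 calibrate an analog detection chain (S = 1,
offset = sigma0 = 0 for photon counting, where B reduces to Var/mean) and
epsilon is the molecular brightness in detected photons per dwell time per
diffusing unit.  Immobile structures contribute shot noise only (B = 1);
n-mers of a monomer with brightness epsilon1 give B = 1 + n*epsilon1, which
is what lets a calibration curve built from monomeric, dimeric and trimeric
reference constructs translate B values into oligomeric classes
(monomer ... hexamer).

Slow intensity drifts (photobleaching, cell movement) bias the variance;
they are removed by a per-pixel moving-average high-pass filter that adds
back the pixel's overall mean ("detrending") before the moments are taken.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .exceptions import CalibrationError, ParameterError

__all__ = [
    "DetectorCalibration",
    "BrightnessMap",
    "OligomerCurve",
    "PHOTON_COUNTING_CALIBRATION",
    "calibrate_detector",
    "detrend_series",
    "brightness_map",
    "oligomer_calibration_curve",
    "partition_brightness",
]

log = logging.getLogger(__name__)

N_OLIGOMER_CLASSES = 6  # monomer ... hexamer
MIN_CALIBRATION_R = 0.99
SIGMA0_ZERO_THRESHOLD = 0.1


@dataclass(frozen=True)
class DetectorCalibration:
    """Analog-detection calibration (S, offset, sigma0) with fit quality R."""

    gain_s: float
    offset: float
    sigma0: float
    r_value: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_s <= 0:
            raise ParameterError("gain S must be positive")
        if self.sigma0 < 0:
            raise ParameterError("sigma0 must be non-negative")


#: identity calibration for photon-counting detection
PHOTON_COUNTING_CALIBRATION = DetectorCalibration(gain_s=1.0, offset=0.0, sigma0=0.0)


def calibrate_detector(
    series_at_powers: Sequence[np.ndarray],
    dark_series: Optional[np.ndarray] = None,
) -> DetectorCalibration:
    """Calibrate S, offset and sigma0 from reflection series at >= 3 powers.

    Each series contributes one (<I>, <Var>) point — the spatial averages
    of its per-pixel temporal mean and variance — and the points are fitted
    with the straight line <Var> = S <I> + q; the slope gives S.  sigma0 is
    estimated from the dark-count histogram as half-maximum width of its
    peak (converted to an SD), and approximated to zero when below 0.1;
    the offset follows from the intercept as (sigma0^2 - q)/S.  The
    calibration is rejected when the line's |r| < 0.99.
    """
    if len(series_at_powers) < 3:
        raise ParameterError("need series at >= 3 laser power levels")
    means, variances = [], []
    for s in series_at_powers:
        s = np.asarray(s, dtype=float)
        if s.ndim != 3 or s.shape[0] < 2:
            raise ParameterError("each series must be (n_frames >= 2, h, w)")
        means.append(float(s.mean()))
        variances.append(float(s.var(axis=0, ddof=1).mean()))
    fit = stats.linregress(means, variances)
    r = abs(float(fit.rvalue))
    if r < MIN_CALIBRATION_R:
        raise CalibrationError(
            f"variance-vs-intensity line has |r| = {r:.4f} < {MIN_CALIBRATION_R}"
        )
    gain_s = float(fit.slope)
    q = float(fit.intercept)
    sigma0 = 0.0
    if dark_series is not None:
        sigma0 = _dark_sigma0(np.asarray(dark_series, dtype=float))
    if sigma0 < SIGMA0_ZERO_THRESHOLD:
        sigma0 = 0.0
    offset = (sigma0**2 - q) / gain_s
    return DetectorCalibration(gain_s=gain_s, offset=offset, sigma0=sigma0, r_value=r)


def _dark_sigma0(dark: np.ndarray) -> float:
    """SD-equivalent of the dark-count histogram peak's half-maximum width."""
    vals = dark.ravel()
    counts, edges = np.histogram(vals, bins="auto")
    centers = 0.5 * (edges[:-1] + edges[1:])
    ipk = int(np.argmax(counts))
    half = counts[ipk] / 2.0
    left = centers[0]
    for i in range(ipk, 0, -1):
        if counts[i - 1] <= half:
            left = np.interp(half, [counts[i - 1], counts[i]], [centers[i - 1], centers[i]])
            break
    right = centers[-1]
    for i in range(ipk, counts.size - 1):
        if counts[i + 1] <= half:
            right = np.interp(half, [counts[i + 1], counts[i]], [centers[i + 1], centers[i]])
            break
    fwhm = max(right - left, 0.0)
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@lru_cache(maxsize=32)
def _detrend_variance_factor(t: int, half: int) -> float:
    """Expected sample-variance shrinkage of the high-pass on white noise.

    The residual operator y = (I - A) x (A = shrinking-window boxcar) is
    linear, so for iid noise E[s^2(y)] = V * tr(M' C M)/(t - 1) with
    C = I - J/t the centering projector.  The exact factor accounts both
    for the variance removed by the trend subtraction and for the
    sample-variance inflation caused by the induced anticorrelation.
    """
    idx = np.arange(t)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, t)
    a = np.zeros((t, t))
    for i in range(t):
        a[i, lo[i]:hi[i]] = 1.0 / (hi[i] - lo[i])
    m = np.eye(t) - a
    cm = m - m.mean(axis=0, keepdims=True)
    return float(np.trace(cm.T @ cm) / (t - 1))


def detrend_series(stack: np.ndarray, window: int = 10) -> np.ndarray:
    """High-pass filter each pixel's intensity trace, preserving its mean.

    The trend is a centered moving average of ``window`` frames (edge
    frames shrink the window).  Residuals around the trend are recentred
    and rescaled so that the expected sample variance of stationary white
    noise is exactly preserved (the rescale factor is computed from the
    high-pass's linear map, see :func:`_detrend_variance_factor`), and the
    pixel's overall mean is added back, so the per-pixel mean is unchanged
    exactly.  Constant traces pass through unchanged.
    """
    x = np.asarray(stack, dtype=float)
    if x.ndim != 3:
        raise ParameterError("stack must be (n_frames, h, w)")
    t = x.shape[0]
    if not (2 <= window < t):
        raise ParameterError(f"window must be in [2, n_frames), got {window}")
    half = window // 2
    csum = np.concatenate([np.zeros((1, *x.shape[1:])), np.cumsum(x, axis=0)], axis=0)
    idx = np.arange(t)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, t)
    trend = (csum[hi] - csum[lo]) / (hi - lo)[:, None, None]
    resid = x - trend
    resid -= resid.mean(axis=0, keepdims=True)
    scale = 1.0 / np.sqrt(_detrend_variance_factor(t, half))
    return x.mean(axis=0, keepdims=True) + scale * resid


@dataclass
class BrightnessMap:
    """Per-pixel apparent brightness with its intensity map."""

    b: np.ndarray  # NaN where undefined (mean <= offset)
    mean_intensity: np.ndarray
    n_frames: int
    detrend_window: Optional[int]
    n_masked: int = 0

    def mean_b(self, mask: Optional[np.ndarray] = None) -> float:
        """Pixel-mean brightness over a mask (default: all defined pixels)."""
        sel = np.isfinite(self.b)
        if mask is not None:
            sel &= np.asarray(mask, dtype=bool)
        if not sel.any():
            raise ParameterError("no defined brightness pixels in the mask")
        return float(np.mean(self.b[sel]))

    @property
    def valid_b(self) -> np.ndarray:
        return self.b[np.isfinite(self.b)]


def brightness_map(
    stack: np.ndarray,
    calibration: DetectorCalibration = PHOTON_COUNTING_CALIBRATION,
    detrend_window: Optional[int] = 10,
) -> BrightnessMap:
    """Per-pixel apparent brightness B = (Var - sigma0^2)/(S (mean - offset)).

    The stack is detrended first unless ``detrend_window`` is None.  Pixels
    whose mean does not exceed the offset are masked (NaN), counted and
    logged.  In photon-counting calibration the formula reduces to
    Var/mean and B = 1 marks pixels with immobile features only.
    """
    x = np.asarray(stack, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ParameterError("stack must be (n_frames >= 2, h, w)")
    if detrend_window is not None:
        x = detrend_series(x, window=detrend_window)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    denom = calibration.gain_s * (mean - calibration.offset)
    bad = denom <= 0
    n_bad = int(bad.sum())
    if n_bad:
        log.info("masking %d pixels with mean <= offset", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (var - calibration.sigma0**2) / denom
    b = np.where(bad, np.nan, b)
    return BrightnessMap(
        b=b,
        mean_intensity=mean,
        n_frames=x.shape[0],
        detrend_window=detrend_window,
        n_masked=n_bad,
    )


@dataclass
class OligomerCurve:
    """Linear map from oligomer order n to apparent brightness B.

    Built from reference B values of monomeric, dimeric and trimeric
    constructs and extrapolated to the hexamer; class boundaries sit at
    midpoints between consecutive predicted B values.
    """

    slope: float
    intercept: float
    reference_b: Tuple[float, float, float]

    def predicted_b(self, n: np.ndarray | int) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(n, dtype=float)

    @property
    def class_centers(self) -> np.ndarray:
        """Predicted B for n = 1..6."""
        return self.predicted_b(np.arange(1, N_OLIGOMER_CLASSES + 1))

    @property
    def class_boundaries(self) -> np.ndarray:
        """Midpoint boundaries between consecutive classes (length 5)."""
        c = self.class_centers
        return 0.5 * (c[:-1] + c[1:])


def oligomer_calibration_curve(b1: float, b2: float, b3: float) -> OligomerCurve:
    """Fit B vs n over the monomer/dimer/trimer references (n = 1, 2, 3)."""
    if not (b1 < b2 < b3):
        raise ParameterError(
            f"reference B values must increase strictly: {b1}, {b2}, {b3}"
        )
    n = np.array([1.0, 2.0, 3.0])
    b = np.array([b1, b2, b3])
    fit = stats.linregress(n, b)
    return OligomerCurve(
        slope=float(fit.slope), intercept=float(fit.intercept),
        reference_b=(float(b1), float(b2), float(b3)),
    )


def partition_brightness(
    bmap: BrightnessMap,
    curve: OligomerCurve,
    random_state: int = 0,
) -> np.ndarray:
    """Partition pixel B values into six oligomer classes; percentages.

    K-means with k = 6 centers seeded at the calibration curve's predicted
    class B values; each final cluster is ascribed to the oligomer class
    whose predicted B is nearest its center (so clusters that split one
    brightness mode still land in the same class).  When the data carry
    fewer distinct values than classes, pixels are assigned to the nearest
    predicted class center directly.  Returns percentages (summing to 100)
    for monomer ... hexamer.
    """
    vals = bmap.valid_b
    if vals.size < N_OLIGOMER_CLASSES:
        raise ParameterError(
            f"need at least {N_OLIGOMER_CLASSES} brightness pixels, got {vals.size}"
        )
    centers0 = curve.class_centers.reshape(-1, 1)
    if np.unique(vals).size < N_OLIGOMER_CLASSES:
        labels = np.argmin(np.abs(vals[:, None] - centers0.ravel()[None, :]), axis=1)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(
                n_clusters=N_OLIGOMER_CLASSES, init=centers0, n_init=1,
                random_state=random_state,
            ).fit(vals.reshape(-1, 1))
        cluster_class = np.argmin(
            np.abs(km.cluster_centers_.ravel()[:, None] - centers0.ravel()[None, :]),
            axis=1,
        )
        labels = cluster_class[km.labels_]
    pct = np.bincount(labels, minlength=N_OLIGOMER_CLASSES) / vals.size * 100.0
    return pct
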