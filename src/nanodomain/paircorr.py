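"""Radial pair-correlation estimation for 2D localization data.

The pair-correlation function g(r) is the density-normalized probability of
finding a second localization at distance r from a given one; it equals 1
for complete spatial randomness.  Repeated localizations of single blinking
fluorophores add an apparent self-clustering ("overcounting") peak at small
r, and genuine molecular clustering adds a slowly decaying excess — the
model fitting that disentangles the two lives in :mod:`nanodomain.clusterfit`.

The estimator here bins localizations onto a fine grid, computes the full
2D autocorrelation by FFT, divides by the autocorrelation of the ROI mask
(translational edge correction) and by the squared mean density, and then
averages radially.  Curves are normalized so that the tail (outer quartile
of r bins) averages to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .exceptions import InsufficientDataError, ParameterError
from .geometry import NM2_PER_UM2, RoiGeometry

__all__ = [
    "LocalizationTable",
    "PairCorrelationCurve",
    "compute_pair_correlation",
    "estimate_density",
]


@dataclass
class LocalizationTable:
    """Single-molecule localizations inside a rectangular ROI.

    Coordinates are in nanometres relative to the ROI lower-left corner;
    every record has a non-negative acquisition frame index and, optionally,
    a photon count.
    """

    frame: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    roi: RoiGeometry
    photons: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        if not (self.frame.shape == self.x_nm.shape == self.y_nm.shape):
            raise ParameterError("frame, x_nm and y_nm must have equal length")
        if self.frame.size and self.frame.min() < 0:
            raise ParameterError("frame indices must be non-negative")
        if self.frame.size and not np.all(self.roi.contains(self.x_nm, self.y_nm)):
            raise ParameterError("all localizations must lie inside the ROI box")
        if self.photons is not None:
            self.photons = np.asarray(self.photons, dtype=float)
            if self.photons.shape != self.x_nm.shape:
                raise ParameterError("photons column length mismatch")

    def __len__(self) -> int:
        return int(self.x_nm.size)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"frame": self.frame, "x_nm": self.x_nm, "y_nm": self.y_nm}
        cols["photons"] = (
            self.photons if self.photons is not None else np.full(len(self), np.nan)
        )
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, roi: RoiGeometry) -> "LocalizationTable":
        photons = None
        if "photons" in df.columns and not df["photons"].isna().all():
            photons = df["photons"].to_numpy(dtype=float)
        return cls(
            frame=df["frame"].to_numpy(dtype=np.int64),
            x_nm=df["x_nm"].to_numpy(dtype=float),
            y_nm=df["y_nm"].to_numpy(dtype=float),
            roi=roi,
            photons=photons,
        )


@dataclass
class PairCorrelationCurve:
    """Radially averaged normalized pair-correlation curve."""

    r_nm: np.ndarray
    g: np.ndarray
    bin_nm: float
    density_per_um2: float
    n_localizations: int
    tail_normalized: bool = True
    #: mean g over the tail window before renormalization (1.0 if not applied)
    tail_factor: float = 1.0
    roi: Optional[RoiGeometry] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.r_nm = np.asarray(self.r_nm, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.r_nm.size != self.g.size:
            raise ParameterError("r and g must have equal length")
        if np.any(np.diff(self.r_nm) <= 0):
            raise ParameterError("r bin centers must be strictly increasing")
        if np.any(self.g < 0):
            raise ParameterError("g values must be non-negative")
        if not self.density_per_um2 > 0:
            raise ParameterError("localization density must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r_nm, "g": self.g})


def estimate_density(locs: LocalizationTable) -> float:
    """Localization density in localizations per um^2 (count / ROI area)."""
    if locs.roi.area_nm2 <= 0:
        raise ParameterError("ROI area must be positive")
    if len(locs) == 0:
        warnings.warn("empty localization table: density is zero", stacklevel=2)
        return 0.0
    return len(locs) / locs.roi.area_um2


def compute_pair_correlation(
    locs: LocalizationTable,
    bin_nm: float = 10.0,
    r_max_nm: float = 500.0,
    grid_nm: float = 10.0,
    tail_normalize: bool = True,
    tail_fraction: float = 0.25,
) -> PairCorrelationCurve:
    """Estimate the radial pair-correlation function g(r) of a pattern.

    Parameters
    ----------
    locs:
        Localization table (needs >= 100 points).
    bin_nm:
        Width of the radial averaging bins.
    r_max_nm:
        Largest pair distance retained; must not exceed half the shorter
        ROI side (beyond that the edge correction is poorly conditioned).
    grid_nm:
        Pixel of the binning grid used for the FFT autocorrelation.  The
        default 10 nm is well below typical localization errors (~20 nm).
    tail_normalize:
        Rescale the curve so the mean of g over the outer ``tail_fraction``
        of r bins equals 1.

    Returns
    -------
    PairCorrelationCurve
        Bin centers are the pair-count-weighted mean lag distances, which
        removes most of the grid discretization bias.
    """
    n = len(locs)
    if n < 100:
        raise InsufficientDataError(
            f"pair correlation needs >= 100 localizations, got {n}"
        )
    if bin_nm <= 0 or grid_nm <= 0:
        raise ParameterError("bin_nm and grid_nm must be positive")
    short_side = min(locs.roi.width_nm, locs.roi.height_nm)
    if r_max_nm > short_side / 2:
        raise ParameterError(
            f"r_max_nm={r_max_nm} exceeds half the shorter ROI side ({short_side / 2})"
        )

    nx = int(round(locs.roi.width_nm / grid_nm))
    ny = int(round(locs.roi.height_nm / grid_nm))
    ix = np.floor(locs.x_nm / grid_nm).astype(np.int64)
    iy = np.floor(locs.y_nm / grid_nm).astype(np.int64)
    # guard against points numerically at the upper edge
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)
    img = np.zeros((ny, nx), dtype=float)
    np.add.at(img, (iy, ix), 1.0)

    # full 2D autocorrelation: counts of ordered localization pairs per lag
    acf = fftconvolve(img, img[::-1, ::-1], mode="full")
    # rectangular mask autocorrelation (number of pixel pairs per lag),
    # exact separable form for a full rectangle
    dy = np.arange(-(ny - 1), ny)
    dx = np.arange(-(nx - 1), nx)
    mask_acf = np.outer(ny - np.abs(dy), nx - np.abs(dx)).astype(float)

    mu = n / (nx * ny)  # mean counts per grid pixel
    lag_r = grid_nm * np.hypot(*np.meshgrid(dy.astype(float), dx.astype(float), indexing="ij"))

    keep = (lag_r <= r_max_nm) & (lag_r > 0)  # exclude the self-pair lag (0,0)
    r_flat = lag_r[keep]
    pair_counts = np.maximum(acf[keep], 0.0)  # clip FFT round-off
    weights = mask_acf[keep]

    nbins = int(np.floor(r_max_nm / bin_nm))
    idx = np.minimum((r_flat / bin_nm).astype(np.int64), nbins - 1)
    sum_pairs = np.bincount(idx, weights=pair_counts, minlength=nbins)
    sum_weights = np.bincount(idx, weights=weights, minlength=nbins)
    sum_r = np.bincount(idx, weights=weights * r_flat, minlength=nbins)

    valid = sum_weights > 0
    g = np.full(nbins, np.nan)
    g[valid] = sum_pairs[valid] / (mu**2 * sum_weights[valid])
    r_centers = np.full(nbins, np.nan)
    r_centers[valid] = sum_r[valid] / sum_weights[valid]

    g = g[valid]
    r_centers = r_centers[valid]

    tail_factor = 1.0
    if tail_normalize:
        n_tail = max(1, int(np.ceil(tail_fraction * g.size)))
        tail_factor = float(np.mean(g[-n_tail:]))
        if tail_factor <= 0:
            raise InsufficientDataError("tail of g(r) is empty; cannot normalize")
        g = g / tail_factor

    return PairCorrelationCurve(
        r_nm=r_centers,
        g=g,
        bin_nm=bin_nm,
        density_per_um2=n / locs.roi.area_um2,
        n_localizations=n,
        tail_normalized=tail_normalize,
        tail_factor=tail_factor,
        roi=locs.roi,
    )
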