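"""Region-of-interest geometry.

All coordinates in this package are continuous, in nanometres, relative to
the lower-left corner of a rectangular region of interest (ROI).  A point
belongs to the ROI iff it lies in the half-open box [0, width) x [0, height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

NM2_PER_UM2 = 1.0e6


@dataclass(frozen=True)
class RoiGeometry:
    """Rectangular analysis region.

    Parameters
    ----------
    width_nm, height_nm:
        Side lengths in nanometres.  The default 4000 x 4000 nm matches the
        4 x 4 um membrane regions conventionally selected for
        pair-correlation analysis of localization data.
    """

    width_nm: float = 4000.0
    height_nm: float = 4000.0

    def __post_init__(self) -> None:
        if not (self.width_nm > 0 and self.height_nm > 0):
            raise ParameterError(
                f"ROI sides must be positive, got {self.width_nm} x {self.height_nm} nm"
            )

    @property
    def area_nm2(self) -> float:
        return self.width_nm * self.height_nm

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / NM2_PER_UM2

    def contains(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the half-open ROI box."""
        x = np.asarray(x_nm)
        y = np.asarray(y_nm)
        return (x >= 0.0) & (x < self.width_nm) & (y >= 0.0) & (y < self.height_nm)
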