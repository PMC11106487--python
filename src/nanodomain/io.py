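"""File-format adapters.

Localization tables travel as CSV with header columns
``frame,x_nm,y_nm,photons`` plus a small JSON sidecar (``<name>.json``)
carrying the ROI geometry; image and gated stacks as multi-frame TIFF with
a JSON sidecar of acquisition metadata (gate width, detector parameters,
...); pair-correlation curves as two-column CSV (``r_nm,g``) plus JSON
metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ParameterError
from .flim import GatedStack
from .geometry import RoiGeometry
from .paircorr import LocalizationTable, PairCorrelationCurve

__all__ = [
    "write_localizations",
    "read_localizations",
    "write_ground_truth",
    "write_stack",
    "read_stack",
    "write_gated_stack",
    "read_gated_stack",
    "write_curve",
    "read_curve",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_localizations(table: LocalizationTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    meta = {"roi_width_nm": table.roi.width_nm, "roi_height_nm": table.roi.height_nm}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_localizations(
    path: str | Path, roi: Optional[RoiGeometry] = None
) -> LocalizationTable:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("frame", "x_nm", "y_nm"):
        if col not in df.columns:
            raise ParameterError(f"localization CSV missing column {col!r}")
    if roi is None:
        sc = _sidecar(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
            roi = RoiGeometry(meta["roi_width_nm"], meta["roi_height_nm"])
        else:
            raise ParameterError(
                f"no ROI sidecar found for {path}; pass roi= explicitly"
            )
    return LocalizationTable.from_dataframe(df, roi)


def write_ground_truth(molecules_xy_nm: np.ndarray, path: str | Path) -> Path:
    """Ground-truth molecule positions as a sidecar CSV (x_nm, y_nm)."""
    path = Path(path)
    pd.DataFrame(molecules_xy_nm, columns=["x_nm", "y_nm"]).to_csv(path, index=False)
    return path


def write_stack(array: np.ndarray, path: str | Path, meta: Optional[dict] = None) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    _sidecar(path).write_text(json.dumps(meta or {}, indent=1))
    return path


def read_stack(path: str | Path) -> Tuple[np.ndarray, dict]:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sc = _sidecar(path)
    meta = json.loads(sc.read_text()) if sc.exists() else {}
    return data, meta


def write_gated_stack(stack: GatedStack, path: str | Path) -> Path:
    return write_stack(
        stack.data, path,
        meta={"gate_ns": stack.gate_ns, "n_gates": stack.n_gates,
              "smoothed": stack.smoothed},
    )


def read_gated_stack(path: str | Path) -> GatedStack:
    data, meta = read_stack(path)
    if "gate_ns" not in meta:
        raise ParameterError(f"gated stack {path} lacks gate metadata sidecar")
    return GatedStack(
        data=data, gate_ns=float(meta["gate_ns"]),
        smoothed=bool(meta.get("smoothed", False)),
    )


def write_curve(curve: PairCorrelationCurve, path: str | Path) -> Path:
    path = Path(path)
    curve.to_dataframe().to_csv(path, index=False)
    meta = {
        "bin_nm": curve.bin_nm,
        "density_per_um2": curve.density_per_um2,
        "n_localizations": curve.n_localizations,
        "tail_normalized": curve.tail_normalized,
        "tail_factor": curve.tail_factor,
    }
    if curve.roi is not None:
        meta["roi_width_nm"] = curve.roi.width_nm
        meta["roi_height_nm"] = curve.roi.height_nm
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_curve(path: str | Path) -> PairCorrelationCurve:
    path = Path(path)
    df = pd.read_csv(path)
    sc = _sidecar(path)
    if not sc.exists():
        raise ParameterError(f"no metadata sidecar found for curve {path}")
    meta = json.loads(sc.read_text())
    roi = None
    if "roi_width_nm" in meta:
        roi = RoiGeometry(meta["roi_width_nm"], meta["roi_height_nm"])
    return PairCorrelationCurve(
        r_nm=df["r_nm"].to_numpy(float),
        g=df["g"].to_numpy(float),
        bin_nm=float(meta["bin_nm"]),
        density_per_um2=float(meta["density_per_um2"]),
        n_localizations=int(meta["n_localizations"]),
        tail_normalized=bool(meta.get("tail_normalized", True)),
        tail_factor=float(meta.get("tail_factor", 1.0)),
        roi=roi,
    )
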