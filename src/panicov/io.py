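"""File formats at the package boundary.

Images are RGB PNG/JPEG; masks are single-channel PNG with 0 = background
and any nonzero value (conventionally 255) = panicle. Coverage series
travel as CSV with columns plot_id, day, coverage; fitted parameters and
yield tables as CSV with the canonical column names (K, g, d0, a, d1,
r_squared; Yield, GN, PN, GNP, TGW, FGR).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .coverage_extraction import CoverageSeries

__all__ = [
    "read_image",
    "write_image",
    "read_mask_png",
    "write_mask_png",
    "write_series_csv",
    "read_series_csv",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel maps to class 1 (panicle)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 0).astype(np.uint8)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as single-channel PNG with 1 stored as 255."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask must be binary {{0,1}}, found {vals}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def write_series_csv(path: str | Path, series_list: list[CoverageSeries]) -> None:
    rows = [
        {"plot_id": s.plot_id, "day": d, "coverage": c}
        for s in series_list
        for d, c in zip(s.days, s.coverage)
    ]
    pd.DataFrame(rows, columns=["plot_id", "day", "coverage"]).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> list[CoverageSeries]:
    df = pd.read_csv(path)
    missing = {"plot_id", "day", "coverage"} - set(df.columns)
    if missing:
        raise ValueError(f"series CSV missing columns {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("plot_id", sort=False):
        grp = grp.sort_values("day")
        out.append(
            CoverageSeries(str(pid), grp["day"].to_numpy(), grp["coverage"].to_numpy())
        )
    return out
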