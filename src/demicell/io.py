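"""Readers and writers for the package's plain-text and TIFF artifacts.

CSV files may start with ``# key=value`` comment lines recording provenance
(seed, stage); readers skip them.  Cell contours travel as WKT polygons.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely import wkt as shapely_wkt

__all__ = [
    "write_image",
    "read_image",
    "write_csv",
    "read_csv",
    "read_contours",
    "write_json",
]


def write_image(path, image: np.ndarray) -> None:
    """Write a single-channel image as 16-bit TIFF (clipped and rounded)."""
    data = np.clip(np.rint(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_csv(df: pd.DataFrame, path, header: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_contours(cells_csv) -> dict[int, np.ndarray]:
    """Map cell_id -> (N, 2) contour vertices from a cells table with WKT."""
    df = read_csv(cells_csv)
    out = {}
    for cid, wkt_str in zip(df["cell_id"], df["contour_wkt"]):
        poly = shapely_wkt.loads(wkt_str)
        out[int(cid)] = np.asarray(poly.exterior.coords)[:-1]
    return out


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
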