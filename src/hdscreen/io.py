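"""Readers and writers for the plain-text interchange formats.

All tables are tab-separated with a header line; missing values are written
as ``NA``. Plate images are 16-bit grayscale PNG or TIFF.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .tables import DENSITY_COLUMNS, DensityTable

_NA = "NA"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=True)


def write_density_table(table: DensityTable, path) -> None:
    df = table.data.loc[:, list(DENSITY_COLUMNS)].copy()
    df["stage"] = table.stage
    write_tsv(df, path)


def read_density_table(path) -> DensityTable:
    df = read_tsv(path)
    stage = "raw"
    if "stage" in df.columns:
        stages = df["stage"].dropna().unique()
        if len(stages) > 1:
            raise ValueError(f"mixed stages in {path}: {sorted(stages)}")
        if len(stages) == 1:
            stage = str(stages[0])
        df = df.drop(columns="stage")
    return DensityTable(df, stage=stage)


def write_image(image: np.ndarray, path) -> None:
    """Write a 2-D array as 16-bit grayscale PNG or TIFF (by extension)."""
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG/TIFF as a float64 array."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) scan to grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(float)


def read_gmt(path) -> dict:
    """Read gene sets from GMT (set name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")
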