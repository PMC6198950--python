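"""Tabular and image I/O with strict schemas.

Tables are plain CSV with a header; each table kind declares its required
columns and dtypes. Reading validates the header (missing columns are a
:class:`~sstembatch.exceptions.SchemaError` naming the column; unknown extra
columns warn and are preserved), so write-then-read round-trips are identity
on values.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "CENTROID_SCHEMA",
    "CYCLE_SCHEMA",
    "ANNOTATION_SCHEMA",
    "read_table",
    "write_table",
    "load_image",
    "save_image",
]

# table kind -> ordered {column: dtype}
CENTROID_SCHEMA = {
    "section_id": int,
    "row": int,
    "col": int,
    "dx_um": float,
    "dy_um": float,
    "fragment": bool,
}
CYCLE_SCHEMA = {"section_id": int, "pickup_s": float, "cycle_s": float}
ANNOTATION_SCHEMA = {
    "vesicle_id": int,
    "x_ext": float,
    "y_ext": float,
    "x_int": float,
    "y_int": float,
}


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a CSV against a declared schema.

    Declared columns are coerced to their dtypes (float columns tolerate
    NaN; int/bool columns do not). Column order is normalized to declared
    columns first, extras after.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected columns {list(schema)}") from None
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: unknown column(s) {extra} preserved", stacklevel=2)
    for col, dtype in schema.items():
        if dtype is float:
            df[col] = df[col].astype(float)
        elif dtype is bool:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False, 0: False, 1: True}
            )
            if df[col].isna().any():
                raise SchemaError(f"{path}: column 'fragment' has non-boolean values")
            df[col] = df[col].astype(bool)
        else:
            try:
                df[col] = df[col].astype(dtype)
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: column {col!r} not coercible to {dtype}: {exc}") from None
    return df[[*schema, *extra]]


def write_table(df: pd.DataFrame, path, schema: dict) -> None:
    """Write a CSV, validating the schema columns are present."""
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in schema]
    df[[*schema, *extra]].to_csv(path, index=False)


def load_image(path) -> np.ndarray:
    """Load a single-channel TIFF or PNG as a float 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise SchemaError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    return arr.astype(float)


def save_image(image: np.ndarray, path) -> None:
    """Save a 2-D array as 8-bit (values in [0, 255]) or 16-bit grayscale."""
    path = Path(path)
    arr = np.asarray(image)
    peak = arr.max() if arr.size else 0
    dtype = np.uint8 if peak <= 255 else np.uint16
    quantized = np.clip(np.round(arr), 0, np.iinfo(dtype).max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, quantized)
    else:
        from PIL import Image

        Image.fromarray(quantized).save(path)
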