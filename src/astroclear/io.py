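"""Readers/writers for tabular and image artifacts, with provenance sidecars.

CSV dialect: comma-separated, UTF-8, mandatory header row, '.' decimal
separator.  Numbers are serialized at full double precision; any display
rounding happens only in logs.  Every output written through this module
gets a ``<name>.provenance.json`` sidecar recording the tool version, the
configuration snapshot (including the seed), SHA-256 digests of the inputs,
and a timestamp, so a recorded run can be reproduced byte-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "read_table",
    "write_table",
    "read_mask",
    "write_mask",
    "write_provenance",
]


def _package_version() -> str:
    from . import __version__

    return __version__


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a CSV with a declared column schema.

    Missing required columns or values that fail type coercion raise
    :class:`SchemaError` with the offending row/column; unknown extra
    columns are accepted with a warning (tolerant reader).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file does not exist: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty input file: {path}") from None
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    for col, dtype in schema.items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            bad = None
            for i, v in enumerate(df[col]):
                try:
                    dtype(v)
                except (ValueError, TypeError):
                    bad = i
                    break
            raise SchemaError(
                f"{path}: column {col!r}, row {bad}: cannot coerce to "
                f"{dtype.__name__} ({exc})"
            ) from None
    return df


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: Mapping | None = None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write a CSV at full double precision plus a provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    write_provenance(path, config=config or {}, inputs=inputs)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG label mask as a boolean array."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"mask file does not exist: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # collapse RGB(A)
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def write_mask(
    mask: np.ndarray,
    path: str | Path,
    config: Mapping | None = None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write a boolean mask as 8-bit TIFF/PNG plus a provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = (np.asarray(mask) > 0).astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
    write_provenance(path, config=config or {}, inputs=inputs)
    return path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_provenance(
    output_path: str | Path,
    config: Mapping,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write ``<output>.provenance.json`` next to an output file."""
    output_path = Path(output_path)
    record = {
        "tool": "astroclear",
        "version": _package_version(),
        "output": output_path.name,
        "config": {k: _jsonable(v) for k, v in config.items()},
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).exists()
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    sidecar = output_path.with_suffix(output_path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True))
    return sidecar


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v
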