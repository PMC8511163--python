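"""File formats: multi-page TIFF movies with JSON sidecars, CSV tables.

CSV dialect: comma-separated, UTF-8, header row, units suffixed in column
names (``x_um``, ``t_s``).  Every sidecar and JSON report records the RNG
seed and a hash of the parameters that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def config_hash(params: dict) -> str:
    """Stable short hash of a parameter dictionary."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_movie(path: str | Path, movie: np.ndarray, metadata: dict) -> None:
    """Write a movie as multi-page TIFF with a ``.json`` metadata sidecar.

    ``metadata`` should carry ``pixel_size_um``, ``exposure_s``,
    ``frame_interval_s`` and ``seed``; a config hash is added.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32),
                     photometric="minisblack")
    meta = dict(metadata)
    meta["config_hash"] = config_hash(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF movie and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    movie = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(movie), meta


REQUIRED_CALIBRATION = ("pixel_size_um", "exposure_s", "frame_interval_s")


def require_calibration(meta: dict) -> dict:
    """Validate that movie metadata carries the calibration fields."""
    for field in REQUIRED_CALIBRATION:
        if field not in meta:
            raise KeyError(f"missing calibration metadata field: {field}")
    return meta


def write_tracks(path: str | Path, tracks) -> None:
    from .detection import tracks_to_dataframe
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_tracks(path: str | Path):
    from .detection import tracks_from_dataframe
    return tracks_from_dataframe(pd.read_csv(path))


def write_ground_truth(path: str | Path, truth) -> None:
    truth.frame_table().to_csv(path, index=False)


def write_report(path: str | Path, payload: dict, seed: int | None = None) -> None:
    """Versioned JSON report embedding the seed and config hash."""
    out = {"fabtirf_report_version": 1, "seed": seed,
           "config_hash": config_hash(payload), **payload}
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
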