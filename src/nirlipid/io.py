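"""File formats: ENVI-style hyperspectral cubes, CSV reports, model files.

Cubes are stored in the de facto line-scan-instrument convention: a text
header (``.hdr``) declaring geometry, interleave and the full-precision
wavelength list, next to a band-sequential (BSQ) float64 binary payload.
The round trip is lossless.  Models are serialized with joblib as a
format-versioned dict.
"""

from __future__ import annotations

import re
from pathlib import Path

import joblib
import numpy as np

from .preprocess import HyperspectralCube
from .regress import RegressionModel

__all__ = ["write_cube", "read_cube", "save_model", "load_model"]

_HEADER_TEMPLATE = """ENVI
description = {{nirlipid hyperspectral cube}}
samples = {samples}
lines = {lines}
bands = {bands}
header offset = 0
file type = ENVI Standard
data type = 5
interleave = bsq
byte order = 0
frame role = {frame_role}
wavelength units = Nanometers
wavelength = {{
{wavelengths}
}}
"""


def _data_path(path: Path) -> Path:
    return path.with_suffix(".raw")


def write_cube(cube: HyperspectralCube, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.hdr`` (text header) and ``<path>.raw`` (BSQ float64).

    Wavelengths are printed with 17 significant digits so the round trip
    preserves them bit-exactly.
    """
    path = Path(path).with_suffix(".hdr")
    path.parent.mkdir(parents=True, exist_ok=True)
    lines, samples, bands = cube.shape
    wl_text = ",\n".join(f"  {w:.17g}" for w in cube.wavelengths)
    path.write_text(
        _HEADER_TEMPLATE.format(
            samples=samples,
            lines=lines,
            bands=bands,
            frame_role=cube.frame_role,
            wavelengths=wl_text,
        )
    )
    # BSQ: band-major on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.intensities, 2, 0))
    data_path = _data_path(path)
    bsq.astype("<f8").tofile(data_path)
    return path, data_path


def _parse_header(text: str, path: Path) -> dict:
    fields: dict[str, str] = {}
    braces = dict(re.findall(r"(\w[\w ]*?)\s*=\s*\{([^}]*)\}", text, re.S))
    for m in re.finditer(r"^([\w ]+?)\s*=\s*([^\s{].*)$", text, re.M):
        fields[m.group(1).strip()] = m.group(2).strip()
    out: dict = {}
    for key in ("samples", "lines", "bands"):
        if key not in fields:
            raise ValueError(f"{path}: header missing {key!r}")
        out[key] = int(fields[key])
    out["frame_role"] = fields.get("frame role", "raw")
    if "wavelength" not in braces:
        raise ValueError(f"{path}: header missing the wavelength vector")
    out["wavelengths"] = np.array(
        [float(tok) for tok in re.split(r"[\s,]+", braces["wavelength"].strip()) if tok]
    )
    if out["wavelengths"].size != out["bands"]:
        raise ValueError(
            f"{path}: wavelength list length {out['wavelengths'].size} "
            f"!= bands {out['bands']}"
        )
    return out


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube` (or any BSQ float64 ENVI
    pair with a wavelength list).  Raises on header/payload size mismatch."""
    path = Path(path).with_suffix(".hdr")
    hdr = _parse_header(path.read_text(), path)
    data_path = _data_path(path)
    payload = np.fromfile(data_path, dtype="<f8")
    expected = hdr["bands"] * hdr["lines"] * hdr["samples"]
    if payload.size != expected:
        raise ValueError(
            f"{data_path}: payload holds {payload.size} values, "
            f"header declares {expected}"
        )
    bsq = payload.reshape(hdr["bands"], hdr["lines"], hdr["samples"])
    return HyperspectralCube(
        intensities=np.moveaxis(bsq, 0, 2),
        wavelengths=hdr["wavelengths"],
        frame_role=hdr["frame_role"],
    )


MODEL_FORMAT_VERSION = 1


def save_model(model: RegressionModel, path: str | Path) -> Path:
    """Serialize a fitted model to a single self-describing file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(
        {
            "format": "nirlipid-model",
            "format_version": MODEL_FORMAT_VERSION,
            "target": model.target,
            "config": model.config,
            "svr": model.svr,
            "y_mean": model.y_mean,
            "y_scale": model.y_scale,
            "wavelengths": model.wavelengths,
        },
        path,
    )
    return path


def load_model(path: str | Path) -> RegressionModel:
    blob = joblib.load(path)
    if blob.get("format") != "nirlipid-model":
        raise ValueError(f"{path}: not a nirlipid model file")
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {blob.get('format_version')}"
        )
    return RegressionModel(
        target=blob["target"],
        config=blob["config"],
        svr=blob["svr"],
        y_mean=blob["y_mean"],
        y_scale=blob["y_scale"],
        wavelengths=blob["wavelengths"],
    )
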