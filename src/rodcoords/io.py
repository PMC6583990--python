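"""Readers, writers and run configuration.

TIFF images (single frame or stack) are read with tifffile; localization
tables are delimited text in the style ThunderSTORM and similar SMLM tools
emit, with header aliases like ``x [nm]`` resolved and nm coordinates
converted to px at load.  All internal coordinates are px with the
(0.5, 0.5) pixel-centre convention; nm appears only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from rodcoords.cell import ImageElement, LocalizationTable

__all__ = ["RunConfig", "read_image_stack", "write_image", "read_localizations",
           "load_config"]

_ALIASES = {
    "x": ("x", "x [nm]", "x_nm", "x [px]", "x_px", "xnano", "x (nm)"),
    "y": ("y", "y [nm]", "y_nm", "y [px]", "y_px", "ynano", "y (nm)"),
    "frame": ("frame", "frame_ix", "t"),
    "intensity": ("intensity", "intensity [photon]", "intensity [photons]",
                  "photons", "i"),
}


@dataclass
class RunConfig:
    """Validated run configuration for the command-line pipeline."""

    mask: str | None = None
    channels: list = field(default_factory=list)
    localizations: str | None = None
    output: str = "."
    pixel_size_nm: float = 80.0
    localization_units: str = "px"
    method: str = "binary"
    element: str | None = None
    seed: int = 0
    verbosity: str = "INFO"
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        for path in [self.mask, self.localizations] + list(self.channels):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured path does not exist: {path}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    extra = {k: v for k, v in raw.items() if k not in RunConfig.__dataclass_fields__}
    cfg = RunConfig(**known)
    cfg.options.update(extra)
    return cfg


def read_image_stack(path, role: str = "fluorescence") -> list[ImageElement]:
    """Read a 2-D or 3-D TIFF as a list of image elements, one per frame."""
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D image or 3-D stack, got {arr.ndim}-D")
    name = Path(path).stem
    out = []
    for i, frame in enumerate(arr):
        frame_name = name if len(arr) == 1 else f"{name}_{i:03d}"
        pixels = frame if np.issubdtype(frame.dtype, np.integer) else frame.astype(np.float32)
        out.append(ImageElement(pixels, role, frame_name))
    return out


def write_image(path, pixels) -> None:
    pixels = np.asarray(pixels)
    if not np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float32)
    tifffile.imwrite(path, pixels)


def _sniff_delimiter(line: str) -> str:
    for delim in (",", ";", "\t"):
        if delim in line:
            return delim
    return r"\s+"


def read_localizations(path, pixel_size_nm: float = 80.0,
                       units: str = "px") -> LocalizationTable:
    """Read a delimited localization table; nm coordinates become px.

    The header must name at least x and y columns (aliases such as
    ``x [nm]`` are resolved); missing frame/intensity columns default to 0.
    """
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim, engine="python")
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    lower = {c.lower(): c for c in df.columns}

    resolved = {}
    for target, aliases in _ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[target] = lower[alias]
                break
    missing = [k for k in ("x", "y") if k not in resolved]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; found headers {list(df.columns)}")

    out = pd.DataFrame({k: pd.to_numeric(df[v]) for k, v in resolved.items()})
    if units == "nm":
        out["x"] = out["x"] / pixel_size_nm
        out["y"] = out["y"] / pixel_size_nm
    elif units != "px":
        raise ValueError(f"unknown localization units {units!r}")
    return LocalizationTable(out)
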