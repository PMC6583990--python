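"""Single-cell data model: crop/orient cells from labelled masks, attach data.

A :class:`Cell` bundles one cropped, horizontally oriented cell: named data
elements (a binary mask, any number of intensity images, optional
localization tables) plus the six :class:`~rodcoords.geometry.CoordinateParameters`
of its coordinate system.  :class:`CellCollection` is an ordered, filterable
list of cells with unique ids, persisted losslessly to a single HDF5 archive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage

from rodcoords import geometry
from rodcoords.geometry import CoordinateParameters

logger = logging.getLogger(__name__)

__all__ = [
    "ImageElement",
    "LocalizationTable",
    "Cell",
    "CellCollection",
    "orientation_angle",
    "extract_cells",
    "initial_coordinate_guess",
    "filter_cells",
    "save_cells",
    "load_cells",
]

LOC_COLUMNS = ["x", "y", "frame", "intensity"]


@dataclass
class ImageElement:
    """One 2-D image data element of a cell.

    ``role`` is one of ``{"binary", "brightfield", "fluorescence"}``; a binary
    element contains only values 0 and 1.
    """

    pixels: np.ndarray
    role: str
    name: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"element {self.name!r}: pixels must be 2-D")
        if self.role not in ("binary", "brightfield", "fluorescence"):
            raise ValueError(f"unknown image role {self.role!r}")
        if self.role == "binary":
            vals = np.unique(self.pixels)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"binary element {self.name!r} contains values other than 0/1")

    @property
    def shape(self):
        return self.pixels.shape


class LocalizationTable:
    """Sparse SMLM data: one row per localization with x, y (px), frame, intensity."""

    def __init__(self, data=None):
        if data is None:
            data = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})
        df = pd.DataFrame(data).copy()
        for c in ("frame", "intensity"):
            if c not in df.columns:
                df[c] = 0.0
        missing = [c for c in ("x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"localization table missing columns {missing}")
        df = df[LOC_COLUMNS].astype(float).reset_index(drop=True)
        if len(df) and not np.all(np.isfinite(df[["x", "y"]].to_numpy())):
            raise ValueError("non-finite localization coordinates")
        if len(df) and (df["frame"] < 0).any():
            raise ValueError("negative frame index")
        self.data = df

    def __len__(self):
        return len(self.data)

    @property
    def x(self):
        return self.data["x"].to_numpy()

    @property
    def y(self):
        return self.data["y"].to_numpy()

    @property
    def intensity(self):
        return self.data["intensity"].to_numpy()

    def __eq__(self, other):
        return isinstance(other, LocalizationTable) and self.data.equals(other.data)

    def __repr__(self):
        return f"LocalizationTable({len(self)} localizations)"


@dataclass
class Cell:
    """One cropped cell: named data elements plus its coordinate parameters."""

    id: str
    coords: CoordinateParameters | None = None
    elements: dict = field(default_factory=dict)
    #: provenance of the crop (origin, rotation angle, shapes, full-frame
    #: centroid) set by :func:`extract_cells`; empty for constructed cells
    meta: dict = field(default_factory=dict)

    def add_element(self, name: str, element):
        self.elements[name] = element
        return self

    def __getitem__(self, name):
        try:
            return self.elements[name]
        except KeyError:
            raise KeyError(
                f"cell {self.id!r} has no data element {name!r}; "
                f"available: {sorted(self.elements)}"
            ) from None

    @property
    def binary(self) -> ImageElement:
        """The unique data element with role 'binary'."""
        binaries = [e for e in self.elements.values()
                    if isinstance(e, ImageElement) and e.role == "binary"]
        if len(binaries) != 1:
            raise ValueError(f"cell {self.id!r} must have exactly one binary element")
        return binaries[0]

    @property
    def shape(self):
        return self.binary.shape

    # -- derived properties usable in selection predicates ------------------
    @property
    def length(self) -> float:
        """Midline length (px) under the current coordinate parameters."""
        if self.coords is None:
            raise ValueError(f"cell {self.id!r} has no coordinate parameters")
        return geometry.cell_length(self.coords)

    @property
    def radius(self) -> float:
        if self.coords is None:
            raise ValueError(f"cell {self.id!r} has no coordinate parameters")
        return self.coords.r

    @property
    def area(self) -> int:
        """Foreground pixel count of the binary."""
        return int(self.binary.pixels.sum())

    def mean_intensity(self, name: str) -> float:
        el = self[name]
        if not isinstance(el, ImageElement):
            raise TypeError(f"element {name!r} is not an image")
        return float(el.pixels.mean())

    def localization_count(self, name: str) -> int:
        el = self[name]
        if not isinstance(el, LocalizationTable):
            raise TypeError(f"element {name!r} is not a localization table")
        return len(el)


class CellCollection:
    """Ordered list of cells with unique ids."""

    def __init__(self, cells=()):
        cells = list(cells)
        ids = [c.id for c in cells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cell ids in collection")
        self._cells = cells

    def __len__(self):
        return len(self._cells)

    def __iter__(self):
        return iter(self._cells)

    def __getitem__(self, key):
        if isinstance(key, str):
            for c in self._cells:
                if c.id == key:
                    return c
            raise KeyError(key)
        if isinstance(key, slice):
            return CellCollection(self._cells[key])
        return self._cells[key]

    def ids(self):
        return [c.id for c in self._cells]

    def append(self, cell: Cell):
        if cell.id in self.ids():
            raise ValueError(f"duplicate cell id {cell.id!r}")
        self._cells.append(cell)

    def filter(self, predicate) -> "CellCollection":
        return filter_cells(self, predicate)

    def __repr__(self):
        return f"CellCollection({len(self)} cells)"


def orientation_angle(binary: ImageElement | np.ndarray) -> float:
    """Principal-axis angle of a binary mask, degrees in (-90, 90].

    Computed from the second-order central image moments as
    ``theta = 0.5 * atan2(2*mu11, mu20 - mu02)`` with x = columns, y = rows
    (y-down image convention): 0 for a horizontal rod, 90 for a vertical one.
    """
    pixels = binary.pixels if isinstance(binary, ImageElement) else np.asarray(binary)
    rows, cols = np.nonzero(pixels)
    if rows.size < 2:
        raise ValueError("orientation requires at least 2 foreground pixels")
    x = cols + 0.5
    y = rows + 0.5
    xm, ym = x.mean(), y.mean()
    mu20 = np.mean((x - xm) ** 2)
    mu02 = np.mean((y - ym) ** 2)
    mu11 = np.mean((x - xm) * (y - ym))
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    # fold into (-90, 90]
    if theta <= -90.0:
        theta += 180.0
    if theta == -0.0:
        theta = 0.0
    # atan2 yields [-90, 90]; map -90 to the equivalent +90
    if np.isclose(theta, -90.0):
        theta = 90.0
    return float(theta)


def _rotation_transform(angle_deg: float, in_shape, out_shape):
    """Point map (x, y) -> rotated frame matching scipy.ndimage.rotate(reshape=True).

    ``ndimage.rotate(img, angle)`` with reshape maps the input centre to the
    output centre; a point at offset v from the input centre ends up at offset
    R(theta) v in array (row, col) space, theta = radians(angle).  Returned as
    a function on (x, y) pixel coordinates (x = col + 0.5 convention).
    """
    theta = np.radians(angle_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    cin = (np.asarray(in_shape) / 2.0)   # (row, col) centre
    cout = (np.asarray(out_shape) / 2.0)

    def transform(x, y):
        # to (row, col) offsets from centre
        dr = np.asarray(y, float) - cin[0]
        dc = np.asarray(x, float) - cin[1]
        r2 = cos * dr - sin * dc
        c2 = sin * dr + cos * dc
        return c2 + cout[1], r2 + cout[0]

    return transform


def _rotate_image(pixels, angle_deg, binary=False):
    order = 0 if binary else 1
    out = ndimage.rotate(np.asarray(pixels, float), angle_deg, reshape=True,
                         order=order, mode="constant", cval=0.0)
    if binary:
        out = (out > 0.5).astype(np.uint8)
    return out


def extract_cells(labelled_mask, channels=(), localizations=None, pad: int = 3) -> CellCollection:
    """Cut out, rotate and collect single cells from a labelled mask.

    For every label k > 0 the bounding box (dilated by ``pad``) is cropped
    from the mask and every channel, rotated by the negative principal-axis
    angle so the cell lies horizontally (bilinear for intensity images,
    nearest-neighbour for the re-binarised mask), and localizations inside
    the padded box are mapped through the identical point transform into the
    cropped frame.
    """
    mask = labelled_mask.pixels if isinstance(labelled_mask, ImageElement) else np.asarray(labelled_mask)
    mask = np.asarray(mask)
    channels = list(channels)
    for ch in channels:
        if ch.pixels.shape != mask.shape:
            raise ValueError(f"channel {ch.name!r} shape {ch.pixels.shape} != mask {mask.shape}")

    cells = []
    labels = [int(v) for v in np.unique(mask) if v > 0]
    for lab in labels:
        binary_full = (mask == lab).astype(np.uint8)
        rows, cols = np.nonzero(binary_full)
        if rows.size == 0:
            logger.warning("label %d is empty, skipped", lab)
            continue
        r0 = max(rows.min() - pad, 0)
        r1 = min(rows.max() + 1 + pad, mask.shape[0])
        c0 = max(cols.min() - pad, 0)
        c1 = min(cols.max() + 1 + pad, mask.shape[1])
        crop_bin = binary_full[r0:r1, c0:c1]
        try:
            theta = orientation_angle(crop_bin)
        except ValueError:
            logger.warning("label %d has < 2 pixels, skipped", lab)
            continue

        # ndimage.rotate by +theta turns a +theta principal axis horizontal
        rot_bin = _rotate_image(crop_bin, theta, binary=True)
        cy, cx = ndimage.center_of_mass(binary_full)
        cell = Cell(id=f"cell_{lab:05d}")
        cell.meta = {
            "origin": (r0, c0),
            "angle": theta,
            "crop_shape": crop_bin.shape,
            "rot_shape": rot_bin.shape,
            "centroid_full": (cx + 0.5, cy + 0.5),
        }
        cell.add_element("binary", ImageElement(rot_bin, "binary", "binary"))
        for ch in channels:
            crop = ch.pixels[r0:r1, c0:c1]
            rot = _rotate_image(crop, theta, binary=False)
            cell.add_element(ch.name, ImageElement(rot, ch.role, ch.name))

        if localizations is not None and len(localizations):
            x = localizations.x
            y = localizations.y
            inside = (x >= c0) & (x < c1) & (y >= r0) & (y < r1)
            if np.any(inside):
                tf = _rotation_transform(theta, crop_bin.shape, rot_bin.shape)
                xi, yi = tf(x[inside] - c0, y[inside] - r0)
                df = localizations.data.loc[inside].copy()
                df["x"] = xi
                df["y"] = yi
                cell.add_element("storm", LocalizationTable(df))
            else:
                cell.add_element("storm", LocalizationTable())

        try:
            cell.coords = initial_coordinate_guess(cell.binary)
        except ValueError:
            logger.warning("label %d: no coordinate guess possible", lab)
        cells.append(cell)
    return CellCollection(cells)


def initial_coordinate_guess(binary: ImageElement | np.ndarray) -> CoordinateParameters:
    """Guess coordinate parameters from a horizontally oriented binary.

    The midline coefficients come from a least-squares quadratic fit to the
    per-column foreground centre of mass; ``r`` is half the median per-column
    foreground height; the midline endpoints are the foreground column
    extrema pulled inward by ``r`` (the hemispherical poles extend beyond
    the midline domain).
    """
    pixels = binary.pixels if isinstance(binary, ImageElement) else np.asarray(binary)
    rows, cols = np.nonzero(pixels)
    if rows.size == 0:
        raise ValueError("empty binary image")
    col_centers = np.unique(cols) + 0.5
    com = np.array([np.mean(rows[cols == c] + 0.5) for c in np.unique(cols)])
    heights = np.array([np.sum(cols == c) for c in np.unique(cols)])

    deg = 2 if len(col_centers) >= 3 else min(len(col_centers) - 1, 1)
    coeffs = np.polyfit(col_centers, com, deg) if deg >= 1 else np.array([0.0, com[0]])
    coeffs = np.concatenate([np.zeros(3 - len(coeffs)), coeffs])  # pad to quadratic
    a2, a1, a0 = float(coeffs[0]), float(coeffs[1]), float(coeffs[2])

    r = max(float(np.median(heights)) / 2.0, 0.5)
    x_min, x_max = col_centers.min(), col_centers.max()
    xl = x_min + r
    xr = x_max - r
    if not xl < xr:
        # nearly round cell: keep a minimal valid midline around the centre
        mid = 0.5 * (x_min + x_max)
        xl, xr = mid - 0.5, mid + 0.5
    return CoordinateParameters(a0=a0, a1=a1, a2=a2, xl=float(xl), xr=float(xr), r=r)


def filter_cells(cells: CellCollection, predicate) -> CellCollection:
    """Order-preserving subset of cells where ``predicate(cell)`` is true."""
    return CellCollection([c for c in cells if predicate(c)])


# -- persistence (HDF5 archive, one group per cell) -------------------------

def save_cells(path, cells: CellCollection) -> None:
    """Write a collection to a single HDF5 archive (lossless)."""
    with h5py.File(path, "w") as f:
        f.attrs["n_cells"] = len(cells)
        f.attrs["order"] = [c.id for c in cells]
        for cell in cells:
            g = f.create_group(f"cells/{cell.id}")
            if cell.coords is not None:
                g.attrs["coords"] = cell.coords.to_array()
            for name, el in cell.elements.items():
                if isinstance(el, ImageElement):
                    d = g.create_dataset(f"images/{name}", data=el.pixels,
                                         compression="gzip")
                    d.attrs["role"] = el.role
                else:
                    d = g.create_dataset(
                        f"localizations/{name}",
                        data=el.data[LOC_COLUMNS].to_numpy(),
                        compression="gzip",
                    )


def load_cells(path) -> CellCollection:
    """Read a collection written by :func:`save_cells`."""
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise OSError(f"cannot read cell archive {path}: {exc}") from exc
    with f:
        order = [s if isinstance(s, str) else s.decode() for s in f.attrs.get("order", [])]
        cells = []
        for cid in order:
            g = f[f"cells/{cid}"]
            cell = Cell(id=cid)
            if "coords" in g.attrs:
                cell.coords = CoordinateParameters.from_array(g.attrs["coords"])
            if "images" in g:
                for name, ds in g["images"].items():
                    cell.add_element(name, ImageElement(ds[()], ds.attrs["role"], name))
            if "localizations" in g:
                for name, ds in g["localizations"].items():
                    arr = ds[()]
                    cell.add_element(name, LocalizationTable(
                        pd.DataFrame(arr, columns=LOC_COLUMNS)))
            cells.append(cell)
    return CellCollection(cells)
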