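"""Ensemble outputs built on the coordinate transform.

Per-cell and ensemble distributions along the cellular axes, alignment of
many cells onto one model coordinate system, and the membrane-periodicity
pipeline: localization positions along the cell outline -> spatial
autocorrelation -> sliding-window detrend -> Fourier spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rodcoords import geometry
from rodcoords.cell import Cell, CellCollection, ImageElement, LocalizationTable
from rodcoords.geometry import CoordinateParameters

__all__ = [
    "RadialProfile",
    "PerimeterTrace",
    "axial_distribution",
    "ensemble_radial_distribution",
    "align_cells",
    "perimeter_positions",
    "autocorrelate_detrend",
    "dominant_periodicity",
]


@dataclass
class RadialProfile:
    """Binned distribution: bin centres, mean, std and occupancy per bin."""

    x: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.mean = np.asarray(self.mean, float)
        self.std = np.asarray(self.std, float)
        self.n = np.asarray(self.n)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("bin centres must be strictly increasing")

    def to_text(self, path):
        header = "x\tmean\tstd\tn"
        np.savetxt(path, np.column_stack([self.x, self.mean, self.std, self.n]),
                   header=header, delimiter="\t")


@dataclass
class PerimeterTrace:
    """Localization counts per spatial bin along the closed cell outline.

    Positions are in nm, zero at the start of the top membrane segment
    (lc = 0, phi = 0, rc = r) and increasing clockwise.
    """

    positions: np.ndarray  # bin centres, nm
    values: np.ndarray     # counts per bin
    bin_width: float       # nm
    perimeter: float       # nm

    def to_text(self, path):
        np.savetxt(path, np.column_stack([self.positions, self.values]),
                   header="position_nm\tcount", delimiter="\t")


_AXES = ("radial", "longitudinal", "angular")


def _cellular_of_element(cell: Cell, element):
    """(coordinate arrays, weights) of an element's pixels or localizations."""
    if isinstance(element, ImageElement):
        xx, yy = geometry.pixel_centers(element.shape)
        xc, lc, rc, phi = geometry.map_to_cellular(cell.coords, xx.ravel(), yy.ravel())
        return (lc, rc, phi), np.asarray(element.pixels, float).ravel()
    xc, lc, rc, phi = geometry.map_to_cellular(cell.coords, element.x, element.y)
    return (lc, rc, phi), None


def axial_distribution(cell: Cell, element_name: str, axis: str = "radial",
                       bins: int = 50, range_=None) -> RadialProfile:
    """Distribution of one data element along a cellular axis.

    For image elements the mean pixel intensity per coordinate bin is
    returned (with its std and pixel count); for localization elements the
    count per bin.  ``axis`` is ``radial`` (rc, px), ``longitudinal`` (lc,
    px in [0, cell length]) or ``angular`` (phi, degrees in [0, 180]).
    """
    if axis not in _AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {_AXES}")
    if cell.coords is None:
        raise ValueError(f"cell {cell.id!r} has no coordinate parameters")
    element = cell[element_name]
    (lc, rc, phi), weights = _cellular_of_element(cell, element)
    coord = {"radial": rc, "longitudinal": lc, "angular": phi}[axis]

    if range_ is None:
        if axis == "angular":
            range_ = (0.0, 180.0)
        elif axis == "longitudinal":
            range_ = (0.0, geometry.cell_length(cell.coords))
        else:
            range_ = (0.0, float(coord.max()) if coord.size else 1.0)
    edges = np.linspace(range_[0], range_[1], bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(coord, edges) - 1, 0, bins - 1)
    inside = (coord >= range_[0]) & (coord <= range_[1])
    counts = np.bincount(idx[inside], minlength=bins)

    if weights is None:  # localizations: counts per bin
        return RadialProfile(centers, counts.astype(float),
                             np.sqrt(counts), counts)
    w = weights[inside]
    sums = np.bincount(idx[inside], weights=w, minlength=bins)
    sq = np.bincount(idx[inside], weights=w * w, minlength=bins)
    mean = np.divide(sums, counts, out=np.zeros(bins), where=counts > 0)
    var = np.divide(sq, counts, out=np.zeros(bins), where=counts > 0) - mean**2
    return RadialProfile(centers, mean, np.sqrt(np.clip(var, 0, None)), counts)


def ensemble_radial_distribution(cells: CellCollection, element_name: str,
                                 n_bins: int = 50, x_max: float = 2.0) -> RadialProfile:
    """Mean radial distribution over cells on a normalised grid.

    Each cell's radial profile is computed as a function of rc / r (its
    fitted radius maps to x = 1) and normalised to its own maximum; mean and
    std are then taken across cells per bin.
    """
    profiles = []
    for cell in cells:
        if cell.coords is None:
            raise ValueError(f"cell {cell.id!r} has no fitted radius")
        prof = axial_distribution(cell, element_name, "radial", bins=n_bins,
                                  range_=(0.0, x_max * cell.coords.r))
        peak = prof.mean.max()
        if peak <= 0:
            raise ValueError(f"cell {cell.id!r} has an empty radial profile")
        profiles.append(prof.mean / peak)
    if not profiles:
        raise ValueError("empty collection")
    stack = np.vstack(profiles)
    centers = np.linspace(0.0, x_max, n_bins + 1)
    centers = 0.5 * (centers[:-1] + centers[1:])
    return RadialProfile(centers, stack.mean(axis=0), stack.std(axis=0),
                         np.full(n_bins, len(profiles)))


def align_cells(cells: CellCollection, element_name: str,
                model: CoordinateParameters, sigma: float = 0.5,
                shape=None) -> np.ndarray:
    """Align many cells onto one model coordinate system and render the sum.

    Every pixel centre (weighted by its intensity) or localization of each
    cell is transformed to cellular coordinates, rescaled to the model cell
    (lc by the length ratio, rc by the radius ratio), mapped back to model
    Cartesian coordinates and rendered as a 2-D Gaussian of width ``sigma``
    (truncated at 4 sigma).  Total rendered mass matches the total input
    weight up to the Gaussian truncation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if shape is None:
        x_dom = np.linspace(model.xl, model.xr, 64)
        pad = model.r + 4 * sigma
        shape = (int(np.ceil(model.p(x_dom).max() + pad)),
                 int(np.ceil(model.xr + pad)))
    L_model = geometry.cell_length(model)
    out = np.zeros(shape, float)
    trunc = int(np.ceil(4 * sigma))
    offs = np.arange(-trunc, trunc + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")

    for cell in cells:
        L_cell = geometry.cell_length(cell.coords)
        if L_cell <= 0:
            raise ValueError(f"cell {cell.id!r} has zero length")
        (lc, rc, phi), weights = _cellular_of_element(cell, cell[element_name])
        if weights is None:
            weights = np.ones(lc.shape)
        lc_m = lc * (L_model / L_cell)
        rc_m = rc * (model.r / cell.coords.r)
        xm, ym = geometry.map_to_cartesian(model, lc_m, rc_m, phi)

        # splat each weighted point as a truncated Gaussian patch normalised
        # to the point's weight (mass is lost only to frame clipping)
        for lo in range(0, len(xm), 2048):
            sl = slice(lo, min(lo + 2048, len(xm)))
            jc = np.floor(xm[sl] - 0.5).astype(int)
            ic = np.floor(ym[sl] - 0.5).astype(int)
            ii = ic[:, None, None] + oy[None]
            jj = jc[:, None, None] + ox[None]
            gx = jj + 0.5 - xm[sl, None, None]
            gy = ii + 0.5 - ym[sl, None, None]
            g = np.exp(-(gx**2 + gy**2) / (2 * sigma**2))
            g *= (weights[sl] / g.sum(axis=(1, 2)))[:, None, None]
            valid = (ii >= 0) & (ii < shape[0]) & (jj >= 0) & (jj < shape[1])
            np.add.at(out, (ii[valid], jj[valid]), g[valid])
    return out


def perimeter_positions(params: CoordinateParameters, locs: LocalizationTable,
                        pixel_size_nm: float = 80.0,
                        bin_width_nm: float = 10.0) -> PerimeterTrace:
    """Histogram of localization positions along the cell outline.

    Localizations are projected onto the closed isodistance outline at
    distance ``r``; the position runs clockwise from the start of the top
    membrane segment (lc = 0, phi = 0).
    """
    _, lc, rc, phi = geometry.map_to_cellular(params, locs.x, locs.y)
    s_px = geometry.perimeter_position(params, lc, phi)
    P_nm = geometry.perimeter_length(params) * pixel_size_nm
    s_nm = s_px * pixel_size_nm
    n_bins = max(int(np.ceil(P_nm / bin_width_nm)), 1)
    edges = np.linspace(0.0, n_bins * bin_width_nm, n_bins + 1)
    counts, _ = np.histogram(s_nm, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PerimeterTrace(positions=centers, values=counts.astype(float),
                          bin_width=float(bin_width_nm), perimeter=P_nm)


def autocorrelate_detrend(trace: PerimeterTrace, window_nm: float = 150.0) -> np.ndarray:
    """Detrended spatial autocorrelation of a perimeter trace.

    The unbiased autocorrelation of the binned counts is computed for lags
    0 ... perimeter/2 and its low-frequency envelope, estimated by a centred
    moving average of width ``window_nm``, is subtracted.
    """
    values = np.asarray(trace.values, float)
    n = len(values)
    win_bins = int(round(window_nm / trace.bin_width))
    if win_bins < 3:
        raise ValueError("detrend window must span at least 3 bins")
    if n < 2 * win_bins:
        raise ValueError("trace too short for the requested detrend window")

    x = values - values.mean()
    max_lag = n // 2
    full = np.correlate(x, x, mode="full")[n - 1:n - 1 + max_lag + 1]
    acf = full / (n - np.arange(max_lag + 1))  # unbiased normalisation

    kernel = np.ones(win_bins) / win_bins
    pad = win_bins // 2
    padded = np.pad(acf, pad, mode="reflect")
    trend = np.convolve(padded, kernel, mode="same")[pad:pad + len(acf)]
    return acf - trend


def dominant_periodicity(signal, bin_width_nm: float, pad_factor: int = 4) -> float:
    """Wavelength (nm) of the largest-amplitude Fourier component.

    The spectrum is computed with ``pad_factor``-times zero padding for peak
    resolution; the zero-frequency term is excluded.
    """
    signal = np.asarray(signal, float)
    if not np.any(signal):
        raise ValueError("all-zero signal has no dominant periodicity")
    n_pad = pad_factor * len(signal)
    spectrum = np.abs(np.fft.rfft(signal, n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=bin_width_nm)
    k = 1 + int(np.argmax(spectrum[1:]))
    return float(1.0 / freqs[k])
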