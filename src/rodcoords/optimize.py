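"""Chi-square objectives and the minimisation driver refining a cell's coordinates.

Three objective functions measure how well a candidate coordinate system
describes a data element:

* binary  -- the model mask (radial distance <= r) is compared pixel-wise
  with the measured binary; chi2 is the count of disagreeing pixels;
* image   -- an isotropic model image is bootstrapped from the measurement
  itself (angular average as a function of radial distance, histogram
  binning) and chi2 is the sum of squared pixel differences;
* localizations -- chi2 = sum_i (rc_i - r)^2 over all localizations.

``optimize_cell`` minimises the selected objective with a derivative-free
Nelder-Mead simplex started from the cell's current parameters; for the
image objective the radius is set afterwards from the half-maximum point of
the radial intensity profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from rodcoords import geometry
from rodcoords.cell import Cell, ImageElement, LocalizationTable
from rodcoords.geometry import CoordinateParameters

__all__ = [
    "OptimizeResult",
    "radial_distance_image",
    "objective_binary",
    "radial_profile_of_image",
    "simulate_isotropic_image",
    "objective_image",
    "objective_localizations",
    "fit_radius_halfmax",
    "optimize_cell",
]

#: characteristic simplex step per parameter (a0, a1, a2, xl, xr, r)
PARAM_STEPS = np.array([1.0, 0.01, 1e-4, 1.0, 1.0, 0.5])

#: pixels with rc beyond r + this margin are excluded from the image objective
IMAGE_MARGIN = 5.0

DEFAULT_BIN_WIDTH = 0.5


@dataclass
class OptimizeResult:
    """Outcome of one coordinate-system optimisation."""

    params: CoordinateParameters
    chi2: float
    n_eval: int
    converged: bool
    method: str


def radial_distance_image(params: CoordinateParameters, shape) -> np.ndarray:
    """Image of the radial coordinate rc evaluated at every pixel centre."""
    return geometry.radial_distance_map(params, shape)


def objective_binary(params: CoordinateParameters, binary) -> float:
    """Disagreement count between the model mask (rc <= r) and a binary image."""
    pixels = binary.pixels if isinstance(binary, ImageElement) else np.asarray(binary)
    rc = radial_distance_image(params, pixels.shape)
    model = (rc <= params.r).astype(float)
    return float(np.sum((model - pixels) ** 2))


def radial_profile_of_image(params, image, bin_width: float = DEFAULT_BIN_WIDTH,
                            rc=None, max_rc=None):
    """Angular average of pixel intensity as a function of radial distance.

    Pixels are binned by their rc value in bins of ``bin_width``; empty bins
    take the value of the nearest non-empty bin.  Returns
    ``(bin_centers, mean_intensity)``.
    """
    pixels = image.pixels if isinstance(image, ImageElement) else np.asarray(image)
    if rc is None:
        rc = radial_distance_image(params, pixels.shape)
    rc_flat = rc.ravel()
    val_flat = np.asarray(pixels, float).ravel()
    if max_rc is None:
        max_rc = float(rc_flat.max())
    n_bins = max(int(np.ceil(max_rc / bin_width)), 1)
    idx = np.minimum((rc_flat / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=val_flat, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    mean = np.full(n_bins, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    if not nz.all():
        # nearest non-empty fill
        filled = np.flatnonzero(nz)
        if filled.size == 0:
            raise ValueError("radial profile has no occupied bins")
        empty = np.flatnonzero(~nz)
        nearest = filled[np.argmin(np.abs(empty[:, None] - filled[None, :]), axis=1)]
        mean[empty] = mean[nearest]
    return centers, mean


def simulate_isotropic_image(params, image, bin_width: float = DEFAULT_BIN_WIDTH,
                             rc=None):
    """Isotropic model image: each pixel takes the radial profile value at its rc."""
    pixels = image.pixels if isinstance(image, ImageElement) else np.asarray(image)
    if rc is None:
        rc = radial_distance_image(params, pixels.shape)
    centers, mean = radial_profile_of_image(params, pixels, bin_width, rc=rc)
    return np.interp(rc, centers, mean)


def objective_image(params, image, bin_width: float = DEFAULT_BIN_WIDTH) -> float:
    """Sum of squared differences between the image and its isotropic model.

    Pixels with rc > r + margin are excluded so the flat background far from
    the cell dominates neither the profile nor the chi-square.
    """
    pixels = image.pixels if isinstance(image, ImageElement) else np.asarray(image)
    pixels = np.asarray(pixels, float)
    rc = radial_distance_image(params, pixels.shape)
    mask = rc <= params.r + IMAGE_MARGIN
    if not np.any(mask):
        return float("inf")
    rc_m = rc[mask]
    val_m = pixels[mask]
    centers, mean = radial_profile_of_image(params, val_m, bin_width, rc=rc_m)
    sim = np.interp(rc_m, centers, mean)
    return float(np.sum((val_m - sim) ** 2))


def objective_localizations(params: CoordinateParameters, locs) -> float:
    """Sum of squared radial deviations of localizations from the radius r."""
    if isinstance(locs, LocalizationTable):
        x, y = locs.x, locs.y
    else:
        x, y = np.asarray(locs[0], float), np.asarray(locs[1], float)
    if x.size == 0:
        raise ValueError("empty localization table")
    _, _, rc, _ = geometry.map_to_cellular(params, x, y)
    return float(np.sum((rc - params.r) ** 2))


def fit_radius_halfmax(params, image, bin_width: float = DEFAULT_BIN_WIDTH) -> float:
    """Cell radius from the half-maximum point of the radial intensity profile.

    The profile peak is located (the interior membrane peak for ring-like
    profiles, rc = 0 for monotonically decreasing ones); the radius is the rc
    where the profile first crosses halfway between the peak and the
    far-field baseline, moving outward of the peak, with linear interpolation
    between bins.
    """
    centers, mean = radial_profile_of_image(params, image, bin_width)
    if np.ptp(mean) < 1e-12:
        raise ValueError("flat radial profile: no half-maximum point")
    # far-field baseline: average of the outermost 20% of bins
    n_tail = max(len(mean) // 5, 1)
    baseline = float(np.mean(mean[-n_tail:]))
    ipk = int(np.argmax(np.abs(mean - baseline)))
    peak = float(mean[ipk])
    half = 0.5 * (peak + baseline)
    seg = mean[ipk:]
    if peak >= baseline:
        crossing = np.flatnonzero((seg[:-1] >= half) & (seg[1:] < half))
    else:
        crossing = np.flatnonzero((seg[:-1] <= half) & (seg[1:] > half))
    if crossing.size == 0:
        raise ValueError("profile never crosses its half-maximum outward of the peak")
    k = ipk + crossing[0]
    y0, y1 = mean[k], mean[k + 1]
    frac = (half - y0) / (y1 - y0)
    return float(centers[k] + frac * bin_width)


_OBJECTIVES = {
    "binary": objective_binary,
    "image": objective_image,
    "localizations": objective_localizations,
}


def _objective_for(method, element):
    if method == "binary":
        return lambda p: objective_binary(p, element)
    if method == "image":
        return lambda p: objective_image(p, element)
    if method == "localizations":
        return lambda p: objective_localizations(p, element)
    raise ValueError(f"unknown optimization method {method!r}")


def _minimize_params(fun, start: CoordinateParameters, free: np.ndarray,
                     bounds=None):
    """Nelder-Mead over the free subset of (a0, a1, a2, xl, xr, r)."""
    x_full = start.to_array()
    idx = np.flatnonzero(free)
    n_eval = 0

    def wrapped(x_free):
        nonlocal n_eval
        n_eval += 1
        x = x_full.copy()
        x[idx] = x_free
        if not x[3] < x[4] or not x[5] > 0:
            return 1e300
        if bounds is not None:
            for i, (lo, hi) in zip(range(6), bounds):
                if lo is not None and x[i] < lo:
                    return 1e300
                if hi is not None and x[i] > hi:
                    return 1e300
        try:
            return fun(CoordinateParameters.from_array(x))
        except ValueError:
            return 1e300

    x0 = x_full[idx]
    f0 = wrapped(x0)
    if not np.isfinite(f0) or f0 >= 1e300:
        raise ValueError("objective is not finite at the starting parameters")

    # initial simplex scaled to the natural step of each parameter
    simplex = np.vstack([x0] + [x0 + PARAM_STEPS[idx] * e
                                for e in np.eye(len(idx))])
    res = minimize(
        wrapped, x0, method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": 1e-4,
            "fatol": 1e-6 * max(1.0, f0),
            "maxfev": 4000,
            "adaptive": True,
        },
    )
    x_best = x_full.copy()
    if res.fun <= f0:
        x_best[idx] = res.x
        chi2 = float(res.fun)
    else:  # never return a point worse than the start
        chi2 = f0
    return CoordinateParameters.from_array(x_best), chi2, n_eval, bool(res.success)


def optimize_cell(cell: Cell, element_name: str, method: str,
                  bounds=None, bin_width: float = DEFAULT_BIN_WIDTH) -> OptimizeResult:
    """Refine a cell's coordinate system against one of its data elements.

    ``method`` is one of ``{"binary", "image", "localizations"}``.  The binary
    and localization methods optimise all six parameters; the image method
    optimises the five geometry parameters and then sets ``r`` from the
    half-maximum point of the radial profile.  On success the cell's
    parameters are replaced by the optimum; the returned chi2 never exceeds
    the starting value.
    """
    if cell.coords is None:
        raise ValueError(f"cell {cell.id!r} has no coordinate parameters to refine")
    element = cell[element_name]
    if method == "localizations" and not isinstance(element, LocalizationTable):
        raise TypeError(f"element {element_name!r} is not a localization table")
    if method in ("binary", "image") and not isinstance(element, ImageElement):
        raise TypeError(f"element {element_name!r} is not an image")
    if method == "binary" and element.role != "binary":
        raise TypeError(f"element {element_name!r} does not have role 'binary'")

    if method == "image":
        fun = lambda p: objective_image(p, element, bin_width)
        free = np.array([1, 1, 1, 1, 1, 0], bool)
    else:
        fun = _objective_for(method, element)
        free = np.ones(6, bool)

    params, chi2, n_eval, converged = _minimize_params(fun, cell.coords, free, bounds)

    if method == "image":
        r = fit_radius_halfmax(params, element, bin_width)
        params = params.with_updates(r=r)
        chi2 = fun(params)

    cell.coords = params
    return OptimizeResult(params=params, chi2=float(chi2), n_eval=n_eval,
                          converged=converged, method=method)
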