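"""Synthetic rod-cell benchmark: ground-truth generation, rendering, scoring.

Ground-truth cells are drawn from configurable geometry distributions and
rendered as exact binaries, brightfield-like images (background 1.0 scaled by
a photon count, Poisson shot noise plus Gaussian read noise of 20 photons)
and membrane-localized SMLM tables with Gaussian radial scatter.  Cells can
be composed into full fields (10 +/- 3 cells per 512x512 frame, >= 5 px
between binaries), measured cells matched back to truth by centroid, and
fits scored with the relative chi-square: the localization objective at the
fitted parameters divided by its value at the ground truth (1 = perfect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from rodcoords import geometry
from rodcoords.cell import (
    Cell,
    CellCollection,
    ImageElement,
    LocalizationTable,
    _rotation_transform,
    initial_coordinate_guess,
)
from rodcoords.geometry import CoordinateParameters
from rodcoords.optimize import objective_localizations, optimize_cell

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryConfig",
    "FieldConfig",
    "GroundTruthCell",
    "sample_geometry",
    "make_ground_truth_cell",
    "render_binary",
    "render_brightfield",
    "sample_membrane_localizations",
    "degrade_binary",
    "compose_field",
    "match_measured_to_truth",
    "relative_chi2",
    "run_benchmark",
]

READ_NOISE_SD = 20.0  # photons
LOC_SIGMA_PX = 0.25   # radial scatter of membrane localizations
OUTER_OFFSET_NM = 100.0


@dataclass
class GeometryConfig:
    """Distributions of the synthetic-cell geometry (units px unless noted).

    Defaults emulate E. coli imaged at 80 nm/px: radius ~ N(5, 0.5) px,
    midline length ~ N(25, 5) px truncated above 10 px, curvature
    a2 ~ N(0, 0.004) /px.
    """

    radius_mean: float = 5.0
    radius_sd: float = 0.5
    radius_bounds: tuple = (3.0, 7.0)
    length_mean: float = 25.0
    length_sd: float = 5.0
    length_bounds: tuple = (10.0, 45.0)
    curvature_sd: float = 0.004
    curvature_bounds: tuple = (-0.012, 0.012)
    pixel_size_nm: float = 80.0
    margin: float = 3.0  # empty frame border beyond the cell outline

    def __post_init__(self):
        if self.radius_sd < 0 or self.length_sd < 0 or self.curvature_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.radius_bounds[0] <= 0:
            raise ValueError("radius bounds must keep r > 0")
        if self.length_bounds[0] <= 0:
            raise ValueError("length bounds must keep xl < xr")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class FieldConfig:
    """Composition of synthetic fields from individual cells."""

    shape: tuple = (512, 512)
    cells_mean: float = 10.0
    cells_sd: float = 3.0
    min_distance: float = 5.0
    photons: int = 1000
    read_noise_sd: float = READ_NOISE_SD
    max_tries: int = 200

    def __post_init__(self):
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if self.photons <= 0:
            raise ValueError("photon count must be positive")


@dataclass
class GroundTruthCell:
    """A synthetic cell with its true parameters and noiseless data elements."""

    id: str
    true_params: CoordinateParameters
    cell: Cell
    membrane_radii: dict = field(default_factory=dict)  # element name -> true mean rc

    @property
    def scoring_params(self) -> CoordinateParameters:
        """True geometry with r set to the inner-membrane radius (the radius
        the localization chi-square is evaluated against)."""
        return self.true_params.with_updates(r=self.membrane_radii["storm_inner"])


def _truncated_normal(rng, mean, sd, bounds, max_draws=1000):
    if sd == 0:
        val = mean
        if not bounds[0] <= val <= bounds[1]:
            raise ValueError(f"mean {mean} outside bounds {bounds}")
        return val
    for _ in range(max_draws):
        val = rng.normal(mean, sd)
        if bounds[0] <= val <= bounds[1]:
            return float(val)
    raise ValueError(f"could not draw a value in {bounds} after {max_draws} tries")


def sample_geometry(config: GeometryConfig, rng) -> CoordinateParameters:
    """Draw one cell's coordinate parameters; deterministic under a fixed seed.

    The cell is laid out in its own frame: the midline starts at
    ``xl = r + margin``, the slope is centred (zero at mid-domain) and ``a0``
    places the midline vertically so the outline clears the frame border.
    """
    r = _truncated_normal(rng, config.radius_mean, config.radius_sd, config.radius_bounds)
    length = _truncated_normal(rng, config.length_mean, config.length_sd, config.length_bounds)
    a2 = _truncated_normal(rng, 0.0, config.curvature_sd, config.curvature_bounds)

    m = r + config.margin
    xl = m
    xr = xl + length
    a1 = -a2 * (xl + xr)  # zero slope at the domain centre
    x = np.linspace(xl, xr, 64)
    sag = a1 * x + a2 * x * x
    a0 = m - sag.min()
    return CoordinateParameters(a0=a0, a1=a1, a2=a2, xl=xl, xr=xr, r=r)


def frame_shape(params: CoordinateParameters, margin: float = 3.0) -> tuple:
    """Smallest frame that holds the cell outline plus a border."""
    x = np.linspace(params.xl, params.xr, 64)
    p = params.p(x)
    height = int(np.ceil(p.max() + params.r + margin))
    width = int(np.ceil(params.xr + params.r + margin))
    return height, width


def render_binary(params: CoordinateParameters, shape) -> ImageElement:
    """Exact binary: pixel = 1 iff the radial distance of its centre <= r."""
    rc = geometry.radial_distance_map(params, shape)
    binary = (rc <= params.r).astype(np.uint8)
    border = np.concatenate([binary[0], binary[-1], binary[:, 0], binary[:, -1]])
    if border.any():
        raise ValueError("cell outline is clipped by the frame")
    return ImageElement(binary, "binary", "binary")


def brightfield_radial_model(rc, r, contrast: float = 0.5, ring_width: float = 1.5):
    """Relative brightfield intensity: background 1 plus a Gaussian membrane ring.

    The ring centre sits at ``r - ring_width*sqrt(2*ln 2)`` so that the
    half-maximum point of the profile, moving outward of the peak, falls
    exactly at the geometric radius ``r``: the radius measured from the
    brightfield image by the half-maximum criterion then agrees with the
    radius defining the binary, as it does for the real-cell profiles the
    model emulates.
    """
    center = r - ring_width * np.sqrt(2.0 * np.log(2.0))
    return 1.0 + contrast * np.exp(-((rc - center) ** 2) / (2.0 * ring_width**2))


def render_brightfield(params: CoordinateParameters, shape, photons: float,
                       rng=None, contrast: float = 0.5, ring_width: float = 1.5,
                       read_noise_sd: float = READ_NOISE_SD) -> ImageElement:
    """Brightfield-like image with Poisson shot noise and Gaussian read noise.

    The noiseless image is ``photons`` times the relative radial intensity
    model (background 1.0, fixed membrane-ring contrast).  With ``rng=None``
    the noiseless expectation is returned.
    """
    if photons <= 0:
        raise ValueError("photon count must be positive")
    rc = geometry.radial_distance_map(params, shape)
    expected = photons * brightfield_radial_model(rc, params.r, contrast, ring_width)
    if rng is None:
        pixels = expected
    else:
        pixels = rng.poisson(expected).astype(float)
        pixels += rng.normal(0.0, read_noise_sd, size=pixels.shape)
    return ImageElement(pixels, "brightfield", "brightfield")


def sample_membrane_localizations(params: CoordinateParameters, mean_radius: float,
                                  sigma: float, n: int, rng) -> LocalizationTable:
    """Homogeneous membrane localizations with Gaussian radial scatter.

    Positions are uniform along the closed outline at ``mean_radius``; the
    radial coordinate of each localization is ``mean_radius + N(0, sigma)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    P = geometry.perimeter_length(params, mean_radius)
    s = rng.uniform(0.0, P, size=n)
    lc, phi = geometry.cellular_from_perimeter(params, s, mean_radius)
    rc = mean_radius + (rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0)
    rc = np.clip(rc, 0.0, None)
    x, y = geometry.map_to_cartesian(params, lc, rc, phi)
    return LocalizationTable(pd.DataFrame({
        "x": x, "y": y, "frame": np.zeros(n), "intensity": np.ones(n)}))


def make_ground_truth_cell(config: GeometryConfig, rng, cell_id: str = "truth_0",
                           photons: float | None = None,
                           n_locs: int = 200,
                           inner_radius_factor: float = 0.9,
                           loc_sigma: float = LOC_SIGMA_PX) -> GroundTruthCell:
    """Sample one ground-truth cell with binary, brightfield and two membrane
    localization elements (inner membrane, and outer 100 nm further out)."""
    params = sample_geometry(config, rng)
    shape = frame_shape(params, config.margin)
    cell = Cell(id=cell_id, coords=params)
    cell.add_element("binary", render_binary(params, shape))
    if photons is not None:
        cell.add_element("brightfield",
                         render_brightfield(params, shape, photons, rng))
    r_inner = inner_radius_factor * params.r
    r_outer = r_inner + OUTER_OFFSET_NM / config.pixel_size_nm
    cell.add_element("storm_inner",
                     sample_membrane_localizations(params, r_inner, loc_sigma, n_locs, rng))
    cell.add_element("storm_outer",
                     sample_membrane_localizations(params, r_outer, loc_sigma, n_locs, rng))
    return GroundTruthCell(id=cell_id, true_params=params, cell=cell,
                           membrane_radii={"storm_inner": r_inner,
                                           "storm_outer": r_outer})


def degrade_binary(binary: ImageElement, rng, severity: float = 0.3,
                   asymmetry: float = 2.0) -> ImageElement:
    """Morphological boundary noise emulating imperfect segmentation.

    Pixels of the one-pixel boundary bands are flipped at random: the outer
    band (background pixels touching the cell) with probability ``severity``
    and the inner band with ``severity / asymmetry``.  The asymmetry gives
    the mild over-segmentation bias real low-contrast images produce (the
    blurred halo around a cell is picked up as foreground), so degraded
    masks get both noisier and slightly fatter as ``severity`` grows.
    """
    pixels = binary.pixels.astype(bool)
    eroded = ndimage.binary_erosion(pixels)
    dilated = ndimage.binary_dilation(pixels)
    inner_band = pixels & ~eroded
    outer_band = dilated & ~pixels
    out = pixels.copy()
    out[inner_band & (rng.random(pixels.shape) < severity / asymmetry)] = False
    out[outer_band & (rng.random(pixels.shape) < severity)] = True
    # keep the largest connected component so the guess stays rod-shaped
    lab, n = ndimage.label(out)
    if n > 1:
        sizes = ndimage.sum_labels(out, lab, index=np.arange(1, n + 1))
        out = lab == (1 + int(np.argmax(sizes)))
    return ImageElement(out.astype(np.uint8), "binary", "binary")


def sample_cell_count(config: FieldConfig, rng) -> int:
    """Number of cells for one field: round(N(mean, sd)), floored at 0."""
    return max(int(round(rng.normal(config.cells_mean, config.cells_sd))), 0)


@dataclass
class PlacementRecord:
    """Where one ground-truth cell landed in a composed field."""

    truth: GroundTruthCell
    angle: float        # rotation applied (degrees)
    origin: tuple       # (row, col) of the pasted patch's top-left corner
    patch_shape: tuple  # rotated patch shape
    centroid: tuple     # field-frame (x, y) of the binary centre of mass
    loc_rows: np.ndarray  # row indices of this cell in the combined table

    def to_field(self, x, y):
        """Map cell-frame coordinates into the field frame."""
        tf = _rotation_transform(self.angle, self.truth.cell.shape, self.patch_shape)
        xr_, yr_ = tf(x, y)
        return xr_ + self.origin[1], yr_ + self.origin[0]

    def to_cell(self, x, y):
        """Map field-frame coordinates back into the truth cell frame."""
        tf = _rotation_transform(-self.angle, self.patch_shape, self.truth.cell.shape)
        return tf(np.asarray(x, float) - self.origin[1],
                  np.asarray(y, float) - self.origin[0])


def compose_field(truth_cells, config: FieldConfig, rng, n_cells=None):
    """Randomly rotate and place cells into one field.

    Returns ``(labelled_mask, brightfield, combined_locs, placements)``.  The
    pairwise distance between distinct cells' binaries is kept >= the
    configured minimum; cells that cannot be placed after ``max_tries``
    attempts are skipped with a log message.
    """
    truth_cells = list(truth_cells)
    if n_cells is None:
        n_cells = sample_cell_count(config, rng)
    shape = tuple(config.shape)
    mask = np.zeros(shape, dtype=np.int32)
    relative = np.ones(shape, dtype=float)  # brightfield before photon scaling
    occupied = np.zeros(shape, dtype=bool)
    placements = []
    loc_frames = []
    next_row = 0

    for k in range(n_cells):
        truth = truth_cells[rng.integers(len(truth_cells))]
        angle = float(rng.uniform(0.0, 360.0))
        bin_rot = ndimage.rotate(truth.cell.binary.pixels.astype(float), angle,
                                 reshape=True, order=0, mode="constant") > 0.5
        bf_el = truth.cell.elements.get("brightfield")
        ph, pw = bin_rot.shape
        if ph >= shape[0] or pw >= shape[1]:
            logger.warning("cell %s too large for the field, skipped", truth.id)
            continue

        if occupied.any():
            dist_to_cells = ndimage.distance_transform_edt(~occupied)
        else:
            dist_to_cells = np.full(shape, np.inf)

        placed = False
        for _ in range(config.max_tries):
            r0 = int(rng.integers(0, shape[0] - ph))
            c0 = int(rng.integers(0, shape[1] - pw))
            region = dist_to_cells[r0:r0 + ph, c0:c0 + pw]
            if np.min(region[bin_rot]) >= config.min_distance:
                placed = True
                break
        if not placed:
            logger.warning("no room for cell %d/%d, field has %d cells",
                           k + 1, n_cells, len(placements))
            continue

        label = len(placements) + 1
        mask[r0:r0 + ph, c0:c0 + pw][bin_rot] = label
        occupied[r0:r0 + ph, c0:c0 + pw] |= bin_rot
        if bf_el is not None:
            # noiseless relative model of this cell (background 1 subtracted)
            rc_map = geometry.radial_distance_map(truth.true_params, truth.cell.shape)
            rel_patch = brightfield_radial_model(rc_map, truth.true_params.r) - 1.0
            rel_rot = ndimage.rotate(rel_patch, angle, reshape=True,
                                     order=1, mode="constant", cval=0.0)
            relative[r0:r0 + ph, c0:c0 + pw] += rel_rot

        rows, cols = np.nonzero(bin_rot)
        centroid = (cols.mean() + 0.5 + c0, rows.mean() + 0.5 + r0)

        frames = []
        for name in ("storm_inner", "storm_outer"):
            el = truth.cell.elements.get(name)
            if el is None or len(el) == 0:
                continue
            rec = PlacementRecord(truth, angle, (r0, c0), bin_rot.shape, centroid,
                                  np.array([], int))
            fx, fy = rec.to_field(el.x, el.y)
            df = el.data.copy()
            df["x"] = fx
            df["y"] = fy
            frames.append(df)
        combined = (pd.concat(frames, ignore_index=True)
                    if frames else pd.DataFrame(columns=["x", "y", "frame", "intensity"]))
        loc_rows = np.arange(next_row, next_row + len(combined))
        next_row += len(combined)
        loc_frames.append(combined)
        placements.append(PlacementRecord(truth, angle, (r0, c0), bin_rot.shape,
                                          centroid, loc_rows))

    all_locs = (pd.concat(loc_frames, ignore_index=True)
                if loc_frames else pd.DataFrame(columns=["x", "y", "frame", "intensity"]))
    expected = config.photons * relative
    brightfield = rng.poisson(np.clip(expected, 0, None)).astype(float)
    brightfield += rng.normal(0.0, config.read_noise_sd, size=shape)
    return (mask,
            ImageElement(brightfield, "brightfield", "brightfield"),
            LocalizationTable(all_locs),
            placements)


@dataclass
class MatchResult:
    """Outcome of matching measured cells back to ground truth."""

    pairs: list            # (placement, measured Cell, recovery_fraction)
    unmatched_truth: list
    unmatched_measured: list
    flagged: list          # matched but with recovery fraction below threshold


def match_measured_to_truth(placements, measured: CellCollection, gate: float = 5.0,
                            min_recovery: float = 0.5,
                            membership_margin: float = 2.5) -> MatchResult:
    """Greedy nearest-centroid matching of measured cells to placements.

    Matches within a ``gate`` px centre-of-mass distance; for each matched
    cell, localizations that do not belong to the truth cell (radial distance
    under the true parameters beyond r + margin once mapped back to the truth
    frame) are removed, and cells recovering less than ``min_recovery`` of
    the truth localization count are flagged.
    """
    if not placements or len(measured) == 0:
        return MatchResult([], list(placements), list(measured), [])

    t_cent = np.array([p.centroid for p in placements])
    m_cent = np.array([c.meta.get("centroid_full", (np.nan, np.nan)) for c in measured])
    d = np.linalg.norm(t_cent[:, None, :] - m_cent[None, :, :], axis=2)

    order = np.argsort(d, axis=None)
    used_t, used_m, pairs = set(), set(), []
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > gate:
            break
        if i in used_t or j in used_m:
            continue
        used_t.add(int(i))
        used_m.add(int(j))
        pairs.append((placements[i], measured[int(j)]))

    results, flagged = [], []
    for placement, cell in pairs:
        truth = placement.truth
        n_truth = sum(len(truth.cell.elements[n]) for n in ("storm_inner", "storm_outer")
                      if n in truth.cell.elements)
        frac = 1.0
        if "storm" in cell.elements and n_truth > 0:
            locs = cell.elements["storm"]
            if len(locs):
                # measured cell frame -> field frame -> truth cell frame
                ox, oy = cell.meta["origin"][1], cell.meta["origin"][0]
                tf = _rotation_transform(-cell.meta["angle"],
                                         cell.meta["rot_shape"], cell.meta["crop_shape"])
                fx, fy = tf(locs.x, locs.y)
                fx, fy = fx + ox, fy + oy
                cx, cy = placement.to_cell(fx, fy)
                _, _, rc, _ = geometry.map_to_cellular(truth.true_params, cx, cy)
                keep = rc <= truth.true_params.r + membership_margin
                kept = locs.data.loc[keep].reset_index(drop=True)
                cell.elements["storm"] = LocalizationTable(kept)
                frac = len(kept) / n_truth
            else:
                frac = 0.0
        results.append((placement, cell, frac))
        if frac < min_recovery:
            flagged.append((placement, cell, frac))

    unmatched_t = [placements[i] for i in range(len(placements)) if i not in used_t]
    unmatched_m = [measured[j] for j in range(len(measured)) if j not in used_m]
    return MatchResult(results, unmatched_t, unmatched_m, flagged)


def relative_chi2(measured_params: CoordinateParameters,
                  true_params: CoordinateParameters,
                  locs: LocalizationTable) -> float:
    """Localization chi-square at the fit divided by its ground-truth value."""
    denom = objective_localizations(true_params, locs)
    if denom <= 1e-12 * max(len(locs), 1):  # exactly-on-outline data
        raise ValueError("ground-truth chi-square is zero; cannot normalize")
    return objective_localizations(measured_params, locs) / denom


#: default boundary-flip severity per photon level, emulating segmentation
#: quality degrading with signal-to-noise
DEGRADE_SEVERITY = {500: 0.5, 1000: 0.35, 10000: 0.2}


def run_benchmark(geometry_config: GeometryConfig | None = None,
                  methods=("binary", "image", "localizations"),
                  photon_levels=(500, 1000, 10000),
                  n_cells: int = 50,
                  n_locs: int = 200,
                  seed: int = 0,
                  inner_radius_factor: float = 0.9,
                  loc_sigma: float = LOC_SIGMA_PX) -> pd.DataFrame:
    """Generate cells, fit them with each method and score against truth.

    For every cell and photon level, the truth binary is degraded (severity
    tied to the photon level, emulating segmentation quality), the initial
    coordinate guess is taken from the degraded binary, and each requested
    method refines the coordinate system against its data element (the
    degraded binary, the noisy brightfield, or the inner-membrane
    localizations).  Per cell the table reports the relative chi-square
    (localization objective at the fit over at the ground truth), the fitted
    radius, and the deviation statistics of the recovered radial coordinates
    of all membrane localizations, normalised to the true inner-membrane
    radius: D (mean absolute deviation), D2 (root mean squared deviation)
    and the per-cell median absolute relative deviation.
    """
    if geometry_config is None:
        geometry_config = GeometryConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cells):
        truth = make_ground_truth_cell(
            geometry_config, rng, cell_id=f"cell_{i:04d}",
            photons=max(photon_levels), n_locs=n_locs,
            inner_radius_factor=inner_radius_factor, loc_sigma=loc_sigma)
        inner = truth.cell.elements["storm_inner"]
        outer = truth.cell.elements["storm_outer"]
        r_inner = truth.membrane_radii["storm_inner"]
        score_params = truth.scoring_params

        all_x = np.concatenate([inner.x, outer.x])
        all_y = np.concatenate([inner.y, outer.y])
        _, _, rc_true, _ = geometry.map_to_cellular(truth.true_params, all_x, all_y)

        for photons in photon_levels:
            severity = DEGRADE_SEVERITY.get(photons, 0.3)
            degraded = degrade_binary(truth.cell.binary, rng, severity)
            bf = render_brightfield(truth.true_params, truth.cell.shape, photons, rng)
            guess = initial_coordinate_guess(degraded)

            for method in methods:
                work = Cell(id=truth.id, coords=guess)
                work.add_element("binary", degraded)
                work.add_element("brightfield", bf)
                work.add_element("storm_inner", inner)
                element = {"binary": "binary", "image": "brightfield",
                           "localizations": "storm_inner"}[method]
                try:
                    res = optimize_cell(work, element, method)
                except ValueError as exc:
                    logger.warning("cell %s %s: %s", truth.id, method, exc)
                    continue

                rel = relative_chi2(res.params, score_params, inner)
                _, _, rc_est, _ = geometry.map_to_cellular(res.params, all_x, all_y)
                dev = (rc_est - rc_true) / r_inner
                rows.append({
                    "cell_id": truth.id,
                    "method": method,
                    "photons": photons,
                    "rel_chi2": rel,
                    "r_est": res.params.r,
                    "r_true": truth.true_params.r,
                    "r_membrane_true": r_inner,
                    "D": float(np.mean(np.abs(dev))),
                    "D2": float(np.sqrt(np.mean(dev**2))),
                    "median_abs_rel_dev": float(np.median(np.abs(dev))),
                    "converged": res.converged,
                })
    return pd.DataFrame(rows)
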