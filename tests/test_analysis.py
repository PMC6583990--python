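"""Distributions, multi-cell alignment and the membrane-periodicity pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, pearsonr

from rodcoords import geometry
from rodcoords.analysis import (
    PerimeterTrace,
    align_cells,
    autocorrelate_detrend,
    axial_distribution,
    dominant_periodicity,
    ensemble_radial_distribution,
    perimeter_positions,
)
from rodcoords.cell import Cell, CellCollection, ImageElement, LocalizationTable
from rodcoords.geometry import CoordinateParameters
from rodcoords.synthetic import (
    GeometryConfig,
    frame_shape,
    make_ground_truth_cell,
    render_binary,
    sample_membrane_localizations,
)

PX_NM = 80.0


@pytest.fixture
def rod():
    return CoordinateParameters(a0=9.3, a1=0.0, a2=0.0, xl=8.0, xr=33.0, r=4.5)


def _cell_with(rod, name, element):
    shape = frame_shape(rod)
    cell = Cell(id="c0", coords=rod, elements={"binary": render_binary(rod, shape)})
    cell.add_element(name, element)
    return cell


class TestAxialDistribution:
    def test_uniform_image_gives_flat_radial_profile(self, rod):
        shape = frame_shape(rod)
        img = ImageElement(np.full(shape, 4.0), "fluorescence", "f")
        cell = _cell_with(rod, "f", img)
        prof = axial_distribution(cell, "f", "radial", bins=20)
        occupied = prof.n > 0
        np.testing.assert_allclose(prof.mean[occupied], 4.0)

    def test_membrane_localizations_peak_at_radius(self, rod, rng):
        locs = sample_membrane_localizations(rod, rod.r, 0.25, 5000, rng)
        cell = _cell_with(rod, "storm", locs)
        prof = axial_distribution(cell, "storm", "radial", bins=40, range_=(0, 2 * rod.r))
        mean_rc = np.sum(prof.x * prof.mean) / np.sum(prof.mean)
        assert mean_rc == pytest.approx(rod.r, abs=0.15)

    def test_longitudinal_distribution_matches_counting_oracle(self, rod):
        shape = frame_shape(rod)
        binary = render_binary(rod, shape)
        cell = _cell_with(rod, "img", ImageElement(binary.pixels.astype(float),
                                                   "fluorescence", "img"))
        bins = 10
        prof = axial_distribution(cell, "img", "longitudinal", bins=bins)
        # brute force: per-bin mean over pixels grouped by their lc value
        xx, yy = geometry.pixel_centers(shape)
        _, lc, rc, _ = geometry.map_to_cellular(rod, xx.ravel(), yy.ravel())
        L = geometry.cell_length(rod)
        edges = np.linspace(0, L, bins + 1)
        vals = binary.pixels.astype(float).ravel()
        for b in range(bins):
            sel = (lc >= edges[b]) & (lc < edges[b + 1]) if b < bins - 1 else \
                  (lc >= edges[b]) & (lc <= edges[b + 1])
            if sel.sum():
                assert prof.mean[b] == pytest.approx(vals[sel].mean(), abs=1e-9)

    def test_mass_conservation_for_localizations(self, rod, rng):
        locs = sample_membrane_localizations(rod, rod.r, 0.25, 3000, rng)
        cell = _cell_with(rod, "storm", locs)
        prof = axial_distribution(cell, "storm", "angular", bins=18)
        assert prof.n.sum() == 3000

    def test_unknown_axis_rejected(self, rod, rng):
        locs = sample_membrane_localizations(rod, rod.r, 0.25, 10, rng)
        cell = _cell_with(rod, "storm", locs)
        with pytest.raises(ValueError, match="axis"):
            axial_distribution(cell, "storm", "diagonal")


class TestEnsembleRadialDistribution:
    def _membrane_cell(self, cid, r, rng, n=3000):
        params = CoordinateParameters(a0=r + 4.3, a1=0, a2=0, xl=r + 4, xr=r + 29, r=r)
        locs = sample_membrane_localizations(params, r, 0.25, n, rng)
        shape = frame_shape(params)
        return Cell(id=cid, coords=params,
                    elements={"binary": render_binary(params, shape), "storm": locs})

    def test_identical_cells_have_zero_std(self, rng):
        cell = self._membrane_cell("a", 4.5, np.random.default_rng(0))
        clone = Cell(id="b", coords=cell.coords, elements=cell.elements)
        prof = ensemble_radial_distribution(CellCollection([cell, clone]), "storm", 30)
        np.testing.assert_allclose(prof.std, 0.0, atol=1e-12)

    def test_varying_radii_peak_at_normalized_one(self):
        rng = np.random.default_rng(1)
        cells = CellCollection([
            self._membrane_cell(f"c{i}", r, rng)
            for i, r in enumerate(rng.uniform(3.5, 6.0, 20))])
        prof = ensemble_radial_distribution(cells, "storm", n_bins=40)
        peak_x = prof.x[int(np.argmax(prof.mean))]
        bin_w = prof.x[1] - prof.x[0]
        assert abs(peak_x - 1.0) <= bin_w

    def test_missing_coords_error_names_cell(self):
        bad = Cell(id="nocoords")
        with pytest.raises(ValueError, match="nocoords"):
            ensemble_radial_distribution(CellCollection([bad]), "storm", 10)


class TestAlignCells:
    def test_self_alignment_correlates_with_original(self, rod, rng):
        shape = frame_shape(rod)
        rc = geometry.radial_distance_map(rod, shape)
        img = np.exp(-((rc - rod.r) ** 2) / 2.0) + 0.1
        cell = _cell_with(rod, "f", ImageElement(img, "fluorescence", "f"))
        out = align_cells(CellCollection([cell]), "f", rod, sigma=0.5, shape=shape)
        fg = rc <= rod.r + 2
        r, _ = pearsonr(img[fg], out[fg])
        assert r > 0.95

    def test_mass_conservation(self, rod):
        shape = frame_shape(rod)
        img = np.ones(shape)
        cell = _cell_with(rod, "f", ImageElement(img, "fluorescence", "f"))
        big = (shape[0] + 20, shape[1] + 20)
        model = rod.with_updates(a0=rod.a0 + 10, xl=rod.xl + 10, xr=rod.xr + 10)
        out = align_cells(CellCollection([cell]), "f", model, sigma=0.5, shape=big)
        ratio = out.sum() / img.sum()
        assert 0.99 <= ratio <= 1.0 + 1e-9

    def test_alignment_is_linear_in_the_collection(self, rod, rng):
        shape = frame_shape(rod)
        a = _cell_with(rod, "f", ImageElement(rng.random(shape), "fluorescence", "f"))
        b = Cell(id="c1", coords=rod, elements={
            "binary": a.binary, "f": ImageElement(rng.random(shape), "fluorescence", "f")})
        both = align_cells(CellCollection([a, b]), "f", rod, sigma=0.5, shape=shape)
        sep = (align_cells(CellCollection([a]), "f", rod, sigma=0.5, shape=shape)
               + align_cells(CellCollection([b]), "f", rod, sigma=0.5, shape=shape))
        np.testing.assert_allclose(both, sep, atol=1e-12)

    def test_rescaling_onto_larger_model(self, rng):
        # uniform-interior cell mapped onto a model twice its size stays
        # uniform inside the model outline (edge bins excluded)
        params = CoordinateParameters(a0=8.3, a1=0, a2=0, xl=8, xr=24, r=4)
        shape = frame_shape(params)
        rc = geometry.radial_distance_map(params, shape)
        img = (rc <= params.r).astype(float)
        cell = Cell(id="c", coords=params,
                    elements={"binary": render_binary(params, shape),
                              "f": ImageElement(img, "fluorescence", "f")})
        model = CoordinateParameters(a0=16.3, a1=0, a2=0, xl=16, xr=48, r=8)
        out = align_cells(CellCollection([cell]), "f", model, sigma=1.0,
                          shape=frame_shape(model))
        rc_m = geometry.radial_distance_map(model, frame_shape(model))
        interior = rc_m <= model.r - 2
        assert out[interior].std() / out[interior].mean() < 0.25


class TestPerimeterPositions:
    def test_zero_point_definition(self, rod):
        x, y = geometry.map_to_cartesian(rod, 0.0, rod.r, 0.0)
        locs = LocalizationTable(pd.DataFrame({"x": [x], "y": [y]}))
        trace = perimeter_positions(rod, locs, PX_NM, bin_width_nm=10.0)
        assert np.argmax(trace.values) == 0

    def test_bottom_segment_start_closed_form(self, rod):
        # straight cell: the start of the bottom segment lies at L + pi*r
        L = geometry.cell_length(rod)
        x, y = geometry.map_to_cartesian(rod, L - 1e-9, rod.r, 180.0)
        locs = LocalizationTable(pd.DataFrame({"x": [x], "y": [y]}))
        trace = perimeter_positions(rod, locs, PX_NM, bin_width_nm=10.0)
        pos = trace.positions[int(np.argmax(trace.values))]
        expected = (L + np.pi * rod.r) * PX_NM
        assert pos == pytest.approx(expected, abs=10.0)

    def test_uniform_membrane_gives_flat_trace(self, rod):
        rng = np.random.default_rng(3)
        locs = sample_membrane_localizations(rod, rod.r, 0.25, 10_000, rng)
        trace = perimeter_positions(rod, locs, PX_NM, bin_width_nm=10.0)
        n_full = int(trace.perimeter // trace.bin_width)
        _, p = chisquare(trace.values[:n_full])
        assert p > 0.01


class TestAutocorrelateDetrend:
    def _trace(self, values, bin_width=10.0):
        n = len(values)
        return PerimeterTrace(positions=(np.arange(n) + 0.5) * bin_width,
                              values=np.asarray(values, float),
                              bin_width=bin_width, perimeter=n * bin_width)

    def test_white_noise_has_no_structure(self):
        rng = np.random.default_rng(4)
        sig = autocorrelate_detrend(self._trace(rng.poisson(20, 600)), window_nm=150)
        n = 600
        assert np.max(np.abs(sig[5:] / sig.std())) < 6  # no coherent peaks
        assert abs(sig[1:].mean()) < 4 * sig[1:].std() / np.sqrt(len(sig) - 1)

    def test_cosine_period_is_preserved(self):
        x = np.arange(600) * 10.0
        trace = self._trace(10 + 5 * np.cos(2 * np.pi * x / 56.0))
        sig = autocorrelate_detrend(trace, window_nm=150)
        # first maximum beyond lag zero sits at one period
        lags = np.arange(len(sig)) * 10.0
        search = (lags > 30) & (lags < 85)
        peak = lags[search][np.argmax(sig[search])]
        assert peak == pytest.approx(56.0, abs=10.0)

    def test_linear_trend_is_removed(self):
        x = np.arange(600) * 10.0
        trace = self._trace(10 + 0.01 * x + 5 * np.cos(2 * np.pi * x / 56.0))
        sig = autocorrelate_detrend(trace, window_nm=150)
        assert dominant_periodicity(sig, 10.0) == pytest.approx(56.0, abs=4.0)

    def test_window_below_three_bins_rejected(self):
        with pytest.raises(ValueError):
            autocorrelate_detrend(self._trace(np.ones(100)), window_nm=20.0)


class TestDominantPeriodicity:
    def test_pure_sine(self):
        x = np.arange(512) * 10.0
        sig = np.sin(2 * np.pi * x / 56.0)
        lam = dominant_periodicity(sig, 10.0)
        assert lam == pytest.approx(56.0, abs=56.0**2 / (4 * 512 * 10.0) + 1e-9)

    def test_dominant_component_wins(self):
        x = np.arange(512) * 10.0
        sig = 2 * np.sin(2 * np.pi * x / 56.0) + np.sin(2 * np.pi * x / 30.0)
        assert dominant_periodicity(sig, 10.0) == pytest.approx(56.0, abs=0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dominant_periodicity(np.zeros(100), 10.0)


def modulated_membrane_locs(params, period_nm, n, rng, px_nm=PX_NM, depth=0.9):
    """Membrane localizations whose density is cosine-modulated along the outline."""
    P = geometry.perimeter_length(params)
    s_acc = []
    while sum(len(a) for a in s_acc) < n:
        cand = rng.uniform(0, P, 4 * n)
        keep = rng.random(4 * n) < 0.5 * (1 + depth * np.cos(2 * np.pi * cand * px_nm / period_nm))
        s_acc.append(cand[keep])
    s = np.concatenate(s_acc)[:n]
    lc, phi = geometry.cellular_from_perimeter(params, s)
    rc = np.clip(params.r + rng.normal(0, 0.25, n), 0, None)
    x, y = geometry.map_to_cartesian(params, lc, rc, phi)
    return LocalizationTable(pd.DataFrame({"x": x, "y": y}))


class TestPeriodicityPipeline:
    @pytest.mark.parametrize("period", [40.0, 56.0, 80.0])
    def test_end_to_end_recovery(self, rod, period):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            locs = modulated_membrane_locs(rod, period, 10_000, rng)
            trace = perimeter_positions(rod, locs, PX_NM, bin_width_nm=10.0)
            sig = autocorrelate_detrend(trace, window_nm=150.0)
            lam = dominant_periodicity(sig, trace.bin_width)
            bin_nm = period**2 / (4 * len(sig) * trace.bin_width)
            hits += abs(lam - period) <= bin_nm
        assert hits >= n_seeds - 1
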