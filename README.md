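# rodcoords

Per-cell curvilinear coordinate systems for fluorescence microscopy of
rod-shaped bacteria (E. coli and friends).

Sub-cellular structure in rod-shaped cells is naturally described not by
image (x, y) coordinates but by *cellular* coordinates: how far along the
cell a signal sits, how far from the midline, and whether it is on the
top/bottom membrane or a pole cap. `rodcoords` builds that coordinate
system for every cell, refines it against the data, and uses it to pool
signal from thousands of cells — for pixel images (brightfield,
fluorescence) and for single-molecule localization microscopy (SMLM/STORM)
tables alike.

Each cell is described by a quadratic midline p(x) = a0 + a1·x + a2·x² on
[xl, xr] plus a radius r — six parameters. Every Cartesian point maps to
(l_c, r_c, φ): the arc-length position along the midline, the distance from
it, and an angle that distinguishes top from bottom and parametrises the
hemispherical poles. The closest-point problem is a cubic solved in closed
form, so transforming millions of points is cheap. The parameters are
refined by minimising a χ² objective against a segmentation mask, against
any rotationally isotropic image (via a bootstrapped radial model image),
or against membrane-marker localizations (Σ(r_c − r)²), with the radius
from image data set by the half-maximum point of the radial intensity
profile.

The package is aimed at microscopists who already have segmentation masks
(from any tool) and want quantitative per-cell and ensemble outputs:
radial/longitudinal/angular distributions, many-cell "average cell"
images, membrane periodicity analysis, and a fully synthetic benchmark
that measures how accurate the recovered coordinate systems are.

## Worked example

Generate a synthetic field, extract the cells and refine their coordinate
systems on the membrane localizations:

```python
import numpy as np
from rodcoords import (GeometryConfig, FieldConfig, make_ground_truth_cell,
                       compose_field, extract_cells, optimize_cell)

rng = np.random.default_rng(1)
pool = [make_ground_truth_cell(GeometryConfig(), rng, cell_id=f"t{i}",
                               photons=1000) for i in range(12)]
mask, brightfield, locs, placements = compose_field(pool, FieldConfig(), rng)

cells = extract_cells(mask, channels=[brightfield], localizations=locs)
for cell in cells[:3]:
    res = optimize_cell(cell, "storm", "localizations")
    print(f"{cell.id}: chi2={res.chi2:7.1f}  r={res.params.r:.2f} px")
```

```
cell_00001: chi2=  180.6  r=4.48 px
cell_00002: chi2=  180.3  r=4.87 px
cell_00003: chi2=  179.1  r=4.74 px
```

Each cell's χ² is the summed squared radial deviation of its ~400
localizations from the fitted outline. The field's localization table
combines the inner- and outer-membrane markers (two rings 100 nm apart),
so the fitted radius settles on the mean membrane radius and the χ² floor
is dominated by the ring separation — exactly what the objective promises.

How accurate the recovered coordinate systems are is measured by the
synthetic benchmark, which scores each fit against the generating
parameters:

```python
from rodcoords import run_benchmark

df = run_benchmark(methods=("localizations",), photon_levels=(1000,),
                   n_cells=20, seed=1)
r_err = (df.r_est - df.r_membrane_true).abs() / df.r_membrane_true
print("median relative chi2:", round(df.rel_chi2.median(), 3))
print("median radius error: %.2f%%" % (100 * r_err.median()))
```

```
median relative chi2: 0.976
median radius error: 0.31%
```

The relative χ² divides each cell's fitted localization χ² by its value
under the ground-truth coordinate system, so 1.0 is a perfect fit; values
just below 1 are expected because a finite sample can be fitted slightly
better than the parameters that generated it. The radius error compares
the fitted radius with the true mean radius of the membrane marker.

The same pipeline is available from the shell:

```sh
rodcoords synth --out-dir field --seed 1
rodcoords extract --mask field/mask.tif --locs field/localizations.csv --out cells.h5
rodcoords optimize --cells cells.h5 --element storm --method storm --out cells_opt.h5
rodcoords profile --cells cells_opt.h5 --element storm --out radial.tsv
```

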