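"""Survey trajectory geometry and the image-coverage raster it produces.

Plans a Reef Record spiral and a Mow-the-lawn plot, prints their closed-form
geometry, then rasterizes image footprints along a lawnmower path at
0.5 cm/pixel and summarises coverage per 2 x 2 m quadrat.
"""

import numpy as np

from reefrugosity import (
    DIVER_RIG_CAMERA,
    QuadratGrid,
    footprint,
    gen_trajectory_views,
    lawnmower_plan,
    quadrat_coverage,
    rasterize_coverage,
    spiral_plan,
)

w, h, gsd = footprint(DIVER_RIG_CAMERA, 2.0)
print(f"camera footprint at 2 m range: {w:.2f} x {h:.2f} m, GSD {gsd:.2f} mm/px")

spiral = spiral_plan(drum_diameter=0.16, tether_length=6.0)
print(f"Reef Record spiral: track spacing {spiral.track_spacing:.3f} m, "
      f"plot diameter {spiral.plot_diameter:.1f} m "
      f"({spiral.swept_area:.0f} m^2 swept)")

mow = lawnmower_plan(line_length=8.0, n_passes=8, cross_spacing=0.5)
print(f"Mow-the-lawn: {mow.n_passes} passes x {mow.line_length:.0f} m, "
      f"area {mow.area:.0f} m^2")

views = gen_trajectory_views(mow, DIVER_RIG_CAMERA, range_m=2.0, image_spacing=0.5)
raster = rasterize_coverage(views, extent=(1.0, 0.0, 7.0, 3.5), cell_size=0.01)
grid = QuadratGrid((1.0, 0.0), 1, 3, 2.0)
print(f"\n{len(views)} image footprints rasterized; "
      f"counts {raster.counts.min()}..{raster.counts.max()}")
for m in quadrat_coverage(raster, grid):
    print(f"  quadrat {m.quadrat_id}: avg coverage {m.avg_coverage:.1f} images, "
          f"variation {m.coverage_variation:.2f}")
print("\nAverage coverage is the mean number of images seeing each point;")
print("coverage variation (sd of that count) flags uneven imaging.")
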