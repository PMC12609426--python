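"""Footprint preprocessing: QC screen, cross-band combination, smoothing.

Samples one day of striped two-band footprints with band noise, applies
the three screening steps, and measures how much each step suppresses the
noise relative to the known per-cell truth.
"""

import datetime as dt

import numpy as np

from sifmstws import WorldConfig, generate_world, sample_footprints
from sifmstws.preprocess import combine_bands, knn_smooth, qc_filter
from sifmstws.synthetic import true_sif_raster

sigma = 0.1
world = generate_world(WorldConfig(sigma_band=sigma, sigma_refl=0.0), seed=2)
date = dt.date(2022, 8, 13)

fps = sample_footprints(world, date, seed=2)
print(f"{len(fps)} footprints in the swath on {date}, "
      f"{(fps.qc_flag != 0).sum()} with failing QC")

fps = qc_filter(fps, allowed_flags=(0,))
fps = fps.assign(sif_daily=combine_bands(fps["sif_757"], fps["sif_771"]))
smoothed, dropped = knn_smooth(fps, k=5, max_radius=0.1)
print(f"{len(dropped)} footprints dropped for thin neighborhoods")

truth = true_sif_raster(world, date).values
row, col = world.geom.cell_of(smoothed["lat"].to_numpy(), smoothed["lon"].to_numpy())
cell_truth = truth[row, col]

v_raw = np.var(smoothed["sif_757"] - cell_truth)
v_combined = np.var(smoothed["sif_daily"] - cell_truth)
v_smoothed = np.var(smoothed["sif_smoothed"] - cell_truth)
print(f"\nresidual variance vs truth (band noise sigma^2 = {sigma**2:.4f}):")
print(f"  raw 757 nm band    : {v_raw:.5f}  (ratio {v_raw / sigma**2:.3f})")
print(f"  cross-band combined: {v_combined:.5f}  (ratio {v_combined / sigma**2:.3f}, "
      "analytic 0.8125)")
print(f"  5-NN smoothed      : {v_smoothed:.5f}  (ratio {v_smoothed / sigma**2:.3f}; "
      "the i.i.d. floor is 0.8125/5 = 0.163, approached when every\n"
      "    neighborhood stays within one cell — QC gaps pull in neighbors "
      "from adjacent cells, whose truth differs)")
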