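"""Detect two tumors in a noisy acquisition with IC-DMAS.

The two-tumor phantom adds measurement noise at ~20 dB per-sample SNR on the
tumor response.  The iterative correction cleans the map enough that the two
strongest well-separated maxima each land on a distinct tumor.
"""

from dataclasses import replace

import numpy as np

import mwibeam as mw

geom = mw.build_cylindrical_array(4, 4, 0.1, 10, 36.0)
freqs = mw.default_frequency_grid(101)

phantom = mw.make_phantom("C", seed=7)
sigma = 0.1 * mw.scatterer_signal_rms(phantom, geom, freqs)
phantom = replace(phantom, noise_sigma=sigma)
truths = np.asarray([p for p, _ in phantom.scatterers])
print(f"two tumors at {np.round(truths[:, :2] * 1e3, 1).tolist()} mm; "
      f"noise sigma {sigma:.2f} per complex sample")

td = mw.preprocess_dataset(mw.simulate_scatter_dataset(phantom, geom, freqs))
grid = mw.build_imaging_grid(0.08, 0.002, array_radius=0.1)
delays = mw.compute_delay_table(mw.compute_distance_tables(grid, geom))

for name, m in (("DMAS", mw.dmas_image(td, delays, grid)),
                ("IC-DMAS", mw.icdmas_reconstruct(td, delays, grid)[0])):
    res = mw.localization_error(m, truths, min_separation=0.012)
    errs = ", ".join("missed" if np.isnan(e) else f"{e*1e3:.1f} mm"
                     for e in res.errors)
    print(f"{name:8s} detections {res.n_detections}, per-tumor errors: {errs}")
print("Each detection is the strongest local maximum at least 12 mm from any")
print("stronger one; errors are distances to the matched true positions.")
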