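"""Reconstruct a single-tumor phantom with DAS, DMAS and IC-DMAS.

Simulates a desk-scale multistatic acquisition (4 Tx x 4 Rx antennas on a
10 cm ring, 10 rotation positions, 101 frequency points over 2.7-8 GHz) of a
phantom with a skin ring, a retarding interior and one tumor, then runs the
full chain: rotation subtraction, time synthesis, beamforming, iterative
delay correction, metrics.
"""

import numpy as np

import mwibeam as mw

geom = mw.build_cylindrical_array(n_tx=4, n_rx=4, radius=0.1, n_phi=10,
                                  phi_step=36.0)
freqs = mw.default_frequency_grid(101)
phantom = mw.make_phantom("B")          # skin ring + one tumor at (8.5, 8.5) mm
truth = np.asarray(phantom.scatterers[0][0])

dataset = mw.simulate_scatter_dataset(phantom, geom, freqs)
td = mw.preprocess_dataset(dataset)     # odd/even split, subtract, IFFT

grid = mw.build_imaging_grid(extent=0.08, spacing=0.002, array_radius=0.1)
delays = mw.compute_delay_table(mw.compute_distance_tables(grid, geom))

maps = {"DAS": mw.das_image(td, delays, grid),
        "DMAS": mw.dmas_image(td, delays, grid)}
maps["IC-DMAS"], state = mw.icdmas_reconstruct(td, delays, grid)

mask = mw.tumor_mask_spheres(grid, [truth])
print(f"true tumor position: ({truth[0]*1e3:.1f}, {truth[1]*1e3:.1f}) mm")
for name, m in maps.items():
    peak = grid.points[np.argmax(m.values)]
    err = np.linalg.norm(peak - truth) * 1e3
    pk = mw.smr(m, mask, mode="peak").smr_db
    rm = mw.smr(m, mask, mode="region_mean").smr_db
    print(f"{name:8s} argmax ({peak[0]*1e3:5.1f}, {peak[1]*1e3:5.1f}) mm, "
          f"error {err:4.1f} mm, SMR peak {pk:5.2f} dB, region-mean {rm:5.2f} dB")
print(f"IC-DMAS ran {state.n} iterations; "
      f"E history: {['%.2e' % e for e in state.e_history]}")
print("Higher SMR = brighter tumor relative to background clutter; the")
print("iterative correction recovers the carrier-phase loss caused by tissue")
print("retardation, so both SMR variants rise and the peak moves toward truth.")
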