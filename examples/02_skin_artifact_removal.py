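"""Rotation subtraction: the skin reflection cancels, the tumor survives.

The air-skin interface reflection is orders of magnitude stronger than the
tumor response but identical at every rotation position, so differencing
odd and even rotation frames removes it exactly while the tumor response,
which moves with the rotating array, persists.
"""

import numpy as np

import mwibeam as mw

geom = mw.build_cylindrical_array(4, 4, 0.1, 10, 36.0)
freqs = mw.default_frequency_grid(101)

skin_only = mw.make_phantom("A")
ds = mw.simulate_scatter_dataset(skin_only, geom, freqs)
residual = mw.rotation_subtract(*mw.split_even_odd(ds))
print(f"skin-only phantom: raw |S| up to {np.abs(ds.s).max():.3g}, "
      f"residual after rotation subtraction {np.abs(residual).max():.3g}")

with_tumor = mw.make_phantom("B")
ds_b = mw.simulate_scatter_dataset(with_tumor, geom, freqs)
diff_b = mw.rotation_subtract(*mw.split_even_odd(ds_b))
ratio = np.abs(ds_b.s).max() / np.abs(diff_b).max()
print(f"skin+tumor phantom: raw |S| up to {np.abs(ds_b.s).max():.3g}, "
      f"differenced |S| up to {np.abs(diff_b).max():.3g} "
      f"(skin dominated the raw data by ~{ratio:.0f}x)")
print("The residual cube now carries only the tumor response (plus its")
print("sign-flipped replica at one rotation step), ready for beamforming.")
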