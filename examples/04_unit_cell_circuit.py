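"""Lumped LC circuit model of the metasurface unit cell.

The complementary split-ring patch that loads the imaging antennas resonates
like a passive LC circuit: the split gap acts as a parallel-plate capacitor,
the metal loop as a microstrip inductor.  These closed forms let one size a
cell for a target resonance before any full-wave simulation.
"""

import mwibeam as mw

# split gap: 0.25 mm x 0.25 mm area, 0.25 mm length, substrate eps_r 2.2
C = mw.split_capacitance(eps_r=2.2, A=0.25e-3 * 0.25e-3, d=0.25e-3)
print(f"split capacitance: {C*1e15:.2f} fF")

# loop modeled as a 4 mm microstrip, 0.25 mm wide, 0.035 mm copper,
# on a 1.57 mm thick, 5 mm wide substrate
kg = mw.microstrip_kg(w_sub_mm=1.57, h_sub_mm=5.0)
L = mw.microstrip_inductance(4.0, 0.25, 0.035, kg=kg)
print(f"ground correction K_g = {kg:.3f}; loop inductance: {L:.3f} nH")

f = mw.resonant_frequency(L * 1e-9, C)
print(f"predicted LC resonance: {f/1e9:.2f} GHz")

# inverting the resonance formula: what LC product puts the peak at 7.2 GHz?
import numpy as np
lc = 1.0 / (np.pi * 7.2e9) ** 2
print(f"a 7.2 GHz transmission peak pins L*C at {lc:.3e} H*F "
      f"(e.g. {lc/C*1e9:.2f} nH with the split capacitance above)")
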