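"""Milk-energy cost of a heat-stress growth deficit.

Converts a body-weight difference into the daily milk energy needed to
produce it, using the allometric requirement 226 * W^0.837 kcal/d.
"""

import deerheat as dh

for w in (1.0, 1.2, 10.0, 45.0):
    kcal, kj = dh.milk_energy(w)
    print(f"W = {w:5.1f} kg  ->  {kcal:8.1f} kcal/d  =  {kj:8.1f} kJ/d")

kcal_lo, _ = dh.milk_energy(45.0)
kcal_hi, _ = dh.milk_energy(46.2)
print(f"\nproducing the extra 1.2 kg at weaning costs about "
      f"{kcal_hi - kcal_lo:.0f} kcal/d in maintenance terms")
# The sub-linear exponent (0.837) means each extra kilogram of calf is
# cheaper, per kilogram, than the previous one.
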