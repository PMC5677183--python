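"""Front-end electrical model: skin current, current density, transfer map.

The wearable drives a constant current through the skin via an 825 kΩ
reference resistor from a 3.3 V rail and reads skin conductance off the
output voltage.  This prints the safety-relevant constants and shows the
voltage<->conductance maps are inverses.
"""

from edaflow import SensorConfig, current_density, skin_conductance, skin_current
from edaflow.acquisition import conductance_to_voltage

cfg = SensorConfig()
i = skin_current(cfg)
density, safe = current_density(cfg)

print(f"skin current        : {i * 1e6:.3f} uA")
print(f"current density     : {density:.3f} uA/cm^2 (limit 10, safe={safe})")
# a typical palm conductance of 5 uS and its round trip through the sensor
g = 5.0
v = conductance_to_voltage(g, cfg)
print(f"5 uS reads as       : {v:.4f} V at the front-end output")
print(f"inverse map returns : {skin_conductance(v, cfg):.6f} uS")
# The current density sits a factor ~4 under the sweat-duct damage limit,
# which is the design point of the reference resistor choice.
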