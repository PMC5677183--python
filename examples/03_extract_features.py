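"""Extract the 21 SCR features from each 70 s condition segment.

Continues from the single-participant simulation: cuts the phasic series
into its calm and distress segments and prints the features side by side.
Distress segments carry more and larger responses, so the amplitude
features (MSC, INSC, RMSC) and band powers come out higher there.
"""

from edaflow import SensorConfig, decompose, extract_all, make_schedule, simulate_recording
from edaflow.features import Segment
from edaflow.preprocessing import apply_filter, design_lowpass
from edaflow.synthetic import EffectModel, ProtocolConfig, recording_to_conductance, segment_bounds

protocol = ProtocolConfig()
sensor = SensorConfig()
schedule, bounds = make_schedule(protocol, seed=2)
raw, _ = simulate_recording(schedule, EffectModel(), sensor,
                            duration_s=protocol.total_duration_s, seed=2)
filtered = apply_filter(recording_to_conductance(raw, sensor), design_lowpass())
dec = decompose(filtered, schedule)

vectors = {}
for cond in ("calm", "distress"):
    seg = Segment(dec.phasic[segment_bounds(bounds, cond, sensor.fs)],
                  fs=sensor.fs, condition=cond)
    vectors[cond] = extract_all(seg).as_dict()

print(f"{'feature':>8} {'calm':>12} {'distress':>12}")
for name in vectors["calm"]:
    print(f"{name:>8} {vectors['calm'][name]:>12.5g} {vectors['distress'][name]:>12.5g}")
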