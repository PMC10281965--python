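"""Extract the three screening features from a single pen recording.

Simulates one participant tracing the spiral, then computes drawing
time (DT, seconds), average stylus pressure (AP, device units, range
0-4.166667) and SPARC smoothness of the pressure signal (SP, negative;
closer to zero = smoother pressure control).
"""

from pentrace import SubjectDraw, extract_features, simulate_recording
from pentrace.shapes import default_template

draw = SubjectDraw(duration=9.5, base_pressure=1.8,
                   pressure_drift_amp=0.2, roughness_amp=0.45,
                   roughness_band=(2.5, 13.0), n_components=12,
                   tremor_amp=1.5, seed=7)
rec = simulate_recording(default_template("spiral"), draw,
                         participant_id="demo")

fv = extract_features(rec)
print(f"recording: {rec.n_samples} samples at {rec.nominal_rate:.0f} Hz")
print(f"DT = {fv.DT:.2f} s      (time from first to last pen contact)")
print(f"AP = {fv.AP:.3f} units (time-averaged stylus pressure)")
print(f"SP = {fv.SP:.1f}       (spectral arc length of the pressure "
      f"signal; more negative = rougher)")
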