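"""Render a simulated acquisition as a dynamic image stack.

Builds the transverse imaging plane (aorta between the two myocardial
cylinders), paints each ROI's signal curve into per-heartbeat frames with
pixel noise, extracts the curves back from the ROI masks, and writes the
stack as 16-bit PNGs with a JSON sidecar under scratch/.
"""

from pathlib import Path

import numpy as np

import perftwin as pt
from perftwin.experiments import calibrate_signal_model, simulate_signal_curves

model = calibrate_signal_model()
seq = pt.SequenceParams()
config = pt.reference_circuit(3.0, perfusion_right=10.0, perfusion_left=2.5)
sig = simulate_signal_curves(config, pt.InjectionProtocol(0.01), seq, model,
                             duration_s=120.0)

stack = pt.render_image_series(sig, noise_sigma=14.0, seed=1)
print(f"rendered {len(stack.frames)} frames of {stack.frames.shape[1:]} px "
      f"({stack.pixel_size_mm} mm pixels)")

for roi in ("aorta", "myo_right", "myo_left"):
    curve = pt.extract_roi(stack, roi)
    n_pix = int(stack.roi_map[roi].sum())
    err = np.std(curve.values - sig[roi].values)
    print(f"  {roi:>9}: {n_pix:4d} px, peak {pt.peak_si(curve):7.0f} au, "
          f"extraction noise sd {err:.1f} au")

out = Path("scratch/example_stack")
pt.write_stack(stack, out)
print(f"wrote PNG frames + sidecar to {out}/")
print()
print("Averaging over the mask suppresses pixel noise by ~1/sqrt(n_pixels);")
print("the right compartment (10 mL/mL/min) peaks earlier than the left (2.5).")
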