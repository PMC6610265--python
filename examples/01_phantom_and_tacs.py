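"""Build a synthetic dynamic FET-PET acquisition and extract lesion TACs.

Creates a brain phantom with one lesion following early-peak kinetics, and
prints the frame schedule, the lesion's time-activity curve, its time to
peak and its pattern labels.
"""

import numpy as np

from fetdyn import phantom
from fetdyn.core import ImageGeometry
from fetdyn.kinetics import classify_pattern_2, classify_pattern_3, extract_tac, time_to_peak

geometry = ImageGeometry((32, 48, 48), (2.0, 2.0, 2.0))
cz, cy, cx = geometry.center_world
spec = phantom.PhantomSpec(
    geometry=geometry,
    brain=phantom.brain_structure(geometry, amplitude=1.0),
    structures=[
        phantom.Structure(
            "lesion",
            phantom.Sphere((cz, cy, cx - 16), 7.0),
            phantom.KineticModel("gamma_variate", amplitude=3.0, tp=8.0, alpha=2.0),
        )
    ],
    noise_sigma0=0.05,
    seed=11,
)
img, truth, labels = phantom.build_phantom(spec)

print("frame ends (min):", img.schedule.ends)
tac = extract_tac(img, truth["lesion"])
print("lesion TAC (mean SUV):", np.round(tac.mean_suv, 3))
frame, minute = time_to_peak(tac)
print(f"time to peak: frame {frame} ({minute:g} min after injection)")
print("2-class pattern:", classify_pattern_2(tac))
print("3-class pattern:", classify_pattern_3(tac), "| generator truth:", labels["lesion"])
# An early peak (within 20 min) followed by a clear descent marks the most
# aggressive uptake pattern in the clinical categorisation.
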