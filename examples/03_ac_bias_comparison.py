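"""Compare TAC evaluation across simulated attenuation-correction methods.

Applies three multiplicative bias fields (uniform, radial, smooth random) to
a reference acquisition — the image-space signature of reconstructing the
same dynamic data with different AC maps — reruns the full per-lesion
evaluation, and prints the change table against the reference.
"""

import numpy as np

from fetdyn import comparison, phantom
from fetdyn.core import ImageGeometry, RegionMask
from fetdyn.experiments import standard_bias_suite

geometry = ImageGeometry((32, 48, 48), (2.0, 2.0, 2.0))
cz, cy, cx = geometry.center_world
spec = phantom.heterogeneous_lesion_scene(
    geometry,
    core_model=phantom.KineticModel("gamma_variate", amplitude=3.0, tp=26.0, alpha=1.8),
    rim_model=phantom.KineticModel("increasing", amplitude=2.9, tau=8.0),
    seed=4,
)
img, truth, _ = phantom.build_phantom(spec)
hint = RegionMask(np.vstack([truth["core"].voxels, truth["rim"].voxels]))
envelope = phantom.brain_envelope(spec)
manual_center = spec.structures[0].shape.center

ref = comparison.analyze_lesion(
    img, hint, manual_sphere_center=manual_center, brain_mask=envelope
)
records = []
for label, bias_spec in standard_bias_suite(seed=4).items():
    biased = phantom.apply_bias(img, phantom.make_bias_field(bias_spec, geometry))
    test = comparison.analyze_lesion(
        biased, hint, manual_sphere_center=manual_center, brain_mask=envelope
    )
    records += comparison.compare_to_reference(ref, test, "lesion1", label)

table = comparison.aggregate(records)
cols = ["definition", "ac_method", "pattern3_change_pct", "ttp_summary",
        "tbr_rel_diff_mean", "volume_rel_diff_mean"]
print(table[cols].to_string(index=False))
# Pattern changes, when they occur, come from the bias moving the segmented
# region between lesion compartments; the fixed manual sphere (SPHERE_MANUAL)
# is immune because its location and voxel set never change.
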