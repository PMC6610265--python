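# Methods

## Data model

A dynamic acquisition is a 4D SUV array indexed `(frame, z, y, x)` with an
axis-aligned geometry (shape, spacing, origin in mm; z axial) and a frame
schedule — a gap-free partition of the 40-min acquisition starting at
injection time 0.  The standard schedule is 2×2, 4×4 and 2×10-min frames
(ends at 2, 4, 8, 12, 16, 20, 30, 40 min).  Images are stored as 4D NIfTI
(float32) with a YAML frame-schedule sidecar; masks as 0/1 3D NIfTI.

The "summed" late image is implemented as the duration-weighted *mean* SUV
over the window, not a raw sum: SUV is intensive, the mean preserves its
units, and every relative threshold (90 % of maximum) is invariant to the
choice.  Windows must be unions of whole frames — frames are the atomic unit
of reconstructed data — so a window such as 21–40 min is snapped to the
nearest frame edges (20–40) with a logged warning.

## Kinetic models and the phantom

Tissue kinetics come in three analytic families (`C(t)` in SUV, `t` in min):

* increasing: `C(t) = A (1 − exp(−t/τ))` — saturating uptake, the
  lower-grade pattern; τ ~ 5–20 min is typical;
* gamma-variate: `C(t) = A (t/tp)^α exp(α(1 − t/tp))`, unique maximum `A` at
  `t = tp`; early `tp` (≤ 15 min) gives the aggressive early-peak shape,
  late `tp` (~25 min) the plateau shape; a small `α` with `tp ≈ 2` min
  mimics a blood-pool curve that spikes early yet retains late activity;
* constant: background tissue.

A reconstructed frame measures the *time average* of `C` over the frame, so
voxel values are frame averages computed by adaptive quadrature (relative
tolerance 1e−8; verified in tests against a 10,000-point trapezoid sum).

Scenes are declarative: a brain ellipsoid plus spheres / cylinders /
ellipsoid shells, each filled with one kinetic model.  Overlaps are an error
unless an explicit priority order is given (used deliberately for
two-compartment lesions and the lesion-vessel scene).  Default geometry is
96×96×64 voxels at 2 mm isotropic — brain-scale but fast; the simulation
studies use slightly smaller grids (e.g. 48×48×32 at 2 mm) chosen so a full
cohort runs in seconds to a couple of minutes on one CPU.

Noise is additive zero-mean Gaussian on SUV with per-frame standard
deviation `σ0 / sqrt(Δt/10 min)` — shorter frames collect fewer counts —
which emulates frame-wise count statistics without modelling the sinogram
domain (reconstruction is out of scope).  A lesion-mean TAC over `n` voxels
therefore has per-frame noise `σ0 / sqrt(Δt/10) / sqrt(n)`; the TAC-level
simulator uses this directly with `n = 115` (a 6-mm-radius sphere at 2 mm
spacing) as the default lesion size.

AC error is a single strictly positive 3D field multiplying every frame —
the image-space consequence of correcting all frames with the same imperfect
attenuation map.  Three families are provided: uniform scale; radial
(linear from a centre scale to an edge scale at the bounding sphere,
emulating the centre-vs-skull gradient of missing bone); and smooth random
(Gaussian-filtered white noise rescaled to 1 ± amplitude).  Magnitudes
default to ≤ 10 %, the scale reported in the MR-AC literature; no published
per-method magnitudes exist, so these are stand-ins, configurable per run.

## Segmentation

Region growing takes the connected component of `{SUV ≥ threshold}`
containing the seed, with 26-neighbour connectivity in 3D and 8-neighbour in
2D (matching common clinical implementations; configurable).  Thresholds are
inclusive.  The seed is the maximum-uptake voxel, searched within a
user-supplied coarse tumour hint when given (stand-in for the reader's
visual lesion selection), otherwise the whole volume; ties break to the
lexicographically smallest `(z, y, x)` index.  Sphere VOIs include every
voxel whose *centre* lies within the radius — deterministic, no partial
volumes — so the voxelised ~2 mL fixed VOI converges to the analytic
`(4/3)πr³` as spacing shrinks.  Contralateral background placement defaults,
in synthetic mode, to the lesion maximum mirrored across the mid-sagittal
plane; with real data the centre must be supplied.

A segmentation is excluded as implausible when its volume exceeds 50 mL or,
given a brain mask, when more than 20 % of its voxels fall outside the
brain.  Both limits are operationalisations of "the segmentation flooded
into the neck/viscerocranium" — the verbal clinical exclusion rule gives no
numbers — and are configurable and logged.

## Pattern categorisation

The clinical rules are verbal ("constantly increasing", "plateau or slight
descent", "continuous descent"); two fractions make them operational, both
configurable and logged:

* `descent_fraction = 0.10`: the relative drop from peak to last frame,
  `d = (max − last)/max`, that counts as a true descent;
* `increase_tolerance = 0.025`: how close the last frame must stay to the
  maximum for a late-peaking, still-rising curve to count as increasing.

2-class: *decreasing* iff TTP ≤ 20 min (inclusive) and `d > 0.10`;
everything else *increasing*.  3-class: *decreasing* as above; *increasing*
iff the maximum is in the final frame, or the peak is late, the last frame is
within 2.5 % of the maximum and the curve still rises into it; otherwise
*plateau*.  A late peak followed by a strong descent has no class in the
clinical 3-class scheme; it is assigned plateau with a logged warning.
2-class *decreasing* implies 3-class *decreasing* by construction.

Family-typical parameter ranges for recovery studies need one care: with the
8-frame schedule, a gamma-variate peaking past ~30 min frame-averages to a
monotone non-decreasing curve — indistinguishable from a constantly
increasing one — and steep gamma-variates with `tp ≤ 23` min can
frame-average their peak onto the 20-min frame end, i.e. into early-peak
territory.  The plateau family is therefore sampled with `tp ∈ [24, 29]` min
and `α ∈ [1.2, 2.2]`; decreasing with `tp ∈ [5, 15]`, `α ∈ [1.5, 3]`;
increasing with `τ ∈ [5, 20]` min.

## Cross-AC comparison

Per lesion and reconstruction the harness computes all five definitions,
applies the plausibility check, extracts TACs and reports pattern labels,
TTP (frame index and minutes), TBR (30–40-min frame over background) and
volume.  The reference method is a labelled input (CT-based AC in the study
design), never inferred.  Changes are reported per definition as label
flips, signed TTP frame shifts, and relative TBR/volume differences
`(test − ref)/ref`; aggregation gives percent-changed (rounded to whole
percent, raw fractions kept alongside) and TTP summaries formatted
`changed/evaluated (|shift| multiset)`.

## What the simulations show — and what they cannot

The phantom reproduces the *mechanisms*: exact fixed-region invariance under
time-independent bias (a scaling cannot change a TAC's shape), segmentation-
mediated pattern changes for threshold definitions when lesions are
heterogeneous, threshold flooding for low-uptake lesions, and vessel
contamination.  It does not reproduce the clinical cohort: real patient
anatomy, reconstruction point-spread, motion, scatter and true per-method AC
maps are absent, so simulated change *rates* characterise the pipeline under
the stated generator conditions, not the clinical frequencies.  The
heterogeneous-lesion cohort draws rim amplitudes within 85–100 % of the core
so the two compartments compete for the uptake maximum — the regime in which
AC bias can move the segmentation; cohorts of well-separated compartments
would show no changes at all.

## Numerical choices and degenerate inputs

Quadrature: `scipy.integrate.quad`, relative tolerance 1e−8.  TTP ties break
to the earliest frame.  All-NaN frames are rejected at load; schedules must
be contiguous and start at 0.  Empty masks and seeds below threshold raise
typed errors that the harness converts into exclusion records.  Bias fields
must be strictly positive.  Randomness is always an explicit
`numpy.random.Generator` seeded from the caller.

## Known limitations

* No projection/reconstruction simulation; bias is applied in image space.
* Bias magnitudes per AC method are stand-ins, not calibrated values.
* The gamma-variate family cannot represent a late peak with a strong
  descent; such TACs only arise as mixtures and are flagged when classified.
* The mid-sagittal mirror background assumes lateralised lesions; midline
  lesions need an explicit background centre.
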