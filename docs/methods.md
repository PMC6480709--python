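# Methods

This note documents the models, conventions and numerical choices behind
`dynaverify`, in the order the pipeline uses them.

## Dynalog model and file dialects

A dynalog field is the merged A/B pair of per-carriage controller logs:
one record per tick (50 ms Clinac, 20 ms TrueBeam) carrying beam status,
beam hold-off, segment counter, gantry, jaws, cumulative dose fraction and
the expected/actual position of every leaf of that carriage. In memory,
positions are float centimetres at the isocenter plane; leaf-error
statistics are reported in millimetres.

No single published column layout covers the text dialects found in
practice, so the on-disk format is parameterised by a dialect descriptor
(delimiter, integer position unit, gantry and dose scaling). Two dialects
ship: `clinac` (fixed point — positions in hundredths of a millimetre,
gantry in tenths of a degree, dose counter with full scale 25000) and
`native` (plain floats; exact round trip of any value). Quantising a bank
to a dialect's file resolution makes write→parse an exact identity; the
synthetic generator emits positions already quantised to 0.01 mm, which is
also the resolution real controllers log.

**Sign convention.** Every leaf coordinate increases in its opening
direction: a leaf pair's aperture spans [−pos_B, +pos_A] and its width is
pos_A + pos_B. Consequently a *positive* error ε = P_e − P_a always means
the actual leaf encroaches on the aperture, and subtracting a positive
quantity from any position shrinks the field. This is what makes the
absolute-value magnification mode well defined. On DICOM export the
convention maps to the standard MLCX layout (bank 1 = −pos_B, bank 2 =
+pos_A).

Merging checks that the two banks agree on timestamps and segment exactly,
and on gantry (0.2°), jaws (0.005 cm) and dose fraction (10⁻³) within
tolerance; shared scalars are then taken from bank A.

## Reconstruction

Control points are selected records; MLC positions come from the expected
or the actual column. The first and last records are always included so
the beam has well-defined weight endpoints (the sampling rules themselves
do not define endpoint handling; this is our choice). Cumulative meterset
weights are the recorded dose fractions shifted by the first selected
value and scaled so the last is 1 — the shift is required for a
well-formed beam whose first control point has weight 0.

* **UR** — every `interval/tick`-th record, interval a multiple of the
  tick; at the minimum interval all records are control points.
* **PSR** — the record at which the segment counter first takes each new
  value. When every transition appears once, the reconstruction has
  exactly the original plan's control-point count.
* **PSR-ED** — PSR plus every record where some leaf's |ε| exceeds the
  tolerance *t*. Two boundary behaviours are fixed by the method's
  definition: *t* = 0 selects all records, and *t* ≥ MLE reduces exactly
  to PSR. Both hold simultaneously only with a strict comparison
  (|ε| > t) plus the special case at zero, which is what is implemented.

Beam-hold records deliver no dose; they are never selected by PSR/PSR-ED
(a transition landing on a hold is deferred to the next non-hold record)
and produce a logged warning if UR selects them. Records with unchanged
dose fraction yield zero-weight segments, which are retained — they are
harmless to any dose computation.

## Error magnification

With f = Σ/MLE computed once per field (MLE over both banks jointly), the
altered actual positions are P'_a = P_e − f·ε (signed) or P_e − f·|ε|
(absolute). Errors at or below the 0.01 mm floor are not rescaled; in
absolute mode their sign is still folded (P'_a = P_e − |ε|) so the mode's
defining guarantee — no leaf ever widens its aperture — holds exactly
rather than only to within the floor. The post-condition MLE(result) = Σ
follows from f·MLE = Σ and holds to floating precision whenever no
physical clipping triggers.

Because linear scaling can produce impossible positions at large Σ,
magnified positions are clipped to the leaf travel range (±20 cm) and
colliding pairs (gap < 0) are pushed back to zero gap symmetrically; both
events are counted and logged. The standard sweep Σ ∈ {2, 3, 4, 5, 10,
30} mm ships as the default sensitivity grid.

## Dose comparison

**DVH / PA.** Cumulative DVHs use a fixed bin width (default: reference
maximum over the body mask divided by 1000) and relative volumes (% of
structure volume), so PA is comparable across structures of different
size. PA = 100·[1 − δ_A/max(A₁,A₂)] with δ_A the bin-wise absolute area
difference. PA is symmetric, lies in [0, 100], equals 100 iff the
histograms coincide bin-wise, and equals 0 against an empty histogram.

**Gamma.** Global normalisation to the reference maximum (over the body
mask when called through `compare`), low-dose cutoff 10% by default. The
evaluated distribution is tri-linearly interpolated on a sub-grid of step
dta/10 within radius 3·dta (both configurable). The search visits offsets
shell by shell in increasing distance and stops a voxel as soon as the
distance term alone exceeds its current best γ — an exact early
termination, verified in the tests against exhaustive enumeration over
the identical offset set. Outside-grid samples clamp to the nearest voxel.

**α/Δ.** The per-voxel systematic deviation is estimated by quadrature
subtraction, s = √max(0, d² − (σ_ref² + σ_eval²)), and α(Δ) is the
fraction of voxels (inside the body, above 30% of the reference maximum)
with s ≥ Δ% of the reference maximum. This estimator follows the standard
reporting convention for separating systematic differences from Monte
Carlo noise, but it is a deliberate simplification: it subtracts the
declared variances voxel-by-voxel rather than fitting the joint deviation
distribution. Pure noise at the declared σ is strongly suppressed but not
annihilated — at Δ = 1% and σ = 0.4% of maximum, α ≈ 4%; larger σ relative
to Δ leaks proportionally more. The threshold-style results it produces
(step response to a constant offset, monotone decrease in Δ) are exact.

## Toy dose engine

Per control-point interval: the mean aperture is rendered as a binary
fluence on the isocenter plane (0.25 cm pixels, strict aperture bounds so
a zero-width pair exposes nothing), blurred with a Gaussian penumbra
(σ = 0.3 cm), and every voxel picks up the fluence at its divergent
projection (SAD = 100 cm) attenuated exponentially with depth
(μ = 0.04 cm⁻¹, 10 cm buildup offset), weighted by the interval's meterset
fraction. Optional seeded Gaussian noise (relative σ, with a floor of 10%
of maximum) emulates Monte Carlo uncertainty and populates the grid's σ
field for α/Δ studies.

The engine is linear in meterset, additive over beams, rotation-consistent
for cylindrical targets, and — crucially for the sensitivity study —
monotone: shrinking any aperture can only decrease dose, everywhere. It
models no scatter, heterogeneity, interleaf leakage, tongue-and-groove or
MU-to-Gy calibration, and must not be read as a transport calculation:
agreements and degradations it reports are *relative* statements about
aperture sequences, which is all the verification statistics need.

## Synthetic study conditions

* Plan: single 358° arc, 60 leaf pairs of 0.5 cm, a 12-pair sliding window
  whose centre sweeps ±2 cm while the gap breathes 4 ± 1.5 cm; uniform
  cumulative weights; 200 MU. These give realistically modulated apertures
  a few centimetres wide.
* Delivery: 8.5 records per original control point at the 50 ms tick —
  the clinical regime, where ~180-control-point arcs produce ~1500
  records (the default 178-CP plan yields 1513).
* Error models: `gaussian` (zero mean, both directions), `unidirectional`
  (half-normal, always aperture-shrinking — a carriage-failure signature),
  `drift` (linear in time). A half-normal |N(0,σ)| has the same second
  moment as N(0,σ), so gaussian and unidirectional fields generated at the
  same σ (and seed) have identical RMS — the clean way to compare "same
  RMS, different directionality". With `active_leaves_only` errors attach
  only to pairs forming an open aperture, as parked leaves track exactly
  in practice.
* Phantom: 31×31×17 voxels of (0.5 cm)³, ellipsoidal body, 2 cm-radius
  spherical PTV at the isocenter, box OAR at +4 cm.

Tests and the acceptance script use 40-control-point arcs (340 records)
and this phantom; they finish in seconds while preserving the
records-per-control-point ratio and the aperture scale of the full-size
conditions.

What passing on synthetic data does *not* show: behaviour under real
controller artefacts (beam holds with realistic timing, dose-rate
modulation), real anatomy and heterogeneity, or absolute dose accuracy.
What it does show: the sampling rules, the error algebra and every
comparison statistic behave exactly as specified, and the end-to-end
pipeline ranks deliveries correctly — one-directional errors are detected
at far smaller RMS than symmetric ones, and PA responds where GPR at
3%,3 mm stays saturated.

## Verification verdict

`verify_delivery` reconstructs the expected- and actual-position beams
with the same sampling mode, computes both doses, and fails the delivery
when the PA of any PTV structure is ≤ 99% (configurable). The threshold
mirrors the observation that once ~50% of voxels carry systematic
deviations above ~1.2% of the maximum dose, PA drops below 99%.

## Known limitations

* DICOM support covers dynamic-MLC RTPLAN and multi-frame RTDOSE with
  axis-aligned orientation; RTSTRUCT contour rasterisation is not
  implemented — structures enter as boolean voxel masks (native arrays or
  the synthetic phantom).
* The α/Δ estimator is the quadrature-subtraction variant described
  above, not a re-derivation of the original noise-separation estimator.
* Decimal serialisation in DICOM limits round-trip fidelity to ~10⁻⁸
  (values are rounded to 8 decimals on write); dynalog round trips are
  exact at each dialect's file resolution.
* The collision guard resolves leaf-bank overlaps by closing the pair
  symmetrically; real controllers would interlock instead.
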