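# Methods

This note documents the models implemented in `igmhinge`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that affect results.

## 1. Geometry: the pivot frame and arm angles

A flexible F(ab')₂ unit is treated as a rigid body attached to a fixed core
by a single pivot at the Cμ2/Cμ3 interface.  Orientations are described in
a `PivotFrame`:

* **pivot point** — midpoint of the two Cμ2 C-terminal anchor atoms;
* **in-plane zero axis (α = 0)** — the two-fold symmetry axis of the Cμ4
  dimer, computed as the axis of the half-turn rotation that best maps one
  Cμ4 chain onto the other (Kabsch superposition; mapping rotations more
  than 20° away from 180° are rejected as not-a-dimer);
* **platform normal (β = 0 plane)** — normal of the least-squares plane
  through the platform atoms, with the in-plane axis re-orthogonalized
  against it;
* **β sign** — a ±1 flag selecting which side of the platform is positive
  elevation, since the platform alone does not orient its two faces.
  Physically the negative side is the one marked by the J-chain hairpin.

An arm's direction is the unit vector from the Cμ2 C-terminal Cα to the
centroid of the constant-domain Cα atoms ("C-terminus" and "centre of the
domain" are operationalized as Cα references — the conventional backbone
choice when no atom is specified).  α is the signed angle of the in-plane
projection from the zero axis; β is the signed elevation.  When the arm is
parallel to the normal the projection vanishes and α := 0 by convention.
Rotations used by the simulator compose in-plane first (about the normal),
then out-of-plane (about the rotated in-plane perpendicular); with this
composition, constructing an orientation by (α, β) and re-measuring it
round-trips exactly, and the in-plane/out-of-plane grids of the ensemble
simulation are independent.

Superposition pairs atoms in order when selections have equal counts, and
falls back to the intersection of (residue number, atom name) keys
otherwise (deposited models of the same molecule share numbering).  RMSD is
the root mean square of post-fit residuals.

## 2. Forward model: pseudo-atom rendering and the pivot ensemble

Each atom contributes an isotropic 3-D Gaussian of unit integral;
amplitudes are element-independent because the analysis operates on shape
envelopes at low threshold, not absolute densities.  Defaults:

| parameter | default | why |
|---|---|---|
| `atom_sigma` | 2.0 Å | intermediate-resolution features (6–8 Å) are the object of study; atomic detail is unnecessary |
| voxel size | 2.0 Å | desk-scale speed at the same resolution regime |
| kernel support | 5 σ | per-atom truncation error ~10⁻⁶, so ensemble averaging conserves mass to that level |
| orientation grid | ±50° / 10° steps | the grid used for model-based cloud interpretation |
| angular weights | uniform (cosine taper optional) | the orientation distribution of the real clouds is unknown; uniform is the least-informative box |

The ensemble map is the weighted average of per-orientation renders —
i.e., the density of the molecule convolved with its orientation
distribution.  Mass is conserved relative to a single render (weights sum
to 1), which is both an invariant test and a sanity check on grid margins:
a grid must enclose every atom at every orientation with ≥3 σ (for error
reporting) and ≥5 σ (for strict mass conservation).

MRC/CCP4 I/O goes through gemmi, mode-2 float, origin stored in the
MRC2014 header origin words; voxel size and origin round-trip bit-exact.

## 3. Inverse model: the arc quantifier

Pipeline per axis (in-plane / out-of-plane):

1. smooth the map with an isotropic 3-D Gaussian, σ = 3 px by default (the
   value used when the measurement is done by hand in an image viewer);
2. take six consecutive cross-sections at one-voxel spacing centred on the
   pivot plane (offsets −2.5 … +2.5 voxels): in-plane sections are
   parallel to the platform; out-of-plane sections contain the platform
   normal and the zero axis, oriented so positive profile angle equals
   positive β under the frame's sign convention;
3. sample grey values by bilinear interpolation along an arc of fixed
   radius around the projected pivot, 1° steps (profiles for the inner /
   constant-domain and outer / variable-domain arcs are both computed);
4. background mean and sd (n−1) over pixels farther than 1.5× the outer
   arc radius from the centre (the background region is a choice; any
   region clearly outside the cloud works because the criterion only uses
   its mean and sd);
5. walking outward from the central peak, the boundary is the first angle
   where (grey − BKḠ)/σ_BKG crosses the threshold (default 2), linearly
   interpolated between the adjacent 1° samples;
6. per-axis result: per-section boundaries per sign, their means, and the
   half-range (mean |boundary| over sections and signs).

**Boundary refinement (lobe fit).**  The raw threshold crossing sits on the
Gaussian-blurred outer tail of the *last orientation* of the ensemble.
When the background is nearly noise-free the threshold is far down that
tail and the crossing overshoots the generating range by roughly
3 σ_blur/r radians (σ_blur² = atom σ² + (smoothing σ)², r the arc radius)
— with the defaults and r ≈ 77 Å that is ~15°.  `motion_range` therefore
refines each crossing to the centre of the outermost orientation lobe by
fitting log(grey − BKḠ) as a quadratic in angle over the outer falloff
(samples between 15 % and 90 % of the local lobe peak) and reporting the
parabola vertex.  The refinement is a deconvolution-minded estimate of
where the edge orientation actually sits; the raw crossing is retained in
the result (`raw_neg`/`raw_pos`) and the refinement can be disabled
(`refine="crossing"`).  The fit falls back to the raw crossing when it has
fewer than 4 usable samples, the curvature has the wrong sign, or the
vertex leaves the falloff region.

**Degenerate backgrounds.**  σ_BKG = 0 makes the ratio undefined
(`snr_ratio` raises).  For synthetic noise-free maps `motion_range`
substitutes a floor of 10⁻³ of the profile's peak contrast (and half a grey
level in 8-bit mode, the quantization limit); with the lobe refinement the
result is insensitive to the exact floor because the floor only moves the
raw crossing along the same tail whose centre is being estimated.

**8-bit mode.**  The original measurements passed through an 8-bit image
conversion; `to_8bit` (min–max rescale, round half up) reproduces it and
`use_8bit=True` runs the whole measurement on quantized sections.  The
default is raw floats: the criterion is scale-free, so quantization only
adds discretization error.  A test asserts the two modes agree within 2°.

**Choice of arc.**  The boundary is measured on the outer (variable-domain)
arc by default: at fixed blur the largest radius gives the best angular
resolution.  The inner arc is always computed alongside and can be selected
(`boundary_arc="inner"`).

## 4. Synthetic hinge generator

`make_toy_hinge_model` builds a deterministic two-arm rigid body: a planar
core slab on the negative-x side (static platform), a pivot anchor at the
origin, and two pseudo-atom arms from the pivot along +x, splayed ±splay/2
out of plane.  Defaults: arm length 90 Å (pivot to Fab tip, the scale of an
antibody arm), atoms every 2.5 Å starting 8 Å from the pivot, splay 50°
(the inter-arm angle of the rigid F(ab')₂), pivot ranges ±50° at 10° steps.

`make_pivot_map` renders the ensemble of the *arms only*: the static core
is ~two orders of magnitude brighter than the motion-diluted cloud (each
orientation carries weight 1/N) and would dominate any min–max grey scale;
the real measurement likewise works within the cloud region.  The grid
extends 1.65× the arm length so the 1.5× background annulus exists inside
the map.  Optional voxel noise is i.i.d. Gaussian with sd given relative to
the clean peak (`noise_sd_rel = 0.2` ⇒ peak SNR 5); the quantifier's
criterion only uses the background mean/sd, so colored noise is not
modelled.

What passing recovery tests shows — and does not: the quantifier recovers
generating ranges on blurred, optionally noisy renders of a rigid two-arm
body with a *known* pivot and *uniform* orientation weights.  Real maps add
colored noise, neighbouring subunit density, imperfect pivot knowledge and
non-uniform orientation distributions; the tilt of real cloud symmetry axes
relative to the platform (~10°) is likewise not simulated (the sections can
be tilted via the frame if desired).  Small arms are measured poorly: below
roughly r ≈ 5 σ_blur per 10° step the orientation lobes merge and the lobe
fit loses its meaning.

## 5. smFRET analysis

Channel model and corrections (intensities in camera counts):

* donor bleed-through α = ⟨F/D⟩ over donor-only molecules,
* direct excitation β = ⟨F/A⟩ over acceptor-only molecules,
* detection factor γ = (F_before − F_after)/(D_after − D_before) around
  acceptor photobleaching, means over 10-frame windows on each side of the
  bleach frame (the bleach frame itself excluded),
* efficiency E = (F − αD − βA)/(F − αD − βA + γD), computed per frame;
  frames with non-positive denominator or E outside [−0.2, 1.2] are masked
  invalid rather than raised — correction noise can exceed physical bounds.

**Bleach detection** finds the dominant downward jump in a series: the
step statistic is the difference of 5-frame means; events must exceed 4×
the expected statistic noise, estimated robustly from frame-to-frame
differences (1.4826·MAD/√2); two or more qualifying events classify the
molecule multi-step (rejected).  Donor bleach is detected on the
*recovered donor* D + F/γ, which is independent of the FRET state — raw D
and F both jump at every state transition and would masquerade as steps.
Acceptor bleach is detected on the direct-excitation acceptor series when
available, else on the FRET channel.  Valid frames for the E histogram are
those before the earliest detected bleach.

**γ pooling** averages per-molecule γ over molecules whose FRET drop and
donor recovery both clear 4× the channel noise — this implements the
"molecules exhibiting non-zero FRET" requirement and excludes molecules
whose donor died before the acceptor (their windows contain only noise);
values outside (0.2, 10) are discarded as implausible.  Note the Eq-style
γ estimator is mildly biased when bleed-through is present
(bias = −α + βA/(IE), < 2 % at the default conditions); this is a property
of the estimator, not of the implementation.

**State fitting** is a 1-D Gaussian mixture (scikit-learn) for k = 1 and
k = 2 with 10 restarts at a fixed seed, selected by BIC; means, sds and
weights are reported sorted ascending.

**Dwell analysis** assigns frames to the nearer state mean with a
hysteresis band of one fitted sd around each mean (a switch requires
entering the other state's band), suppressing noise chatter; transition
rate = switch count / valid observation time; occupancies are frame
fractions.  At 30 ms frames a k₁₂ = k₂₁ = 2 s⁻¹ chain has a frame-sampled
switch rate of (1 − e^(−4Δt))/(2Δt) ≈ 1.88 s⁻¹ — the counting estimator is
expected to sit slightly below the generating rate; no discretization
correction is applied.

**Accessible volume (AV).**  Dyes are virtually attached at the labelled
residue's Cβ (a pseudo-Cβ is constructed from N/CA/C for glycine, and the
residue's own side chain is removed from the obstruction set).  Candidate
dye centres on a 1 Å cubic grid within the linker length are kept if the
dye sphere clears every atom (dye radius + 1.5 Å atom radius) and the
straight path from the attachment is unobstructed at half the linker width
(no path search).  Defaults — linker 20 Å, width 4.5 Å, dye radius 3.5 Å —
are generic maleimide-linker values, all configurable; dye-specific
settings should be supplied when known.  Predicted FRET averages
E(r) = 1/(1 + (r/R₀)⁶) over donor × acceptor position pairs (dye
re-orientation fast, position exchange slow), exactly when the pair count
is ≤ 4·10⁶ and by a seeded Monte-Carlo subsample otherwise; the
FRET-weighted mean distance is R_E with E(R_E) equal to that average.
R₀ = 51 Å for the Alexa Fluor 555/647 pair.

## 6. Synthetic FRET generator

Per molecule: a two-state continuous-time Markov chain (exponential
dwells, stationary initial state), sampled at the 30 ms frame pitch; true
E per frame; channels built by inverting the efficiency equation
(D = I(1−E), F = γIE + αD + βA, A constant); single-step photobleaching of
each dye at exponential times (acceptor mean 5 s, donor mean 10 s over
10 s traces); noise Gaussian with variance = shot (∝ intensity) + camera
read noise (sd 5 counts).  Defaults: I = 300, A = 150 counts (acceptor
snapshots routinely use reduced red-laser power), E states 0.35/0.75,
rates 2 s⁻¹, α/β/γ = 0.09/0.08/1.8.  Noise-free traces invert exactly:
applying the efficiency equation with the true factors returns the true
state E per frame (a generator invariant under test).

The generator emulates trace-level phenomenology only — no TIRF images,
spot detection, channel registration or background maps; traces are the
starting point, as the deposited sample data are per-spot intensity
tables.

## 7. Pipeline and reproducibility

`RunConfig` is a single YAML mapping (unknown keys rejected; referenced
paths validated); angles in degrees, lengths in Å, times in s; R₀ handled
internally in Å.  Every stage records its fully-resolved parameters
(defaults included) in the report so silent default drift is detectable;
identical config + seed reproduce identical numeric summaries.  All
generators take explicit seeds.

Problem sizes used by the shipped benchmarks: 90 Å arms on ~150³–2 Å
grids, 11–121 orientation renders per map, 100 molecules × 10 s × 30 ms
for FRET — sizes chosen so a full run takes seconds on one core while
keeping the orientation lobes resolvable at the measurement radius.

## 8. Known limitations

* The quantifier needs the pivot position supplied (or arc-fitted); it
  does not segment which cloud belongs to which subunit.
* The lobe refinement assumes a locally Gaussian outer falloff — true for
  blurred rigid-body ensembles, approximate for real clouds.
* The AV obstruction test uses straight-line reachability, which slightly
  overfills clouds behind thin obstacles compared with path-search AV.
* Dwell counting underestimates fast kinetics near the frame rate (see
  §5); rates within ~±15 % of truth at the default conditions is the
  tested regime.
* Element-independent rendering means simulated absolute densities are not
  comparable to experimental map values; only shapes and envelopes are.
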