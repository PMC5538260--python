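# Methods

`fbctract` scores streamlines in a tractogram by their *fiber-to-bundle
coherence* (FBC), removes poorly supported ("spurious") streamlines by
thresholding the relative coherence, and selects that threshold by a
test–retest stability analysis of a landmark-to-bundle distance.  The
intended application is the optic radiation (OR): spurious streamlines near
the anterior tip of the Meyer's loop corrupt the Meyer's-loop-to-temporal-pole
(ML-TP) distance, the quantity a surgeon needs when planning a temporal lobe
resection.  Everything here runs on synthetic bundles, so all claims that the
tests establish are claims about the method, not about any scan.

## The coherence model

A streamline is lifted to position–orientation space R³×S² by attaching the
unit tangent **n**ₖ (central differences inside, one-sided at the ends) to
each point **y**ₖ after resampling to a fixed 0.2 mm spacing.  The coherence
of a lifted point is the kernel-density mass contributed by the points of all
*other* streamlines:

    FBCᵢᵏ = Σ_{j≠i} Σ_l  k( yⱼˡ − yᵢᵏ, nⱼˡ, nᵢᵏ )

where `k` is the transition density of a hypo-elliptic Brownian motion on the
rigid-motion group SE(3): a walker moves forward or backward along its
orientation (longitudinal diffusivity `d_long`, mm²/u) and reorients by
Brownian motion on the sphere (angular diffusivity `d_ang`, rad²/u), but can
never move sideways; `t_diff` is the total diffusion time.  Alignment with
neighbours therefore counts only when positions *and* orientations agree in
the way fiber geometry does.

Per-streamline scores follow from the FBC profile:

* `AFBC^α(γᵢ)` — the minimum over sliding windows of physical length α
  (default 2 mm = 10 points at 0.2 mm) of the window-averaged FBC;
* `AFBC(Γ)` — the bundle average, pooled over all points of all streamlines
  (point-weighted, so long streamlines carry proportional weight);
* `RFBC^α(γᵢ, Γ) = AFBC^α(γᵢ) / AFBC(Γ)` — the relative coherence.

A streamline is retained when `RFBC ≥ ε`.  Scores are computed once on the
full bundle; thresholding never re-scores, so the ε sweep acts on fixed
scores and ε_max (the threshold emptying the bundle) is well defined.  A
streamline's own points are excluded from its density so that an isolated
streamline scores exactly zero rather than being supported by itself.

## The kernel approximation

The exact hypo-elliptic heat kernel has no elementary closed form.  We use a
Gaussian estimate in exponential (logarithmic) coordinates c₁…c₅ of the
relative pose (the axial rotation coordinate c₆ vanishes when the relative
orientation is reached by the minimal rotation):

* reachable coordinates: axial offset c₃ with variance `2·d_long·t`, tilt
  angle θ with variance `2·d_ang·t` per tangent axis, times the
  sphere-volume correction √(θ/sin θ);
* forbidden (sideways) coordinates c₁, c₂: Gaussian with *conditional*
  variances derived from the second moments of the process.  Writing the
  lateral displacement as the stochastic integral of the tilt path against
  the forward motion and conditioning on the endpoint (a Brownian-bridge
  calculation) gives, per axis,

      σ∥² = d_long·d_ang·t²/3 + d_long·t·θ²/6 + d_ang·t·c₃²/6
      σ⊥² = d_long·d_ang·t²/3 + d_ang·t·c₃²/6

  where ∥ is the lateral axis aligned with the tilt azimuth.  Exponential
  coordinates decorrelate the axial–lateral cross moments, so the quadratic
  form is diagonal in this frame.

The coefficients are analytic, not fitted.  The estimate is validated against
a Monte-Carlo simulation of the defining walk (1 000 000 walkers, 140 Euler
steps): on (z, ρ, β) bins holding ≥ 5 % of the peak bin mass — about 87 % of
all walker mass — the binned densities agree to ≤ 12 % relative error
(median ≈ 4 %).  The same simulation confirms the hypo-elliptic anisotropy:
at equal displacement magnitude, along-orientation mass exceeds sideways
mass by growing factors (the sideways density collapses with σ ≈ 0.16 mm at
aligned poses, the commutator scale t·√(d_long·d_ang/3)).

The kernel is symmetrized over antipodal flips of both orientation
arguments, because streamline head/tail direction is arbitrary; this makes
every downstream score invariant to streamline reversal (tested).  The
kernel is also even in the displacement and symmetric under exchanging the
two poses, so one evaluation serves both directions of a point pair.

Default parameters: `d_long = 1.0` mm²/u, `d_ang = 0.04` rad²/u,
`t_diff = 1.4`, giving a few-mm axial reach (σ ≈ 1.7 mm) and ≈ 19° angular
spread — comparable to the streamline spacing and curvature of an OR bundle
at 0.2 mm tracking steps.  They are configuration-exposed and echoed into
every run manifest.  Contributions beyond a 6 mm cutoff are culled (the
kernel has decayed below 1 % of its mode by 5.1 mm axially, much earlier in
every other direction).

## Lookup tables

`build_table` precomputes kernel values on a cubic grid of relative
positions (default half-width 6 mm, spacing 0.5 mm) times an antipodally
collapsed icosahedral direction set (default 42 → 21 representatives) for
both orientation arguments.  Lookups snap orientations to the nearest
tessellation direction and interpolate positions trilinearly *on the
log-values*: the kernel spans many orders of magnitude within one cell, and
interpolating the exponent keeps relative error bounded where arithmetic
interpolation is off by orders of magnitude.  Tables are exact at grid nodes
and serialize to a self-describing `.npz` container.

The sharp lateral core is below any feasible grid resolution, so
interpolated values at generic off-node poses carry appreciable error:
measured medians are ≈ 80 % at 1 mm spacing, ≈ 38 % at 0.5 mm and ≈ 11 % at
0.25 mm (clean ~quadratic convergence, asserted by the refinement test);
bundle-level FBC sums via the default table deviate from direct evaluation
by ≈ 23 % (median) at 0.5 mm spacing.  Because RFBC is a ratio, much of this
bias cancels, and the direct numba-accelerated evaluation is fast enough
that tables are an optional cache rather than the default path.  The
table-path oracle test therefore uses a lattice-aligned toy bundle (points
on the grid, tangents on tessellation directions), where the mechanism is
exact; the generic-pose accuracy is the figure quoted above.

## Threshold selection by test–retest stability

Given repeated tractograms of the same anatomy (here: repeated synthetic
realizations) and a landmark, the sweep scores each repetition once, filters
it at every ε on a grid (default step 0.005 from 0 to ε_max), and computes
the ML-TP distance of the filtered bundle.  The ML-TP distance is the
*closest approach*: the minimum Euclidean distance between any landmark
point and any streamline point.  Removing streamlines can only increase it,
which makes the per-repetition distance monotone in ε (tested).  μ(ε) and
σ(ε) are the mean and sample standard deviation (n−1) over the repetitions
whose filtered bundle is nonempty; the grid is truncated at the first ε
where every repetition empties.

ε_selected is the smallest grid ε > 0 whose variability is a non-strict
discrete local minimum at or below the bound σ_max = 2 mm (the accuracy
achievable in resective surgery).  If the variability dips below the bound
without an interior local minimum, the smallest compliant ε is returned with
a fallback flag; if it never reaches the bound the analysis fails loudly.

## Damage arithmetic

With pre-/post-operative ML-TP distances and a resection length (all mm):

    predicted damage = max(0, resection length − pre-op ML-TP)
    observed damage  = max(0, post-op ML-TP − pre-op ML-TP)
    margin of error  = (observed + σ_obs) − (predicted − σ_pred)

with the convention σ_pred = pre-op variability and σ_obs = pre-op + post-op
variabilities.  This reconstruction reproduces the published case reports it
was checked against for two of three patients exactly (10.9/12.0/4.3 mm and
16.3/19.5/5.6 mm); the third case's printed margin (1.6 mm) does not follow
the same convention (the formula gives 2.3 mm) and is not asserted.
Damages are floored at zero, matching the printed 0.0 for a resection
shorter than the pre-operative distance.

## The synthetic generator

`synthetic` emulates the *statistical situation* of OR tractometry, not OR
anatomy: a C-shaped circular arc (radius 15 mm, arc length 60 mm — a
Meyer's-loop-like sweep) translated per streamline by an isotropic 3-D
normal offset (σ = 1 mm, 30 streamlines), resampled at 0.2 mm; a
temporal-pole stand-in on the tip axis 32 mm out, putting the clean ML-TP
near 30 mm, the scale reported for adults, so millimetre tolerances are
meaningful.  Planted spurious streamlines depart from a bundle point at
≈ 45° to the local tangent and run straight to an endpoint 10 mm (default)
beyond the bundle's most anterior point, scattered on a 4 mm ring about the
tip axis.  The ring makes planted tips mutually farther apart than the 6 mm
cutoff, so they cannot lend each other coherence: their windowed coherence
is exactly zero and planted-vs-clean separation is exact, enabling
exact-recovery tests instead of probabilistic ones.  Test–retest sets are
n_rep = 10 independent redraws (seeds spawned in order from
`numpy.random.SeedSequence(master_seed)`, a scheme we keep stable across
releases), each planting spurious streamlines independently with
probability 0.5 — emulating the stochastic appearance of spurious anterior
tips across probabilistic-tracking runs.

What the generator does *not* emulate: along-streamline positional noise,
curvature dispersion, branching/fanning anatomy, partial-volume or
distortion effects, and any relationship between streamline density and
FOD amplitude.  Passing tests therefore show that the measures and the
selection rule behave as designed on bundles with planted outliers; they do
not certify performance on scanner data.

## Numerical choices and degenerate inputs

* Resampling marches at fixed Euclidean step (the tracking convention), so
  the output polyline is equally spaced in its own arc length and the
  operation is exactly idempotent; the endpoint is always kept.  A step not
  shorter than the streamline returns the two endpoints.
* The length filter keeps arc length ≤ 114 mm inclusive (with a 1 nm
  tolerance), reading the anatomical bound as satisfied by itself.
* A single-streamline bundle has an all-zero FBC profile; the bundle
  average, and hence RFBC, is then undefined and raised as an error.
* Streamlines shorter than one window fall back to a whole-profile window.
* Sweep statistics over a single surviving repetition report σ = 0; ε
  values where every repetition is empty are truncated (defining ε_max).
* Orientation snapping at θ = 0 (tilt azimuth undefined) uses an arbitrary
  orthonormal split; the two lateral variances coincide there.
* TRK files are converted to world-space mm at read time using the header
  affine; a TRK whose affine was never recorded is rejected rather than
  passed through in voxel space.

## Known limitations

* The kernel is an approximation; its ≤ 12 % bulk error against the process
  is inherited by FBC values (but largely cancels in RFBC ratios).
* Lookup tables trade accuracy for caching as quantified above; use direct
  evaluation when exactness matters.
* The closest-approach ML-TP reading is one of several possible
  "landmark-to-bundle distance" conventions; it is the one under which
  removing anterior outliers increases the distance.
* The selection rule assumes the variability curve actually stabilizes;
  bundles whose coherence scores are all similar produce flat sweeps where
  ε_selected degenerates to the first grid point.
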