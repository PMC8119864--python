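# Methods

## Data model and conventions

All positions are in cm in an arena-centered frame (y up); angles are
degrees in [0, 360), counterclockwise positive, 0° along +x. Signed
rotations are reported in (−180, 180], positive = counterclockwise; when
shifts from clockwise and anticlockwise manipulation days are pooled, they
are sign-normalized to the commanded rotation so that +90° always means
"with the landmark". Tracking is assumed uniformly sampled (synthetic data
uses 50 Hz; any uniform rate is accepted). Spikes are assigned to their
nearest trajectory sample in time, ties to the earlier sample; the same
sample mask drives spike selection and occupancy, so filters can never
bias the rate normalization.

## Arenas

Four geometries cover the designs the analyses target:

* **octagon** — regular octagon with vertices on a 100 cm circle (the
  100 cm figure is the maximal width, vertex to vertex), optionally with a
  cue-card angle on the wall.
* **octagon_barrier** — the octagon plus a 70 cm barrier segment through
  the center (default along the y axis), with traversable gaps at both
  ends. The walkable area excludes a 1 cm strip around the barrier.
* **parallel4 / radial4** — four 40.5 × 35.5 cm compartments opening onto
  a 20 cm-wide corridor; parallel compartments share a long-axis direction,
  radial compartments are offset 60° from their neighbors along an
  annular corridor. Compartment polygons are sunk into the corridor for a
  doorway and then differenced against it, so the named regions are
  pairwise disjoint while their union is a single connected walkable space.

## Synthetic data generator

The generator exists to give every estimator a ground truth; it emulates
the statistical structure the analyses rely on, not rat behavior.

* **Foraging** is a correlated random walk: per-step turning is
  wrapped-Gaussian with sd (1 − persistence) · 60° (defaults: persistence
  0.8, 50 Hz), per-step speed is a truncated Gaussian around 15 cm/s
  (fractional sd 0.3), and wall collisions reverse the movement direction
  with 30° scatter without advancing. Confinement is enforced against a
  1 cm-resolution lookup of the walkable polygon shrunk by a 1 cm wall
  margin, so every sample is strictly inside the arena. A 1200 s run
  covers ≥ 90% of 5 cm bins in the octagon. Head direction is movement
  direction plus 10° sd wrapped-Gaussian jitter — keeping heading and
  movement direction distinct so tuning estimation is honest.
* **HD cells** fire as inhomogeneous Poisson processes with rate
  λ(θ) = baseline + (peak − baseline)·exp(κ_t(cos(θ − pfd) − 1)) — a von
  Mises-shaped unimodal tuning curve. Defaults κ_t = 4, peak 30 Hz,
  baseline 0.5 Hz give mean-vector lengths ≈ 0.7, comfortably above the
  r ≥ 0.2 criterion, as real HD cells are.
* **Place cells** use λ(x, y) = baseline + (peak − baseline)·
  exp(−d²/2σ²) with a single isotropic Gaussian field (default σ = 8 cm,
  peak 15 Hz, baseline 0.05 Hz).
* **Cue manipulations** rotate the tuning reference by
  δ = rotation × gain + N(0, noise), wrapped: gain 1 is full stimulus
  control, gain 0 a complete failure, intermediate gains produce the
  under-rotation seen with weakly controlling landmarks (gain 0.7 on a 90°
  rotation centers recovered shifts at 63°). Local-reference populations
  are simulated by re-anchoring the preferred direction per compartment
  polygon (offset by the compartment's axis angle).

What the generator does **not** emulate: theta modulation and bursting,
multi-field or irregular place fields, conjunctive tuning, behavioral
door-crossing dynamics, tracking artifacts, or drift within a session.
Passing tests therefore demonstrate that the estimators recover the
parameters of this generative family under realistic sampling noise — not
that they are robust to every pathology of real recordings.

## Estimators

* **Tuning curves**: 1° bins; occupancy-normalized; bins under a 0.1 s
  occupancy floor are filled by circular linear interpolation before
  circular-Gaussian smoothing (σ = 6°). 1° bins make the 1° shift search
  exact without interpolation; the smoothing width was chosen once as a
  conventional value (the shift estimator is insensitive to it because
  both curves are smoothed identically).
* **Mean vector** is computed on the smoothed, occupancy-normalized curve
  (rate-weighted), which removes occupancy bias relative to a per-spike
  resultant. Mean rate is total spikes over total (filtered) time. An
  all-zero curve has no direction: it is flagged undefined rather than
  reported as r = 0.
* **Rate maps**: 2.5 cm bins, 0.1 s occupancy floor, Gaussian smoothing
  (σ = 5 cm) over valid bins only with kernel renormalization; unvisited
  bins stay invalid (NaN). Spatial information is computed on unsmoothed
  rates, since smoothing deflates the index against the 0.5 bits/spike
  criterion threshold.
* **Shift estimation** maximizes Pearson correlation over circular lags.
  For curves the full 360-lag profile comes from an FFT circular
  cross-correlation (exact for full-overlap lags; verified against a
  direct per-lag loop). For maps, one session's raw samples are rotated
  about the arena center and re-binned at each 5° step
  (rotate-then-bin avoids raster interpolation artifacts and makes the
  self-comparison exactly 1.0); correlation runs over bins valid in both
  maps, requiring ≥ 20 overlapping bins. Argmax ties break toward the
  smallest |shift|, then the positive sign, so symmetric inputs give
  deterministic output.
* **Compartment analysis** restricts the sample mask to each compartment
  polygon (corridor excluded). A compartment is unusable below 50 spikes
  or 180° of sampled heading coverage — floors the source protocols leave
  unstated, so they are explicit and configurable here.
* **Barrier adjacency**: a field is "adjacent" when its peak (maximum
  smoothed-rate bin center) lies within 10 cm of the barrier segment,
  inclusive; the distance is configurable and reported with the output.
* **Rotation response**: "rotated" within ±30° of the commanded rotation
  (inclusive), "unchanged" within 30° of zero (exclusive), else "other";
  rotations under 60° would make the windows overlap and are rejected.

## Classification

Boundary semantics follow the criteria wording literally: r and mean-rate
thresholds are inclusive (≥), spatial information and spike width strict
(>), the rate band inclusive at both ends. The HD mean rate uses the whole
session without a speed filter (the HD protocol states none); place-cell
metrics apply the > 3 cm/s filter before everything. Decisions are pure
functions of the returned metrics, so they can be re-derived from any
emitted table.

## Circular inference

Degrees at the interface, radians internally.

* **V-test**: u = n·r·cos(mean − θ0)·√(2/n), one-sided normal upper tail;
  requires n ≥ 5 (below that the normal approximation is unreliable).
* **Kuiper**: V_n = D⁺ + D⁻ against the uniform; p from the asymptotic
  series at V_n(√n + 0.155 + 0.24/√n) (Stephens' finite-n modification).
* **Watson U² (von Mises GOF)**: μ̂, κ̂ by maximum likelihood, then U² on
  the fitted CDF; because the null parameters are estimated, p comes from
  a seeded parametric bootstrap (default 2,000 resamples) instead of
  table interpolation — calibrated by construction for the composite null.
* **Moore's paired test**: difference vectors ranked by magnitude;
  R′ = |Σ rank·(cos φ, sin φ)|/n^{3/2}. The null is simulated (default
  10,000 seeded replicates of uniform difference directions with ranks
  kept), giving exact-size p-values at any n rather than interpolating
  the 1980 critical-value table. Zero-magnitude differences have no
  direction and are excluded with n reduced. Monte-Carlo p-values use
  (b + 1)/(B + 1), so p > 0 always.
* **κ estimation**: solve I₁(κ)/I₀(κ) = r with the standard piecewise
  starting approximation refined by Newton to |A₁(κ̂) − r| < 1e−8; r = 0
  gives κ̂ = 0, r = 1 raises (unbounded).
* **Concentration comparison** (Mardia & Jupp): regime chosen by the
  pooled resultant length r̄ — below 0.45 an arcsine
  variance-stabilizing transform of r̄ᵢ (normal Z), 0.45–0.70 the
  asinh((r̄ᵢ − 1.089)/0.258) transform with standard error
  0.893·√(1/(n₁−3) + 1/(n₂−3)) (normal Z), above 0.70 the F-ratio
  of n(1 − r̄)/(n − 1) with (n₁ − 1, n₂ − 1) df. Two-sided p in every
  regime. The test assumes von Mises samples; callers can request a
  Watson-U² pre-check that warns when either input rejects at α = 0.05,
  mirroring the caveat that shift distributions often fail this
  assumption.

## Pipelines and problem sizes

Sessions default to 1,200 s (the 20–30 min session scale of the designs
analyzed). One trajectory per session is shared by all simulated cells of
that session, as in a real recording day. All randomness descends from a
single `numpy.random.SeedSequence`, making every experiment byte-for-byte
reproducible; summary reports are pure functions of the emitted per-cell
CSV.

Monte-Carlo study sizes used by the validation suite and
`scripts/acceptance.py`: 10,000 replicates for V-test/Kuiper/Moore type-I
calibration (Moore's inner null at 1,999 replicates there — a precision
parameter, not a study condition), 5,000 for the concentration-comparison
null, 200 replicates for the Moore's-test power study (cue gain 1.0
vs barrier gain 0.5, 30 cells per replicate, 600 s sessions — shift
estimates saturate well below that length), and 20-cell populations for
discrimination and classification-rate checks.

## Known limitations

* The Kuiper and V-test p-values are asymptotic; both are calibrated to
  within the tested [0.040, 0.060] band at n = 30 but are not exact at
  very small n.
* The concentration comparison inherits the von Mises assumption and the
  mid-regime's published constants; near r̄ ≈ 0.45 and ≈ 0.70 the regime
  switch can make the statistic mildly discontinuous in the data.
* Compartment tuning curves from short visits can be dominated by a few
  heading bins; the usability floors guard the obvious failure modes but
  occupancy-matched comparisons are not implemented.
* The map-shift estimator assumes both sessions share an arena outline
  and center; it does not handle translated or rescaled enclosures.
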