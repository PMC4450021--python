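# Methods

This note documents the models implemented in `aimmtrack`, the parameter
defaults and why they were chosen, the numerical decisions that matter,
and what the synthetic studies do and do not establish.

## State and motion models

Each cell carries the augmented state

    X = [x, y, ẋ, ẏ, ω, s]ᵀ

position in pixels, velocity in px per frame interval T, turn rate ω in
rad per frame interval (reported in rad/s by dividing by T), and blob
area s in px². Three motion modes cover the interaction regimes:

* **ACV** (independent motion): x ← x + Tẋ, area unchanged.
* **ACT1** (collision): the velocity rotates by ωT per frame (standard
  coordinate-turn kinematics) and the area is multiplied by the
  collision control λ ∈ [1, 2] — a blob absorbing its collision partner
  grows toward the sum of the two areas.
* **ACT2** (division/splitting): same kinematics with the area
  multiplied by κ ∈ [0, 1].

Process noise enters as G·v with v ~ N(0, diag(Q)) and
G = diag(T²/2, T²/2, T, T, 1, 1): an acceleration-like gain on position,
direct gain on velocity, unit gain on ω and s. This diagonal reading is
the dimensionally consistent one given that Q is specified as six
diagonal variances. Measurements observe z = (x, y, s) + w,
w ~ N(0, diag(R)); velocity and turn rate are never observed directly.

`ct_transition` returns the full 6×6 coordinate-turn matrix including
the turn-rate sensitivity column [f11, f21, f31, f41] (the derivative of
the position/velocity map with respect to ω, with closed-form ω→0
limits; unit-tested against central finite differences to 1e-6). Particle
propagation, however, applies the *exact nonlinear rotation* at each
particle's own ω rather than the linearized matrix: applying the
sensitivity column as part of a transition on the raw state would add a
spurious J·ω displacement, break speed preservation, and mis-rotate the
velocity. The matrix form exists for linearization-based uses and as the
documented object; the filter is fully nonlinear.

Below |ωT| < 1e-6 all trigonometric factors switch to their series
limits.

## Event probabilities and controls

Collision and division evidence comes from detected areas and centroid
distances:

    P(c_k) = f₁ · exp(−(α₁ − μ₁)² / 2σ₁²) · exp(−σ|d_{k−1}|)
    P(β_k) = f₂ · exp(−C (α₂ − 0.5)²)     · exp(−γ|d_k|)

with α = s_k / s_{k−1} the ratio of a track's detected area between
consecutive frames. The kernels are peak-normalized (maximum 1) rather
than probability densities so that λ = 1 + P(c) stays in [1, 2] and
κ = P(β) in [0, 1] by construction; f₁, f₂ ≤ 1 absorb any
proportionality.

Defaults: f₁ = f₂ = 0.9; μ₁ = 2 (a merged blob of two similar cells has
about twice one cell's area) with σ₁ = 0.4; C = 25 (the division kernel
drops to e⁻¹ at α = 0.5 ± 0.2); σ = γ = 1/D̄ with D̄ = 12 px the mean
cell diameter, tying the length scale of "close" to the cell population.
Event assessment is per track: α against the track's previously
associated area, d against the nearest other track (previous frame) for
collision and the nearest other detection (current frame) for division.
When no neighbour lies within 3·D̄ the controls default to λ = 1,
κ = 0.

## The AIMMPF cycle

Per cell and frame: **mix → predict(λ, κ) → update → mode-probability
update → resample → estimate**, with N = 500 particles per mode and the
Markov transition matrix rows (0.8, 0.1, 0.1), (0.1, 0.8, 0.1),
(0.1, 0.1, 0.8).

* **Mixing** uses mixture resampling — mode j's new cloud is drawn from
  the pooled clouds with weights P_ij·M_i / c̄_j — the standard IMM
  construction for particle filters (moment matching without Gaussian
  assumptions). A particle entering a coordinate-turn mode *from ACV*
  carries no meaningful turn rate (ACV dynamics never exercise ω, so its
  ω marginal is unselected noise); such particles are re-seeded from the
  destination mode's fed-back posterior estimate ω̂ plus a N(0, Δ)
  increment with Δ = 0.01 rad². Particles already in a CT mode keep
  their persistent per-particle ω, so selection can integrate turn-rate
  evidence across frames. An alternative that redraws *every* ACT
  particle's ω from ω̂ each frame was evaluated and rejected: it reduces
  the turn-rate memory to a scalar updated by a weak per-frame gradient
  and converges far more slowly.
* **Update** computes Gaussian log-likelihoods of z = (x, y, s) and
  keeps everything in log space with a shared shift across modes. This
  matters: at a merge the measured area can sit 30+ residual standard
  deviations from the ACV prediction, and the mode competition is only
  decided correctly if likelihood ratios on the order of e⁻¹⁰⁰⁰ survive
  arithmetic. Per-mode likelihood Λ_j is the weighted mean unnormalized
  weight; posterior mode probabilities are M_j ∝ c̄_j Λ_j (if every mode
  underflows entirely, the predicted c̄ is kept and the bank is flagged).
* **Resampling** is systematic, every frame, followed by light
  roughening: each resampled particle is jittered by 0.2 × the
  *pre-resampling* per-dimension cloud spread. Without roughening the
  bootstrap filter occasionally (≈2–5% of 50-frame runs at the
  collision-profile noise levels) collapses to a single particle with a
  wrong velocity and never recovers, because velocity is only weakly
  identified through position selection; with it the filter tracks
  within a few percent of the exact Kalman filter on linear-Gaussian
  data and pathological runs disappear.
* **Estimate** forms the mode-probability-weighted mixture of per-mode
  weighted means, and writes the ACT1/ACT2 posterior mean turn rates
  back into the bank (the ω̂ feedback). A missed detection triggers a
  predict-only step that keeps c̄ as the mode probabilities.

Track birth from a single detection: position ~ N(detection, 1 px),
velocity ~ N(0, 2 px/frame) — wide enough to cover typical cell speeds
of 1–5 px/frame, since velocity is unobserved at birth — ω ~ N(ω₀,
0.4 rad) and area ~ N(s_det, 2 px²).

## Correspondence and label management

Association per frame, in precedence order (chosen so a merged track's
split is never misread as a division):

1. **Split** of a merged carrier: the carrier gates onto ≥2 unclaimed
   detections whose areas are 0.35–0.65 of its last (merged) detected
   area; the saved *pre-merge* predicted areas of the carried labels are
   matched to the detections by the feasible bijection (area difference
   < δ₂) with minimal summed difference, distance breaking ties.
2. **Division** of a plain track onto two half-area detections: the
   spatially closer daughter keeps the parent label, a fresh
   monotonically increasing label is created, and two lineage records
   point at the parent.
3. **Merge**: two unassigned tracks gate onto one detection whose area
   over the mean of their predicted areas lies in 1.7–2.3; the closer
   track becomes the carrier of both labels, the other is frozen with
   status `merged-into`. A third nearby track is left to compete in the
   one-to-one case.
4. **One-to-one**: among (track, detection) pairs passing both gates
   (distance < δ₁, area difference < δ₂), assignments are made greedily
   in order of (area difference, distance, index) — deterministic and
   conflict-free.

Remaining detections become tentative tracks, confirmed after two
consecutive associations and discarded otherwise (first-frame detections
are confirmed immediately). Unassociated tracks coast up to
`max_coast` = 2 consecutive frames before termination; a coasting track
whose prediction leaves the image bounds is closed as exited.

The "predicted area" used in gating is the track's last associated
detection area, not the filter's area state. The filter's area component
cannot follow the discontinuous jump at a merge (its process noise is
tiny and importance weighting cannot move particle values), so
detected-area continuity is the reading under which the merge/split area
ratios — themselves defined on detected areas — remain consistent. The
filter's area estimate is still reported in the output tables.

Parameter profiles (δ₁ = 25, δ₂ = 8, ω₀ = 0.8,
Q = diag(30/40, ·, 0.1, 0.1, 0.01, 0.01), R = I₃ for the collision-rich
profile; δ₁ = δ₂ = 5, ω₀ = 0.1, larger position noise for the division
profile) are exposed as `scenario1` / `scenario2`; a third `smooth`
profile (Q = diag(0.5, 0.5, 0.05, 0.05, 0.0025, 0.01),
R = diag(0.25, 0.25, 1), ω₀ = 0) serves low-noise smooth-motion studies
such as turn-rate estimation, where the collision-profile position noise
(std ≈ 2.7 px/frame) would swamp the turn-induced displacement signal
(|v|·Δω ≈ 0.3 px/frame) and make ω unidentifiable in principle.

## Detection

The frame pipeline is threshold → binarize → mend → fill holes → median
→ dilate → extract components. Conventions: 0-based (x = column,
y = row) coordinates; 8-connectivity for foreground components, the dual
4-connectivity for background reachability in hole filling; a 3×3 square
dilation element, one pass; binary median = majority over a 3×3 window.
Edge mending promotes a background pixel when both opposite neighbours
along any of the four directions are foreground; it is monotone but not
idempotent in general (repairs can create new bridges) and is applied
once. Components outside the configured area range or with bounding-box
width/height ratio outside [0.5, 5.0] are discarded.

The iterative two-class mean threshold starts at the intensity midrange
(min+max)/2. The basin of attraction matters: starting from the image
*mean* collapses onto the background-noise mode whenever bright cells
cover a small fraction of the frame, because the midpoint update is
dominated by the noise tail rather than by the cells. Midrange
initialization lands between the modes. Even so, the two-class mean
rule needs the histogram gap to be real: when the background noise is so
heavy that its upper tail outweighs the total cell intensity, no
initialization separates the classes (Otsu-style variance criteria would
degrade more gracefully, but the two-class mean rule is the method
implemented). Convergence uses |TH′ − TH| < 0.5 with a cap of 100
iterations; on a constant image the constant is returned with a
degenerate flag.

## Synthetic data: what it emulates, what it does not

`simulate` generates ground truth from declarative scripts: per-cell
birth frames, initial states and motion segments (constant velocity or
coordinate turn), pairwise collision spans (partners co-located at their
midpoint, one shared detection with summed area), divisions (daughters
of complementary area placed half a mean diameter either side of the
motion axis, drifting apart at 0.5 px/frame) and exits. Detections add
N(0, R) noise, Bernoulli misses (default rate 0.02) and Poisson clutter
(default 0.05/frame, uniform positions, cell-scale areas). Rendered
images are isotropic Gaussian blobs whose integrated intensity is
proportional to area (σ = 2.5 px, peak SNR 20 by default) on a noisy
background.

This emulates the geometry and event structure of adherent-cell
sequences but not their texture: no shape deformation beyond scalar
area, no intensity heterogeneity, no partial occlusion or uneven
illumination, and detection noise is exactly the Gaussian the filter
assumes. Passing the synthetic studies therefore establishes that the
algorithmic machinery (mode switching, control feedback, label
management) behaves as designed under its own model class — not that the
defaults transfer to any particular microscope. On rendered images the
per-frame independent threshold makes pixel-count areas jitter by more
than the δ₂ = 8 gate on some frames, which causes visible track churn;
the detections-mode route is the validated one, and image-mode users
should widen δ₂ or stabilize the threshold across frames.

The reference benchmark (`benchmark_script`) uses 200×200 px frames, 40
frames, five initial cells with one collision + split (frames 18–20),
one division (frame 26, 0.48/0.52 area split), one exit, one entry, the
collision-profile noise, and ~220 ground-truth positions; study sizes
throughout (20 seeds, 50–60 frames, N = 500) keep every scripted study
in the seconds-to-a-minute range.

## Evaluation

PAP (percentage of attained positions): each track label is mapped once
to a ground-truth cell at its first match within the match radius
(10 px by default — clearly above steady-state position error, clearly
below typical inter-cell distances); a ground-truth position counts as
correctly tracked if a label mapped to its cell reports a position
within the radius in that frame. During collision spans the carrier
emits positions for both carried labels, so a well-tracked merged blob
credits both cells. `evaluate` adds birth/termination counts, identity
switches (changes in which label covers a cell) and the mean per-frame
cardinality error.

## Known limitations

* Merges are pairwise only; a three-way collision resolves as a pair
  plus a coasting track.
* The filter's area state lags through merges by design (see above);
  area-based gating uses detected areas instead.
* Division daughters are symmetric about the parent's path, so the
  closer-daughter-keeps-the-label rule can swap identities when
  measurement noise exceeds the geometric asymmetry; the lineage records
  are unaffected.
* The two-class mean threshold requires cells to contribute a
  non-negligible share of total image intensity (see Detection above).
* Clutter that persists near a cell for two consecutive frames can be
  confirmed as a spurious track; no appearance model exists to reject
  it.
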