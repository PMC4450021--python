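# aimmtrack

Multi-cell tracking through collision and division in time-lapse
microscopy, built around an **augmented interacting-multiple-model
particle filter (AIMMPF)**.

Cells in live imaging do not just drift: they collide and transiently
merge into one blob, split apart again, divide into daughters, and enter
or leave the field of view. Trackers that assume one detection per object
with smooth motion lose identities exactly at those events. This package
implements a full pipeline for that regime, for anyone who needs
per-cell trajectories, velocities, turn rates and lineage from grayscale
frame sequences (or from an existing detection table):

1. **Detection** — hybrid morphological segmentation: iterative two-class
   mean thresholding, broken-edge mending, hole filling by morphological
   reconstruction, binary median smoothing, dilation, and a size /
   aspect-ratio component filter.
2. **Event model** — collision and division probabilities from two cues,
   the detected-area ratio α and the inter-cell distance d:

       P(c_k)  = f₁ · exp(−(α₁−μ₁)²/2σ₁²) · exp(−σ|d_{k−1}|)
       P(β_k)  = f₂ · exp(−C(α₂−½)²)      · exp(−γ|d_k|)

   feeding the area-scaling controls λ_k = 1 + P(c_k) ∈ [1,2] and
   κ_k = P(β_k) ∈ [0,1].
3. **AIMMPF** — per cell, three mode-conditioned particle clouds over the
   augmented state X = [x, y, ẋ, ẏ, ω, s]ᵀ (position, velocity, turn
   rate, area): ACV (constant velocity), ACT1 (coordinate turn for
   collision, area scaled by λ) and ACT2 (coordinate turn for division,
   area scaled by κ), mixed by a Markov chain over modes. Two feedback
   loops distinguish it from a plain IMM particle filter: the event
   probabilities drive λ/κ, and the posterior per-mode turn-rate
   estimates ω̂ seed the next frame's coordinate-turn propagation.
4. **Correspondence and label management** — nearest-neighbour gating
   (d^distance < δ₁) refined by area difference (d^area < δ₂), with
   explicit merge (α ≈ 2), split and division (α ≈ ½) cases, lineage
   records, track births, coasting and exit handling.
5. **Simulator and metrics** — scripted scenarios (collisions, divisions,
   entries/exits) with ground truth, noisy detections, rendered image
   frames, and the PAP score (percentage of ground-truth positions
   covered by a track with the correct persistent identity).

## Worked example

Track the bundled collision-rich scenario (five initial cells, one
collision with later split, one division, one exit, one mid-sequence
entry, measurement noise R = diag(1,1,1), occasional missed detections
and clutter):

```python
import numpy as np
from aimmtrack import simulate as sim, pipeline as pl

rng = np.random.default_rng(7)
script = sim.benchmark_script()
truth = sim.simulate_truth(script, rng)
detections = sim.render_detections(
    truth, script.R, script.miss_rate, script.clutter_rate, rng,
    script.width, script.height)

result = pl.track_sequence(detections=detections,
                           config=pl.RunConfig(seed=7),
                           bounds=(script.width, script.height))
metrics = pl.evaluate(result.tracks, truth, match_radius=10.0)
print(f"tracks: {result.tracks.label.nunique()}, "
      f"lineage records: {len(result.lineage)}")
for k, v in metrics.items():
    print(f"{k}: {v:.2f}" if isinstance(v, float) else f"{k}: {v}")
```

prints

```
tracks: 7, lineage records: 2
pap: 99.54
births: 2
terminations: 1
label_switches: 0
cardinality_error: 0.03
```

Seven labels cover the scenario: five initial cells, the mid-sequence
entry and the division daughter (the two `births`); the one
`termination` is the cell that leaves the field of view. PAP 99.5 means
essentially every ground-truth position was covered by the correctly
labelled track, with no identity switches; the colliding pair shares one
merged track through frames 18–20 and recovers its original labels at
the split. The two lineage records both point at parent cell 4 — the
daughter that keeps the parent label and the fresh label created at the
division.

The same run works from the shell:

```bash
aimmtrack simulate --out sim --scenario benchmark --seed 7
aimmtrack track --input sim/detections.csv --out tracks.csv --seed 7
aimmtrack evaluate --tracks tracks.csv --truth sim/truth.csv
```

`aimmtrack track --input <dir-of-frames>` runs the morphological
detector first; `--profile scenario2` switches to the tight-gate,
slow-turn parameter set, `--config file.yaml` overrides any parameter
section.

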