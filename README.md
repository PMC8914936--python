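# limbintent

Action-intention recognition for upper-limb prosthetic control from
wearable inertial sensors.

A person reaching to put on a sock moves their arm in a characteristic
sequence of rests and reaches. `limbintent` takes 50 Hz streams of Euler
angles (roll/pitch/yaw, degrees) and gyroscope rates (deg/s) from three
IMUs — upper arm, lower arm, hand — and answers two questions a prosthetic
hand controller needs answered *during* the movement, not after it:

1. **Which action is underway?** (putting on socks, putting on shoes, or
   tying shoelaces) — so the device can anticipate the remaining steps.
2. **When should the hand open or close?** — grasping happens when the arm
   comes to rest after decelerating.

It is aimed at rehabilitation- and assistive-device engineers who want a
testable, scriptable reference implementation of this recognition chain,
with a synthetic-trace generator standing in for volunteer recordings.

## Method

**Motion units.** A sliding FIFO window of N = 10 samples is labeled from
the 9 angle channels: if every channel's largest adjacent-sample change is
below 0.3°, the window is *static*; if any channel exceeds 1°, it is
*movement* (the band between inherits the previous label). Maximal
movement runs are *motion units*; the 9 angle deltas (angle at unit end
minus unit start) of the first two units form the 18-value feature vector

T = [Δ₁(upper arm r,p,y), Δ₁(lower arm r,p,y), Δ₁(hand r,p,y), Δ₂(…)].

**Template matching.** T is compared with one reference vector R per
action using the distortion

D[T, R] = Σₙ (tₙ − rₙ)²,

the diagonal special case of dynamic time warping (the vectors share a
fixed length; unequal lengths are first reconciled by linear expansion of
the shorter one). The action with the smallest D wins. A default
three-action reference library is bundled; users can supply their own as
JSON.

**Motion state.** Each window of the hand's composite angular velocity
Eᵢ = √(ωxᵢ² + ωyᵢ² + ωzᵢ²) is summarized by four features — sample
variance VAR, net change E_N − E₁, max and min — and classified as
acceleration (1), deceleration (−1) or static (0) by a generalized
regression neural network: a Gaussian-kernel weighted average of stored
training targets, ŷ(x) = Σᵢ wᵢyᵢ / Σᵢ wᵢ with
wᵢ = exp(−‖x − xᵢ‖²/2σ²) in standardized feature space. The single
smoothing parameter σ is chosen by seeded 10-fold cross-validation,
minimizing mean held-out MSE over a grid (0.1–2.0, step 0.1 by default).

**Grasp trigger.** A command is emitted exactly on deceleration → static
transitions of the decoded state stream, toggling the hand between open
and closed.

## Worked example

```python
import limbintent as li

# generate one noisy putting-on-socks trial
trace, truth = li.generate_action_trace(
    li.canonical_script("socks"), li.NoiseSpec(seed=3)
)

# train a motion-state model on synthetic grasp windows
data = li.generate_state_dataset(300, seed=5)
X = data[["var", "diff", "emax", "emin"]].to_numpy()
cv = li.cross_validate_sigma(X, data["state"], sigma_grid=[0.3, 0.7, 1.1], seed=5)
model = li.train_state_model(X, data["state"], cv.selected_sigma)

# full pipeline: action call after the second motion unit + grasp commands
report = li.run_full_pipeline(
    trace, li.PipelineConfig(), model, li.default_templates()
)
print("action:", report.action)
print("distances:", {a: round(d, 3) for a, d in report.distances.items()})
print("margin:", round(report.margin, 3))
print("sigma:", cv.selected_sigma)
print("commands:", [(round(c["t"], 2), c["command"]) for c in report.commands])
```

This prints:

```
action: socks
distances: {'socks': 0.024, 'shoes': 2.712, 'laces': 3.604}
margin: 2.688
sigma: 0.3
commands: [(3.38, 'close'), (6.58, 'open'), (9.78, 'close'), (12.98, 'open')]
```

The trial's first two motion units land within distortion 0.024 of the
socks reference vector — an order of magnitude closer than the runner-up
(margin 2.688) — so the action call is *socks*, made as soon as the second
unit closes. The state decoder then fires one command at the end of each
of the four reaches: the arm decelerates into a rest, and the hand toggles
close/open/close/open at t ≈ 3.4, 6.6, 9.8 and 13.0 s.

The same chain is available from a shell:

```sh
limbintent simulate --action socks --n 1 --seed 11 --out trials/
limbintent classify-action --in trials/socks_000.csv --out action.json
limbintent train-state --in labeled.csv --sigma-grid 0.1:2.0:0.1 --seed 42 --out model.json
limbintent run --in trials/socks_000.csv --model model.json --out report.json
```

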