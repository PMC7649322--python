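# mtsurround

A rate-model simulator of adaptive surround modulation in primate area MT.

Neurons in the middle temporal (MT) area integrate local motion signals
from V1, but their extra-classical surround is not fixed: the same neuron
shows a *facilitatory* surround when the stimulus around it moves
coherently (helping unambiguous motion signals propagate) and an
*antagonistic* surround at discontinuities and high contrast (helping
segment overlapping objects).  `mtsurround` implements a two-stage
V1 → MT model of this switch and the analyses that probe it:

* **Complex V1 units** — opponent motion energy from quadrature Gabor
  pairs and biphasic multi-stage temporal filters, 8 direction channels.
  These carry the aperture problem: along an extended edge they signal
  only the edge-normal motion component.
* **End-stopped V1 units** — shunting dynamics with annular lateral
  inhibition that silence extended-edge responses and preserve the
  unambiguous motion of contour end-points (terminators).
* **ECRF form units** — orientation-tuned difference-of-Gaussians units
  with suppressive surrounds; they respond most at intrinsic terminators
  and are suppressed at occlusion junctions, letting the model tell true
  object ends from spurious crossing features.
* **A recurrent MT sheet** — for each unit, with `S` the logistic sigmoid,
  the surround term is

  ```
  chi = k * S(|a| * (k (Lambda - c_r) - 1 + b Delta + alpha * beta)) - 1,
  alpha = 1 - (Lambda - c_r),   beta = 1 - Delta,
  ```

  where `Lambda` is local image contrast and `Delta` the cosine-weighted
  motion discontinuity over the 7x7 (M = 49) surround window.  `chi` is
  facilitatory (negative) below the contrast threshold `c_r = 0.2`,
  suppressive above it, saturates at `k - 1 = 1`, and applies only to
  active units.  MT activity follows a clipped Euler update of

  ```
  dv/dt = Gmtcx v_cx + Gmtes v_es + Gmtmt1 lambda + Gcsmt kappa
          - Gmtmt2 gamma(t - T_in) - Gmtmt3 xi(t - T_in)
          - tau_mt v - chi
  ```

  with lateral excitation `lambda`, ECRF-gated V1 drive `kappa`, and two
  delayed inhibitions: same-location cross-direction `gamma` and
  long-range cross-direction `xi` (delay `T_in` = 40 steps).

Stimuli (crossing bars, occluded plaids, single bars, drifting gratings)
are generated procedurally with ground-truth masks; there is no external
data and no randomness anywhere in the pipeline.

## Worked example

Two bright bars of equal contrast cross while translating in opposite
directions.  Early complex-V1 responses label each bar with its
edge-normal (wrong) direction; end-stopped and form-gated terminator
signals seed the true directions, which the recurrent MT sheet then
propagates along each bar:

```python
from mtsurround import ModelParams, StimulusSpec, run_model
from mtsurround.stimuli import crossing_bars
from mtsurround.analysis import time_to_disambiguation

p = ModelParams()
seq, gt = crossing_bars(StimulusSpec(kind="crossing_bars"), p)
trace = run_model(seq, p, mode="component")
report = time_to_disambiguation(trace, gt, p)
print(report.latency_steps, report.latency_ms, report.trajectory.max().round(3))
```

prints

```
87 870.0 0.948
```

i.e. after 87 integration steps (870 ms at 10 ms per step) at least 90%
of on-bar locations decode to their bar's true direction, peaking at
94.8%; activity at the crossing junction is suppressed.  The same model
run on an occluded plaid classifies as `"component"` (oblique edge-normal
channels dominate) with the ECRF projection at full strength and as
`"pattern"` (the coherent upward channel dominates, emerging only after a
delay) with the projection removed:

```python
from mtsurround.stimuli import plaid_spec, occluded_plaid
from mtsurround.analysis import pattern_component_class

seq, gt = occluded_plaid(plaid_spec(), p)
for mode in ("component", "pattern"):
    print(mode, pattern_component_class(run_model(seq, p, mode=mode), gt))
```

```
component component
pattern pattern
```

A command-line interface wraps the same pipeline:

```
mtsurround run --stimulus bars --mode component --out out/
mtsurround metrics out/trace.h5
mtsurround sweep-chi --out out/      # chi vs. contrast / discontinuity CSVs
```

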