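# Methods

## Model overview

The simulator is a two-stage rate model on a pixel grid (one model unit
per stimulus pixel, 0.25° per pixel).  Stage one computes three V1
streams from the stimulus frames; stage two integrates a recurrent MT
sheet of 8 direction channels per location with a forward-Euler step of
`dt = 0.01` time units.  One time unit maps to one second for reporting
(`ms_per_time_unit = 1000`), so one step is 10 ms and the recurrent
inhibition delay `T_in = 0.4` is a 40-step ring buffer.

### Complex V1: opponent motion energy

Quadrature Gabor pairs (even/odd phase, carrier along the preferred
motion direction, `f = 1.1` cyc/deg, envelope SDs 0.5°) are combined with
two multi-stage low-pass temporal kernels,

    g_n(t) = (t/tau)^n e^(-t/tau) [1/n! - (t/tau)^2/(n+2)!],

of orders 6 (fast) and 9 (slow), `tau_g = 0.01`.  Per direction the
energy is `(e*g_f - o*g_s)^2 + (o*g_f + e*g_s)^2`, the opposite
direction's energy is subtracted, and the result is half-wave rectified.
Spatial convolution is zero-padded (a border ring of half the patch
width, 8 px, is unreliable); temporal filtering is causal.

Two output conventions matter downstream:

* **Calibration.**  Responses are divided by a frozen constant: the peak
  true-direction response at the intrinsic terminators of a
  unit-contrast reference bar (default geometry, drifting edge-normal at
  2.5°/s).  Anchoring the scale to the *unambiguous* corner signal puts
  terminator responses near 1 — where the end-stopped threshold
  (`rho_es = 0.3`) and the MT surround threshold operate — while the much
  stronger ambiguous extended-edge responses clip at 1, making the stage
  effectively contrast-insensitive for extended contours.
* **Output threshold.**  The activity threshold `rho_cx = 0.13` is
  applied to the normalized maps.  The Gabor envelope smears energy
  several pixels beyond a contour; unthresholded, that halo reaches into
  the low-contrast zone where the MT surround is facilitatory and ignites
  spurious activity.

### End-stopped V1: annular lateral inhibition

    dv/dt = (1 - v) Gescx1 v_cx - v (tau_es + Gescx2 Gamma)

`Gamma` sums same-channel complex-V1 activity over an annular discretized
Gaussian: zero inside a central core, positive out to twice the core
radius.  The core is sized to the motion-energy point spread (the Gabor
patch radius, 8 px; outer radius 16 px, SD 6 px), because a compact
2-D feature is itself smeared over the core by the front end — with a
smaller core every terminator blob inhibits itself and the circuit stops
end-stopping.  Each neighbour contributes only if it individually
exceeds `rho_cx` (per-neighbour thresholding keeps the field smooth).
The shunting form bounds v in [0, 1]; the closed-form equilibrium
`v* = G1 v_cx / (G1 v_cx + tau_es + G2 Gamma)` is used for validation
and for the drive-preference mask below.

### ECRF form units

Oriented difference-of-Gaussians kernels (4 orientations; variances enter
*without* the conventional factor 2, exactly as the model defines them),
applied per frame and half-wave rectified with a 1e-9 noise floor.
Responses peak at intrinsic terminators, are intermediate along extended
contours, and are suppressed at crossing junctions — the form signal that
separates true object ends from occlusion features.

The **form gate** declares ECRF units "active" where the summed response
reaches 92% of its frame peak.  The frame-relative form is what makes one
rule produce both regimes the model needs: when intrinsic terminators are
visible they carry the peak and the gate opens only there; in an occluded
plaid the (uniform) bar bodies carry the peak and the gate opens along
them.  The gated V1 drive `kappa` additionally passes only the direction
channels that end-stopping locally favours (end-stopped equilibrium
within 0.9 of the local best), so the strong `Gcsmt` pathway cannot seed
the recurrent sheet with aperture-ambiguous edge motion at a terminator.
The published gate is binary on form activity; both the activity notion
and the channel pairing are unspecified there, and the choices above are
the ones under which the circuit performs its stated function.

### MT sheet

Per unit and channel:

* lateral excitation `lambda`: 7x7 same-channel window sum, passed where
  the sum exceeds the unit's own activity by `T_mt` and form activity is
  present (gain `Gmtmt_ex = 1`, following the rate equation as printed;
  the strong lateral drive is what lets terminator-seeded activity claim
  whole contours);
* same-location cross-direction inhibition `gamma` (gain 0.1) and
  long-range cross-direction inhibition `xi` (13x13 window, gain 1),
  both read from the population state 40 steps in the past (zeros during
  warm-up);
* the surround term `chi(Lambda, Delta)` (README equation), gated by
  center activity;
* afferent drives `Gmtcx v_cx + Gmtes v_es' + Gcsmt kappa` with `v_es'`
  thresholded at `rho_es`.

The state update is `v <- clip(v + dt * rhs, 0, 1)` — the piecewise
saturation acts on the state, preserving the range while allowing decay
(applying it to the derivative, which forces monotone growth, is
available behind `literal_derivative_saturation`).  Because the surround
applies only to active centers, the right-hand side is discontinuous at
v = 0; the gate is evaluated on the provisional state so that a resting
unit whose base drive cannot overcome its surround stays exactly at rest
(the sliding-mode solution) instead of chattering and leaking activity
through the lateral term.

### Support-aligned contrast field

The analytic `Lambda` (mean absolute center-neighbour intensity
difference over the 7x7 window, out-of-frame neighbours contributing
zero) is used as printed for the modulation-curve analyses.  The field
fed to `chi` during simulation is additionally held at its causal
running maximum over the temporal span of the motion-energy kernels
(0.3 time units) and its local maximum over the surround half-width:
the motion signals the surround gates persist and spread by exactly
those amounts, and gating them with the instantaneous pixel-local
contrast would classify the wake behind (and flank beside) a moving
contour as a facilitatory low-contrast zone.  The ECRF stream feeding
the gates carries the same temporal persistence.

## How the pieces produce the behaviours

* **Aperture-ambiguous edge motion stays subthreshold.**  On a
  high-contrast bar `Lambda ≈ 0.7`, so `chi ≈ 1`; the direct V1 drive
  (0.5) cannot overcome it.  Only locations with terminator evidence
  (end-stopped drive + form-gated drive) exceed the surround threshold.
* **Seeds propagate.**  Lateral excitation from an established region
  (window sums of order 10) dwarfs the surround threshold, so veridical
  activity claims each bar at about 3 px per step; the form gate confines
  propagation to the contour's neighbourhood.
* **The junction is suppressed.**  Where the two bars' claims meet, each
  side's delayed long-range inhibition (sums of order 10-30) exceeds any
  local drive; the contested zone oscillates at a low mean instead of
  resolving, matching the suppressed crossing region.
* **Pattern vs. component.**  With the ECRF projection removed, nothing
  exceeds the surround threshold except the junction of the occluded
  plaid — the only *moving* 2-D feature — whose end-stopped upward signal
  ignites after its integrator crosses `rho_es` and then claims the whole
  figure: pattern selectivity, with the observed delay.  With the
  projection at full strength, the form gate opens along the plaid's bar
  bodies and the edge-normal channels claim each bar immediately:
  component selectivity.

## Study conditions and problem sizes

Defaults: 64x64 frames (16°), bars 10° x 0.5° at contrast 1.0 drifting at
2.5°/s, 280 frames (2.8 s); the occluded plaid uses 80x80 frames, 18°
bars, 160 frames and 6° occluders of luminance 0.35, so that the visible
arms exceed the end-stopping core and clear the other bar's inhibition
range while the occluders cover the hidden terminators' full excursion.
Bars are rendered by 4x4-subpixel coverage so sub-pixel motion is smooth.
The drift speed is a typical slow MT stimulus speed; at much slower
speeds the rendered stimulus barely changes between frames and the
energy model is starved, while much faster speeds drive the bars out of
frame within the integration window.  A full two-bar run takes ~10 s on
one CPU; the plaid runs ~10-30 s.

The measured disambiguation latency under these conditions is 87 steps
(870 ms at the 10 ms/step mapping), reported by `scripts/acceptance.py`.
The biphasic temporal kernels alone span ~30 steps, so latencies below
~100 ms from stimulus onset are not reachable under this time mapping;
the latency should be read as a property of this implementation's
operating point, not a physiological prediction.

## What the synthetic stimuli do and do not emulate

The generator produces noise-free, rigidly translating, hard-luminance
figures with exact ground truth.  It does not emulate luminance noise,
texture, natural contrast statistics, dot-field stimuli, or
depth/disparity cues; passing tests therefore demonstrate the circuit's
mechanisms (end-stopping, form gating, adaptive surround sign,
propagation, winner-take-all), not robustness of those mechanisms to
real-scene variability.

## Numerical choices

* Forward Euler at `dt = 0.01` throughout; all convolutions zero-padded;
  FFT-based spatial convolution, causal FIR temporal filtering.
* Ties in direction decoding break to the lowest channel index;
  locations are "decoded" only above an activity threshold (0.05).
* The disambiguation criterion is 90% of on-bar locations decoding to
  their bar's true direction (reported alongside the latency).
* Analytic sign structure under the default constants: at zero
  discontinuity the surround term crosses zero exactly at
  `Lambda = c_r = 0.2`; at zero contrast it crosses at `Delta = 1/6`.
  The discontinuity term's `1/(10 M)` normalization makes `Delta`
  operationally small (≤ ~0.05) for sparse channel maps, so the
  simulated surround sign is in practice contrast-led.

## Known limitations

* The delayed blanket inhibition produces a slow breathing limit cycle
  in contested regions and a gradual decay of claimed territory behind a
  moving figure; steady-state metrics are therefore taken at the
  disambiguated epoch or as averages over the final delay windows.
* Pattern/component selectivity is exposed as a binary mode (projection
  gain 2 or 0) plus a continuous `gcsmt` dial; intermediate gains are
  not characterized.
* The surround is isotropic; offset/asymmetric surround geometries and
  speed or disparity tuning are out of scope.
* With unequal bar contrasts the dimmer bar's form responses fall below
  the frame-relative gate, weakening its terminator seeding; the
  depth-ordering percept this produces is rendered (brighter bar drawn
  in front) but not further analysed.
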