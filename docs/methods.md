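# Methods

## The model

The muscle–tendon complex (MTC) is lumped into three components: a
contractile component (CC) representing the fibers, a parallel elastic
component (PEC) for connective tissue and titin in parallel with the
fibers, and a series elastic component (SEC) for tendon plus aponeurosis
in series with both. The SEC therefore carries the total lever force and
the geometry is `l_MTC = l_SEC0 + Δl_SEC + l_CC`. The CC force is the
product `A · F_im · f_l(l_CC) · f_v(v_CC)`:

- **Force–length** `f_l` is piecewise linear with normalized breakpoints
  `l1 < l2 < 1 ≤ l3 < l4` (fractions of the optimal CC length
  `l_CCopt`): zero below `l1`, rising to `f_c` at `l2`, then to 1 at the
  optimum, a plateau to `l3`, and a linear descent to zero at `l4`. The
  second ascending segment is the line through `(l2, f_c)` and `(1, 1)`,
  which is the only slope consistent with `f_l(l_CCopt) = 1`.
- **Force–velocity** `f_v` is the Hill hyperbola
  `(v_CCmax − v)/(v_CCmax + v/curv)` with `v ≥ 0` the shortening speed in
  `l_CCopt/s`; `curv = a/F_im` is the inverse curvature (the Hill
  asymptote `a` is never materialized separately). The relation is only
  well formed under this magnitude convention: `f_v(0) = 1` and
  `f_v(v_CCmax) = 0`.
- **Eccentric extension.** Lengthening was not characterized in situ, so
  the eccentric branch is a modelling choice: a Katz-style hyperbola
  continuous at v = 0, saturating at `f_v_ecc_max` (default 1.5). Its
  slope at v = 0 is `ecc_slope_factor` times the concentric slope,
  default 1.0, i.e. a C1-continuous join. A steeper branch (factor 2–6
  is sometimes used) makes the force decay after an active stretch
  unphysically slow — with factor 2 the plantaris ramp/reference
  transient is still ≈1.4% F_im five hundred milliseconds after the ramp,
  which would masquerade as force enhancement in a model that has none.
  Both the factor and the cap are per-record parameters.
- **Activation** follows `dA/dt = (1 − A)/τ` with `A(0) = 0`; after the
  stimulation ends, A decays to zero with `tau_off` (default: the same τ,
  the minimal assumption — only the rise was characterized in situ).
- **SEC**: exponential toe
  `F1/(e^{k_sh} − 1) · (e^{k_sh·Δl/Δl_SEC1} − 1)` up to the transition
  `(Δl_SEC1, F1)`, linear with stiffness `k` beyond. `k` can be stored
  (the packaged records store the published per-animal fits) or derived
  from stiffness continuity, `k = F1·k_sh·e^{k_sh}/(Δl_SEC1(e^{k_sh}−1))`;
  the stored value is used by default. Note the published mean `k` is not
  the continuity formula applied to the published mean toe parameters
  (30.3 vs 24.0 N/mm for GAS) because per-animal fits do not commute
  with averaging.
- **PEC**: `k1 (e^{k2·Δl} − 1)` above its slack length `l_PEC0`.

Units are fixed package-wide: mm, N, s, g, degrees; cross-sections in
cm²; normalized CC velocities in `l_CCopt/s`. The packaged GAS/PLA/SOL
records are read from TOML fixtures and round-trip bit-exactly through
the reader/writer.

## Forward simulation

The model is quasi-static: no mass or lever inertia, so the only
mechanical state is `l_CC`, plus the closed-form activation. At each
instant the SEC/PEC balance dictates the force the CC must produce;
inverting the force–velocity relation turns that demand into a CC
velocity. Length-controlled protocols impose `l_MTC(t)`; force-controlled
(isotonic) operation clamps the total force, so the SEC stretch is
constant and the lever follows the CC.

Numerical choices:

- LSODA with `rtol 1e-10`, `atol 1e-11`, maximum step `min(5 ms, τ/4)`,
  integrated phase-by-phase between protocol discontinuities (stimulation
  edges, ramp edges, clamp transitions); output resampled at the protocol
  sample rate (default 1 kHz).
- Where the drive `A·F_im·f_l` falls below 1e-7 `F_im` the inversion is
  ill-posed (an inactive CC); the velocity then follows a bounded
  relaxation law `v = −v_CCmax·clip(F_req/(1e-3·F_im), −1, 1)` that holds
  rest states and relaxes slack transients without chatter.
- When the demanded force is unreachable — above the eccentric cap, or
  negative (a stretched PEC pulling against a slack SEC during the
  terminal recoil of a fast release) — the CC speed is capped at
  `±v_CCmax` and the sample is flagged `sat`. In the packaged protocols
  flagged samples occur only while the lever force is below 0.25% F_im.
  On all unflagged samples the recorded state satisfies
  `|F_SEC − F_CC − F_PEC| < 1e-4 N` (the conservation test asserts both).
- Isotonic mode releases the length clamp either at a set time (after
  the tetanic plateau; the generator default, so activation is saturated
  during the velocity measurement) or when the force first reaches the
  afterload; the clamp disengages and the length is held once the CC can
  no longer shorten against the load.

Halving the maximum step changes terminal forces by far less than 0.1%;
the isometric steady state agrees with the independent static equilibrium
solver to better than 0.5%.

## Synthetic in-situ experiments

The generator emulates the in-situ protocol families so the estimation
pipeline can be validated against known ground truth:

- **Isometric series**: 15–20 lengths with 1–2 mm increments, coarser
  below the working range and ~1 mm through the plateau region, starting
  with the CC just below its active range and ending exactly where the
  passive force reaches 0.2 F_im (muscles were not stretched further in
  situ to avoid damage). Passive steady forces are recorded per length.
- **Isotonic after-load releases**: ten trials at 0.1–0.9 F_im, each a
  quick release from the tetanic plateau into a force clamp.
- **Fast isokinetic release**: lever speed `2·v_CCmax·l_CCopt` mm/s
  (twice the CC speed limit), long enough to slacken the SEC fully.
- **Tetanic rise** at the optimum MTC length for the activation fit.
- **History ramps**: shortening and lengthening ramps of `0.3 l_fm` at
  0.35/0.7/1.4 `l_fm/s` (`l_fm` = mean fascicle length), starting at the
  optimum ±0.15 `l_fm` after a 300 ms isometric pre-contraction (the
  in-situ pre-contraction was 200–400 ms), stimulation continuing 500 ms
  past the ramp (1300 ms for the fatigue-resistant soleus), each paired
  with an isometric reference of equal duration at the target length.

Measurement noise is additive Gaussian on the sampled force channel,
SD 0.5% F_im by default (the recordings' noise spectrum was not
characterized; this is the simplest defensible model and configurable),
applied after simulation; lever-position noise and a per-coordinate
digitizer jitter (0.07 mm, the stated accuracy of the manual digitizer)
are separate knobs. All randomness flows through one seeded generator and
regeneration with the same seed is bit-identical.

The experiment set also carries anatomical metadata: muscle mass,
reference MTC length, mean fascicle length, and the series-elastic rest
length `l_SEC0`. The last is essential: force–time–length recordings
alone cannot identify the absolute split of the in-series rest lengths —
shifting `l_SEC0` by δ while shifting `l_CCopt`, `l_PEC0` and
renormalizing breakpoints and velocities reproduces identical traces.
Some externally measured length must anchor the split, and the package
uses the series-elastic rest length for that role.

What the generator does **not** emulate: stimulation artifacts, fatigue,
lever compliance, temperature drift, real (colored) recording noise, and
— deliberately — history effects themselves. Passing recovery tests
therefore show that the pipeline inverts this model faithfully under
idealized recording conditions, not that it is robust to every
pathology of real preparations.

## Parameter estimation

Stages run in dependency order; estimators read only measurable channels
(time, lever position, force, stimulation flag), protocol metadata and
the anatomical anchors.

1. **Series elasticity.** Primary method: the force-step (quick-release)
   analysis. At the instant the length clamp releases into a force clamp
   the lever jumps while the speed-limited fibers have not moved, so each
   jump equals the SEC elongation difference between the pre-release
   force and the afterload exactly. The pre-release force is extrapolated
   to the release instant (it still creeps toward the tetanic plateau)
   and the post-release lever position is taken at, or extrapolated to,
   the step. The SEC law is fitted to the ten jump equations with
   `F1, Δl_SEC1, k_sh, k` free, under a tendon-stiffening constraint
   `k ≥` toe-end stiffness — without it Eq-style toe+line curves admit a
   second exact interpolant that rejoins the linear branch where the toe
   curve re-crosses it, with stiffness *dropping* at the transition,
   which tendon does not do. Because the jumps constrain only elongation
   differences over the sampled load range, the transition force can be
   indeterminate within a load-free interval; the fit profiles the cost
   over `F1` and reports the midpoint of the flat interval (which
   collapses onto the optimum when `F1` is well identified), then locally
   refines all SEC and PEC parameters jointly against the passive sweep
   (residuals in force space, noise-weighted). Fallback when no isotonic
   trials are available: the fast-ramp reconstruction with fiber motion
   capped at the speed bound, iterated to self-consistency — documented
   as approximate (the capped correction overestimates fiber motion
   because the Hill hyperbola keeps fiber speed low until the force is
   low).
2. **Parallel elasticity.** Passive lever forces are attributed to the
   PEC after subtracting the SEC stretch at the measured force (series
   arrangement); `k1, k2, l_PEC0` are fitted jointly. The "last length
   with zero force" rule (threshold 0.5% F_im) only initializes
   `l_PEC0` — the exponential toe is so flat that it overestimates the
   slack length by several millimetres if taken literally.
3. **Active force–length.** CC lengths are recovered per series point by
   inverting the fitted SEC at the measured steady force; the fitted PEC
   force at that CC length is subtracted (the naive active-minus-passive
   subtraction is biased because the CC sits longer when passive). The
   piecewise-linear relation is fitted with free breakpoints,
   parametrized by positive increments so the ordering invariants hold by
   construction. Fewer than three points beyond the plateau flag the
   descending limb low-confidence — the passive-force cap truncates the
   long-length data, so that limb is genuinely extrapolated.
4. **Force–velocity.** Within each force-clamp plateau (within 1% of the
   afterload for ≥ 50 ms; activation saturated because the release
   happens well after the rise) every sample yields a normalized
   (force, velocity) pair after correcting for the instantaneous
   force–length factor and PEC force; pairs from all usable trials
   (≥ 4 required) are pooled into one hyperbola fit. Under noise the
   lever-implied CC trajectory is smoothed (Savitzky–Golay) before
   differentiation.
5. **Activation.** The required activation at each sample of the tetanic
   rise is obtained by inverting the model chain (SEC stretch → CC
   length → CC speed → force–velocity factor) and fitted with
   `1 − e^{−t/τ}`.

Nonlinear fits use trust-region least squares with multi-start for the
multi-modal stages and tolerances at machine precision; stage failures
are recorded and the report is emitted with partial results. With noise
off, every parameter of every packaged record is recovered to well under
1% except the PLA SEC transition parameters (~0.6% after profiling);
under the default noise, the median recovery error of `v_CCmax` and
`curv` over 20 seeds stays below 5% for all three muscles (occasional
outlier seeds produce poor force–velocity fits when the SEC toe is
misestimated — visible in the per-stage residual diagnostics).

The effect-size helper implements Cohen's f (population SD of the group
means over the within-group SD) with the small/medium/large thresholds at
0.10/0.25/0.40.

## History effects

Force depression (FD, after active shortening) and force enhancement
(FE, after active stretch) are the force differences between a ramp
experiment and its isometric reference at the same target length, read at
the single sample nearest 500 ms (GAS, PLA) or 1300 ms (SOL) after the
ramp end and expressed in % F_im (a 20 ms averaging window is optional).
Target lengths must agree within 0.1 mm. Values are reported as positive
magnitudes with the direction kept separately. A millimetre-based
fallback protocol (±2 mm start offsets, 4 mm ramps at 5/10/20 mm/s) is
available for records without a fascicle length.

The module measures; it does not model. A memoryless Hill model produces
|FD|, |FE| < 1% F_im once transients decay — the packaged measured values
(5.8–17.8% F_im) are included as reference data precisely because the
model cannot reproduce them. The measured table's qualitative structure
(FD falling with ramp velocity, FE independent of it) is exposed through
a monotonicity helper.

## 3D architecture

Digitized fascicles are 20-point polylines in mm. Fascicle length is the
polyline arc length (digitization at 20 points implies curvature
matters); the chord is exposed alongside. The pennation angle is the
angle between the fascicle chord and the muscle's line of action — the
unit vector from the mean origin landmark to the mean insertion — folded
into [0°, 90°]; a length-weighted per-segment variant is provided for
sensitivity checks. Summaries report count and mean ± sample SD (n − 1)
of lengths and angles and are invariant under rigid motions applied to
fascicles and landmarks jointly.

The plain-text reader auto-detects three layouts: blank-line-separated
point blocks, a single run of rows in fixed 20-row blocks, and rows with
a leading fascicle-index column; rows may be space-, comma- or
semicolon-delimited, `#` starts a comment. Malformed fascicles raise
with line numbers in strict mode and are arc-length-resampled to 20
points in lenient mode. The writer emits blank-line-separated blocks at
full float precision (bit-exact round trip).

The synthetic bundle generator draws lengths and pennation angles from
truncated normal distributions, attaches fascicles over a proximal sheet
(mirrored across the axis for bipennate bellies), bows each fascicle
into a circular arc with a midpoint sagitta of 2% of its length — so
arc- and chord-length conventions differ measurably while the chord
pennation equals the drawn angle exactly — and jitters every point with
the digitizer SD. Point jitter only inflates polyline arc lengths
(E|seg + ε| ≥ |seg|); the inflation bound `2·19·σ²/segment` is part of
the noisy-recovery test, mirroring a bias that real digitized lengths
carry too.

## Problem sizes

The test suite and the acceptance script run the synthetic protocols at
1 kHz sampling with 15–20 isometric lengths, 10 isotonic loads, one fast
release and one tetanus per muscle; the Monte-Carlo robustness study uses
20 noise seeds per muscle applied to the memoized noise-free base
simulations. These sizes reproduce the published derived quantities to
well within the stated tolerances while keeping a full run in minutes on
one core.

## Known limitations

- The eccentric branch and the deactivation time constant are modelling
  extensions, not measurements.
- `l_SEC0` (and hence the absolute CC/SEC length split) must come from an
  anatomical measurement; it is not identifiable from the recordings.
- The SEC transition force is only identified up to the afterload
  spacing when the stored linear stiffness is close to the
  continuity-derived value (quasi-smooth transition).
- The descending limb of the force–length relation rests on few points
  because of the passive-force cap and is flagged accordingly.
- The quasi-static simulator cannot balance a stretched PEC against a
  slack SEC (no fiber mass); such samples are flagged rather than hidden.
- Parameter records describe means across animals; per-animal variation
  (notably the large PEC spread) is not modelled.
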