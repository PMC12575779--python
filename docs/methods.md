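# Methods

`jawfl` reconstructs a complete in vivo / in situ muscle force–length (FL)
analysis for a jaw-closing muscle — signal conditioning, FL-curve
construction, bite-feature extraction, operating-range mapping, and the
accompanying statistics — with a synthetic-data generator that plays the
role of the animal experiment.  Because every generated recording carries
its ground truth, each stage of the analysis can be validated by parameter
recovery rather than by eye.

## The model behind the generator

**Active force–length curve.**  Active stress at strain
ε = (L − L_O)/L_O (tetanic optimal length L_O) is a unimodal, flat-topped
exponential

    σ_act(ε) = σ_O · exp(−|ε/w|^p),  w = w_asc (ε < 0) or w_desc (ε ≥ 0)

with default half-widths w_asc = 0.45, w_desc = 0.40 and exponent p = 2.0.
At ±25 % strain the active curve is at ≈ 70 % of σ_O, with a slightly
gentler ascending limb, matching the qualitative geometry of whole-muscle
FL curves.  The defaults were chosen so that a third-order polynomial — the
curve family the analysis stage fits — can represent the shape over a
±25 % strain ladder without material bias, while still presenting genuine
non-polynomial curvature; a needle-sharp peak would make the cubic fit the
limiting factor rather than the data.

**Twitch curve.**  The twitch FL relationship is the tetanic shape
translated right by the plateau shift s (percent of tetanic L_O) and
scaled by the twitch/tetanic force ratio r:

    σ_twitch(ε) = r · σ_O · exp(−|(ε − s/100)/w|^p)

i.e. a pure activation-dependent plateau shift.  Population draws use
s ~ Normal(11.3, 2.9) % truncated positive and r ~ Normal(0.123, 0.043)
truncated to (0, 1).

**Passive curve.**  Monotone exponential, zero at and below a slack strain
of −0.1:

    σ_pass(ε) = A · (exp(k·(ε + 0.1)) − 1),  k = 5,

with A set so passive stress is 20 % of σ_O at +25 % strain (≈ 3 % of σ_O
at L_O).  The gentle stiffness keeps the cubic passive fit — which the
shortening adjustment leans on — well conditioned across a twitch ladder
that reaches ≈ +40 % tetanic strain.

**Fixed-end contraction.**  During stimulation the fascicles shorten
against the series elastic element linearly in relative force,

    L = L_set − c · F/F_O,   F = PCSA · (a(t)·σ_act(ε(L)) + σ_pass(ε(L))),

solved per sample by damped fixed-point iteration (converges to 1e−13).
The series stretch at peak tetanic force, c, is drawn as a fraction of L_O
(Normal(0.097, 0.028), truncated to [0, 0.15]), i.e. ≈ 0.7 ± 0.2 mm at
the population-mean L_O of 7.2 mm.  Drawing c in absolute millimetres
independent of muscle size occasionally produced preparations whose series
stretch exceeded a quarter of the fascicle length — an anatomy no real
muscle-tendon unit has, and one whose FL ladder genuinely cannot bracket a
plateau; compliance that scales with size resolves this without changing
the stated population magnitude.

**Ergometry ladders.**  A session is 9 fixed-end contractions (250 ms
tetanic trains or single twitches, force and fascicle length at 4 kHz)
whose *fascicle lengths at peak force* span ±25 % strain about the
protocol's own optimum.  Set lengths are raised by the series stretch
expected at each point's peak force, and the twitch ladder is centered on
the twitch optimum: this mirrors how an operator actually runs the
protocol — watching the sonomicrometry readout over consecutive
contractions and repositioning the motor until force drops on both sides
of the plateau.  A ladder frozen at tetanic set lengths leaves the twitch
plateau (≈ 11 % to the right) under-sampled and biases the recovered shift
by 1–2 percentage points.

**Calibration contractions.**  Four to five 300 ms contractions near L_O
provide paired buckle-voltage and motor-force traces.  Voltage is linear
in force; Gaussian noise is scaled from the force excursion of the tetanic
rise so the per-contraction regression r² lands near 0.92, inside the
0.87–0.96 range such buckle validations produce.

**In vivo bites.**  Each bite trial contains raw EMG (mV), sonomicrometry
voltage at 520 Hz, buckle voltage, a schematic gape trace and a TTL sync
marker, all others at 4 kHz.  The EMG burst is band-limited (50–900 Hz)
zero-mean noise under a fast-attack envelope; its amplitude saturates with
food hardness E as E/(E + 4 MPa), so recruitment rises steeply across soft
foods and plateaus above ~20 MPa.  Fascicle strain at peak force rises
with hardness (≈ 0 for the softest to ≈ +0.19 for the hardest food) while
the shortening excursion falls (≈ 0.145 → 0.065), so soft-food bites sit
near the FL plateau and hard-food bites on the descending limb, with a
cohort-mean power-stroke strain magnitude near 10 %.  Peak force follows a
linear EMG→force law (17 N per mV·s of integrated burst) with 6 %
lognormal-like jitter; the trial's truth block records the *realized*
onset time, lengths, peak force and integrated EMG of the emitted traces,
which is what feature extraction is scored against.

Default instrument noise: 0.01 N / 0.01 mm on ergometry force/length,
1 mV RMS on the amplified buckle bridge, 0.02 mm equivalent on
sonomicrometry, 0.01 mV on the EMG baseline.  These are assumptions about
ordinary servo/bridge/DAQ noise floors, not measured values; the r²
regime of the buckle calibration is modeled separately as transmission
residual.

## Analysis pipeline

**Signal conditioning.**  EMG: optional zero-phase FIR band-pass
(default band 30–1000 Hz, off by default because the simulated hardware
chain is already band-limited) → baseline-mean subtraction → full-wave
rectification.  Sonomicrometry: length = (gain·V − epoxy_offset) ·
segment_factor, then a quintic smoothing spline.  The epoxy correction is
an additive length offset (a transit-time delay through the crystal
coating maps to a fixed distance at fixed sound speed); the segment
correction is multiplicative so that strain is invariant to which part of
the fascicle the crystals span.  Nonpositive lengths are masked as
dropouts, never silently interpolated.  Buckle force: per-contraction OLS
of voltage on motor force over the stimulation-to-peak rise; the model
slope is the mean of per-contraction slopes; in vivo force is
(V − rest mean)/slope so a designated resting window maps to exactly 0 N.
Channels are put on one clock by PCHIP resampling on a grid anchored at
the sync-marker edge.

The quintic spline's smoothing parameter ("s.d.", conventional band
0.01–0.05) is the admissible RMS residual as a fraction of the signal
range; the FITPACK residual budget is n·(sd·range)².  Degree-≤5
polynomials are reproduced exactly; with sd at the band's top a
white-noise trace keeps most of its shape but loses variance.

**FL curves.**  Each contraction reduces to a passive point
(pre-stimulation length, mean passive force) and an active point (length
at the force peak, peak force).  Cubics are fit by least squares on the
length axis in stress units (stress = F/PCSA with
PCSA = mass·cosθ/(ρ·L_f), ρ = 1.06 g/cm³).  Active force is corrected for
shortening during stimulation by subtracting the passive cubic evaluated
at the *peak-force* length rather than the pre-stim length.  L_O is the
interior maximum of the active cubic — an edge optimum raises an error
rather than being clamped, because it means the ladder failed to bracket
the plateau.  F_O is the cubic at L_O; the plateau shift is
100·(L_O_twitch − L_O_tet)/L_O_tet; the fatigue check passes at ≥ 90 % of
F_O inclusive.  Preparations whose lengths come from motor position
rather than sonomicrometry are selected by a prep flag
(`use_motor_length`).

**Bite features.**  EMG onset (T_ACT) is the first time a
moving-average envelope of the rectified EMG exceeds baseline mean +
k·SD (k = 3, SD of the raw rectified baseline) for ≥ 10 ms.  The raw
rectified signal crosses zero every few carrier periods, so the
persistence test runs on the envelope; taking the threshold statistics
from the raw signal rather than the envelope keeps 3·SD conservative
(on the smoothed scale it would be ~19 SD), eliminating false triggers
from baseline noise.  T_MIN is the post-onset force peak located on a
20 ms envelope-smoothed force and refined by a local quadratic fit
(±40 ms) whose vertex gives both the peak time and F_MAX — reading a
single noisy sample at the raw argmax carries a max-of-noise bias of
several percent on the weakest bites, while the quadratic fit sits near
the white-noise information floor (~0.25 % SD).  The seven response
variables per power stroke are the integrated rectified EMG over
[T_ACT, T_MIN], L_MAX (length maximum in [T_ACT − 50 ms, T_MIN] — the
fascicles typically peak at bite onset, before this muscle's own EMG
onset, because other jaw adductors act first), L_ACT, L_MIN, the
power-stroke strain (L@T_MIN − L@T_ACT)/L_O_tet, the force rise
F_MAX − F(T_ACT), and F_MAX.  All strain normalization uses the same
preparation's tetanic L_O.  (The integrated-EMG unit is written mV·s;
the conventional "mV/s" label for this quantity is dimensionally an
area.)

**Operating-range mapping.**  Each bite maps to
(strain at F_MAX, F_MAX/PCSA) on its preparation's submaximal tetanic
curve; the plateau is the strain interval where the active cubic stays at
or above 95 % of F_O (threshold configurable — the literature does not
define plateau edges), ascending/descending lie below/above, and strains
outside the fitted range are classified but flagged as extrapolated.
Per-preparation L_O is required; pooling L_O across animals would mix
normalizations.

**Statistics.**  Two-factor linear models (individual × food hardness,
both categorical, hardness E values carried as labels) with Type-III sums
of squares under sum-to-zero contrasts (Type-I available), per-term F and
partial η² = SS_term/(SS_term + SS_residual); individual is a fixed
effect, mirroring the "independent effect" design, and no multiple-testing
correction is applied (flagged in the report).  EMG–force relationships
use simple OLS with t-based pointwise 95 % confidence (LCL/UCL) and
prediction (LPL/UPL) limits.  Fitting and ANOVA go through statsmodels;
the package's own tests check the decomposition against hand-worked sums
of squares and the null type-I error by simulation.

## What the synthetic data do and do not establish

The generator reproduces the statistical structure the analysis assumes:
saturating hardness–recruitment coupling, hardness-dependent operating
lengths, a pure plateau shift, linear buckle response, band-limited EMG.
Passing tests therefore demonstrate that the pipeline recovers known
parameters under that structure at realistic noise levels — they do not
demonstrate robustness to motion artifacts, electrode drift, crystal
misalignment, chewing-side alternation, or bites the semi-automated
windowing of real experiments would reject.  No force–velocity or
history-dependent effects are modeled, EMG is not decomposed into motor
units, and the gape trace is schematic.

## Numerical choices and known limitations

* Problem sizes: recovery checks run 9-muscle noiseless cohorts, a
  20-replicate noisy shift cohort (180 muscles), 100-bite feature
  recovery, 200-point region classification and a 2000-replicate null
  simulation; together they complete in about a minute on one core.
* The recovered plateau shift carries a small positive bias
  (≈ +0.3 pp cohort mean) from cubic-fit asymmetry at extreme truths;
  it is well inside the recovery tolerances and reported, not corrected.
* Cubic coefficients are ordered highest degree first throughout
  (`numpy.polyval` convention).
* Fixed-point contraction solves use 0.5-damped iteration, tolerance
  1e−13, ≤ 300 iterations.
* Degenerate inputs fail loudly: ladders with < 4 lengths, monotone
  cubics, zero-variance calibration force, inverted windows, empty GLM
  cells (named in the error), non-closing gape cycles.
* Determinism: every stochastic routine takes an explicit seed and is
  reproducible bit-for-bit; reports embed no timestamps, so reruns are
  byte-identical.
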