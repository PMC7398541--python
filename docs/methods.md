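# Methods

`cisrd` simulates the complete chain by which a cochlear implant (CI)
converts an acoustic spectral-ripple stimulus into auditory-nerve-fiber
(ANF) activity, and scores how well the evoked activity distinguishes a
ripple spectrum from its phase-inverted counterpart. The scientific
question the pipeline addresses is how the electrode-to-fiber distance —
through current spread and the channel interactions it creates — shapes
spectral resolution.

## Stimuli (`cisrd.stimulus`)

Rippled noises are sums of 200 pure tones spanning 100–5,000 Hz with
independent uniform random phases. The tone frequencies are log-spaced
(the ripple peaks are equally spaced on a log axis, so log spacing keeps
the per-band tone count constant across the 22 analysis bands). Tone
*power* follows a full-wave-rectified sinusoidal envelope in
log2-frequency,

    env_dB(f) = depth * | sin( pi * density * log2(f / f_lo) + phi ) |,

with depth = 30 dB, density in ripples/octave (1, 2 or 4), and phi = 0
(standard) or pi/2 (inverted); for a period-pi rectified sinusoid the
pi/2 shift interchanges peaks and valleys exactly. The phase convention
applies to the pre-rectification argument; the complementarity of the
two variants at their extrema is asserted by tests. Stimuli last 200 ms
with 50 ms raised-cosine rise/fall ramps, are sampled at 20 kHz (>= 4x
the highest component), and are normalized to a fixed RMS (0.1 arbitrary
pressure units). The same seed yields identical component phases for the
standard and inverted variants, so a stimulus pair differs only in its
spectral envelope.

## ACE coding (`cisrd.ace`)

An n-of-m strategy with m = 22 bands and n = 8 maxima per frame at
900 pulses/s/channel. Processing steps:

1. optional first-order high-pass pre-emphasis at 1.2 kHz;
2. a 22-band filterbank of 4th-order Butterworth band-passes on a
   logarithmic partition of 100–5,000 Hz. Fourth order is the lowest
   that keeps inter-band leakage well below a 30 dB spectral ripple
   (second-order skirts lift ripple valleys by ~6 dB). Band envelopes
   are the magnitudes of each band's analytic (Hilbert) signal, sampled
   at the 900 Hz frame instants — fully deterministic;
3. per frame, the 8 largest band envelopes are selected (ties broken
   toward the lower band index);
4. envelopes are normalized by the stimulus-wide maximum, floored at a
   base level of 4/256, compressed by the clinical logarithmic
   loudness-growth function `log(1 + 416.2 p) / log(1 + 416.2)`, and
   mapped onto the channel's electrical dynamic range [T, C]. Envelopes
   below the floor emit no pulse;
5. selected channels fire biphasic, cathodic-first, 25 us/phase pulses
   in base-to-apex order, onsets separated by floor(1e6 / 7200) = 138 us
   (integer truncation, documented; the aggregate rate of 8 x 900 pps is
   7200 pps). Pulses never overlap (non-simultaneous stimulation).

Band 22 (highest frequencies) drives electrode 1 (most basal); band 1
drives electrode 22 (apical), mirroring cochlear tonotopy.

The acoustic dynamic-range window preceding the [T, C] map — the floor
and the use of the stimulus-wide maximum as the ceiling — is a design
choice (the per-stimulus maximum acts as a simple automatic gain
control); both the floor and the loudness-growth curvature are exposed
in `AceConfig`.

## Geometry and current spread (`cisrd.geometry`)

The electrode array is unrolled onto a straight line: 22 hemispherical
electrodes (radius 0.18 mm) with inter-electrode spacing graded linearly
from 0.8 mm at the base to 0.4 mm at the apex (Nucleus CI24-like). One
fiber track faces each electrode on a parallel line offset by the
electrode-to-fiber distance D, measured from the electrode *center*;
the five study conditions are D = 0.23, 0.68, 1.18, 1.88 and 2.08 mm
(surface distances 0.05–1.9 mm). Each fiber runs perpendicular to the
array with its drive node (the 9th active node) aligned with its
electrode. D is uniform along the array — a deliberate simplification.

Current reaching a fiber compartment decays exponentially with the
center-to-compartment Euclidean distance d:

    I_node = I_electrode * exp(-d / lambda),      lambda = 2.784 mm,

equivalent to 3.12 dB/mm. "Without current spread" retains only the
fiber's own electrode as a source. Because the apical spacing is
narrower, spread reaches neighboring fibers apically before it does
basally — this produces the apical-first spread of excitation seen in
the experiments.

## Fiber model (`cisrd.fiber`, `cisrd._cable`)

Each ANF is a 47-compartment cable: a peripheral axon (terminal node,
then three myelinated internodes separated by nodes), the cell body, and
a central axon of 20 internodes each followed by a node — 23 active
Ranvier nodes. Nodes carry Hodgkin–Huxley-type Na (m^3 h) and K (n^4)
currents; internodes and the soma are passive (low capacitance, high
resistance, per myelination). Na rate constants are the
Schwarz–Eikhof-style cat-node set used widely in stochastic ANF
modelling; K kinetics are classic HH n-gate rates temperature-scaled to
body temperature. The leak reversal is set per node so that 0 mV
depolarization (rest, -78 mV absolute) is an exact equilibrium.

Key electrical constants (all in `FiberParams`, none hard-coded):
2 um node diameter, 2 uF/cm^2 nodal capacitance, 25 mS/cm^2 nodal leak
(nodal time constant ~80 us), 70 Ohm*cm axoplasm, 250/300 um
peripheral/central internodes. Maximal nodal conductances are
g_Na = 231 nS and g_K = 50 nS. These are expressed as channel count x
unitary conductance with *lumped* unitary conductances (1000 x 231 pS
Na; 300 x 167 pS K): the count sets the stochastic gating-pool size and
hence the Fox noise variance, giving a relative spread of threshold of
~3–4%, in the range reported for cat fibers, while the total conductance
stays at the canonical value. A 16x larger pool (same conductance)
measurably steepens the firing-efficiency curve, which is asserted by a
test.

Stochasticity follows the Fox diffusion approximation: each gating
variable receives a Gaussian perturbation with variance
(alpha (1-x) + beta x) dt / N per step, clamped to [0, 1]. The variance
expression is validated against binomial subunit statistics in a test.
For speed, noise is injected every 5 us (variance scaled by the stride)
rather than every integration step; 5 us is well below the h and n time
constants and ~half of tau_m at rest, and all stochastic results quoted
here were obtained with this setting.

Extracellular stimulation uses the activating-function formalism: the
per-compartment stimulus current times the extracellular resistivity
(rho_e, 300 Ohm — an arbitrary transfer scale, since all levels are
calibrated) gives the extracellular potential V_e; the discrete
second difference of V_e along the cable, weighted by the axial
conductances, drives the membrane. A cathodic (negative) phase
depolarizes the node nearest the electrode.

Integration: Crank–Nicolson on the linear cable operator (tridiagonal
Thomas solve per step) with ionic conductances frozen at gate values
updated by exact exponential (Rush–Larsen) steps; rate functions are
tabulated on a 0.1 mV grid. dt = 1 us by default; the experiment
drivers use dt = 2.5 us (10 steps per 25 us pulse phase), which the
half-step refinement test bounds at <1% trajectory error in the
deterministic limit. The noise-free integrator is also cross-checked
against an independent stiff-ODE (LSODA) solution of the same equations
on a 3-compartment toy fiber.

Propagated spikes are detected at the 20th active node as upward
crossings of -20 mV absolute (+58 mV re rest) with a 500 us lockout.
Conduction latency from drive to record node is ~0.4 ms; the absolute
refractory period is ~0.7–1.0 ms.

The model deliberately omits an explicit adaptation current: none of the
phenomena simulated here (onset-window calibration, 138 us two-pulse
interaction, 200 ms neurograms at 900 pps/channel) requires
slower-than-refractory dynamics, and the refractoriness and
subthreshold facilitation that drive channel interaction emerge from the
Na/K kinetics alone. The two-pulse inhibition/facilitation crossover has
a transparent mechanism in this model: a weak preceding biphasic pulse
acts quasi-linearly, and because its hyperpolarizing second phase is
more recent, the net residual at 138 us is hyperpolarizing (inhibition);
a near-threshold preceding pulse recruits nonlinear Na activation whose
depolarizing residual outweighs the linear one (facilitation). Current
spread makes the preceding pulse weak at short electrode-to-fiber
distances (the neighbor's path-length excess is large) and near-threshold
at long distances, mapping distance onto the inhibition-to-facilitation
axis.

## Calibration (`cisrd.calibrate`)

The electrical dynamic range is derived from an I/O function: onset
response rate (spikes/s within 0–12 ms, spanning several ~4 ms
refractory periods) to a 900 pps train, versus train level. A coarse
geometric sweep brackets the dynamic range, a linear sweep resolves it,
isotonic regression enforces monotonicity, and T and C are read off at
10% and 90% of the min-to-max rate span (a flag switches to
percent-of-max). Calibration is per distance; the straight-array
geometry makes all channels equivalent relative to their own fiber, so
one calibration serves all 22 channels. A seeded bisection finds levels
for target onset rates (e.g. 360 spikes/s) to within ±5%.

## Neurograms and scoring (`cisrd.neurogram`, `cisrd.metrics`)

Neurograms are 22 fibers x time bins (4 ms, half-open, anchored at 0)
of PSTH rates over 30 repetitions (5 in reduced mode):
rate = pooled count / (n_reps * bin width). NSIM normalizes rates by a
fixed 0–360 spikes/s -> 0–255 anchor (values above are retained) and
computes luminance x structure similarity in a sliding 3x3
Gaussian-weighted window (sigma = 0.5 px, the widest Gaussian whose
support matches 3x3; symmetric border padding), with C1 = (0.01*255)^2,
C2 = (0.05*255)^2, exponents 1. The implementation is held to a
brute-force per-pixel oracle at 1e-12.

The percent-correct score is a sigmoid of NSIM with slope S = 21 and
discrimination threshold D_thr = 0.61, oriented so that *smaller* NSIM
(more discriminable neurograms) gives a *higher* score:
score = 100 / (1 + exp(S (NSIM - D_thr))). The opposite (literal
increasing) orientation is available behind a flag. S and D_thr are
treated as fixed constants fitted elsewhere against human CI data; the
published NSIM-to-score example pairs are not exactly consistent with
any orientation of the sigmoid at these constants (they appear rounded),
so they are not used as oracles. The current-spread factor is
(spikes_with - spikes_without) / spikes_without, undefined at zero
baseline.

## Experiments (`cisrd.experiments`)

All randomness derives from one master seed through explicit
`SeedSequence` splitting over (experiment, distance, density,
repetition, fiber), so every table is bit-reproducible. `reduced` scale
(5 neurogram repetitions, 2 score repetitions, 5 spread repetitions)
preserves the qualitative orderings of the full scale (30/6/10) and is
what the test suite and the acceptance script run; a full-scale SRD grid
takes hours on one core and is opt-in.

Reference behavior at the five distances (reduced scale, master seed 1):
only on-channel fibers respond at 0.23 mm; responding-fiber counts grow
monotonically with distance (apical channels first); the two-pulse
paradigm yields inhibition at 0.23–1.18 mm and facilitation at
1.88–2.08 mm with ~90/100 single-pulse response everywhere; SRD percent
correct falls with ripple density (across-distance means 98.0, 94.4,
80.8 at 1, 2, 4 r/o) and with distance at 1.0 and 2.0 r/o.

One regime deserves explicit mention: at the two nearest distances the
standard- and inverted-ripple neurograms are nearly disjoint (NSIM
0.11–0.16), so the score sigmoid saturates above 99.9% for both 1 and
2 r/o and their ordering there is below measurement resolution (score
differences ~1e-4 points whose sign is repetition noise). This happens
because the fiber's narrow electrical dynamic range (~1 dB between T
and C — a steep, non-adapting single fiber) renders each channel almost
binary, maximizing neurogram contrast at short distances. Tests
therefore assert the per-distance density ordering with a 0.5-point
tolerance (admitting saturation ties, catching real inversions)
alongside strict orderings of the across-distance means and of the
distance effect. Human CI reference means/SDs per density are stored as
constants for context only; no statistical test is made against them.

## Known limitations

- 22 fibers (one per electrode), cat morphology, straight geometry, and
  a uniform electrode-to-fiber distance along the array; no 3D volume
  conduction.
- The synthetic stimulus generator is the study's own data source: tests
  show internal consistency of the pipeline, not agreement with any
  recorded neural data.
- Absolute current levels are arbitrary (rho_e is a free transfer
  scale); only calibrated, relative levels are meaningful.
- NSIM values at reduced repetition counts sit below full-scale values
  (fewer repetitions mean noisier neurograms and hence lower
  similarity); orderings, not absolute scores, are the stable output.
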