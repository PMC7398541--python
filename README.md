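# cisrd

Simulation pipeline for **spectral ripple discrimination (SRD) in
cochlear implants (CIs)**, built around the question: how does the
distance between a stimulating electrode and the auditory nerve fibers
(ANFs) degrade spectral resolution — through spread of excitation alone,
or also through the channel interactions (inhibition and facilitation)
that spread current creates?

The package chains five stages:

1. **Stimuli** — rippled noises: 200 log-spaced tones (100–5,000 Hz,
   random phases) whose power spectrum is a full-wave sinusoidal
   envelope in log frequency with 30 dB peak-to-valley depth, in
   *standard* (phase 0) and *inverted* (phase π/2) variants at 1, 2 and
   4 ripples/octave.
2. **ACE coding** — 22-band analysis, 8-of-22 maxima selection per
   frame, 900 pulses/s/channel; biphasic cathodic-first 25 µs/phase
   pulses, non-simultaneous (onsets 138 µs apart within a frame),
   mapped onto calibrated threshold/comfortable current levels.
3. **Current spread** — 22 electrodes (0.8 → 0.4 mm graded spacing)
   facing 22 fibers at a configurable distance D ∈ {0.23, 0.68, 1.18,
   1.88, 2.08} mm; current decays as `exp(-d/λ)` with λ = 2.784 mm
   (3.12 dB/mm).
4. **Fibers** — stochastic 47-compartment Hodgkin–Huxley cable model of
   a cat ANF (23 Ranvier nodes, Fox diffusion channel noise), driven
   extracellularly via the activating function; propagated spikes
   detected at the 20th node.
5. **Scoring** — 22 × 50 neurograms (4 ms PSTH bins over repeated
   trials); the neurogram similarity index
   `NSIM = l·s` (luminance × structure in a sliding 3×3
   Gaussian-weighted window, inputs normalized 0–360 spikes/s → 0–255)
   between the standard- and inverted-ripple neurograms; percent correct
   `= 100 / (1 + exp(S·(NSIM − D_thr)))` with S = 21, D_thr = 0.61.

Intended users: auditory neuroscientists and CI signal-processing
researchers who want a self-contained, seeded, testable model of the
electrode–nerve interface effects on psychophysical spectral resolution.

## Worked example: channel interaction flips sign with distance

A pulse from a neighboring electrode 138 µs before the test pulse
*inhibits* the fiber when the array sits close to the nerve, and
*facilitates* it when far — the package's central reproduction:

```python
from cisrd.fiber import two_pulse_experiment

table = two_pulse_experiment(distances_mm=[0.23, 2.08], n_reps=100,
                             seed=3, dt_us=2.5)
print(table[["distance_mm", "e2_only", "e1_e2", "p_value", "classification"]]
      .to_string(index=False))
```

prints

```
 distance_mm  e2_only  e1_e2      p_value classification
        0.23       89     33 6.287853e-17      inhibited
        2.08       95    100 2.969161e-02    facilitated
```

Reading: the test-pulse level is calibrated per distance so that the
pulse alone fires the fiber in ~90 of 100 trials (`e2_only`). At
0.23 mm the preceding neighbor pulse cuts the response to 33/100
(inhibition); at 2.08 mm it raises it to 100/100 (facilitation). The
preceding pulse itself never fires the fiber. Mechanistically, the
neighbor's pulse arrives at ~81% of threshold at 0.23 mm (net
hyperpolarizing residual at 138 µs) but ~95% at 2.08 mm (nonlinear Na
recruitment leaves a depolarizing residual).

Higher-level drivers live in `cisrd.experiments`: spread-of-excitation
maps, per-fiber current-spread factors, and the full SRD grid
(`run_srd`), whose percent-correct scores fall with ripple density at
every distance and with distance at 1 and 2 ripples/octave. The same
drivers are scriptable from the shell:

```bash
cisrd stimgen --density 1.0 --variant standard --seed 7 --out stim.wav
cisrd run srd --scale reduced --seed 1 --out results/
```

See `docs/methods.md` for model equations, parameter values and the
reasoning behind every numerical choice.

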