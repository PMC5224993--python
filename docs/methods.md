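# Methods

## The model

`asersim` simulates calcium dynamics in the *C. elegans* ASER chemosensory
neuron, which is excited by decreases ("downsteps") in ambient NaCl
concentration. The neuron is divided into three units — dendrite, soma,
axon — each carrying a dimensionless activity `x_i(t)` (calcium level above
the pre-stimulus baseline) and an inactivation variable `y_i(t)`:

    tau_d dx_d/dt = -x_d + y_d + D (W_d x_s - x_d) + I(t)
    tau_s dx_s/dt = -x_s + Y_s y_s + D (x_d + x_a - x_s)
    tau_a dx_a/dt = -x_a + Y_a y_a + D (W_a x_s - x_a)
    dy_i/dt       = -A x_i      while the stimulation epoch is active
    y_i           =  0          otherwise (hard reset at the epoch end)

The stimulus `I(t)` enters only the dendrite, reflecting sensory transduction
at the ciliated dendritic ending. All state starts at zero and rest is a
fixed point.

**Assumptions.**

- Each unit is spatially homogeneous (no PDE); inter-unit exchange is a
  single diffusive coupling `D`.
- The somatic efflux splits between dendrite and axon through
  state-dependent weights `W_d`, `W_a`: with both neurites active in the
  same direction, `W_d = |x_a|/(|x_d|+|x_a|)` and `W_a = |x_d|/(|x_d|+|x_a|)`
  (the more active neurite receives the smaller share; for same-sign
  negative activities the shares swap); with opposite signs the whole share
  goes to the negative side; a unit at exactly zero forfeits its share. The
  weights are recomputed from the instantaneous state at every integrator
  stage evaluation, since the table is defined pointwise in state.
- The inactivation variable integrates the unit's own activity and feeds it
  back, producing the slow decay observed during a sustained downstep. It is
  gated to the stimulation epoch and clamped to zero outside it: without the
  clamp the model would hyperpolarize after stimulus offset, which imaging
  does not show. For flickering or pseudorandom stimuli, where `I(t)`
  alternates between two nonzero levels, the whole alternation is one epoch
  — `y_i` stays engaged across brief upsteps and is reset only when the
  epoch ends. (Whether `y_i` should instead be reset at every mid-epoch
  upstep is not determined by the data; epoch-level gating is the reading
  adopted here.)

## Parameters

| name | meaning | default | unit |
|------|---------|---------|------|
| tau_d, tau_s, tau_a | unit time constants, fixed from imaging | 1.4, 3.7, 1.2 | s |
| D | diffusive coupling strength | free; fitted | – |
| Y_s, Y_a | inactivation magnitudes (soma, axon; dendrite fixed at 1) | free; fitted | – |
| A | inactivation timescale (smaller = slower) | free; fitted | – |

The reference fitted set (`REFERENCE_PARAMETERS`), used as ground truth for
all synthetic data, is `D = 7.1`, `Y_s = 0.3`, `Y_a = -0.2`, `A = 0.03` —
the genetic-algorithm fit of the model to imaging of the 60-s downstep.

Stimulus levels are dimensionless with a fixed linear mapping of 50 mM NaCl
change to `I = 1.0`. The canonical protocols are: a single 60-s downstep
(`I = 1` on t = 10–70 s of a 120-s horizon); a 0.5-Hz flicker
(`I = 1.5/1.0` alternating, 1 s per phase by default — the flicker duty
cycle is not pinned down by its description, so the phase length is an
explicit argument); a pseudorandom two-level sequence with 1-s dwell driven
by bit 0 of successive MT19937 draws; and graded steps with `I`
proportional to the concentration change.

## Numerics

The ODE system is integrated with classical fourth-order Runge–Kutta under
step-doubling local-error control: each trial step is taken once at `h` and
twice at `h/2`; the maximum per-variable difference is tested against an
absolute tolerance of 1e-8, with the internal step capped at 0.05 s and
safety-factor growth/shrinkage `0.9 (tol/err)^(1/5)`. Protocol breakpoints
and output sample times are hard restart points, so no internal step ever
straddles a discontinuity of `I(t)`; output is sampled on a uniform grid
(0.1 s by default, ten samples per second as in the imaging). The piecewise
right-hand side is compiled with numba; a step-size underflow below 1e-10 s
raises an integration error with the failure time. With coupling and
inactivation off, the dendrite trace matches the first-order closed form to
better than 1e-6 at every sample, and halving the tolerance moves no sample
by more than 1e-6.

## Fitting

The four free parameters are scored by `dL`: the sum of absolute
differences between target and simulated traces over all three regions on
the 1201-point grid t = 0, 0.1, …, 120 s (endpoints inclusive). Both sides
are min-max scaled to [0, 1] per region first, so only response shape is
compared; an exactly constant trace scales to zeros. Integration failures
score +inf so one stiff grid point cannot abort a sweep.

**Brute force.** The production grid is D ∈ [0, 10] step 0.1, Y_s and
Y_a ∈ [-1, 1] step 0.1, A ∈ [0, 0.3] step 0.01. Axes use a half-open
endpoint convention (`round((hi-lo)/step)` points per axis), giving
100·20·20·30 = 1,200,000 combinations; an inclusive convention (1,380,771)
is available behind a flag. The wide pilot grid — D[0, 50], Y_s/Y_a[-10, 10],
A[0, 10] at resolutions 200/20/20/100 = 8,000,000 points — supports the
screening histograms (combinations with `dL` under a threshold, 800 by
default, binned per parameter) that justify the narrower production ranges.

**Genetic algorithm.** Binary genomes of 8 bits per parameter (32 bits),
population 100, single-point crossover with probability 0.6 (cut uniform
over the 31 interior positions; first child = first parent's head + second
parent's tail, and vice versa; non-crossing pairs pass through as copies),
per-bit mutation probability 0.01, up to 500 generations, all randomness
from a seeded Mersenne Twister. Each generation scores one population's
worth of candidates, so a full run evaluates exactly 100 × 500 = 50,000.
Survivor selection is elitist truncation of parents plus offspring.

Two design choices were made where the procedure was genuinely open, and
both matter for parameter recovery:

- **Grid-snapped decoding** (`GAConfig.snap_to_grid`, on by default). A
  genome field decodes linearly onto its full range
  (`lo + k/255 · (hi - lo)`) and is then rounded to the brute-force grid
  step before evaluation. The min-max-scaled fitness surface has a shallow
  ridge along which a higher `D` trades off against `Y_s`/`Y_a`; on the
  fine 256-level lattice this ridge is littered with near-ties, while on
  the coarser grid lattice the basin around the generating parameters is
  sharp and converged runs report values on the same lattice as the
  brute-force search (and as the reference set itself).
- **Restart on stagnation** (`GAConfig.restart_stall`, default 40). When the
  best-ever fitness has not improved for 40 generations, the next
  generation scores a fresh random population instead of offspring; the
  best-ever individual is retained aside as the running result, so the
  best-so-far trajectory is still monotone and the evaluation budget is
  unchanged. A single converged population cannot leave a ridge basin by
  bit-flip mutation alone (moving one quantization step in a parameter can
  require flipping several bits at once); restarts let one run sample
  several basins and keep the best. With both choices, repeated seeded runs
  on the noiseless step target recover (7.1, 0.3, -0.2, 0.03) exactly in
  nearly all seeds, with run-to-run SDs of ~0.

An optional early stop (`stall_generations`) ends a run once the best-ever
fitness has stagnated that long across restarts; the acceptance script uses
150 so converged runs stop around generation 200–350 instead of always
spending the full 500.

## Evaluation

`VAF = 100 (1 - var(actual - simulated)/var(actual))` per region; 100 at a
perfect fit, negative for fits worse than a constant. The variance in the
denominator is the *actual* trace's (a switch flips the convention), which
keeps VAF = 100 exactly at zero residual. Temporal metrics quantify the
response shape: time from stimulus onset to the half-peak crossing
(linearly interpolated); time from the peak until the trace falls halfway
toward its pre-upstep level; and time after the epoch end until the trace
first re-enters a band of ±5% of peak amplitude around baseline (the band
width is a parameter; no canonical tolerance exists). Traces with no peak
above baseline are flagged undefined rather than scored.

The measured peak-vs-downstep relation saturates while the model's peak
grows linearly with `I`, so a saturating transfer
`P_max / (1 + exp(-k (s - p0)))` is least-squares fitted to reconcile them;
the logistic form is a choice (the shape is saturating and roughly
symmetric; Hill and tanh alternatives are selectable), and fits with large
residuals (above 2% of the response range), steepness at its bounds, or a midpoint pushed outside the sampled range (the small-`k`
limit in which a logistic degenerates to a line) are flagged poor.

## Preprocessing

Raw ROI fluorescence passes through: scalar background subtraction (the
background is supplied per trace, not estimated); photobleaching correction
by a single exponential `a·exp(-b t)` least-squares fitted jointly to
pre- and post-stimulation baseline windows and divided out (division is the
default; subtraction of the fitted trend is a switch — which of the two the
original procedure used is not stated); then either min-max normalization
to [0, 1] or baseline normalization `(F - F_0)/F_0` with `F_0` the mean over
the 5 s before onset (shorter windows fall back to all available pre-onset
samples, with a 1-s floor). A brightening trend (`b < 0`) or non-convergent
fit leaves the trace unchanged with a warning.

## Synthetic data

No raw imaging traces are publicly deposited, so all tests and examples run
against surrogates: the model is integrated at the reference parameters,
each region min-max scaled, and independent Gaussian noise added per
replicate and sample (n = 10 replicates matching the imaging group size,
SD 0.02 on the unit scale — small relative to the unit-scaled response, so
near-perfect fits keep VAF well above 90%). The mean and SEM envelopes are
stored alongside the replicates. The raw-fluorescence fixture variant maps
the clean trace to counts (baseline 100, range 400), applies exponential
bleach (0.002/s) and a flat 50-count background, and round-trips through the
preprocessing pipeline to 1e-3 RMS.

What the surrogates do **not** contain: photon/shot noise statistics, motion
artifacts, and — importantly — the gradual amplitude adaptation real ASER
neurons show over long flickering or pseudorandom stimulation. The
deterministic model holds its peak amplitude roughly constant under such
stimuli, so surrogate-based tests demonstrate internal consistency of the
simulator, fitting and evaluation machinery, not the model's remaining
discrepancies from living neurons.

## Problem sizes

Unit and property tests run on tiny grids (3^4 brute-force sweeps, 10–20
individual GA populations over a handful of generations). The end-to-end
checks use: one GA fit against the noisy step target for the VAF floor, and
three (test suite) or five (acceptance script) full seeded GA recovery runs
with the 150-generation early stop. Full-scale 1.2M-point brute-force
sweeps are supported (raise the `cap` argument) but are not exercised by
the default suite; the grid cardinality itself is verified by enumeration.

## Known limitations

- The model has no adaptation mechanism, so long-stimulation amplitude
  decline is not reproduced (by design).
- Parameter recovery is measured against self-generated targets; with real
  imaging targets the fitness floor is set by biological variability, and
  the best-fit parameters of noisy targets can drift along the D–Y_s ridge
  even when the fitted trace is visually and VAF-wise excellent.
- The Y_s sign ambiguity seen between independently converged optimizers on
  noisy targets (positive vs negative basins with similar dL) is a real
  feature of the scaled fitness and is not resolved here.
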