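# asersim

A simulator and fitting library for calcium dynamics in the *C. elegans*
ASER salt-sensing neuron.

ASER is excited by decreases ("downsteps") in ambient NaCl concentration:
calcium rises to a peak within seconds of the downstep, decays slowly while
the stimulus persists, and returns rapidly to baseline after the upstep.
`asersim` models the neuron as three coupled units — dendrite, soma, axon —
each a first-order ODE in a dimensionless activity x_i with an inactivation
variable y_i providing slow negative feedback:

    τ_d dx_d/dt = −x_d + y_d + D (W_d x_s − x_d) + I(t)
    τ_s dx_s/dt = −x_s + Y_s y_s + D (x_d + x_a − x_s)
    τ_a dx_a/dt = −x_a + Y_a y_a + D (W_a x_s − x_a)
    dy_i/dt     = −A x_i         (during the stimulation epoch; y_i ≡ 0 outside)

with fixed time constants τ_d = 1.4 s, τ_s = 3.7 s, τ_a = 1.2 s and four
free parameters: the diffusive coupling D, the inactivation magnitudes
Y_s, Y_a, and the inactivation timescale A. The state-dependent weights
W_d, W_a split the somatic calcium efflux between the neurites. The free
parameters are fitted to per-region activity traces by minimizing

    dL = Σ_t |f_d − x̂_d| + |f_s − x̂_s| + |f_a − x̂_a|

over t = 0, 0.1, …, 120 s (both traces min-max scaled to [0, 1] per
region), either by exhaustive grid search (1,200,000 combinations on the
default grid) or by a binary genetic algorithm (population 100, 8 bits per
parameter, single-point crossover p = 0.6, bit-flip mutation p = 0.01,
500 generations ≙ 50,000 evaluations). Fits are judged by variance
accounted for, VAF = 100·(1 − var(f − x̂)/var(f)), and by temporal response
metrics (half-rise time, in-stimulus decay, return to baseline).

The package also provides the stimulus protocols used to probe the neuron
(single downstep, 0.5-Hz flicker, seeded pseudorandom switching, graded
steps), fluorescence preprocessing (background subtraction, photobleach
correction, ΔF/F_max and ΔF/F_0 normalization), and a synthetic-data
generator that emulates imaging datasets (replicates, noise, SEM
envelopes) so everything is testable without raw recordings. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import asersim as a

# 60-s downstep (50 -> 0 mM NaCl mapped to I = 1) at t = 10 s
protocol = a.step_protocol(onset=10, duration=60, I_down=1.0, horizon=120)

# synthetic "imaging" target: reference parameters + replicate noise
data = a.generate_surrogates(a.REFERENCE_PARAMETERS, protocol,
                             noise_sd=0.02, n=10, seed=1234)
target = data.target()

# genetic-algorithm fit of (D, Y_s, Y_a, A)
result = a.ga_optimize(a.GAConfig(seed=11, stall_generations=150),
                       a.GridSpec(), target, protocol)
print(result.best.params, round(result.best.dL, 2))

# evaluate the fit per region
from asersim.fitting import minmax_unit
best = a.ModelParameters(**{"tau_d": 1.4, "tau_s": 3.7, "tau_a": 1.2,
                            **result.best.params})
sim = a.integrate(best, protocol)
for region, f, x in zip(("dendrite", "soma", "axon"),
                        target.scaled().stacked(), sim.stacked()):
    print(region, round(a.vaf(f, minmax_unit(x)), 2))
```

prints

```
{'D': 7.4, 'Y_s': 0.40000000000000013, 'Y_a': -0.3999999999999999, 'A': 0.03} 49.97
dendrite 99.88
soma 99.89
axon 99.8
```

The fitted trace explains ~99.9% of the variance of each noisy region
trace. Note the fitted parameters drift slightly along a shallow D–Y_s
fitness ridge when the target is noisy — the fitted *shape* is excellent
while individual parameters are less constrained; on noiseless targets the
same runs recover the generating parameters (7.1, 0.3, −0.2, 0.03)
exactly.

A command-line interface wraps the same functionality:

```sh
asersim simulate --protocol step --out sim.csv
asersim make-fixtures --out fixtures/
asersim fit-ga --target fixtures/step_target.csv --seed 1 --out runs.csv
asersim evaluate --actual fixtures/step_target.csv --simulated sim.csv \
    --report report.json
```

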