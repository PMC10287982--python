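# termkin

Kinetics of translation termination in bacteria: single-molecule dwell-time
analysis of class-I release factor (RF1/RF2) recycling by the GTPase RF3,
and a whole-cell steady-state model of the termination flows that decides
whether ribosome-catalyzed or spontaneous guanine nucleotide exchange on RF3
sustains termination in a growing cell.

## Who this is for

Researchers analysing real-time single-molecule fluorescence recordings of
translating ribosomes (zero-mode-waveguide or TIRF style assays with a
ribosome-conformation channel and factor-occupancy channels), and anyone
who wants to reproduce or perturb the steady-state flux argument for why
RF3 needs the ribosome as its nucleotide exchange factor in vivo.

## The model

A class-I release factor (RF_i, i = 1 or 2) bound to the post-termination
ribosome leaves via intersubunit rotation. For a first-bound factor the
ribosome first passes an RF3-independent activation step, then rotates
slowly on its own or fast with RF3 bound; RF3 occupancy is a rapid
pre-equilibrium with dissociation constant K3:

```
tau_iBR([RF3]) = 1/k_iIA + (K3 + [RF3]) / (k_iAR- K3 + k_iAR+ [RF3])
tau_iRD([RF3]) = (1/k_iRD+) [RF3] / (K3 + [RF3])
tau_iBD        = tau_iBR + tau_iRD
```

Dwell-time distributions are fitted as 1-3 component exponential mixtures
`f(t) = sum_j a_j (1 - exp(-k_j t))`, by maximum likelihood on
left-truncated (100 ms dead time), right-censored (movie end,
photobleaching) data.

The cell model embeds termination in the full ribosome cycle: three stop
codon classes (UAA read by RF1 and RF2, UGA by RF2, UAG by RF1) share free
pools of RF1, RF2 and RF3 (speciated GDP-bound / apo / GTP-bound). Class-I
RF release from the post-termination complex proceeds through
ribosome-catalyzed nucleotide exchange (pathway A), direct binding of
solution-exchanged RF3.GTP (pathway B), or spontaneous release (pathway C);
free RF3.GDP regenerates RF3.GTP in solution at the slow GDP off-rate
q_S_3D (pathway D). The population doubling time is proportional to the
ribosome-averaged cycle time `tau_R = 1 / sum_X f_X / tau_R^X`.

## Worked example

```python
import math
from termkin import (load_scheme_rates, load_rf3_kinetics, mean_rotation_time,
                     simulate_timelines, render_trace, idealize_trace,
                     extract_dwells, fit_exponential_mixture)

rates = load_scheme_rates("RF1", 20)          # published 20 C constants
print(round(mean_rotation_time(rates, 0.0), 1))       # 66.4  s, no RF3
print(round(mean_rotation_time(rates, math.inf), 1))  # 29.7  s, saturating RF3

# simulate an experiment at 75 nM RF3-GTP, recover the post-rotation dwell
rf3k = load_rf3_kinetics("GTP")
timelines = simulate_timelines(rates, rf3k, 0.075, 2, 500, seed=1)
dwells = []
for tl in timelines:
    tr = render_trace(tl, noise_sd=0.05, seed=1)
    dwells += [r for r in extract_dwells(idealize_trace(tr), bleach_times=tr.bleach_times)
               if r.dwell_class == "t_iRD" and not r.censored and r.duration > 0]
fit = fit_exponential_mixture([r.duration for r in dwells],
                              n_components=1, frame_period=0.1)
print(round(fit.rates[0], 2))                 # 0.73 1/s
```

The two closed-form numbers are the mean RF1 residence time on the
terminating ribosome without RF3 (66.4 s) and at saturating RF3 (29.7 s) —
RF3 accelerates departure roughly two-fold at this temperature because the
activation step stays rate limiting. The fitted rate recovers the
post-rotation RF1 dissociation rate the traces were generated with
(k+_1RD = 0.69 1/s, the dye-labelled-RF3 estimate) to within sampling
error.

The cell model:

```python
from termkin import CellParams, build_network, solve_steady_state, \
    compute_times, pathway_flux_fractions
sol = solve_steady_state(build_network(CellParams()))
print(round(compute_times(sol).tau_R, 1))     # 17.6 s average cycle time
fr = pathway_flux_fractions(sol).overall
print(round(fr["A"] / (fr["A"] + fr["B"]), 3))  # 0.986: exchange is ribosomal
```

A command-line surface wraps the same functions:

```
termkin simulate --rf3 0.075 --n 500 --seed 7 --out traces/
termkin idealize --traces traces/ --out dwells.csv
termkin fit-dwells --dwells dwells.csv --dwell-class t_iRD --components 1 --out fit.json
termkin cellmodel --out cell.json
termkin titrate --species F_tot --from 0.5 --to 12 --points 24 --out titration.csv
```

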