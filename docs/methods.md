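# Methods

## Termination scheme and closed-form mean times

The package models class-I release factor (RF1/RF2, generically RF_i)
departure from the post-termination ribosome as a two-branch scheme. A
first-bound RF_i finds the ribosome rotation-blocked; an RF3-independent
activation step (rate `k_iIA`, min-range at 20 C) unlocks intersubunit
rotation, which then proceeds slowly without RF3 (`k_iAR-`) or fast with
RF3 bound (`k_iAR+`). RF3 occupancy during this phase is treated as a fast
pre-equilibrium with dissociation constant `K3`; the mean time from RF_i
binding to rotation is

    tau_iBR(c) = 1/k_iIA + (K3 + c) / (k_iAR- K3 + k_iAR+ c),  c = [RF3].

Without RF3 the factor leaves together with rotation (tau_iRD = 0); with
RF3 bound a short post-rotation dwell with mean `1/k_iRD+` follows, giving
`tau_iRD(c) = (1/k_iRD+) c/(K3 + c)` and `tau_iBD = tau_iBR + tau_iRD`
exactly. A rebound factor finds the ribosome already activated, dropping
the `1/k_iIA` term. The pre-equilibrium treatment is validated in the test
suite against the exact first-passage time of the chain with explicit fast
binding/unbinding (linear solve) and against a Monte-Carlo simulation of
that chain.

One subtlety: `tau_iBD(c)` is *not* globally monotone. It decreases
steeply up to `c ~ K3` and then rises by at most `1/k_iRD+` as the
post-rotation term saturates while the rotation term flattens; the
crossover sits at `c* ~ K3` for any parameter set. The measured trend
(strong decrease) reflects the steep initial branch.

`K3` is not tabulated in the source literature; the bundled fixture carries
an assumed mid-titration value of 0.03 uM (flagged `synthetic` in the JSON)
chosen so saturation is reached below ~0.2 uM. No test asserts it; fitting
tests recover whatever `K3` generated their data.

## Synthetic traces

The synthetic-data generator is the stand-in for the study's unreleased raw
recordings. It emulates a zero-mode-waveguide experiment: 6-minute movies
at 10 frames/s, a Cy3B channel reporting ribosome conformation (high =
free 30S complex or split subunits, low = non-rotated 70S, medium =
rotated, with an interim level for the GDPCP partial rotation), a Cy5.5
channel for class-I RF occupancy and a Cy5 channel for RF3 occupancy.

Timelines are drawn exactly from the continuous-time Markov chain: subunit
joining and elongation cycles as exponential stages (plumbing defaults
0.2 s^-1 joining, 1 s^-1 per half elongation cycle — order-of-magnitude
choices for a 20 C assay, not fitted quantities), class-I RF arrival at
`k_ion [RF_i]` (default 20 nM factor), RF3 sampling arrivals at
`k_3on [RF3]` with occupancies drawn from the measured `k_3off` mixture
(component chosen with probability = amplitude), and a productive branch
(GTP/GDPCP only) in which rotation at `k_3BR` races the sampling
dissociation on the activated ribosome, followed by RF_i release at
`k_1RD+` and RF3 release at `k_31D`. With GDP no productive branch exists;
sampling continues indefinitely.

Rendering bins events into half-open frames `[k/f, (k+1)/f)`: a frame shows
the state in force just before its right edge, so an event appears in the
frame containing it and two events inside one frame are seen as
simultaneous — this reproduces the experimentally observed "apparently
concurrent" event classes (e.g. a fraction `1 - exp(-k_31D/f)` of post-RF1
RF3 departures fall inside one frame). Gaussian noise is i.i.d. per frame;
photobleaching (off by default) truncates a channel at an exponential time
recorded for censoring tests. Camera physics (EMCCD gain, shot noise) and
FRET efficiency are not modelled; intensity levels are ordinal choices on
an arbitrary scale.

What passing tests therefore show: the pipeline is correct against data
whose noise is Gaussian, stationary and level-separated. Real recordings
add baseline drift, blinking and non-Gaussian noise that the thresholding
idealizer here does not face.

## Idealization and dwell extraction

Idealization is nearest-level classification with a calibration half-width
(frames outside it become `unknown` and are excluded) plus a two-frame
persistence rule: a one-frame excursion is kept only when its intensity
sits exactly on the excursion level (noiseless data) or when it separates
two different states (a genuine fast transition); A-B-A blips are merged
back. This is deterministic and exactly invertible on noiseless traces; a
trained HMM could replace it behind the same contract. Same-frame events
are ordered RF3 binding < rotation < class-I RF dissociation < RF3
dissociation, the sequential order of the mechanism; a rotation detected
one frame *after* the factor release is classification jitter and is
clamped to the release frame. Durations are frame counts times the period
— no sub-frame interpolation — so the decomposition
`t_iBD = t_iBR + t_iRD` is exact in frame counts. Any dwell truncated by
the final frame or a bleach time is flagged censored with its truncated
duration and a reason.

## Dwell-time fitting

Cumulative dwell distributions are modelled as 1-3 component exponential
mixtures with amplitudes summing to one. The default estimator is maximum
likelihood on left-truncated, right-censored data: the 100 ms frame time is
a dead time (the likelihood conditions on `t >= frame_period`), and
censored records contribute survival terms. Rates are optimized on a log
scale with softmax amplitudes, multi-start (quantile-matched initial rates,
five seeded starts, Nelder-Mead polished by BFGS); standard errors come
from a finite-difference Hessian with a delta-method transform. The
original least-squares-on-CDF analysis is retained as `method="cdf_lsq"`
and agrees with the MLE on uncensored data (tested). Empirical CDFs use the
product-limit (Kaplan-Meier) estimator so censoring does not bias rates
upward. Model order is user-chosen; a BIC is reported for guidance, and an
amplitude below 0.02 triggers an over-specification warning. The fit is
exactly invariant to time-unit rescaling.

Recorded durations are treated as continuous despite frame quantisation;
for rates up to ~1.5 s^-1 at 10 frames/s the discretisation bias is within
the recovery tolerances used here, and an interval-censored likelihood
would be the next refinement.

Association rate constants come from fitting each concentration's arrival
times to a single exponential and regressing `k_obs` on concentration
through the origin (single-condition fallback `k_obs/c`).

## Whole-cell termination flow model

The cell model answers a supply/demand question: protein synthesis at
20 uM ribosomes, 20 codons/s and 300-codon proteins terminates
`20*20/300 = 1.33 uM/s` of chains, each consuming one activated RF3.GTP if
termination is RF3-driven; spontaneous nucleotide exchange on free RF3
(GDP off-rate 0.03 s^-1, 1 uM total RF3) can supply at most 0.03 uM/s —
2.25% of demand — so ribosome-catalyzed exchange must carry the flux.
The network model makes this argument self-consistently.

Structure: three codon classes (UAA: RF1+RF2, UGA: RF2, UAG: RF1) with
*fixed ribosome subpopulations* `f_X * 20 uM`, f = 0.64/0.27/0.09 — the
stop-codon usage frequencies — coupled only through the shared free factor
pools. Each class cycles through a lumped elongation stage (15 s), the
resolved termination pathway (pre-termination waiting, class-I RF binding,
peptide release, the RF3 branch or spontaneous release, splitting) and a
lumped initiation+recycling stage. The average cycle time is the
ribosome-fraction-weighted harmonic mean `tau_R = 1/sum f_X/tau_R^X`, and
the doubling time is proportional to `tau_R`.

RF3 is speciated as GDP-bound, apo and GTP-bound, in solution and on the
ribosome. Free GDP is held at zero — the limit that *maximises* the
spontaneous pathway, making the supply/demand conclusion conservative — so
apo-RF3 in solution can only bind GTP (pseudo-first-order, 50 s^-1 at
0.5 mM GTP, non-limiting by construction). On-ribosome GDP release
defaults to 50 s^-1 ("rapid" in the source; effectively instantaneous
relative to its neighbours). Sampling dissociation of ribosome-bound RF3
uses single effective rates `1/(sum a_j/k_j)` of the measured mixtures.

Parameter provenance and calibration: measured constants (k_ion 21 and
10.5 uM^-1 s^-1, k_3on 2.3, k_3BR 3.2, k_31D 4, spontaneous release 0.1
and 1 s^-1 for RF1/RF2, RF2 clearance 3.5 s^-1) are used directly. Stage
rates without in-vivo measurements — peptide release (10 s^-1), subunit
splitting (10 s^-1), the initiation+recycling lump (0.3 s), and RF1
post-rotation clearance, where the 30 C estimate 2.5 s^-1 is the closest
available to growth temperature — were set once so the model reproduces
the reference operating point: average cycle time ~17.6 s with RF3 and
~18.6 s without at ~2 uM class-I RF, with sub-second RF2 waiting times.
They were not revisited afterwards.

Solver: the only nonlinear couplings are the five free-factor pools, so
the steady state is found by fixed-point sweeps that root-solve each
pool's conservation balance (a monotone bracketed scalar equation, solved
by Brent's method with an inner linear solve of the per-class balances,
plus one step of iterative refinement because the rate constants span many
orders of magnitude), with the RF3 GDP/apo/GTP split relaxed between
sweeps from solution-phase flux balance. The accepted state must satisfy
`max |dx/dt| <= 1e-8 * max flux`; long-time BDF integration of the same
mass-action system is kept as an independent oracle and agrees to <0.1%
on randomized parameter sets (tested on 20).

Pathway attribution: pathway C is the spontaneous-release flux. RF3-driven
rotations split between A (nucleotide exchanged on the ribosome) and B
(exchanged in solution) by a linear tracer that tracks where each GTP was
loaded — necessary because RF3.GTP that escapes a ribosome by sampling
dissociation re-binds directly and would otherwise be miscounted as B.

Behaviour at the defaults: pathway A carries 98.6% of the RF3-dependent
flux at physiological concentrations (>=94.6% across a 0.5-12 uM class-I
RF titration); with ribosomal exchange disabled, solution-exchanged
RF3.GTP serves ~1% of terminations (supply-capped at 2.5%); removing RF3
entirely lengthens the average cycle by ~5.8%, dominated by the 1-s
spontaneous RF2 release, because RF2 reads 91% of stop codons.

Known limitations. (i) The per-codon absolute titration curves are
reproduced qualitatively (starvation / dissociation / rebinding-inhibition
phases), not quantitatively — the original simulation's full parameter set
is not public. In particular UAG waiting times here stay in the
several-second range at 0.8 uM RF3: RF1 conservation (0.225 uM at a 2 s
bound time per event) caps UAG throughput below the sub-second-waiting
regime. (ii) Fixed ribosome subpopulations mean a starved minor codon
class accumulates queued ribosomes rather than re-allocating initiation
toward other mRNAs; mRNA competition is not modelled. (iii) Readthrough,
drop-off and other indirect effects of stalled termination are outside the
model. (iv) Temperatures are separate parameter sets; no Arrhenius
interpolation.

## Reproducibility

Every stochastic routine takes an explicit seed; identical inputs and seed
give bit-identical timelines, traces and fits. The CLI writes a manifest
(command, config hash, seed, package version) next to each output. Problem
sizes used by the bundled analysis script: single evaluations for the
closed forms, 20 seeded replicates of 4 x 300 arrival times for the
association-rate study, and a 12-point titration plus two steady-state
solves of the 44-species network for the cell-model quantities.
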