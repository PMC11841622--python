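# polkin

Single-molecule fluorescence-polarization kinetics of the AdiC
arginine/agmatine transporter: from four-channel polarized photon-count
traces to a fully parameterized 24-state conformational-kinetic model, and
onward to transporter flux predictions and two-compartment exchange
thermodynamics.

## The scientific problem

AdiC exchanges extracellular arginine (Arg+) for cytosolic agmatine (Agm2+)
in enteric bacteria, cycling through four canonical transporter
conformations — externally open (E_o), externally occluded (E_x),
internally open (I_o) and internally occluded (I_x).  A fluorophore
rigidly attached to helix 6A adopts a distinct spatial orientation in each
conformation, so the emission split over four polarization channels
(I0, I45, I90, I135, recorded at 10 ms/frame) tracks the conformational
state of one molecule in real time:

- phi = 1/2 atan2(I45 − I135, I0 − I90), and
  sin(theta_app) = 2 sqrt((I0 − I90)^2 + (I45 − I135)^2) / I_tot, with
  theta corrected for fast fluorophore wobble through the order parameter
  S(delta) = cos(delta)(1 + cos(delta))/2;
- conformational transitions are found by a recursive Poisson
  log-likelihood-ratio (LLR) changepoint search summed over the four
  channels, with Monte-Carlo-calibrated 95% confidence thresholds;
- events cluster into states C1–C4 on the unit sphere and are expressed in
  a molecule-local frame (mean phi(C1) = 0, C1/C4 span the x–y plane);
- each conformation's dwell-time distribution is double-exponential
  (tau1, tau2, f), revealing two energetic substates per conformation: an
  entry substate S_i exchanging with the other conformations and a
  cul-de-sac partner S_{i+4}.  With the exit-branching probabilities
  p_ij, the serial scheme inverts in closed form:
  k_out = f·lambda1 + (1−f)·lambda2, k_ba = lambda1·lambda2/k_out,
  k_ab = lambda1 + lambda2 − k_out − k_ba, k_ij = k_out·p_ij;
- apparent rates follow one-site isotherms
  app_k = (k + L_k·[L]/K_half) / (1 + [L]/K_half) across ligand
  concentrations, yielding the 20 apo, 20 Arg-bound and 20 Agm-bound rate
  constants (60 total) plus dissociation constants K_D from the
  concentration dependence of the eight energetic-state probabilities;
- the resulting 24-state model (8 apo + 8 per ligand branch, binding only
  at the open substates S6/S7 with kon = 1e7 /M/s, koff = kon·K_D) is
  simulated stochastically (Gillespie) and deterministically (24 coupled
  ODEs with two-compartment substrate bookkeeping) to predict vesicle flux
  assays, Michaelis–Menten behavior, and the uniporter-vs-exchanger
  dichotomy: an obligatory 1:1 exchanger is thermodynamically pinned to
  F_max = 1/(1 + r_v/r_c), while a transporter with an apo pathway relaxes
  to the volume partition 1/(1 + r_v).

The microscopy recordings behind these analyses are not publicly
deposited, so the package ships a first-class synthetic-data generator
(`polkin.synthgen`) that emulates them — Markov dwell kinetics, dipole
orientations, wobble depolarization, Poisson shot noise at SNR 5–20,
single-step photobleaching, and noisy fractional-uptake flux assays — and
an end-to-end benchmark that recovers the generator's rate constants
through the full analysis chain.

## Worked example

```python
import numpy as np
from polkin import synthgen, pipeline, changepoint

truth = synthgen.make_ground_truth("adic-like", seed=1)
spec = synthgen.TraceSpec()                      # 10 ms frames, SNR ~ 19
traces = pipeline.simulate_condition(truth, "arg", 1e-4, 8, spec, seed=3)
res = pipeline.analyze_condition(traces, pipeline.PipelineConfig(seed=1))
print("occupancies:", np.round(res.stats.occupancy, 3))
print("C1 dwell fit: tau1=%.3f s  tau2=%.2f s  f=%.2f"
      % (res.fits[1].tau1, res.fits[1].tau2, res.fits[1].f))
print("apparent k(1->2) = %.2f /s" % res.appk[(1, 2)])
```

prints (exact values vary with the seed; this is a small 8-particle run,
so the slow-component parameters are still noisy):

```
occupancies: [0.219 0.246 0.272 0.263]
C1 dwell fit: tau1=0.123 s  tau2=2.59 s  f=0.98
apparent k(1->2) = 2.45 /s
```

i.e. the four conformations are occupied roughly as the stationary
distribution of the ground-truth scheme dictates, C1 dwells are
double-exponential (a fast ~0.12 s entry component and a slow cul-de-sac
component), and the inverted apparent rate constants land near the
generator's inputs.  The full benchmark across a two-ligand concentration
series is

```python
concs = list(np.geomspace(1.2e-5, 1.2e-3, 6))
rec = pipeline.run_recovery(truth, {"arg": concs, "agm": concs}, seed=1)
```

which recovers all 20 apo rate constants within 25% and the consequential
dissociation constants (external S6, internal S7 binding) within a factor
of two at realistic event counts (~2,600–3,000 events per condition).

A thin command line mirrors the stages: `polkin simulate-traces`,
`polkin detect`, `polkin states`, `polkin fit-dwell`,
`polkin simulate-flux`, `polkin predict-mm`, `polkin recover`.

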