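# Methods

This note documents the models, numerical choices and known limitations of
`polkin`, module by module, in the order the analysis runs.

## Polarimetry

A fluorophore dipole with inclination theta (from the optical axis) and
in-plane angle phi splits its emission over four polarization channels.
The implemented forward model is the exact inverse of the estimation
formulas:

    I0,I90   = (I_tot/4) (1 ± S sin(theta) cos(2 phi))
    I45,I135 = (I_tot/4) (1 ± S sin(theta) sin(2 phi))

with S(delta) = cos(delta)(1 + cos(delta))/2 the second-rank
wobble-in-cone order parameter for fast restricted rotation of half-cone
angle delta (a configuration choice; any alternative S(delta) can be
substituted).  Estimation divides the apparent modulation amplitude by S
before the arcsine, which corrects the wobble-induced underestimate of
theta.  The estimate depends only on intensity ratios, so it is invariant
to total-intensity changes.  Degenerate inputs (theta = 0, phi undefined)
are flagged and excluded from state means.

The intensities determine only sin(theta) and phi mod 180 degrees, so
orientations live on a quarter-sphere: theta in [0, 90], phi in (-90, 90].
Two numerical points matter near theta = 90: (i) the arcsine loses
~sqrt(machine-eps) precision at its endpoint, so amplitude ratios within
1e-12 of 1 are snapped to exactly 90 degrees; (ii) any dilution of the
polarized amplitude (averaging intensities across a transition, mixing
events from different states) drags the estimated theta down by several
degrees per percent of dilution.  The second point drives several design
choices below.

The molecule-local frame takes the mean C1 dipole as x (so C1 maps to
theta = 90, phi = 0) and the C1/C4 plane as x–y with C4 at positive phi.
The sign convention is applied to the *folded* azimuth of C4, since a
dipole representative may point "backwards" along its line.

## Changepoint detection

For each candidate split of a segment the per-channel Poisson LLR

    m ln(m/tau) + (N−m) ln((N−m)/(T−tau)) − N ln(N/T)

is summed over the four channels (terms with zero counts contribute
zero; the frame interval cancels).  Detection thresholds are the 95%
(configurable) quantile of the max-over-splits LLR on Monte-Carlo
transition-free traces, cached on a geometric grid of segment lengths
(interpolated in log length) and factor-of-two count-rate buckets, 400
null traces per grid point.  The search is recursive bisection followed by
refinement passes (re-locate each point between its neighbours, drop
sub-threshold ones, re-test each segment for missed points), capped at 10
iterations; ties break to the earliest frame.  Per-segment-length
thresholds imply roughly one false positive per twenty detected
transitions at 95% confidence — the same budget the underlying detection
theory quotes — and downstream same-state merging removes most of them.

Event intensities are averaged over *interior* frames (first and last
frame of each event dropped when the event has at least three frames):
a camera frame straddling a transition carries mixed intensities, and
through the arcsine sensitivity a single mixed frame in a 20-frame event
would otherwise bias the event's theta by several degrees.

Particle QC follows the acquisition rules: at least 15 events, SNR > 5
(SNR = (mean total signal − background)/SD of total signal), and a single
terminal bleach step.  Bleaching is located by segmenting the
total-intensity trace with the same LLR machinery; a particle whose
intensity drops in two steps (two fluorophores) is rejected, and analysis
uses only the pre-bleach portion.

## State identification

Events are clustered by k-means on the outer-product (Q-tensor) embedding
of their orientation unit vectors — the embedding identifies v with −v, so
clustering is immune to how dipole representatives were folded.  Cluster
means are principal axes of the member outer products.  The number of
states is the largest k (up to 6) for which every pair of clusters is
resolvable under the 2.5-sigma rule.  Resolvability is evaluated by
projecting the pooled members of a pair onto the axis joining their means
and fitting a two-component Gaussian mixture: the pair is resolvable when
the two-mode fit beats one mode by BIC and the fitted mode separation
exceeds 2.5 fitted sigmas.  Measuring sigma through the mixture rather
than within each k-means cell avoids the truncation bias of cells that
merely slice one state in two (a sliced state otherwise looks "resolvable"
at any k).  Near the 2.5-sigma boundary the BIC gate is conservative;
state pairs in this system sit at 3.5 sigma and above and are essentially
always resolved.

Within the pipeline each particle is processed as follows.  Clustering
uses events of at least 2 frames (retrying with 4- and 6-frame floors if
the constellation fails the structural gate below); all events are then
assigned by multinomial likelihood of their summed channel counts against
per-state aggregate channel patterns, iterated to a fixed point.
Aggregates sum corrected intensities over a state's events (at least
3 frames long), which maximizes SNR and sidesteps the arcsine bias.

The local frame and the C1..C4 labels come from a structural match: every
ordered pair of state means is tried as the (C1, C4) frame anchors, and
the phi sequence of the phi-ordered states is compared against the
crystallographic reference orientations of E_x, E_o, I_o, I_x.  Only phi
enters this decision because phi is a pure intensity-ratio angle immune to
amplitude dilution, whereas theta near 90 is not; the phi fan
(0, ~18, ~27, ~40 degrees) is asymmetric enough to fix the frame
orientation.  A particle whose best match exceeds 45 deg^2 summed squared
misfit has a degenerate constellation and is dropped ("states
unresolved").  A 1-frame event lying between two *different* states and
matching neither is treated as the camera's mixed transition frame and
absorbed into the preceding dwell; consecutive same-state events (the
changepoint false positives) are merged with frame-weighted intensities.
State probabilities are time-weighted occupancies; p_ij are exit counts
normalized per row.

## Dwell-time kinetics

Camera recording quantizes dwells.  For an exponential dwell starting at a
uniform phase within a frame, the number of frames it *spans* follows
(a = lambda dt):

    P(1) = 1 − (1 − e^-a)/a,   P(k≥2) = (1 − e^-a)^2/a · e^{−a(k−2)}

validated against a Monte-Carlo oracle.  Dwells delimited by detected
changepoints snap to the nearest frame boundary, so their length law is
the span law shifted down by one frame ("boundary" convention;
zero-length events are invisible).  Mixtures are renormalized jointly so
the fitted f keeps its continuous-time amplitude meaning.  Fits use
k_min = 3 by default: 1–2-frame dwells are partially missed by detection
and contaminated by transition frames, and truncating them removes the
bias at modest information cost.  First/last dwells of each trace are
right-censored and enter the likelihood as survival terms, which undoes
the length bias against slow dwells that simply dropping them would cause.
A three-phase variant of the dwell law with a missed-excursion merge
probability is provided (`serial_missed_pmf`) for sensitivity analysis;
the merge probability is not separately identifiable per condition, so the
default fits do not use it.

The serial scheme (entry substate A exiting at k_out and exchanging with
cul-de-sac B at k_ab/k_ba) gives a two-exponential dwell with
lambda1 + lambda2 = k_out + k_ab + k_ba, lambda1 lambda2 = k_out k_ba and
f lambda1 + (1−f) lambda2 = k_out; the inversion is closed-form and
checked against the eigen-solution (lambda2 is computed with the stable
quadratic form to avoid cancellation).  Non-physical inversions (f on its
boundary, negative k_ab) raise with diagnostics.

Apparent rates follow one-site isotherms in ligand concentration.  Two
estimation routes exist:

- per-condition: a dwell fit per conformation per condition, inverted to
  20 apparent rates, then isotherm fits across conditions;
- global (used by the pipeline): one joint maximum-likelihood fit per
  conformation over *all* conditions, parameterized at the rate level —
  k_out and k_ab share the entry substate's K_half per ligand, k_ba has
  its own — which is exactly the structure rapid-equilibrium binding
  imposes and which makes the slow-component parameters identifiable at
  realistic event counts.

The isotherm fits run in log space with bounds, grouped by starting state
(all transitions out of one state share its K_half per ligand).  A
Gaussian prior on log K_half, centered on the median tested concentration
with a width of 1.5 log-units (about the tested decade), expresses that a
midpoint far outside the concentration window is not identifiable; without
it the near-flat cul-de-sac isotherms can collapse their midpoint and
decouple the apo intercept from the ligand series.

Energetic-state probabilities are the stationary distribution (null space
of the transposed generator) of the 8-state scheme built from the 20
apparent rates.  Their concentration dependence is fitted globally with
the two-branch equilibrium model (apo ratios K_i1 shared between ligand
series; per-ligand bound ratios and K_D1), and per-state dissociation
constants follow the thermodynamic cycle K_Di = K_D1 K_i1 / LK_i1.  The
F-test for single- vs double-exponential dwell fits uses the
likelihood-ratio F form, F = Delta(2 log L)/2 against F(2, n−3); the null
sits on the mixture boundary, which makes the test slightly conservative
(measured size ~0.04 at nominal 0.05).

## The 24-state transport model

States: 8 apo + 8 bound per substrate species; binding edges only at the
open substates S6 and S7, at kon [L] (kon = 1e7 /M/s, near diffusion
limited) and koff = kon K_D.  Sidedness configuration 1 puts S6 on the
external side and S7 internal; configuration 2 swaps them; random vesicle
orientation is modeled as the average of the two.  Asymmetric conditions
(e.g. different pH per side) are expressed through the per-side K_D's the
model is built with.  The generator's rows sum to zero by construction.

Stochastic simulation is the exact Gillespie algorithm on one transporter,
optionally updating integer substrate counts in a two-compartment system
at every binding/unbinding event.  Deterministic transport integrates the
24 state probabilities coupled to substrate amounts (LSODA, rtol 1e-8):
d n(sp, side) = n_t (koff P_bound − kon c P_apo) summed over that side's
binding edges, which conserves each species (solution + transporter-bound)
to integrator precision.  Fractional uptake is internal tracer over total
tracer.  Compartments are parameterized by the outside-to-inside volume
ratio r_v and an internal volume in "molecules per mol/L" units; because
a single simulated transporter can hold one substrate molecule, volumes
should be chosen so total substrate amounts are at least hundreds of
molecules, or protein sequestration distorts the equilibria.

Net flux through the transport path is evaluated on the five serially
related stages (external binding, serial entry, the three parallel
inter-conformational routes, serial exit, internal release) as forward
minus backward rate; at a stationary state all five agree by node balance,
and the middle stage sums its three parallel cuts.  Michaelis–Menten
parameters come from least-squares fits of quasi-steady-state rates, with
an optional nonzero floor — the signature separating a uniporter (nonzero
efflux at vanishing external substrate) from an obligatory exchanger.

Exchange thermodynamics are closed-form: mixing by 1:1 exchange conserves
per-compartment totals and equalizes the tracer fraction, so
F_max = 1/(1 + r_v/r_c) regardless of kinetics, while a transporter with
an apo pathway ultimately relaxes to the volume partition 1/(1 + r_v).
The exchanger model variant removes the twelve apo inter-conformational
transitions and keeps the apo serial ones.

## Synthetic data

The generator emulates what the analysis assumes: per-branch 8-state
Markov dwell kinetics, four dipole orientations (defaults are the
measured C1–C4 means: theta 90/88.7/77.4/90, phi 0/17.9/27.2/40.5,
delta = 27 degrees), wobble depolarization, Poisson shot noise, physical
frame integration across transitions, single-step photobleaching (plus an
optional second fluorophore for QC-violating particles), and random
molecule rotation about the optical axis (nanodiscs lie in the coverslip
plane, so attachment randomizes the in-plane angle).

The "adic-like" preset is built from state free energies and symmetric
barriers, which imposes detailed balance within and across branches.  At
symmetric substrate detailed balance is thermodynamically required of a
real transporter, and it makes the synthetic world exactly self-
consistent: apparent rates follow one-site isotherms with midpoint equal
to the starting state's K_D, and the equilibrium model of the state
probabilities holds exactly, so end-to-end parameter recovery is well
posed.  Default magnitudes: inter-conformational rates ~1–3 /s (entry-
state exit rates k_out ~ 6–10 /s, fast dwell component tau1 ~ 0.1–0.15 s),
serial forward rates ~0.3–0.35 /s (at least 5x slower than the median of
the other rates — the cul-de-sac signature), serial backward ~1 /s (slow
component tau2 ~ 1 s carrying 5–7% of the amplitude), K_D ~ 60–210 uM.
These sit inside the regime the experimental dwell distributions span
(tens of milliseconds to seconds) and make the two exponential components
clearly separable (lambda1/lambda2 ~ 8).  Traces default to 2400 frames of
10 ms with bleaching at 23 s and ~400 signal photons/frame over a 5
photons/frame/channel background (SNR ~ 19, inside the 5–20 operating
band), giving roughly 100 events per particle; 25 particles per condition
lands event counts in the realistic 945–3,187 per-condition window.  The
"random" preset draws log-uniform rates without detailed balance and is
used for property tests only.

What the generator does *not* emulate: EMCCD excess noise (shot noise is
pure Poisson; the camera's noise statistics are undocumented), drift,
blinking, image formation (pixels are already summed), orientation spread
within a state (cluster widths in synthetic data are purely shot-noise
driven, narrower than the measured 4–10 degree state widths), and
out-of-plane attachment tilt.  Passing the end-to-end benchmark therefore
demonstrates the correctness and statistical calibration of the analysis
chain under its own assumptions, not robustness to every instrumental
nonideality of real recordings.

## Design choices on genuinely open points

- State probabilities are time-weighted occupancies (not event fractions),
  matching their use as stationary probabilities.
- p_ij are exit-conditional (rows sum to one), as "state-to-state
  transition probabilities" implies.
- The 2.5-sigma resolution test uses the mixture-based pair statistic
  described above; a per-axis RMS variant is available via
  ``sigma_mode="total"``.
- Detected dwell lengths use the "boundary" convention (changepoints snap
  to the nearest frame boundary); the raw span law is available as
  ``convention="span"``.
- Instrument-specific channel corrections are reduced to explicit
  per-channel gain/background calibration plus the wobble correction.

## Known limitations

- Short events (1–2 frames) are unreliable: partially missed by detection,
  and their intensities may mix adjacent states.  The dwell likelihood
  truncates them; merged-dwell contamination from missed excursions is
  first-order mitigated but not fully modeled.
- The serial-scheme inversion amplifies errors in f: the slow serial rates
  are the least precise of the 60 constants (the global rate-level fit
  exists for exactly this reason).
- Near theta = 90 the wobble-corrected inclination is intrinsically
  fragile; analyses lean on phi wherever a frame decision is needed.
- The transport model omits membrane potential and treats pH only through
  the parameter sets measured at each pH.
- Single-molecule compartment simulations need compartments holding
  hundreds of substrate molecules to keep transporter sequestration
  negligible.
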