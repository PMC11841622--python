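"""End-to-end driver: simulate -> detect -> cluster -> fit -> model.

The analysis chain mirrors the two-step experimental workflow: transitions
are found first (changepoint), then states are identified from the event
orientations (shortest-distance clustering), each particle is rotated into
the molecule-local frame defined by its C1/C4 states, events are pooled,
dwell-time mixtures are fitted per conformation and condition, and the
apparent rates are inverted and fitted across concentrations to the 60 rate
constants and the equilibrium/K_D set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import changepoint, dwellkin, polarimetry, statecall, synthgen
from .changepoint import PolarizedTrace, ThresholdTable
from .polarimetry import Calibration, SphericalOrientation

# crystallographic reference orientations (E_x, E_o, I_o, I_x), used to
# disambiguate which end of the conformational fan is C1
STRUCT_ORIENTATIONS = (
    SphericalOrientation(93.8, -1.89),
    SphericalOrientation(83.6, 20.9),
    SphericalOrientation(71.7, 27.5),
    SphericalOrientation(95.3, 38.7),
)


@dataclass
class PipelineConfig:
    confidence: float = 0.95
    min_events: int = 15
    min_snr: float = 5.0
    max_bleach_steps: int = 1
    k_max: int = 4                 # states expected per particle
    kmeans_n_init: int = 5
    resolution: float = 2.5
    dwell_k_min: int = 3
    dwell_convention: str = "boundary"
    n_restarts: int = 6
    max_frame_misfit: float = 45.0    # deg^2, phi-pattern structural match
    seed: int = 0

    def validate(self):
        if min(self.min_events, self.min_snr, self.confidence) <= 0:
            raise ValueError("thresholds must be positive")
        return self


def simulate_condition(truth: synthgen.GroundTruth, ligand: str | None,
                       conc: float, n_particles: int, spec: synthgen.TraceSpec,
                       seed: int = 0, rotate: bool = True) -> list[PolarizedTrace]:
    """Render one ligand condition's worth of particles.

    Each particle gets an independent trajectory of the 8-state apparent
    generator and, mimicking random attachment in the coverslip plane, a
    random rotation of the molecule about the optical axis.
    """
    q = truth.generator8(ligand, conc)
    dt = spec.frame_interval
    duration = spec.n_frames * dt + dt
    cal = Calibration(delta_deg=truth.delta_deg,
                      backgrounds=(spec.background_rate,) * 4)
    rng = np.random.default_rng(seed)
    traces = []
    for p in range(n_particles):
        sub = int(rng.integers(0, 2**31 - 1))
        times, states8 = synthgen.simulate_ctmc(q, duration, seed=sub)
        t, confs = synthgen.conformation_path(times, states8)
        if rotate:
            psi = rng.uniform(0, 2 * np.pi)
            cp, sp_ = np.cos(psi), np.sin(psi)
            rz = np.array([[cp, -sp_, 0.0], [sp_, cp, 0.0], [0.0, 0.0, 1.0]])
            orients = [polarimetry.vector_to_orientation(rz @ o.unit_vector())
                       for o in truth.orientations]
        else:
            orients = list(truth.orientations)
        counts = synthgen.render_trace(t, confs, truth, spec, seed=sub + 1,
                                       orientations=orients)
        traces.append(PolarizedTrace(
            counts=counts, frame_interval=dt, calibration=cal,
            condition={"ligand": ligand or "apo", "conc": conc, "particle": p}))
    return traces


def _orient_particle(mean_vectors: np.ndarray):
    """Pick the local frame via the structural match on the phi pattern.

    Every ordered pair of state means is tried as the (C1, C4) frame
    anchors; within each candidate frame the states are ordered by phi and
    the phi sequence is compared (summed squared degrees) with that of the
    crystallographic E_x, E_o, I_o, I_x orientations.  phi is used alone
    because it is a pure intensity-ratio angle, immune to the polarization-
    amplitude dilution that biases theta near 90 degrees.  Returns
    (rotation matrix, order of cluster indices as C1..C4, misfit in deg^2);
    a large misfit signals an unresolved/degenerate state constellation.
    """
    ref_phi = np.array([o.phi_deg for o in STRUCT_ORIENTATIONS])
    best = None
    for c1, c4 in itertools.permutations(range(len(mean_vectors)), 2):
        try:
            r = polarimetry.local_frame_rotation(mean_vectors[c1],
                                                 mean_vectors[c4])
        except ValueError:
            continue
        local = mean_vectors @ r.T
        phis = np.array([polarimetry.vector_to_orientation(v).phi_deg
                         for v in local])
        order = np.argsort(phis)
        diff = (phis[order] - ref_phi + 90.0) % 180.0 - 90.0
        d2 = float(diff @ diff)
        if best is None or d2 < best[0]:
            best = (d2, r, order)
    d2, r, order = best
    return r, order, d2


def analyze_particle(kept: dict, config: PipelineConfig) -> pd.DataFrame | None:
    """Label one particle's events, map to the local frame, merge runs.

    Returns the merged event table (with ``state`` 0..3 as C1..C4 and local
    frame angles) or None when the four states cannot be resolved.
    """
    events = kept["events"]
    delta = kept["trace"].calibration.delta_deg
    ev = events[~events["degenerate"]].reset_index(drop=True)
    vecs_lab = statecall.events_to_vectors(ev)

    # short events may be camera frames straddling a transition, whose
    # averaged intensities mimic an intermediate orientation; cluster on the
    # longer events only, then iterate maximum-likelihood reassignment of
    # all events against aggregate channel patterns (summing intensities
    # over a state's events maximizes SNR and sidesteps the arcsin bias).
    # If the resulting constellation fails the structural-match gate, retry
    # seeding from progressively longer events.
    best = None
    for min_len in (2, 4, 6):
        reliable = events[(events["n_frames"] >= min_len) & ~events["degenerate"]]
        try:
            model, _ = statecall.cluster_orientations(
                reliable, k_max=config.k_max, seed=config.seed,
                n_init=config.kmeans_n_init, resolution=config.resolution,
                min_events=config.min_events)
        except ValueError:
            continue
        if model.k != 4:
            continue
        labels_all = np.argmax(np.abs(vecs_lab @ model.mean_vectors.T), axis=1)
        mean_vectors = model.mean_vectors
        try:
            for _ in range(3):
                patterns, mean_vectors = statecall.aggregate_patterns(
                    ev, labels_all, 4, delta_deg=delta, min_frames=3)
                new = statecall.assign_by_intensity(ev, patterns)
                if (new == labels_all).all():
                    break
                labels_all = new
        except ValueError:
            continue
        r, order, misfit = _orient_particle(mean_vectors)
        if best is None or misfit < best[0]:
            best = (misfit, r, order, labels_all)
        if misfit <= config.max_frame_misfit:
            break
    if best is None or best[0] > config.max_frame_misfit:
        return None        # degenerate constellation; states unresolved
    _, r, order, labels_all = best
    remap = np.full(4, -1)
    remap[order] = np.arange(4)
    new_labels = remap[labels_all]
    orients = [polarimetry.vector_to_orientation(v) for v in vecs_lab @ r.T]
    ev["theta"] = [o.theta_deg for o in orients]
    ev["phi"] = [o.phi_deg for o in orients]
    # transition-frame rule: a camera frame straddling a large orientation
    # jump is split off as a 1-frame event whose mixed intensities mimic an
    # intermediate state; absorb it into the preceding dwell when it sits
    # between two *different* states and matches neither
    nf = ev["n_frames"].to_numpy()
    for i in range(1, len(ev) - 1):
        if (nf[i] == 1 and new_labels[i - 1] != new_labels[i + 1]
                and new_labels[i] not in (new_labels[i - 1], new_labels[i + 1])):
            new_labels[i] = new_labels[i - 1]
    if set(np.unique(new_labels)) != {0, 1, 2, 3}:
        return None
    merged = statecall.merge_same_state(ev, new_labels)
    c1_mean = polarimetry.vector_to_orientation(
        polarimetry.mean_orientation(statecall.events_to_vectors(
            merged[merged["state"] == 0])))
    merged["omega_vs_C1"] = [
        polarimetry.omega(SphericalOrientation(t, p), c1_mean)
        for t, p in zip(merged["theta"], merged["phi"])]
    merged["particle"] = kept["trace"].condition.get("particle", 0)
    return merged


@dataclass
class ConditionResult:
    ligand: str | None
    conc: float
    events: pd.DataFrame
    stats: statecall.TransitionStats
    fits: dict[int, dwellkin.DwellFitResult]
    appk: dict[tuple[int, int], float]
    n_particles_kept: int
    n_particles_rejected: int


def analyze_condition(traces: list[PolarizedTrace], config: PipelineConfig,
                      thresholds: ThresholdTable | None = None) -> ConditionResult:
    """QC, detect, label and fit one ligand condition."""
    config.validate()
    if thresholds is None:
        thresholds = ThresholdTable(confidence=config.confidence)
    kept, rejected = changepoint.filter_particles(
        traces, min_events=config.min_events, min_snr=config.min_snr,
        max_bleach_steps=config.max_bleach_steps,
        confidence=config.confidence, thresholds=thresholds)
    tables = []
    n_unresolved = 0
    for k in kept:
        merged = analyze_particle(k, config)
        if merged is None:
            n_unresolved += 1
            continue
        tables.append(merged)
    if not tables:
        raise ValueError("no particle passed QC and state resolution")
    pooled = pd.concat(tables, ignore_index=True)
    stats = statecall.state_statistics(pooled, k=4)

    # first/last dwell of each particle is censored (start/end unobserved)
    pooled["censored"] = False
    for _, pg in pooled.groupby("particle"):
        pooled.loc[pg.index[0], "censored"] = True
        pooled.loc[pg.index[-1], "censored"] = True

    dt = traces[0].frame_interval
    fits = {}
    for s in range(4):
        grp = pooled[(pooled["state"] == s) & ~pooled["censored"]]
        dwells = grp["n_frames"].to_numpy(dtype=int)
        dwells = dwells[dwells >= config.dwell_k_min]
        cens = pooled[(pooled["state"] == s) & pooled["censored"]]
        fits[s + 1] = dwellkin.fit_dwell(
            dwells, dt, ncomp=2, k_min=config.dwell_k_min,
            convention=config.dwell_convention, seed=config.seed,
            n_restarts=config.n_restarts,
            censored=cens["n_frames"].to_numpy(dtype=int))
    appk = dwellkin.apparent_rates_from_fits(fits, stats.p)
    cond = traces[0].condition
    return ConditionResult(
        ligand=cond.get("ligand"), conc=cond.get("conc", 0.0), events=pooled,
        stats=stats, fits=fits, appk=appk,
        n_particles_kept=len(tables),
        n_particles_rejected=len(rejected) + n_unresolved)


@dataclass
class RecoveryResult:
    rates: dwellkin.RateSet
    equilibrium: dwellkin.EquilibriumSet
    conditions: dict[tuple[str | None, float], ConditionResult]

    def kd(self, ligand: str) -> np.ndarray:
        return self.equilibrium.kd(ligand)


def run_recovery(truth: synthgen.GroundTruth,
                 concentrations: dict[str, list[float]],
                 n_particles: int = 25,
                 spec: synthgen.TraceSpec | None = None,
                 config: PipelineConfig | None = None,
                 seed: int = 0) -> RecoveryResult:
    """Full synthetic benchmark: simulate every condition, analyze, refit.

    ``concentrations`` maps ligand -> positive concentration list; the apo
    condition is always included once and shared between the ligand series.
    """
    spec = spec or synthgen.TraceSpec()
    config = config or PipelineConfig(seed=seed)
    thresholds = ThresholdTable(confidence=config.confidence)
    conditions: dict[tuple[str | None, float], ConditionResult] = {}
    all_conditions = [("apo", 0.0)] + [
        (lig, c) for lig in sorted(concentrations) for c in concentrations[lig] if c > 0]
    for idx, (lig, conc) in enumerate(all_conditions):
        traces = simulate_condition(
            truth, None if lig == "apo" else lig, conc, n_particles, spec,
            seed=(seed * 7919 + idx * 104729) % (2**31 - 1))
        conditions[(lig, conc)] = analyze_condition(traces, config, thresholds)

    # global dwell fits (one joint MLE per conformation over every ligand
    # condition, each exponential component coupled to a binding isotherm)
    # sharpen the slow-component parameters far beyond per-condition fits
    dt = spec.frame_interval
    curves_by_state = {}
    for s in range(1, 5):
        dwell_sets, censored_sets = {}, {}
        for key, res in conditions.items():
            ev = res.events
            dw = ev[(ev["state"] == s - 1) & ~ev["censored"]]["n_frames"]
            dw = dw.to_numpy(dtype=int)
            dwell_sets[key] = dw[dw >= config.dwell_k_min]
            censored_sets[key] = ev[(ev["state"] == s - 1)
                                    & ev["censored"]]["n_frames"].to_numpy(dtype=int)
        gf = dwellkin.global_fit_serial(
            dwell_sets, dt, k_min=config.dwell_k_min,
            convention=config.dwell_convention, seed=config.seed + s,
            censored_sets=censored_sets)
        curves_by_state[s] = gf["rates"]

    appk_by_condition = {}
    for key, res in conditions.items():
        appk = {}
        for s in range(1, 5):
            k_out, k_ab, k_ba = curves_by_state[s][key]
            others = [j for j in range(1, 5) if j != s]
            for j in others:
                appk[(s, j)] = k_out * res.stats.p[s - 1, j - 1]
            appk[(s, s + 4)] = k_ab
            appk[(s + 4, s)] = k_ba
        appk_by_condition[key] = appk
    rates = dwellkin.fit_eq3(appk_by_condition)
    p_by_condition = {key: dwellkin.energetic_state_probabilities(res.appk)
                      for key, res in conditions.items()}
    equilibrium = dwellkin.fit_equilibrium(p_by_condition)
    return RecoveryResult(rates=rates, equilibrium=equilibrium,
                          conditions=conditions)
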