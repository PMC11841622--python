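"""Ground-truth models and synthetic microscopy/flux datasets.

The recordings this package analyzes are not publicly deposited, so every
downstream stage is exercised against synthetic data with the statistical
structure the analysis assumes: an 8-state-per-branch Markov dwell process
(entry substates S1-S4 exchanging among conformations, cul-de-sac partners
S5-S8), four dipole orientations per conformation, wobble depolarization,
Poisson shot noise, single-step photobleaching, and fractional-uptake flux
assays with lognormal sampling noise.

The "adic-like" preset imposes detailed balance within and across branches
(state free energies + symmetric barriers).  At symmetric substrate this is
what thermodynamics requires of a real transporter, and it makes the
binding-isotherm description of the apparent rates (midpoint = the starting
state's K_D under rapid-equilibrium binding) and the two-branch equilibrium
model of the state probabilities exact, so parameter recovery is well posed.
Its four slow serial forward rates (k_1,5 ... k_4,8) are markedly slower
than every other rate, the qualitative signature of the cul-de-sac states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import polarimetry
from .dwellkin import (RateSet, TRANSITIONS, INTER_PAIRS, build_generator8,
                       forward_serial, stationary_distribution)
from .model24 import CompartmentSystem, Model24, Species, integrate_transport
from .polarimetry import SphericalOrientation

LIGANDS = ("arg", "agm")

# reference orientations of C1-C4 (degrees): polarization means measured with
# the bifunctional probe in the presence of Agm
DEFAULT_ORIENTATIONS = ((90.0, 0.0), (88.7, 17.9), (77.4, 27.2), (90.0, 40.5))
DEFAULT_DELTA = 27.0


@dataclass
class GroundTruth:
    """A fully specified synthetic transporter.

    ``rates`` holds the 60 rate constants; ``kd`` maps branch -> state ->
    dissociation constant (mol/L) for all eight states (the consequential
    ones are the open substates S6/S7); ``orientations`` are the four
    conformation dipole orientations; ``delta_deg`` the wobble half-cone.
    """

    rates: RateSet
    kd: dict[str, dict[int, float]]
    orientations: tuple[SphericalOrientation, ...]
    delta_deg: float
    seed: int

    def __post_init__(self):
        self.rates.validate()
        for lig in LIGANDS:
            if any(v <= 0 for v in self.kd[lig].values()):
                raise ValueError("dissociation constants must be positive")
        for o in self.orientations:
            if not (0 <= o.theta_deg <= 90 and -90 < o.phi_deg <= 90):
                raise ValueError("orientation out of range")
        if not 0 <= self.delta_deg < polarimetry.MAX_DELTA_DEG:
            raise ValueError("delta out of range")

    # -- kinetic structure -------------------------------------------------

    def apparent_rates(self, ligand: str | None, conc: float) -> dict:
        """The 20 apparent rates at one ligand concentration.

        Rapid-equilibrium binding makes each transition out of state i an
        isotherm between the apo and bound rate with midpoint K_D(i).
        """
        if ligand in (None, "apo") or conc == 0:
            return dict(self.rates.apo)
        bound = self.rates.branch(ligand)
        kd = self.kd[ligand]
        out = {}
        for (i, j) in TRANSITIONS:
            x = conc / kd[i]
            out[(i, j)] = (self.rates.apo[(i, j)] + bound[(i, j)] * x) / (1.0 + x)
        return out

    def generator8(self, ligand: str | None, conc: float) -> np.ndarray:
        return build_generator8(self.apparent_rates(ligand, conc))

    def analytic_dwell_params(self, ligand: str | None, conc: float,
                              conformation: int):
        """(lambda1, lambda2, f) of conformation 1-4 at this condition."""
        appk = self.apparent_rates(ligand, conc)
        i = conformation
        k_out = sum(appk[(i, j)] for j in range(1, 5) if j != i)
        return forward_serial(k_out, appk[(i, i + 4)], appk[(i + 4, i)])

    def exit_probabilities(self, ligand: str | None, conc: float) -> np.ndarray:
        """4x4 conformation exit-branching matrix p_ij (diagonal 0)."""
        appk = self.apparent_rates(ligand, conc)
        p = np.zeros((4, 4))
        for i in range(1, 5):
            k_out = sum(appk[(i, j)] for j in range(1, 5) if j != i)
            for j in range(1, 5):
                if j != i:
                    p[i - 1, j - 1] = appk[(i, j)] / k_out
        return p

    def to_model24(self, species: tuple[Species, ...] | None = None,
                   sidedness: int = 1, kon: float = 1e7) -> Model24:
        kd = {lig: {6: self.kd[lig][6], 7: self.kd[lig][7]} for lig in LIGANDS}
        if species is None:
            species = (Species("R", "arg"), Species("NR", "arg"))
        return Model24(rates=self.rates, kd=kd, species=tuple(species),
                       kon=kon, sidedness=sidedness)


@dataclass
class TraceSpec:
    """Rendering parameters for one synthetic particle recording."""

    frame_interval: float = 0.010            # s (10 ms camera frames)
    n_frames: int = 2400
    photon_rate: float = 400.0               # expected signal photons/frame
    background_rate: float = 5.0             # photons/frame/channel
    bleach_time: float | None = 23.0          # s; None = no bleach in window
    snr_target: float | None = None

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.snr_target is not None:
            # SNR = r / sqrt(r + 4 b)  =>  r = (S^2 + sqrt(S^4 + 16 S^2 b))/2
            s2 = self.snr_target ** 2
            self.photon_rate = 0.5 * (s2 + np.sqrt(s2 * s2 + 16 * s2 * self.background_rate))
        if self.photon_rate <= 0:
            raise ValueError("photon_rate must be positive")

    @property
    def snr(self) -> float:
        return self.photon_rate / np.sqrt(self.photon_rate + 4 * self.background_rate)


# ---------------------------------------------------------------------------
# ground-truth presets
# ---------------------------------------------------------------------------

def _rates_from_potentials(g: np.ndarray, barriers: dict, k0: float) -> dict:
    """Detailed-balance rates k_ij = k0 exp(-b_ij + (g_i - g_j)/2)."""
    out = {}
    for (i, j) in TRANSITIONS:
        b = barriers[(min(i, j), max(i, j))]
        out[(i, j)] = k0 * np.exp(-b + (g[i - 1] - g[j - 1]) / 2.0)
    return out


def make_ground_truth(preset: str = "adic-like", seed: int = 0) -> GroundTruth:
    """Build a ground-truth model; deterministic given (preset, seed)."""
    rng = np.random.default_rng(seed)
    if preset == "adic-like":
        # free energies (kT); cul-de-sac states S5-S8 sit slightly higher
        # than their entry partners, behind tall serial barriers, so the
        # slow dwell component is long-lived and clearly separated
        g_apo = np.array([0.0, 0.3, 0.5, 0.2, 1.1, 1.4, 1.6, 1.3])
        g_arg = np.array([0.1, -0.4, -0.3, 0.0, 1.2, 0.7, 0.8, 1.1])
        g_agm = np.array([0.0, -0.2, -0.5, 0.1, 1.1, 0.9, 0.6, 1.2])
        barriers = {}
        for (i, j) in INTER_PAIRS:
            if i < j:
                barriers[(i, j)] = rng.uniform(-0.3, 0.3) - 0.24
        for i in range(1, 5):
            # tall serial barriers make k_i,i+4 the slowest rates
            barriers[(i, i + 4)] = 1.35 + rng.uniform(-0.05, 0.05)
        k0 = 2.2

        def jitter(pair):   # bound serial barriers stay tall (cul-de-sac)
            return rng.uniform(0.0, 0.2) if pair[1] == pair[0] + 4 \
                else rng.uniform(-0.25, 0.25)

        b_arg = {k: v + jitter(k) for k, v in barriers.items()}
        b_agm = {k: v + jitter(k) for k, v in barriers.items()}
        rates = RateSet(apo=_rates_from_potentials(g_apo, barriers, k0),
                        arg=_rates_from_potentials(g_arg, b_arg, k0),
                        agm=_rates_from_potentials(g_agm, b_agm, k0))
        # K_D at S6 chosen per ligand; the rest follow the thermodynamic
        # cycle K_D(i) = K_D(6) exp[(gL_i - gL_6) - (g_i - g_6)]
        kd = {}
        for lig, g_l, kd6 in (("arg", g_arg, 1.0e-4), ("agm", g_agm, 2.0e-4)):
            kd[lig] = {i: float(kd6 * np.exp((g_l[i - 1] - g_l[5]) - (g_apo[i - 1] - g_apo[5])))
                       for i in range(1, 9)}
        khalf = {lig: {(i, j): kd[lig][i] for (i, j) in TRANSITIONS} for lig in LIGANDS}
        rates.khalf = khalf
        orientations = tuple(SphericalOrientation(t, p) for t, p in DEFAULT_ORIENTATIONS)
        return GroundTruth(rates=rates, kd=kd, orientations=orientations,
                           delta_deg=DEFAULT_DELTA, seed=seed)
    if preset == "random":
        def branch():
            out = {}
            for (i, j) in TRANSITIONS:
                if j == i + 4:
                    out[(i, j)] = float(np.exp(rng.uniform(np.log(0.3), np.log(1.5))))
                elif i == j + 4:
                    out[(i, j)] = float(np.exp(rng.uniform(np.log(2.0), np.log(8.0))))
                else:
                    out[(i, j)] = float(np.exp(rng.uniform(np.log(2.0), np.log(20.0))))
            return out
        rates = RateSet(apo=branch(), arg=branch(), agm=branch())
        kd = {lig: {i: float(np.exp(rng.uniform(np.log(3e-5), np.log(3e-4))))
                    for i in range(1, 9)} for lig in LIGANDS}
        rates.khalf = {lig: {(i, j): kd[lig][i] for (i, j) in TRANSITIONS}
                       for lig in LIGANDS}
        th = rng.uniform(40, 90, size=4)
        ph = rng.uniform(-80, 80, size=4)
        orientations = tuple(SphericalOrientation(float(t), float(p))
                             for t, p in zip(th, ph))
        return GroundTruth(rates=rates, kd=kd, orientations=orientations,
                           delta_deg=float(rng.uniform(0, 40)), seed=seed)
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# stochastic trajectories and trace rendering
# ---------------------------------------------------------------------------

def simulate_ctmc(q: np.ndarray, duration: float, seed: int = 0,
                  start: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie trajectory of a generator; returns (times, states).

    ``times``/``states`` describe piecewise-constant occupancy: state[i]
    holds on [times[i], times[i+1]); the last entry closes at ``duration``.
    Starts from the stationary distribution unless ``start`` is given.
    """
    rng = np.random.default_rng(seed)
    n = q.shape[0]
    if start is None:
        start = int(rng.choice(n, p=stationary_distribution(q)))
    t, s = 0.0, start
    times, states = [0.0], [s]
    while True:
        rates = q[s].copy()
        rates[s] = 0.0
        total = rates.sum()
        if total <= 0:
            raise RuntimeError(f"absorbing state {s}")
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        s = int(rng.choice(n, p=rates / total))
        times.append(t)
        states.append(s)
    times.append(duration)
    return np.asarray(times), np.asarray(states, dtype=int)


def conformation_path(times: np.ndarray, states8: np.ndarray):
    """Collapse an 8-state path to conformations 0-3, merging serial visits."""
    confs = np.where(states8 < 4, states8, states8 - 4)
    keep = np.concatenate([[True], confs[1:] != confs[:-1]])
    return times[np.concatenate([keep, [True]])], confs[keep]


def frame_occupancy(times: np.ndarray, states: np.ndarray, n_frames: int,
                    dt: float, n_states: int = 4) -> np.ndarray:
    """(n_frames, n_states) fraction of each frame spent in each state."""
    occ = np.zeros((n_frames, n_states))
    t_end = n_frames * dt
    seg_starts = times[:-1]
    seg_ends = times[1:len(states) + 1] if len(times) == len(states) + 1 else times[1:]
    for t0, t1, s in zip(seg_starts, seg_ends, states):
        t0, t1 = max(t0, 0.0), min(t1, t_end)
        if t1 <= t0:
            continue
        f0, f1 = int(t0 / dt), min(int(np.ceil(t1 / dt)), n_frames)
        for f in range(f0, f1):
            lo, hi = f * dt, (f + 1) * dt
            occ[f, s] += (min(t1, hi) - max(t0, lo)) / dt
    return occ


def render_trace(times: np.ndarray, conf_states: np.ndarray, truth: GroundTruth,
                 spec: TraceSpec, seed: int = 0,
                 orientations: list[SphericalOrientation] | None = None,
                 second_fluor_bleach_time: float | None = None) -> np.ndarray:
    """Render a conformation path to four-channel Poisson photon counts.

    Frames straddling a transition mix the states' expected intensities in
    proportion to occupancy (the camera integrates physically).  After
    ``bleach_time`` all channels drop to background in a single step; a
    second fluorophore bleaching at ``second_fluor_bleach_time`` produces a
    two-step QC-violating particle.  Returns an (n_frames, 4) int array.
    """
    if len(conf_states) == 0:
        raise ValueError("empty state path")
    if times[-1] < spec.n_frames * spec.frame_interval - 1e-9:
        raise ValueError("path does not cover the requested trace duration")
    rng = np.random.default_rng(seed)
    orients = list(orientations if orientations is not None else truth.orientations)
    dt = spec.frame_interval
    occ = frame_occupancy(times, conf_states, spec.n_frames, dt,
                          n_states=len(orients))
    chan = np.array([polarimetry.forward_intensities(o, truth.delta_deg, spec.photon_rate)
                     for o in orients])           # (n_states, 4)
    expect = occ @ chan
    frame_t = (np.arange(spec.n_frames) + 0.5) * dt
    if second_fluor_bleach_time is not None:
        expect = expect + np.where(frame_t[:, None] < second_fluor_bleach_time,
                                   expect, 0.0)
    if spec.bleach_time is not None:
        expect = np.where(frame_t[:, None] < spec.bleach_time, expect, 0.0)
    expect = expect + spec.background_rate
    return rng.poisson(expect).astype(int)


def make_flux_protocol(conc_tracer_ext: float, conc_load_int: float, rv: float,
                       t_max: float, n_points: int = 40,
                       load_branch: str = "arg", tracer_branch: str = "arg",
                       volume_int: float = 1e4) -> dict:
    return {"conc_tracer_ext": conc_tracer_ext, "conc_load_int": conc_load_int,
            "rv": rv, "t_max": t_max, "n_points": n_points,
            "load_branch": load_branch, "tracer_branch": tracer_branch,
            "volume_int": volume_int}


def make_flux_dataset(truth: GroundTruth, protocol: dict, noise_cv: float = 0.0,
                      seed: int = 0, recovery_efficiency: float = 1.0,
                      average_sidedness: bool = True) -> pd.DataFrame:
    """Synthetic fractional-uptake assay: model curve x lognormal noise.

    The deterministic curve comes from the 24-ODE transport integration
    (averaged over the two sidedness configurations, mimicking random
    vesicle orientation); each sampled point is multiplied by lognormal
    noise with coefficient of variation ``noise_cv``, and optionally by a
    known recovery-efficiency factor.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    t_grid = np.linspace(protocol["t_max"] / protocol["n_points"],
                         protocol["t_max"], protocol["n_points"])
    species = (Species("R", protocol["tracer_branch"]),
               Species("NR", protocol["load_branch"]))
    curves = []
    for sided in (1, 2) if average_sidedness else (1,):
        m = truth.to_model24(species=species, sidedness=sided)
        comp = CompartmentSystem.from_concentrations(
            {"R": protocol["conc_tracer_ext"], "NR": 0.0},
            {"NR": protocol["conc_load_int"], "R": 0.0},
            rv=protocol["rv"], volume_int=protocol["volume_int"],
            recovery_efficiency=1.0)
        tc = integrate_transport(m, comp, t_grid)
        curves.append(tc.fractional_uptake)
    frac = np.mean(curves, axis=0) * recovery_efficiency
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        frac = frac * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=frac.shape)
    return pd.DataFrame({"time": t_grid, "fractional_uptake": frac})
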