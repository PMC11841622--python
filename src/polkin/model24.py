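"""The 24-state conformational-kinetic transport model.

States: 8 apo (S1..S8) plus 8 ligand-bound states per substrate species
(two species per simulation: e.g. radioactive external vs nonradioactive
internal substrate, or Arg vs Agm).  Binding edges exist only at the open
substates: S6 exchanges with one side of the membrane and S7 with the
other; which side is which is the "sidedness" configuration (1: C2 = E_o so
S6 faces the external solution; 2: swapped).  Binding is treated as rapid
association at kon (default 1e7 /M/s) with koff = kon * K_D.

The same machinery drives stochastic (Gillespie) trajectories, deterministic
transport (24 coupled ODEs with two-compartment substrate bookkeeping), net
flux rates along the five serial transport-path transitions, and the
two-compartment exchange thermodynamics that pin down the maximal fractional
uptake of a 1:1 exchanger.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .dwellkin import RateSet, stationary_distribution

KON_DEFAULT = 1e7        # /M/s, near diffusion-limited
N_APO = 8

FLUX_TRANSITIONS = ("bind_ext", "serial_ext", "inter", "serial_int", "release_int")


@dataclass
class Species:
    """A transportable substrate species.

    ``branch`` names the rate-constant branch ("arg" or "agm") governing the
    bound states; distinct species may share a branch (radioactive vs
    nonradioactive substrate of the same chemical identity).
    """

    name: str
    branch: str


@dataclass
class Model24:
    rates: RateSet
    kd: dict[str, dict[int, float]]     # branch -> {6: K_D(S6), 7: K_D(S7)} mol/L
    species: tuple[Species, ...] = (Species("R", "arg"), Species("NR", "arg"))
    kon: float = KON_DEFAULT
    sidedness: int = 1

    def __post_init__(self):
        if self.sidedness not in (1, 2):
            raise ValueError("sidedness must be 1 or 2")
        if len(self.species) > 2:
            raise ValueError("at most two species branches supported")
        self.rates.validate()

    @property
    def n_states(self) -> int:
        return N_APO + N_APO * len(self.species)

    def state_names(self) -> list[str]:
        names = [f"S{i}" for i in range(1, 9)]
        for sp in self.species:
            names += [f"S{i}.{sp.name}" for i in range(1, 9)]
        return names

    def open_state_side(self) -> dict[int, str]:
        """Which compartment the two open substates face."""
        return {6: "ext", 7: "int"} if self.sidedness == 1 else {6: "int", 7: "ext"}

    def koff(self, branch: str, state: int) -> float:
        return self.kon * self.kd[branch][state]


def make_exchanger(m: Model24) -> Model24:
    """Remove the apo inter-conformational pathway (obligatory 1:1 exchange).

    The 12 directed apo transitions among S1-S4 are deleted; the apo serial
    transitions S_i <-> S_{i+4} and the full bound branches are kept, so the
    protein can only change conformation while loaded.
    """
    apo = {p: k for p, k in m.rates.apo.items() if p[0] > 4 or p[1] > 4}
    rates = RateSet(apo=apo, arg=dict(m.rates.arg), agm=dict(m.rates.agm),
                    khalf=m.rates.khalf)
    out = replace(m)     # validates with the original rates
    out.rates = rates    # the exchanger intentionally lacks the apo inter rates
    return out


def build_generator(m: Model24, conc: dict[str, dict[str, float]]) -> np.ndarray:
    """24x24 generator at the given concentrations (rows sum to zero).

    ``conc`` maps species name -> {"ext": mol/L, "int": mol/L}.  Apo block
    uses the apo rates; each species block uses its branch's bound rates;
    binding edges connect apo S6/S7 to the corresponding bound state at
    kon*[L] (side per the sidedness configuration), unbinding at kon*K_D.
    """
    n = m.n_states
    q = np.zeros((n, n))
    for (i, j), k in m.rates.apo.items():
        q[i - 1, j - 1] = k
    sides = m.open_state_side()
    for b, sp in enumerate(m.species):
        off = N_APO * (b + 1)
        branch = m.rates.branch(sp.branch)
        for (i, j), k in branch.items():
            q[off + i - 1, off + j - 1] = k
        c = conc[sp.name]
        for s in (6, 7):
            cs = c[sides[s]]
            if cs < 0:
                raise ValueError("negative concentration")
            q[s - 1, off + s - 1] = m.kon * cs          # binding
            q[off + s - 1, s - 1] = m.koff(sp.branch, s)  # unbinding
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_state(m: Model24, conc) -> np.ndarray:
    """Stationary probabilities of the 24-state model at fixed concentrations."""
    q = build_generator(m, conc)
    # zero-ligand: bound blocks are unreachable; restrict to the apo block
    reachable = np.ones(m.n_states, dtype=bool)
    for b, sp in enumerate(m.species):
        off = N_APO * (b + 1)
        if all(q[s - 1, off + s - 1] == 0 for s in (6, 7)):
            reachable[off:off + N_APO] = False
    p = np.zeros(m.n_states)
    idx = np.where(reachable)[0]
    p[idx] = stationary_distribution(q[np.ix_(idx, idx)])
    return p


@dataclass
class CompartmentSystem:
    """Two-compartment bookkeeping for flux simulations.

    Substrate amounts are kept as molecule counts; ``volume_int`` converts
    counts to concentration (n / volume, so its unit is "molecules per
    mol/L") and the external volume is rv * volume_int.  ``n_transporters``
    scales the deterministic flux; ``recovery_efficiency`` is the assay
    correction factor applied to reported fractional uptakes.
    """

    rv: float
    volume_int: float = 1e4
    counts: dict[tuple[str, str], float] = field(default_factory=dict)
    n_transporters: float = 1.0
    recovery_efficiency: float = 1.0

    def __post_init__(self):
        if self.rv <= 0:
            raise ValueError("rv must be positive")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_concentrations(cls, conc_ext: dict[str, float], conc_int: dict[str, float],
                            rv: float, volume_int: float = 1e4, **kw) -> "CompartmentSystem":
        counts = {}
        for sp, c in conc_ext.items():
            counts[(sp, "ext")] = c * rv * volume_int
        for sp, c in conc_int.items():
            counts.setdefault((sp, "ext"), 0.0)
            counts[(sp, "int")] = c * volume_int
        for sp in {s for s, _ in counts}:
            counts.setdefault((sp, "int"), 0.0)
        return cls(rv=rv, volume_int=volume_int, counts=counts, **kw)

    def volume(self, side: str) -> float:
        return self.volume_int * (self.rv if side == "ext" else 1.0)

    def concentrations(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for (sp, side), n in self.counts.items():
            out.setdefault(sp, {"ext": 0.0, "int": 0.0})[side] = n / self.volume(side)
        return out

    def fractional_uptake(self, species: str = "R", bound: float = 0.0) -> float:
        tot = self.counts.get((species, "ext"), 0.0) + self.counts.get((species, "int"), 0.0) + bound
        if tot == 0:
            return 0.0
        return self.recovery_efficiency * self.counts.get((species, "int"), 0.0) / tot


@dataclass
class FluxTimeCourse:
    t: np.ndarray
    fractional_uptake: np.ndarray
    probabilities: np.ndarray        # (len(t), 24)
    counts: dict[tuple[str, str], np.ndarray]
    species: str = "R"


def _binding_edges(m: Model24):
    """(apo index, bound index, species, side, substate) per binding edge."""
    sides = m.open_state_side()
    edges = []
    for b, sp in enumerate(m.species):
        off = N_APO * (b + 1)
        for s in (6, 7):
            edges.append((s - 1, off + s - 1, sp, sides[s], s))
    return edges


def gillespie(m: Model24, comp: CompartmentSystem | None, duration: float,
              seed: int = 0, conc: dict | None = None,
              p0: np.ndarray | None = None, max_steps: int = 20_000_000):
    """Exact stochastic simulation of one transporter.

    With a :class:`CompartmentSystem`, substrate counts are updated at every
    binding/unbinding event (uptake and release), so concentrations co-evolve
    with the trajectory; with fixed ``conc`` the bath is treated as infinite.
    Returns (times, states, events, comp) where events is a list of
    (time, species, side, +1 for release into / -1 for uptake from).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    dynamic = comp is not None
    if dynamic:
        comp = replace(comp, counts=dict(comp.counts))
        get_conc = comp.concentrations
    else:
        if conc is None:
            raise ValueError("need a CompartmentSystem or fixed concentrations")
        get_conc = lambda: conc

    q = build_generator(m, get_conc())
    edges = _binding_edges(m)
    if p0 is None:
        state = 0
    else:
        state = int(rng.choice(m.n_states, p=p0))
    t = 0.0
    times, states, events = [0.0], [state], []
    for _ in range(max_steps):
        rates = q[state].copy()
        rates[state] = 0.0
        total = rates.sum()
        if total <= 0:
            raise RuntimeError(f"absorbing state {state}: zero exit rates")
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        nxt = int(rng.choice(m.n_states, p=rates / total))
        if dynamic:
            for apo_i, bound_i, sp, side, _s in edges:
                if state == apo_i and nxt == bound_i:      # uptake from `side`
                    comp.counts[(sp.name, side)] -= 1
                    events.append((t, sp.name, side, -1))
                    q = build_generator(m, get_conc())
                    break
                if state == bound_i and nxt == apo_i:      # release into `side`
                    comp.counts[(sp.name, side)] += 1
                    events.append((t, sp.name, side, +1))
                    q = build_generator(m, get_conc())
                    break
        else:
            for apo_i, bound_i, sp, side, _s in edges:
                if state == apo_i and nxt == bound_i:
                    events.append((t, sp.name, side, -1))
                    break
                if state == bound_i and nxt == apo_i:
                    events.append((t, sp.name, side, +1))
                    break
        state = nxt
        times.append(t)
        states.append(state)
    else:
        raise RuntimeError("max_steps exceeded")
    times.append(duration)
    states.append(state)
    return np.asarray(times), np.asarray(states, dtype=int), events, comp


def integrate_transport(m: Model24, comp: CompartmentSystem, t_grid,
                        tracer: str = "R", rtol: float = 1e-8,
                        atol: float = 1e-12, p0: np.ndarray | None = None) -> FluxTimeCourse:
    """Deterministic transport: 24 state ODEs coupled to substrate counts.

    dy/dt stacks dP = Q(c)^T P with the compartment bookkeeping
    dn(sp, side) = n_t * (koff * P_bound - kon * c * P_apo) summed over the
    binding edges on that side.  Mass of each species (solution + bound) is
    conserved exactly by construction.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if (np.diff(t_grid) <= 0).any():
        raise ValueError("t_grid must be strictly increasing")
    spp = list(m.species)
    keys = [(sp.name, side) for sp in spp for side in ("ext", "int")]
    edges = _binding_edges(m)
    n_states = m.n_states
    if p0 is None:
        # pre-equilibrate the transporter in the starting solutions; an
        # obligatory exchanger's apo block alone is disconnected, so the
        # zero-ligand chain cannot serve as the default
        conc0 = {sp.name: {side: comp.counts.get((sp.name, side), 0.0)
                           / comp.volume(side) for side in ("ext", "int")}
                 for sp in spp}
        try:
            p0 = stationary_state(m, conc0)
        except ValueError:
            p0 = np.concatenate([np.full(N_APO, 1.0 / N_APO),
                                 np.zeros(n_states - N_APO)])
    y0 = np.concatenate([p0, [comp.counts.get(k, 0.0) for k in keys]])
    nt = comp.n_transporters

    def rhs(_, y):
        p = y[:n_states]
        n = dict(zip(keys, y[n_states:]))
        conc = {sp.name: {side: max(n[(sp.name, side)], 0.0) / comp.volume(side)
                          for side in ("ext", "int")} for sp in spp}
        q = build_generator(m, conc)
        dp = q.T @ p
        dn = dict.fromkeys(keys, 0.0)
        for apo_i, bound_i, sp, side, s in edges:
            release = m.koff(sp.branch, s) * p[bound_i]
            uptake = m.kon * conc[sp.name][side] * p[apo_i]
            dn[(sp.name, side)] += nt * (release - uptake)
        return np.concatenate([dp, [dn[k] for k in keys]])

    t0, t1 = 0.0, float(t_grid[-1])
    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", t_eval=t_grid,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")
    probs = sol.y[:n_states].T
    counts = {k: sol.y[n_states + i] for i, k in enumerate(keys)}
    # fractional uptake of the tracer: internal / total (incl. bound)
    bound = np.zeros(len(t_grid))
    for b, sp in enumerate(spp):
        if sp.name == tracer:
            off = N_APO * (b + 1)
            bound = nt * probs[:, off:off + N_APO].sum(axis=1)
    tot = counts[(tracer, "ext")] + counts[(tracer, "int")] + bound
    frac = comp.recovery_efficiency * counts[(tracer, "int")] / np.where(tot > 0, tot, 1.0)
    return FluxTimeCourse(t_grid, frac, probs, counts, tracer)


def flux_rate(m: Model24, probs: np.ndarray, conc: dict, species: str,
              transition: str) -> float:
    """Net inward flux (events/s per transporter) through one path stage.

    The five serially related stages along the transport path, in the inward
    direction (binding outside -> conformational path -> release inside):
    ``bind_ext`` (apo open state + L_ext <-> bound), ``serial_ext`` (bound
    open <-> its entry substate), ``inter`` (the three parallel
    inter-conformational routes between the two entry substates),
    ``serial_int`` and ``release_int``.  At a stationary state all five are
    equal.
    """
    if transition not in FLUX_TRANSITIONS:
        raise ValueError(f"unknown transition {transition!r}; "
                         f"choose from {FLUX_TRANSITIONS}")
    sp = next(s for s in m.species if s.name == species)
    b = list(m.species).index(sp)
    off = N_APO * (b + 1)
    branch = m.rates.branch(sp.branch)
    sides = m.open_state_side()
    s_ext = 6 if sides[6] == "ext" else 7       # open substate facing outside
    s_int = 13 - s_ext                          # the other one (6 <-> 7)
    e_ext, e_int = s_ext - 4, s_int - 4         # their entry substates (2, 3)
    p = probs

    def pb(i):       # bound-state probability, 1-indexed substate
        return p[off + i - 1]

    if transition == "bind_ext":
        return float(m.kon * conc[species]["ext"] * p[s_ext - 1]
                     - m.koff(sp.branch, s_ext) * pb(s_ext))
    if transition == "serial_ext":
        return float(branch[(s_ext, e_ext)] * pb(s_ext)
                     - branch[(e_ext, s_ext)] * pb(e_ext))
    if transition == "inter":
        others = [i for i in range(1, 5) if i not in (e_ext, e_int)]
        j = branch[(e_ext, e_int)] * pb(e_ext) - branch[(e_int, e_ext)] * pb(e_int)
        for o in others:
            j += branch[(e_ext, o)] * pb(e_ext) - branch[(o, e_ext)] * pb(o)
        return float(j)
    if transition == "serial_int":
        return float(branch[(e_int, s_int)] * pb(e_int)
                     - branch[(s_int, e_int)] * pb(s_int))
    # release_int
    return float(m.koff(sp.branch, s_int) * pb(s_int)
                 - m.kon * conc[species]["int"] * p[s_int - 1])


def predict_uptake_rates(m: Model24, conc_series, species: str = "R",
                         transition: str = "release_int") -> np.ndarray:
    """Quasi-steady-state net uptake rate (1/s) per external concentration.

    For each external concentration the 24-state stationary distribution is
    solved at fixed concentrations and the Eq.-6-style net rate through the
    chosen stage is evaluated; this is the model's initial-rate prediction
    for a Michaelis-Menten style uptake experiment.
    """
    out = []
    for conc in conc_series:
        p = stationary_state(m, conc)
        out.append(flux_rate(m, p, conc, species, transition))
    return np.asarray(out)


@dataclass
class MMFit:
    kmax: float
    km: float
    offset: float = 0.0

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        return self.offset + self.kmax * s / (self.km + s)


def fit_mm(conc, rates, allow_offset: bool = False) -> MMFit:
    """Least-squares Michaelis-Menten fit, optionally with a nonzero floor.

    The modified form v = v0 + kmax [S]/(Km + [S]) captures a uniporter's
    nonzero rate at vanishing external substrate; an obligatory exchanger's
    rate goes to zero there (offset ~ 0).
    """
    conc = np.asarray(conc, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if conc.size < 4:
        raise ValueError("need at least 4 concentrations")
    span = rates.max() - rates.min()
    kmax0 = span if span > 0 else max(rates.max(), 1e-12)
    km0 = np.median(conc[conc > 0]) if (conc > 0).any() else 1.0

    def model(x):
        if allow_offset:
            kmax, km, v0 = x[0], np.exp(x[1]), x[2]
        else:
            kmax, km, v0 = x[0], np.exp(x[1]), 0.0
        return v0 + kmax * conc / (km + conc)

    def resid(x):
        return model(x) - rates

    x0 = [kmax0, np.log(km0)] + ([rates.min()] if allow_offset else [])
    sol = optimize.least_squares(resid, x0, max_nfev=10000)
    if not sol.success:
        raise RuntimeError("Michaelis-Menten fit did not converge")
    kmax, km = float(sol.x[0]), float(np.exp(sol.x[1]))
    offset = float(sol.x[2]) if allow_offset else 0.0
    return MMFit(kmax=kmax, km=km, offset=offset)


# ---------------------------------------------------------------------------
# two-compartment exchange thermodynamics
# ---------------------------------------------------------------------------

def fmax_exchanger(rv: float, rc: float) -> float:
    """Maximal fractional tracer uptake of an obligatory 1:1 exchanger.

    F_max = 1 / (1 + rv/rc) with rv the external-to-internal volume ratio
    and rc = [R_ext](0)/[NR_int](0)... the external-to-internal initial
    concentration ratio; it is fixed by the initial condition alone.
    """
    if rv <= 0 or rc <= 0:
        raise ValueError("rv and rc must be positive")
    return 1.0 / (1.0 + rv / rc)


def rv_from_fmax(fmax_obs: float) -> float:
    """Volume ratio from the observed symmetric-condition maximal uptake."""
    if not 0.0 < fmax_obs < 1.0:
        raise ValueError("fmax_obs must be strictly between 0 and 1")
    return (1.0 - fmax_obs) / fmax_obs


def fmax_uniporter(rv: float) -> float:
    """Equilibrium tracer fraction for a uniporter with inert internal load.

    A uniporter equilibrates tracer concentration across the membrane, so
    the internal fraction is just the fractional internal volume 1/(1+rv).
    """
    if rv <= 0:
        raise ValueError("rv must be positive")
    return 1.0 / (1.0 + rv)


def mixing_equilibrium(n_r_e0: float, n_nr_i0: float) -> dict[str, float]:
    """Analytic endpoint of 1:1-exchange mixing of R (outside) and NR (inside).

    Exchange conserves each compartment's total occupancy, and maximal
    entropy makes the NR:R ratio equal in both compartments (and equal to
    the global ratio n_NR(0)/n_R(0)).
    """
    if n_r_e0 <= 0 or n_nr_i0 <= 0:
        raise ValueError("totals must be positive")
    total = n_r_e0 + n_nr_i0
    p_r = n_r_e0 / total
    return {
        "ratio_nr_r": n_nr_i0 / n_r_e0,
        "n_r_int": n_nr_i0 * p_r,
        "n_nr_int": n_nr_i0 * (1.0 - p_r),
        "n_r_ext": n_r_e0 * p_r,
        "n_nr_ext": n_r_e0 * (1.0 - p_r),
        "fmax": n_nr_i0 * p_r / n_r_e0,
    }
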