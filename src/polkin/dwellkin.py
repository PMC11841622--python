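"""Dwell-time kinetics: camera-corrected exponential mixtures and the
serial two-substate scheme.

Each resolved conformation C_i hides two energetic substates: an "entry"
substate S_i that exchanges with the other conformations (serial topology)
and a cul-de-sac partner S_{i+4} reachable only from S_i.  A dwell in C_i is
then phase-type with two exponential components; the three observables
(lambda1, lambda2, f) together with the exit-branching probabilities p_ij
invert in closed form to the underlying rate constants.  Apparent rates vary
with ligand concentration along a binding isotherm (one-site, midpoint
K_1/2), which yields apo and ligand-bound rate constants; stationary
probabilities of the 8-state scheme as a function of concentration yield the
equilibrium constants and K_D values.

Dwells are recorded by a camera at a fixed frame interval, so fits use an
exactly frame-quantized exponential mixture rather than the continuous
density (see :func:`dwell_pmf`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import null_space

INTER_PAIRS = [(i, j) for i in range(1, 5) for j in range(1, 5) if i != j]
SERIAL_PAIRS = [(i, i + 4) for i in range(1, 5)] + [(i + 4, i) for i in range(1, 5)]
TRANSITIONS = INTER_PAIRS + SERIAL_PAIRS   # the 20 rate constants per condition


def rate_key(i: int, j: int) -> str:
    return f"k_{i}_{j}"


@dataclass
class RateSet:
    """The 60 rate constants: 20 each for apo, Arg-bound and Agm-bound.

    Each branch maps (i, j) -> rate (1/s) over the 12 directed
    inter-conformational transitions among S1-S4 plus the 8 serial
    transitions S_i <-> S_{i+4}.  ``khalf`` maps ligand -> (i, j) -> K_1/2
    (mol/L) for the apparent-rate isotherms.
    """

    apo: dict[tuple[int, int], float]
    arg: dict[tuple[int, int], float]
    agm: dict[tuple[int, int], float]
    khalf: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)

    def branch(self, ligand: str | None) -> dict[tuple[int, int], float]:
        if ligand in (None, "apo"):
            return self.apo
        return {"arg": self.arg, "agm": self.agm}[ligand]

    def validate(self):
        for name in ("apo", "arg", "agm"):
            b = self.branch(name)
            missing = [p for p in TRANSITIONS if p not in b]
            if missing:
                raise ValueError(f"{name} branch missing transitions {missing}")
            if any(v <= 0 for v in b.values()):
                raise ValueError(f"{name} branch has non-positive rates")
        return self

    @property
    def n_constants(self) -> int:
        return len(self.apo) + len(self.arg) + len(self.agm)


@dataclass
class DwellFitResult:
    lambda1: float              # fast rate, 1/s (lambda1 >= lambda2)
    lambda2: float
    f: float                    # amplitude fraction of the fast component
    loglik: float
    n: int
    ncomp: int = 2

    @property
    def tau1(self) -> float:
        return 1.0 / self.lambda1

    @property
    def tau2(self) -> float:
        return 1.0 / self.lambda2


@dataclass
class EquilibriumSet:
    """Equilibrium ratios K_i1 (apo), LK_i1 per ligand, and K_D per state.

    S1 is the reference (K_11 = LK_11 = 1).  The per-state dissociation
    constants follow the thermodynamic cycle K_Di = K_D1 * K_i1 / LK_i1.
    The physically consequential ones are the open states: S6 (external
    binding) and S7 (internal binding), for each ligand.
    """

    k_i1: np.ndarray                       # shape (8,), apo, k_i1[0] == 1
    lk_i1: dict[str, np.ndarray]           # ligand -> shape (8,)
    kd1: dict[str, float]                  # ligand -> K_D of S1 (mol/L)

    def kd(self, ligand: str) -> np.ndarray:
        return self.kd1[ligand] * self.k_i1 / self.lk_i1[ligand]

    def consequential_kd(self) -> dict[tuple[str, int], float]:
        return {(lig, s): float(self.kd(lig)[s - 1])
                for lig in self.kd1 for s in (6, 7)}


# ---------------------------------------------------------------------------
# frame-quantized exponential mixture
# ---------------------------------------------------------------------------

def _span_pmf(lam: float, dt: float, k: np.ndarray) -> np.ndarray:
    """Unconditioned span law over k >= 1 (see :func:`dwell_pmf`)."""
    a = lam * dt
    em = -np.expm1(-a)                      # 1 - e^-a, stable for small a
    p1 = 1.0 - em / a
    with np.errstate(under="ignore"):
        return np.where(k == 1, p1, (em * em / a) * np.exp(-a * np.maximum(k - 2, 0)))


def _span_tail(lam: float, dt: float, k0) -> float | np.ndarray:
    """P(span >= k0); closed geometric tail.  Accepts scalar or array k0."""
    a = lam * dt
    em = -np.expm1(-a)
    k0 = np.asarray(k0)
    with np.errstate(under="ignore"):
        tail = np.where(k0 <= 1, 1.0, (em / a) * np.exp(-a * np.maximum(k0 - 2, 0)))
    return float(tail) if tail.shape == () else tail


def dwell_pmf(lam: float, dt: float, k, k_min: int = 1) -> np.ndarray:
    """Probability that an exponential dwell spans k frames.

    A dwell of rate ``lam`` starts at a uniformly distributed phase within a
    frame of length ``dt`` and is recorded as covering every frame it
    touches.  With a = lam*dt the exact span law is

        P(1)      = 1 - (1 - e^-a)/a
        P(k >= 2) = (1 - e^-a)^2 / a * e^{-a (k - 2)}

    renormalized over k >= k_min.  This reduces to a geometric law with mean
    1/a as a -> 0.
    """
    if lam <= 0 or dt <= 0:
        raise ValueError("lam and dt must be positive")
    k = np.asarray(k)
    if (k < k_min).any():
        raise ValueError(f"k must be >= k_min={k_min}")
    p = _span_pmf(lam, dt, k) / _span_tail(lam, dt, k_min)
    return p if p.shape else float(p)


def dwell_mixture_pmf(lam1: float, lam2: float, f: float, dt: float, k,
                      k_min: int = 1, convention: str = "span") -> np.ndarray:
    """Two-component frame-quantized mixture with amplitude fraction f.

    ``f`` is the amplitude fraction of the *continuous-time* mixture; the
    truncated/conditioned pmf renormalizes the mixture jointly, so the
    fitted f keeps that meaning.  ``convention="span"`` is the raw span law;
    ``convention="boundary"`` models dwells delimited by changepoints that
    snap to the nearest frame boundary, whose length law is the span law
    shifted down by one frame (zero-length events are invisible).
    """
    k = np.asarray(k)
    shift = 0 if convention == "span" else 1
    if convention not in ("span", "boundary"):
        raise ValueError(f"unknown convention {convention!r}")
    k_eff = k + shift
    k0 = k_min + shift
    num = f * _span_pmf(lam1, dt, k_eff) + (1 - f) * _span_pmf(lam2, dt, k_eff)
    den = f * _span_tail(lam1, dt, k0) + (1 - f) * _span_tail(lam2, dt, k0)
    return num / den


def dwell_mixture_survival(lam1: float, lam2: float, f: float, dt: float, k,
                           k_min: int = 1, convention: str = "span") -> np.ndarray:
    """P(recorded length >= k) for the frame-quantized mixture.

    Used for right-censored dwells (a dwell cut off by the start or end of
    the observation window, or by photobleaching, is known only to be at
    least this long); same conventions as :func:`dwell_mixture_pmf`.
    """
    k = np.asarray(k)
    shift = 0 if convention == "span" else 1
    k0 = k_min + shift
    num = (f * _span_tail(lam1, dt, k + shift)
           + (1 - f) * _span_tail(lam2, dt, k + shift))
    den = f * _span_tail(lam1, dt, k0) + (1 - f) * _span_tail(lam2, dt, k0)
    return num / den


def fit_dwell(dwells, dt: float, ncomp: int = 2, k_min: int = 1,
              convention: str = "span", seed: int = 0,
              n_restarts: int = 8, censored=None) -> DwellFitResult:
    """Maximum-likelihood exponential(-mixture) fit to dwell frame counts.

    Multi-start bounded quasi-Newton in log-rate (and logit-f) space; the
    observed counts are compressed to unique values for speed.  ``censored``
    holds right-censored lengths (dwells cut off by the observation window),
    which contribute survival terms; including them undoes the length bias
    against long dwells that excluding edge events would cause.
    """
    dwells = np.asarray(dwells, dtype=int)
    if dwells.size == 0:
        raise ValueError("no dwells")
    if (dwells < k_min).any():
        raise ValueError("dwell shorter than k_min")
    if ncomp == 2 and dwells.size < 50:
        raise ValueError("need at least 50 dwells for a two-component fit")
    if censored is not None:
        censored = np.asarray(censored, dtype=int)
        censored = censored[censored >= k_min]
        uc, ccounts = np.unique(censored, return_counts=True)
    else:
        uc, ccounts = np.array([], dtype=int), np.array([], dtype=float)
    uk, counts = np.unique(dwells, return_counts=True)
    n = int(dwells.size)
    mean_frames = float(dwells.mean())
    # crude moment rate accounting for the ~1-frame quantization offset
    offset = 1.0 if convention == "span" else 0.0
    lam0 = 1.0 / (max(mean_frames - offset, 0.25) * dt)
    rng = np.random.default_rng(seed)

    def _nll(l1, l2, fr):
        with np.errstate(all="ignore"):
            p = dwell_mixture_pmf(l1, l2, fr, dt, uk, k_min, convention)
            if not np.all(np.isfinite(p)) or (p <= 0).any():
                return 1e12
            total = -float(counts @ np.log(p))
            if uc.size:
                s = dwell_mixture_survival(l1, l2, fr, dt, uc, k_min, convention)
                if not np.all(np.isfinite(s)) or (s <= 0).any():
                    return 1e12
                total -= float(ccounts @ np.log(s))
        return total

    def nll_1(x):
        lam = np.exp(x[0])
        return _nll(lam, lam, 1.0)

    def nll_2(x):
        return _nll(np.exp(x[0]), np.exp(x[1]), 1.0 / (1.0 + np.exp(-x[2])))

    if ncomp == 1:
        best = None
        for i in range(max(n_restarts // 2, 2)):
            x0 = [np.log(lam0) + (0.0 if i == 0 else rng.normal(0, 0.7))]
            r = optimize.minimize(nll_1, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10})
            if best is None or r.fun < best.fun:
                best = r
        lam = float(np.exp(best.x[0]))
        return DwellFitResult(lam, lam, 1.0, -best.fun, n, ncomp=1)

    best = None
    starts = [[np.log(lam0 * 4), np.log(lam0 / 4), 0.8]]
    for _ in range(n_restarts - 1):
        starts.append([np.log(lam0) + rng.normal(1.0, 0.8),
                       np.log(lam0) + rng.normal(-1.0, 0.8),
                       rng.normal(0.5, 1.0)])
    for x0 in starts:
        r = optimize.minimize(nll_2, x0, method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-10,
                                       "maxiter": 4000})
        if best is None or r.fun < best.fun:
            best = r
    l1, l2 = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    fr = float(1.0 / (1.0 + np.exp(-best.x[2])))
    if l2 > l1:
        l1, l2, fr = l2, l1, 1.0 - fr
    return DwellFitResult(l1, l2, fr, -best.fun, n, ncomp=2)


def ftest_components(fit1: DwellFitResult, fit2: DwellFitResult, n: int) -> float:
    """F-test p-value for double- vs single-exponential nested fits.

    Uses the likelihood-ratio F form F = (2 dlogL)/q against F(q, n - p2)
    with q = 2 extra parameters.  Returns 1.0 when the richer fit is no
    better.  The null lies on the mixture boundary, so the test is
    conservative there.
    """
    if fit2.loglik <= fit1.loglik:
        return 1.0
    q = 2
    fstat = 2.0 * (fit2.loglik - fit1.loglik) / q
    return float(stats.f.sf(fstat, q, max(n - 3, 1)))


def _mixture_span_pmf(lams, weights, dt: float, k, k_min: int = 1,
                      shift: int = 0) -> np.ndarray:
    """Frame span pmf of a signed mixture of exponentials.

    Generalizes :func:`dwell_mixture_pmf` to any number of components with
    (possibly signed) weights, as produced by phase-type eigendecomposition;
    the mixture is renormalized jointly over k >= k_min.
    """
    k = np.asarray(k)
    k_eff = k + shift
    k0 = k_min + shift
    num = np.zeros(k_eff.shape, dtype=float)
    den = 0.0
    for lam, w in zip(lams, weights):
        num = num + w * _span_pmf(lam, dt, k_eff)
        den += w * _span_tail(lam, dt, k0)
    return num / den


def serial_missed_pmf(k_out: float, k_ab: float, k_ba: float, mu: float,
                      gamma: float, dt: float, k, k_min: int = 1,
                      convention: str = "span") -> np.ndarray:
    """Dwell pmf of the serial scheme with missed-excursion merging.

    With probability ``mu`` an exit from the entry substate is a short
    excursion the changepoint detector misses (the camera cannot resolve
    it), after which the recorded dwell continues; the excursion itself
    lasts Exp(gamma).  The observed dwell is then the absorption time of a
    three-phase chain (entry A, cul-de-sac B, missed-gap M):

        A -> absorb at (1-mu) k_out, A <-> B at k_ab / k_ba,
        A -> M at mu k_out, M -> A at gamma.

    The star topology guarantees real eigenvalues, so the density is a
    signed three-exponential mixture, frame-quantized like everything else.
    mu = 0 reduces exactly to the plain serial dwell law.
    """
    if not 0 <= mu < 1:
        raise ValueError("mu must be in [0, 1)")
    if mu == 0:
        l1, l2, f = forward_serial(k_out, k_ab, k_ba)
        return dwell_mixture_pmf(l1, l2, f, dt, k, k_min, convention)
    t_mat = np.array([
        [-(k_out + k_ab), k_ab, mu * k_out],
        [k_ba, -k_ba, 0.0],
        [gamma, 0.0, -gamma]])
    evals, vecs = np.linalg.eig(t_mat)
    vinv = np.linalg.inv(vecs)
    alpha = np.array([1.0, 0.0, 0.0])
    t0 = np.array([(1.0 - mu) * k_out, 0.0, 0.0])
    coef = (alpha @ vecs) * (vinv @ t0)
    lams = -np.real(evals)
    coef = np.real(coef)
    if (lams <= 0).any():
        raise ValueError("non-decaying phase-type component")
    weights = coef / lams                 # integrate each exponential to 1
    shift = 0 if convention == "span" else 1
    return _mixture_span_pmf(lams, weights, dt, k, k_min, shift)


# ---------------------------------------------------------------------------
# serial two-substate scheme
# ---------------------------------------------------------------------------

def forward_serial(k_out: float, k_ab: float, k_ba: float):
    """Eigen-solve the serial scheme: (k_out, k_ab, k_ba) -> (l1, l2, f).

    Dwells start in the entry substate A which exits the conformation at
    total rate k_out and exchanges with the cul-de-sac B at k_ab / k_ba.
    The dwell density is f l1 e^{-l1 t} + (1-f) l2 e^{-l2 t} with
    l1 + l2 = k_out + k_ab + k_ba, l1 l2 = k_out k_ba and
    f l1 + (1-f) l2 = k_out (the density at t = 0).
    """
    if min(k_out, k_ab, k_ba) <= 0:
        raise ValueError("rates must be positive")
    s = k_out + k_ab + k_ba
    disc = np.sqrt(s * s - 4.0 * k_out * k_ba)
    l1 = (s + disc) / 2.0
    l2 = 2.0 * k_out * k_ba / (s + disc)   # stable form of (s - disc)/2
    f = (k_out - l2) / (l1 - l2)
    return float(l1), float(l2), float(f)


class NonPhysicalRatesError(ValueError):
    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


def invert_serial_scheme(lambda1: float, lambda2: float, f: float, p_row):
    """Invert (l1, l2, f, p_ij) to the serial-scheme rate constants.

    Returns (k_inter, k_ab, k_ba) where k_inter maps the 3 destination
    conformations to directed rates k_out * p_ij, k_ab is the entry->cul-de-
    sac rate and k_ba the return rate.  Raises NonPhysicalRatesError when the
    implied k_ab is not positive.
    """
    if not (lambda1 > lambda2 > 0):
        raise ValueError("need lambda1 > lambda2 > 0")
    if not 0 < f < 1:
        raise NonPhysicalRatesError("f on boundary: single-state reduction",
                                    {"f": f})
    p_row = np.asarray(list(p_row.values()) if isinstance(p_row, dict) else p_row,
                       dtype=float)
    if abs(p_row.sum() - 1.0) > 1e-6:
        raise ValueError("exit probabilities must sum to 1")
    k_out = f * lambda1 + (1.0 - f) * lambda2
    k_ba = lambda1 * lambda2 / k_out
    k_ab = lambda1 + lambda2 - k_out - k_ba
    if k_ab <= 0 or k_ba <= 0 or k_out <= 0:
        raise NonPhysicalRatesError(
            "inversion produced non-positive rate",
            {"k_out": k_out, "k_ab": k_ab, "k_ba": k_ba})
    return k_out * p_row, float(k_ab), float(k_ba)


def apparent_rates_from_fits(fits: dict[int, DwellFitResult],
                             p: np.ndarray) -> dict[tuple[int, int], float]:
    """Assemble the 20 apparent rates of one ligand condition.

    ``fits`` maps conformation 1-4 to its dwell fit, ``p`` is the 4x4
    exit-probability matrix (diagonal 0).
    """
    appk: dict[tuple[int, int], float] = {}
    for i in range(1, 5):
        fit = fits[i]
        others = [j for j in range(1, 5) if j != i]
        p_row = np.array([p[i - 1, j - 1] for j in others])
        k_inter, k_ab, k_ba = invert_serial_scheme(
            fit.lambda1, fit.lambda2, fit.f, p_row)
        for j, k in zip(others, k_inter):
            appk[(i, j)] = float(k)
        appk[(i, i + 4)] = k_ab
        appk[(i + 4, i)] = k_ba
    return appk


# ---------------------------------------------------------------------------
# concentration dependence (binding isotherms)
# ---------------------------------------------------------------------------

def isotherm(apo: float, bound: float, conc, khalf: float):
    """One-site interpolation (apo + bound*c/K) / (1 + c/K)."""
    x = np.asarray(conc, dtype=float) / khalf
    return (apo + bound * x) / (1.0 + x)


def fit_eq3(appk_by_condition: dict[tuple[str | None, float], dict[tuple[int, int], float]]) -> RateSet:
    """Fit the apparent-rate isotherms to recover the 60 rate constants.

    ``appk_by_condition`` maps (ligand, concentration) -> the 20 apparent
    rates; the apo condition may appear as (None, 0.0) or ("apo", 0.0) and
    is shared between the two ligand series.  Fitting is done in log space
    (positivity, scale robustness), jointly for all transitions leaving the
    same state: under rapid-equilibrium binding the isotherm midpoint of
    every transition out of state i is that state's dissociation constant,
    so the group shares one K_1/2 per ligand.  This makes the midpoint of
    the weakly determined serial transitions identifiable through the well
    measured inter-conformational ones.
    """
    conditions = sorted(appk_by_condition, key=lambda c: (c[0] or "", c[1]))
    ligands = sorted({lig for lig, _ in conditions if lig not in (None, "apo")})
    n_lig = len(ligands)
    apo_rates: dict[tuple[int, int], float] = {}
    bound_rates = {lig: {} for lig in ligands}
    khalf = {lig: {} for lig in ligands}

    concs = [c for _, c in conditions if c > 0]
    kh0 = np.log(np.median(concs)) if concs else np.log(1e-4)
    kh_lo = np.log(min(concs) / 30.0) if concs else kh0 - 3
    kh_hi = np.log(max(concs) * 30.0) if concs else kh0 + 3

    for state in range(1, 9):
        group = [p for p in TRANSITIONS if p[0] == state]
        nt = len(group)
        obs = {}
        for pair in group:
            obs[pair] = [(cond, appk_by_condition[cond][pair])
                         for cond in conditions if pair in appk_by_condition[cond]]
        scale = {pair: np.exp(np.mean(np.log([y for _, y in obs[pair]])))
                 for pair in group}

        # layout: [log apo]*nt, [log bound]*(nt*n_lig), [log khalf]*n_lig
        def unpack(x):
            k_apo = {p: np.exp(x[t]) * scale[p] for t, p in enumerate(group)}
            kb = {lig: {p: np.exp(x[nt + m * nt + t]) * scale[p]
                        for t, p in enumerate(group)}
                  for m, lig in enumerate(ligands)}
            kh = {lig: np.exp(x[nt * (1 + n_lig) + m])
                  for m, lig in enumerate(ligands)}
            return k_apo, kb, kh

        def resid(x):
            k_apo, kb, kh = unpack(x)
            out = []
            for pair in group:
                for (lig, conc), y in obs[pair]:
                    if lig in (None, "apo") or conc == 0:
                        pred = k_apo[pair]
                    else:
                        pred = isotherm(k_apo[pair], kb[lig][pair], conc, kh[lig])
                    out.append(np.log(pred) - np.log(y))
            return np.asarray(out)

        x0 = np.concatenate([np.zeros(nt * (1 + n_lig)), [kh0] * n_lig])
        lo = np.concatenate([np.full(nt * (1 + n_lig), -6.0), [kh_lo] * n_lig])
        hi = np.concatenate([np.full(nt * (1 + n_lig), 6.0), [kh_hi] * n_lig])
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                     method="trf", max_nfev=8000)
        k_apo, kb, kh = unpack(sol.x)
        for pair in group:
            apo_rates[pair] = float(k_apo[pair])
            for lig in ligands:
                bound_rates[lig][pair] = float(kb[lig][pair])
                khalf[lig][pair] = float(kh[lig])

    return RateSet(apo=apo_rates,
                   arg=bound_rates.get("arg", dict(apo_rates)),
                   agm=bound_rates.get("agm", dict(apo_rates)),
                   khalf=khalf)


def global_fit_multi(dwell_sets: dict[tuple[str | None, float], np.ndarray],
                     dt: float, k_min: int = 1, convention: str = "span",
                     seed: int = 0):
    """Joint dwell fit for one conformation over all ligand conditions.

    lambda1, lambda2 and f each follow a one-site isotherm between their
    apo value and a per-ligand saturating value, with a single K_1/2 per
    ligand shared by all three parameters (one binding process per
    conformation).  Fitting every condition's dwell histogram at once is
    what makes the slow component's parameters identifiable at realistic
    event counts.  Returns {"params": dict, "curves": {(ligand, conc):
    (lambda1, lambda2, f)}, "loglik": float}.
    """
    conditions = sorted(dwell_sets, key=lambda c: (c[0] or "", c[1]))
    ligands = sorted({lig for lig, c in conditions
                      if lig not in (None, "apo") and c > 0})
    data = {cond: np.unique(np.asarray(dwell_sets[cond], dtype=int),
                            return_counts=True) for cond in conditions}
    # seeds for the per-condition starting fits
    fit_apo = None
    fit_sat = {}
    for cond in conditions:
        if cond[0] in (None, "apo") or cond[1] == 0:
            fit_apo = fit_dwell(dwell_sets[cond], dt, 2, k_min, convention, seed)
    for lig in ligands:
        top = max(c for l, c in conditions if l == lig)
        fit_sat[lig] = fit_dwell(dwell_sets[(lig, top)], dt, 2, k_min,
                                 convention, seed + 1)
    if fit_apo is None:
        raise ValueError("need an apo condition")
    n_lig = len(ligands)

    def unpack(x):
        l1 = {None: np.exp(x[0]), **{lig: np.exp(x[1 + m]) for m, lig in enumerate(ligands)}}
        l2 = {None: np.exp(x[1 + n_lig]),
              **{lig: np.exp(x[2 + n_lig + m]) for m, lig in enumerate(ligands)}}
        fr = {None: 1 / (1 + np.exp(-x[2 + 2 * n_lig])),
              **{lig: 1 / (1 + np.exp(-x[3 + 2 * n_lig + m])) for m, lig in enumerate(ligands)}}
        kh = {lig: np.exp(x[3 + 3 * n_lig + m]) for m, lig in enumerate(ligands)}
        return l1, l2, fr, kh

    def curves(x):
        l1, l2, fr, kh = unpack(x)
        out = {}
        for lig, c in conditions:
            if lig in (None, "apo") or c == 0:
                out[(lig, c)] = (l1[None], l2[None], fr[None])
            else:
                out[(lig, c)] = (float(isotherm(l1[None], l1[lig], c, kh[lig])),
                                 float(isotherm(l2[None], l2[lig], c, kh[lig])),
                                 float(isotherm(fr[None], fr[lig], c, kh[lig])))
        return out

    def nll(x):
        total = 0.0
        for cond, (la, lb, f) in curves(x).items():
            uk, cnt = data[cond]
            if lb > la:
                la, lb, f = lb, la, 1 - f
            with np.errstate(all="ignore"):
                p = dwell_mixture_pmf(la, lb, f, dt, uk, k_min, convention)
            if not np.all(np.isfinite(p)) or (p <= 0).any():
                return 1e12
            total -= float(cnt @ np.log(p))
        return total

    def logit(v):
        v = min(max(v, 1e-6), 1 - 1e-6)
        return np.log(v / (1 - v))

    concs_pos = [c for _, c in conditions if c > 0]
    kh0 = np.log(np.median(concs_pos)) if concs_pos else np.log(1e-4)
    x0 = np.concatenate([
        [np.log(fit_apo.lambda1)], [np.log(fit_sat[l].lambda1) for l in ligands],
        [np.log(fit_apo.lambda2)], [np.log(fit_sat[l].lambda2) for l in ligands],
        [logit(fit_apo.f)], [logit(fit_sat[l].f) for l in ligands],
        [kh0] * n_lig])
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(4):
        start = x0 if trial == 0 else x0 + rng.normal(0, 0.3, size=x0.shape)
        r = optimize.minimize(nll, start, method="Nelder-Mead",
                              options={"maxiter": 40000, "maxfev": 40000,
                                       "xatol": 1e-7, "fatol": 1e-8})
        if best is None or r.fun < best.fun:
            best = r
    return {"params": unpack(best.x), "curves": curves(best.x),
            "loglik": -best.fun}


def global_fit_serial(dwell_sets: dict[tuple[str | None, float], np.ndarray],
                      dt: float, k_min: int = 1, convention: str = "span",
                      seed: int = 0,
                      censored_sets: dict | None = None):
    """Rate-level global dwell fit for one conformation.

    The dwell mixture of every condition is generated from the serial
    scheme with rates that follow exact one-site isotherms: k_out and k_ab
    (transitions out of the entry substate) share the entry substate's
    K_1/2 per ligand, while k_ba (return from the cul-de-sac substate) has
    its own.  This matches the apparent-rate structure of rapid-equilibrium
    binding exactly, so the apo and bound serial rates are read off the fit
    directly.  Returns {"params": ..., "rates": {(ligand, conc): (k_out,
    k_ab, k_ba)}, "loglik": ...}.
    """
    conditions = sorted(dwell_sets, key=lambda c: (c[0] or "", c[1]))
    ligands = sorted({lig for lig, c in conditions
                      if lig not in (None, "apo") and c > 0})
    n_lig = len(ligands)
    data = {cond: np.unique(np.asarray(dwell_sets[cond], dtype=int),
                            return_counts=True) for cond in conditions}
    cens = {}
    for cond in conditions:
        c = np.asarray(censored_sets.get(cond, []), dtype=int) \
            if censored_sets else np.array([], dtype=int)
        c = c[c >= k_min]
        cens[cond] = np.unique(c, return_counts=True)

    # starting values from per-condition fits at the series endpoints
    def start_rates(cond):
        fit = fit_dwell(dwell_sets[cond], dt, 2, k_min, convention, seed)
        k_out = fit.f * fit.lambda1 + (1 - fit.f) * fit.lambda2
        k_ba = fit.lambda1 * fit.lambda2 / k_out
        k_ab = max(fit.lambda1 + fit.lambda2 - k_out - k_ba, 0.02 * k_out)
        return k_out, k_ab, k_ba

    apo_cond = next(c for c in conditions if c[0] in (None, "apo") or c[1] == 0)
    s_apo = start_rates(apo_cond)
    s_sat = {lig: start_rates((lig, max(c for l, c in conditions if l == lig)))
             for lig in ligands}

    def unpack(x):
        def block(i):
            return {None: np.exp(x[i]),
                    **{lig: np.exp(x[i + 1 + m]) for m, lig in enumerate(ligands)}}
        k_out = block(0)
        k_ab = block(1 + n_lig)
        k_ba = block(2 * (1 + n_lig))
        base = 3 * (1 + n_lig)
        kh_entry = {lig: np.exp(x[base + m]) for m, lig in enumerate(ligands)}
        kh_cul = {lig: np.exp(x[base + n_lig + m]) for m, lig in enumerate(ligands)}
        return k_out, k_ab, k_ba, kh_entry, kh_cul

    def rates_at(x):
        k_out, k_ab, k_ba, kh_e, kh_c = unpack(x)
        out = {}
        for lig, c in conditions:
            if lig in (None, "apo") or c == 0:
                out[(lig, c)] = (k_out[None], k_ab[None], k_ba[None])
            else:
                out[(lig, c)] = (
                    float(isotherm(k_out[None], k_out[lig], c, kh_e[lig])),
                    float(isotherm(k_ab[None], k_ab[lig], c, kh_e[lig])),
                    float(isotherm(k_ba[None], k_ba[lig], c, kh_c[lig])))
        return out

    def nll(x):
        total = 0.0
        for cond, (ko, ka, kb) in rates_at(x).items():
            try:
                l1, l2, f = forward_serial(ko, ka, kb)
            except ValueError:
                return 1e12
            uk, cnt = data[cond]
            with np.errstate(all="ignore"):
                p = dwell_mixture_pmf(l1, l2, f, dt, uk, k_min, convention)
                if not np.all(np.isfinite(p)) or (p <= 0).any():
                    return 1e12
                total -= float(cnt @ np.log(p))
                uc, cc = cens[cond]
                if uc.size:
                    s = dwell_mixture_survival(l1, l2, f, dt, uc, k_min, convention)
                    if not np.all(np.isfinite(s)) or (s <= 0).any():
                        return 1e12
                    total -= float(cc @ np.log(s))
        # bracketing prior: a K_1/2 outside the tested concentration window
        # is not identifiable (the isotherm looks flat), and letting it
        # collapse would decouple the apo intercept from the ligand series;
        # the prior width matches the tested span (about one decade around
        # the median concentration)
        base = 3 * (1 + n_lig)
        for i in range(2 * n_lig):
            total += 0.5 * ((x[base + i] - kh_prior) / 1.5) ** 2
        return total

    concs_pos = [c for _, c in conditions if c > 0]
    kh0 = np.log(np.median(concs_pos)) if concs_pos else np.log(1e-4)
    kh_prior = kh0
    x0 = np.concatenate([
        [np.log(s_apo[0])], [np.log(s_sat[l][0]) for l in ligands],
        [np.log(s_apo[1])], [np.log(s_sat[l][1]) for l in ligands],
        [np.log(s_apo[2])], [np.log(s_sat[l][2]) for l in ligands],
        [kh0] * (2 * n_lig)])
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(4):
        start = x0 if trial == 0 else x0 + rng.normal(0, 0.3, size=x0.shape)
        r = optimize.minimize(nll, start, method="Nelder-Mead",
                              options={"maxiter": 60000, "maxfev": 60000,
                                       "xatol": 1e-7, "fatol": 1e-8})
        if best is None or r.fun < best.fun:
            best = r
    k_out, k_ab, k_ba, kh_e, kh_c = unpack(best.x)
    return {"params": {"k_out": k_out, "k_ab": k_ab, "k_ba": k_ba,
                       "khalf_entry": kh_e, "khalf_cul": kh_c},
            "rates": rates_at(best.x), "loglik": -best.fun}


def global_fit(dwell_sets: dict[float, np.ndarray], dt: float,
               k_min: int = 1, convention: str = "span", seed: int = 0):
    """Global two-exponential fit over a concentration series for one state.

    Each of tau1, tau2 and f follows the isotherm (x0 + xL c/K)/(1 + c/K)
    with a single shared K_1/2 (one binding site).  Returns a dict with apo
    and saturating values of (lambda1, lambda2, f) plus khalf, and the
    per-concentration parameter curves.
    """
    concs = sorted(dwell_sets)
    if len(concs) < 3 or 0.0 not in concs:
        raise ValueError("need >= 3 concentrations including 0")
    data = {c: np.unique(np.asarray(dwell_sets[c], dtype=int), return_counts=True)
            for c in concs}
    # per-condition seeds keep the multi-start deterministic
    fit0 = fit_dwell(dwell_sets[0.0], dt, 2, k_min, convention, seed)
    fit_hi = fit_dwell(dwell_sets[concs[-1]], dt, 2, k_min, convention, seed + 1)

    def unpack(x):
        l1_0, l1_L, l2_0, l2_L = np.exp(x[:4])
        f_0 = 1 / (1 + np.exp(-x[4]))
        f_L = 1 / (1 + np.exp(-x[5]))
        kh = np.exp(x[6])
        return l1_0, l1_L, l2_0, l2_L, f_0, f_L, kh

    def nll(x):
        l1_0, l1_L, l2_0, l2_L, f_0, f_L, kh = unpack(x)
        total = 0.0
        for c in concs:
            l1 = isotherm(l1_0, l1_L, c, kh)
            l2 = isotherm(l2_0, l2_L, c, kh)
            fr = isotherm(f_0, f_L, c, kh)
            uk, cnt = data[c]
            with np.errstate(all="ignore"):
                p = dwell_mixture_pmf(max(l1, l2), min(l1, l2),
                                      fr if l1 >= l2 else 1 - fr,
                                      dt, uk, k_min, convention)
            if not np.all(np.isfinite(p)) or (p <= 0).any():
                return 1e12
            total -= float(cnt @ np.log(p))
        return total

    concs_pos = [c for c in concs if c > 0]
    x0 = [np.log(fit0.lambda1), np.log(fit_hi.lambda1),
          np.log(fit0.lambda2), np.log(fit_hi.lambda2),
          np.log(fit0.f / (1 - fit0.f + 1e-9)),
          np.log(fit_hi.f / (1 - fit_hi.f + 1e-9)),
          np.log(np.median(concs_pos))]
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-7,
                                     "fatol": 1e-9})
    l1_0, l1_L, l2_0, l2_L, f_0, f_L, kh = unpack(res.x)
    if not (np.log(min(concs_pos)) - 2 < np.log(kh) < np.log(max(concs_pos)) + 2):
        bracketed = False
    else:
        bracketed = True
    return {"lambda1_apo": l1_0, "lambda1_sat": l1_L,
            "lambda2_apo": l2_0, "lambda2_sat": l2_L,
            "f_apo": f_0, "f_sat": f_L, "khalf": kh,
            "loglik": -res.fun, "khalf_bracketed": bracketed}


# ---------------------------------------------------------------------------
# stationary probabilities and equilibrium constants
# ---------------------------------------------------------------------------

def build_generator8(rates: dict[tuple[int, int], float]) -> np.ndarray:
    """8x8 generator (rows sum to zero) from the 20 directed rates."""
    q = np.zeros((8, 8))
    for (i, j), k in rates.items():
        q[i - 1, j - 1] = k
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary probabilities of a generator (null space of Q^T)."""
    ns = null_space(q.T)
    if ns.shape[1] != 1:
        raise ValueError("chain is disconnected (stationary distribution not unique)")
    p = ns[:, 0]
    p = p / p.sum()
    if (p < -1e-9).any():
        raise ValueError("negative stationary probability")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def energetic_state_probabilities(appk: dict[tuple[int, int], float]) -> np.ndarray:
    """P(S1..S8) for one ligand condition from its 20 apparent rates."""
    return stationary_distribution(build_generator8(appk))


def eq4_probabilities(k_i1: np.ndarray, lk_i1: np.ndarray, kd1: float, conc) -> np.ndarray:
    """State probabilities predicted by the two-branch equilibrium model."""
    x = np.asarray(conc, dtype=float) / kd1
    num = k_i1[None, :] + lk_i1[None, :] * np.atleast_1d(x)[:, None]
    p = num / num.sum(axis=1, keepdims=True)
    return p[0] if np.ndim(conc) == 0 else p


def fit_equilibrium(p_by_condition: dict[tuple[str | None, float], np.ndarray]) -> EquilibriumSet:
    """Global fit of the equilibrium model to P(S1..S8) vs concentration.

    Shares the apo ratios K_i1 between the ligand series; each ligand gets
    its own LK_i1 and K_D1.  Returns the full EquilibriumSet; per-state K_D
    follows from the thermodynamic cycle.
    """
    conditions = sorted(p_by_condition, key=lambda c: (c[0] or "", c[1]))
    ligands = sorted({lig for lig, _ in conditions if lig not in (None, "apo")})
    if not ligands:
        raise ValueError("need at least one ligand series")
    n_lig = len(ligands)

    def unpack(x):
        k_i1 = np.concatenate([[1.0], np.exp(x[:7])])
        lk, kd1 = {}, {}
        for m, lig in enumerate(ligands):
            lk[lig] = np.concatenate([[1.0], np.exp(x[7 + 7 * m:14 + 7 * m])])
            kd1[lig] = float(np.exp(x[7 + 7 * n_lig + m]))
        return k_i1, lk, kd1

    def resid(x):
        k_i1, lk, kd1 = unpack(x)
        out = []
        for (lig, conc) in conditions:
            obs = p_by_condition[(lig, conc)]
            if lig in (None, "apo") or conc == 0:
                pred = k_i1 / k_i1.sum()
            else:
                pred = eq4_probabilities(k_i1, lk[lig], kd1[lig], conc)
            out.append(pred - obs)
        return np.concatenate(out)

    apo_obs = None
    for cond in conditions:
        if cond[0] in (None, "apo") or cond[1] == 0:
            apo_obs = p_by_condition[cond]
            break
    if apo_obs is None:
        apo_obs = np.full(8, 1 / 8)
    k0 = np.log(np.clip(apo_obs[1:] / max(apo_obs[0], 1e-6), 1e-4, 1e4))
    concs_pos = [c for _, c in conditions if c > 0]
    kd_lo = np.log(min(concs_pos) / 30.0)
    kd_hi = np.log(max(concs_pos) * 30.0)
    x0 = np.concatenate([k0] + [k0 for _ in ligands]
                        + [[np.log(np.median(concs_pos))] for _ in ligands])
    lo = np.concatenate([np.full(7 * (1 + n_lig), -9.0), np.full(n_lig, kd_lo)])
    hi = np.concatenate([np.full(7 * (1 + n_lig), 9.0), np.full(n_lig, kd_hi)])
    x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
    sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                 method="trf", max_nfev=20000)
    k_i1, lk, kd1 = unpack(sol.x)
    flat = np.abs(sol.fun).max() < 1e-12 and len(conditions) > 1
    if flat and all(np.allclose(p_by_condition[c], apo_obs) for c in conditions):
        raise ValueError("probability curves are flat; equilibrium constants not identifiable")
    return EquilibriumSet(k_i1=k_i1, lk_i1=lk, kd1=kd1)


def conformation_probabilities(p8: np.ndarray) -> np.ndarray:
    """Collapse P(S1..S8) to the four conformations (S_i + S_{i+4})."""
    p8 = np.asarray(p8)
    return p8[..., :4] + p8[..., 4:]
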