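"""Conformational-state identification on the unit sphere.

Events carry a dipole orientation; states are found by shortest-distance
(k-means) clustering of the corresponding unit vectors in Cartesian
coordinates, without any preconceived kinetic model.  The number of states
is the largest k (up to 6) for which every pair of cluster means stays
resolvable under the 2.5-sigma rule; consecutive events assigned to the
same state are changepoint false positives and are merged.  Conformational
states are matched to crystallographic structural states by exhaustive
least-squares over the 24 pairings of four orientations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .polarimetry import (Calibration, SphericalOrientation, estimate_angles,
                          vector_to_orientation)

RESOLUTION_SIGMA = 2.5


@dataclass
class StateModel:
    k: int
    means: list[SphericalOrientation]
    mean_vectors: np.ndarray            # (k, 3) unit vectors
    sigma_theta: np.ndarray             # degrees, per state
    sigma_phi: np.ndarray
    resolvable: np.ndarray              # (k, k) boolean


@dataclass
class TransitionStats:
    p: np.ndarray                       # (k, k) exit probabilities, diagonal 0
    n: np.ndarray                       # (k, k) transition counts
    occupancy: np.ndarray               # time-weighted state fractions
    undefined_rows: np.ndarray          # states with zero observed exits


def events_to_vectors(events: pd.DataFrame) -> np.ndarray:
    t = np.deg2rad(events["theta"].to_numpy(dtype=float))
    p = np.deg2rad(events["phi"].to_numpy(dtype=float))
    return np.column_stack([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def _axial_embedding(vecs: np.ndarray) -> np.ndarray:
    """Sign-invariant outer-product embedding of dipole axes.

    v and -v map to the same point, and squared Euclidean distance in the
    embedding is monotone in the axial angle, so chord-distance k-means
    works regardless of how vectors were folded.
    """
    x, y, z = vecs.T
    s = np.sqrt(2.0)
    return np.column_stack([x * x, y * y, z * z, s * x * y, s * x * z, s * y * z])


def _principal_axis(vecs: np.ndarray) -> np.ndarray:
    """Axial mean: principal eigenvector of the mean outer product."""
    m = vecs.T @ vecs / len(vecs)
    w, v = np.linalg.eigh(m)
    return v[:, -1]


def _pair_separation_sigma(members_a: np.ndarray, members_b: np.ndarray,
                           mean_a: np.ndarray, mean_b: np.ndarray,
                           seed: int = 0) -> float:
    """Separation of two clusters in pooled-sigma units.

    The combined members are projected onto the axis joining the two means
    (dipole sign folded) and a two-component Gaussian mixture is fitted to
    the projections; the statistic |mu1 - mu2| / mean(sigma1, sigma2)
    estimates the mode separation in units of the underlying state width.
    Measuring the widths through the mixture rather than within each
    k-means cell avoids the truncation bias of cells that merely slice one
    state in two.
    """
    signs_a = np.where(members_a @ mean_a < 0, -1.0, 1.0)
    a = members_a * signs_a[:, None]
    mb = mean_b if mean_b @ mean_a >= 0 else -mean_b
    signs_b = np.where(members_b @ mb < 0, -1.0, 1.0)
    b = members_b * signs_b[:, None]
    axis = mb - mean_a
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return 0.0
    axis = axis / norm
    x = np.concatenate([a @ axis, b @ axis]).reshape(-1, 1)
    gm = GaussianMixture(2, random_state=seed, n_init=3,
                         reg_covar=1e-10).fit(x)
    g1 = GaussianMixture(1, random_state=seed).fit(x)
    if gm.bic(x) >= g1.bic(x):
        return 0.0      # one mode describes the pooled projections better
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    return float(abs(mu[0] - mu[1]) / (0.5 * (sd[0] + sd[1])))


def _angular_sigma_total(members: np.ndarray, mean_vec: np.ndarray) -> float:
    """RMS angular deviation (degrees) of members about the cluster mean."""
    dots = np.clip(np.abs(members @ mean_vec), 0.0, 1.0)
    ang = np.rad2deg(np.arccos(dots))
    return float(np.sqrt((ang ** 2).mean()))


def cluster_orientations(events: pd.DataFrame, k_max: int = 6, seed: int = 0,
                         n_init: int = 50, resolution: float = RESOLUTION_SIGMA,
                         sigma_mode: str = "geodesic",
                         min_events: int = 15) -> tuple[StateModel, np.ndarray]:
    """Shortest-distance clustering with the 2.5-sigma resolution rule.

    Unit vectors are clustered by Euclidean (chord) distance with k-means++
    (50 restarts); k is the largest value <= k_max for which every pair of
    cluster means is separated by at least ``resolution`` times the pooled
    angular sigma (mean of the two clusters' sigmas along the inter-mean
    geodesic, or total angular sigma with sigma_mode="total").  Clusters are
    ordered by the phi of their mean orientation.
    """
    usable = events[~events.get("degenerate", pd.Series(False, index=events.index))]
    if len(usable) < min_events:
        raise ValueError(f"need at least {min_events} events, got {len(usable)}")
    vecs = events_to_vectors(usable)

    emb = _axial_embedding(vecs)
    best = None
    for k in range(min(k_max, len(usable)), 0, -1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    random_state=seed).fit(emb)
        labels = km.labels_
        means = np.array([_principal_axis(vecs[labels == c]) for c in range(k)])
        ok = True
        resolvable = np.ones((k, k), dtype=bool)
        for a, b in itertools.combinations(range(k), 2):
            if sigma_mode == "geodesic":
                d = _pair_separation_sigma(vecs[labels == a], vecs[labels == b],
                                           means[a], means[b], seed=seed)
                resolvable[a, b] = resolvable[b, a] = d >= resolution
            else:
                sep = np.rad2deg(np.arccos(np.clip(abs(means[a] @ means[b]), 0, 1)))
                sa = _angular_sigma_total(vecs[labels == a], means[a])
                sb = _angular_sigma_total(vecs[labels == b], means[b])
                resolvable[a, b] = resolvable[b, a] = \
                    sep >= resolution * 0.5 * (sa + sb)
            if not resolvable[a, b]:
                ok = False
        if ok or k == 1:
            best = (k, labels, means, resolvable)
            break
    k, labels, means, resolvable = best

    # order states by mean phi (the transporter fan: C1 at phi=0 ... C4 high)
    orients = [vector_to_orientation(m) for m in means]
    order = np.argsort([o.phi_deg for o in orients])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    means = means[order]
    orients = [orients[i] for i in order]
    resolvable = resolvable[np.ix_(order, order)]

    sig_t, sig_p = np.zeros(k), np.zeros(k)
    for c in range(k):
        sub = usable[labels == c]
        sig_t[c] = sub["theta"].std(ddof=0)
        sig_p[c] = sub["phi"].std(ddof=0)

    full_labels = np.full(len(events), -1, dtype=int)
    full_labels[np.flatnonzero(~events.get(
        "degenerate", pd.Series(False, index=events.index)).to_numpy())] = labels
    model = StateModel(k=k, means=orients, mean_vectors=means,
                       sigma_theta=sig_t, sigma_phi=sig_p, resolvable=resolvable)
    return model, full_labels


CHANNELS = ["I0", "I45", "I90", "I135"]


def aggregate_patterns(events: pd.DataFrame, labels: np.ndarray, k: int,
                       delta_deg: float = 0.0, min_frames: int = 1):
    """Per-state channel patterns and orientations from summed intensities.

    Summing the (corrected) channel intensities of all member events before
    estimating anything maximizes SNR: the returned (k, 4) array holds each
    state's channel fractions and the (k, 3) array the orientation unit
    vector estimated from the aggregate.  ``min_frames`` excludes short
    events whose intensities may mix two states across a transition.
    Raises if a state has no events.
    """
    patterns = np.empty((k, 4))
    vectors = np.empty((k, 3))
    w = events["n_frames"].to_numpy(dtype=float)
    ch = events[CHANNELS].to_numpy(dtype=float)
    long_enough = w >= min_frames
    for c in range(k):
        sel = (labels == c) & long_enough
        if not sel.any():
            sel = labels == c
        if not sel.any():
            raise ValueError(f"state {c} has no events")
        tot = (ch[sel] * w[sel, None]).sum(axis=0)
        tot = np.clip(tot, 1e-9, None)
        patterns[c] = tot / tot.sum()
        o = estimate_angles(*tot, cal=Calibration(delta_deg=delta_deg))
        vectors[c] = o.unit_vector()
    return patterns, vectors


def assign_by_intensity(events: pd.DataFrame, patterns: np.ndarray) -> np.ndarray:
    """Maximum-likelihood state assignment from raw channel proportions.

    Each event's summed channel counts are scored against every state's
    channel-fraction pattern under a multinomial model; this uses the
    photon-level sufficient statistics directly and so weighs short events
    by exactly the information they carry.
    """
    x = events[CHANNELS].to_numpy(dtype=float) \
        * events["n_frames"].to_numpy(dtype=float)[:, None]
    x = np.clip(x, 0.0, None)
    ll = x @ np.log(patterns).T
    return np.argmax(ll, axis=1)


def merge_same_state(events: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Merge consecutive events with identical state labels.

    The transition between two same-state events is a changepoint false
    positive; the merged event re-averages corrected intensities weighted by
    frame count.  Requires events sorted by start within a single trace (or
    carrying a ``particle`` column, within which merging is applied).
    """
    ev = events.copy()
    ev["state"] = labels
    group_cols = ["particle"] if "particle" in ev.columns else []
    out_rows = []
    for _, grp in (ev.groupby(group_cols) if group_cols else [(None, ev)]):
        grp = grp.sort_values("start")
        run_key = (grp["state"].ne(grp["state"].shift())).cumsum()
        for _, run in grp.groupby(run_key):
            w = run["n_frames"].to_numpy(dtype=float)
            row = run.iloc[0].copy()
            row["end"] = run["end"].iloc[-1]
            row["n_frames"] = int(w.sum())
            for col in ("I0", "I45", "I90", "I135", "theta", "phi"):
                if col in run:
                    row[col] = float(np.average(run[col], weights=w))
            out_rows.append(row)
    return pd.DataFrame(out_rows).reset_index(drop=True)


def state_statistics(events: pd.DataFrame, k: int | None = None,
                     frame_interval: float = 1.0) -> TransitionStats:
    """Occupancies and exit-branching probabilities from merged events.

    Occupancy is time-weighted (frames in state / total frames); p_ij counts
    exits i -> j over consecutive events within a particle, normalized per
    row.  States with no observed exits get a flagged undefined row.
    """
    states = events["state"].to_numpy(dtype=int)
    if (states < 0).any():
        raise ValueError("all events must be state-labeled")
    if k is None:
        k = states.max() + 1
    frames = events["n_frames"].to_numpy(dtype=float)
    occ = np.bincount(states, weights=frames, minlength=k)
    occ = occ / occ.sum()
    n = np.zeros((k, k))
    if "particle" in events.columns:
        groups = [g["state"].to_numpy(dtype=int)
                  for _, g in events.sort_values("start").groupby("particle")]
    else:
        groups = [states]
    for seq in groups:
        for a, b in zip(seq[:-1], seq[1:]):
            if a != b:
                n[a, b] += 1
    row_sums = n.sum(axis=1)
    undefined = row_sums == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(row_sums[:, None] > 0, n / np.where(row_sums[:, None] > 0,
                                                         row_sums[:, None], 1.0), np.nan)
    return TransitionStats(p=p, n=n, occupancy=occ, undefined_rows=undefined)


def match_structural_states(conf_means, struct_means):
    """Pair four conformational with four structural orientations.

    Evaluates all 24 permutations; the combined least squares LS_e is the
    sum of squared chord distances between paired unit vectors, and the best
    pairing maximizes 1/LS_e.  Returns (best permutation, LS_e array) where
    permutation[i] is the structural index paired with conformational i.
    """
    cv = np.array([m.unit_vector() if isinstance(m, SphericalOrientation)
                   else np.asarray(m, dtype=float) for m in conf_means])
    sv = np.array([m.unit_vector() if isinstance(m, SphericalOrientation)
                   else np.asarray(m, dtype=float) for m in struct_means])
    if cv.shape != (4, 3) or sv.shape != (4, 3):
        raise ValueError("need exactly four orientations on each side")
    perms = list(itertools.permutations(range(4)))
    ls_e = np.empty(len(perms))
    for idx, perm in enumerate(perms):
        d = cv - sv[list(perm)]
        # chord distance with dipole sign folding
        d2 = np.minimum((d ** 2).sum(axis=1),
                        ((cv + sv[list(perm)]) ** 2).sum(axis=1))
        ls_e[idx] = d2.sum()
    best = perms[int(np.argmin(ls_e))]
    return best, ls_e
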