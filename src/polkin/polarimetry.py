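"""Dipole orientation from four-channel polarized intensities.

A fluorophore dipole with inclination ``theta`` (from the optical axis z) and
in-plane rotation ``phi`` splits its emission over four polarization channels
(0, 45, 90, 135 degrees).  Because the dipole is a line, not a vector, the
orientation lives on a hemisphere: theta in [0, 90] degrees and phi in
(-90, 90] degrees.  Fast restricted "wobble" of the dipole inside a cone of
half-angle ``delta`` attenuates the polarized modulation by an order parameter
S(delta); the inversion corrects the apparent theta with S.

All public angles are degrees; internal math is radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Above the magic angle (54.7356 deg) the second-rank order parameter used
# here would no longer keep sin(theta_app) invertible for all theta.
MAX_DELTA_DEG = 54.7356103


@dataclass(frozen=True)
class SphericalOrientation:
    """Dipole orientation: theta in [0, 90] deg, phi in (-90, 90] deg.

    ``degenerate`` flags theta == 0 inputs where phi is undefined (reported
    as 0); ``clipped`` flags inversions where sin(theta_app)/S exceeded 1
    and was clipped.
    """

    theta_deg: float
    phi_deg: float
    degenerate: bool = False
    clipped: bool = False

    def unit_vector(self) -> np.ndarray:
        t = np.deg2rad(self.theta_deg)
        p = np.deg2rad(self.phi_deg)
        return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


@dataclass(frozen=True)
class Calibration:
    """Per-channel gain/background correction plus the wobble half-cone angle.

    ``gains`` multiply true intensities on the way to the detector, so the
    correction divides; ``backgrounds`` are additive counts/frame, subtracted
    first.  Channel order is (I0, I45, I90, I135).
    """

    delta_deg: float = 0.0
    gains: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    backgrounds: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.delta_deg < MAX_DELTA_DEG:
            raise ValueError(f"delta must be in [0, {MAX_DELTA_DEG}) deg")
        if any(g <= 0 for g in self.gains):
            raise ValueError("gains must be positive")

    def correct(self, counts) -> np.ndarray:
        """Background-subtract and gain-divide raw channel counts."""
        c = np.asarray(counts, dtype=float)
        return (c - np.asarray(self.backgrounds)) / np.asarray(self.gains)


def order_parameter(delta_deg: float) -> float:
    """Wobble-in-cone second-rank order parameter S = cos d (1 + cos d) / 2.

    S(0) = 1 and S decreases monotonically, reaching 0 at the magic angle.
    """
    d = np.deg2rad(delta_deg)
    c = np.cos(d)
    return float(c * (1.0 + c) / 2.0)


def forward_intensities(o: SphericalOrientation, delta_deg: float, itot: float):
    """Expected (I0, I45, I90, I135) for a dipole of total intensity ``itot``.

    The model is the exact inverse of :func:`estimate_angles`:
    I0/I90 = (itot/4)(1 +/- S sin(theta) cos(2 phi)),
    I45/I135 = (itot/4)(1 +/- S sin(theta) sin(2 phi)).
    Components are non-negative and sum to itot.
    """
    if itot < 0:
        raise ValueError("itot must be non-negative")
    s = order_parameter(delta_deg)
    t = np.deg2rad(o.theta_deg)
    p = np.deg2rad(o.phi_deg)
    a = s * np.sin(t)
    q = itot / 4.0
    i0 = q * (1.0 + a * np.cos(2.0 * p))
    i90 = q * (1.0 - a * np.cos(2.0 * p))
    i45 = q * (1.0 + a * np.sin(2.0 * p))
    i135 = q * (1.0 - a * np.sin(2.0 * p))
    return float(i0), float(i45), float(i90), float(i135)


def estimate_angles(i0, i45, i90, i135, cal: Calibration | None = None) -> SphericalOrientation:
    """Invert four channel intensities to a dipole orientation.

    When a :class:`Calibration` is given, raw counts are background/gain
    corrected first and the wobble correction uses its delta.  The estimate
    depends only on intensity ratios, so uniform scaling of the inputs leaves
    the result unchanged.
    """
    if cal is not None:
        i0, i45, i90, i135 = cal.correct([i0, i45, i90, i135])
        delta_deg = cal.delta_deg
    else:
        delta_deg = 0.0
    total = i0 + i45 + i90 + i135
    if total <= 0:
        raise ValueError("total corrected intensity must be positive")
    dx = i0 - i90
    dy = i45 - i135
    amp = 2.0 * np.hypot(dx, dy) / total
    if amp == 0.0:
        # no in-plane modulation: dipole on z, phi undefined
        return SphericalOrientation(0.0, 0.0, degenerate=True)
    phi = 0.5 * np.arctan2(dy, dx)
    s = order_parameter(delta_deg)
    ratio = amp / s
    clipped = ratio > 1.0 + 1e-9
    if ratio > 1.0 - 1e-12:
        # arcsin loses ~sqrt(eps) precision at its endpoint; within a few
        # ulps of 1 the dipole is in-plane to float precision
        theta = np.pi / 2
    else:
        theta = np.arcsin(ratio)
    phi_deg = np.rad2deg(phi)
    if phi_deg <= -90.0:  # fold onto (-90, 90]
        phi_deg += 180.0
    return SphericalOrientation(float(np.rad2deg(theta)), float(phi_deg), clipped=bool(clipped))


def omega(a: SphericalOrientation, b: SphericalOrientation) -> float:
    """Direct angle (degrees) between two dipole orientations, in [0, 90].

    The absolute value of the dot product accounts for the line symmetry of
    the dipole (v and -v are the same orientation).
    """
    dot = abs(float(a.unit_vector() @ b.unit_vector()))
    return float(np.rad2deg(np.arccos(min(1.0, dot))))


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def local_frame_rotation(c1_mean: np.ndarray, c4_mean: np.ndarray) -> np.ndarray:
    """Rotation matrix R mapping lab-frame vectors into the molecule frame.

    The molecular x axis is the mean C1 dipole (so C1 maps to theta=90,
    phi=0), and the x-y plane is spanned by the C1 and C4 means (so C4 maps
    to theta=90 with phi > 0).  Rows of R are the frame axes; apply as
    ``vectors @ R.T``.
    """
    x = _normalize(np.asarray(c1_mean, dtype=float))
    c4 = _normalize(np.asarray(c4_mean, dtype=float))
    z = np.cross(x, c4)
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("C1 and C4 means are (anti)parallel; local frame undefined")
    z = z / nz
    y = np.cross(z, x)
    # sign convention: C4 should land at positive phi *as a dipole line* --
    # fold its representative to non-negative x' before testing the sign
    cx, cy = c4 @ x, c4 @ y
    if cx < 0:
        cy = -cy
    if cy < 0:
        z, y = -z, -y
    return np.vstack([x, y, z])


def to_local_frame(vectors, c1_mean, c4_mean) -> np.ndarray:
    """Re-express unit vectors in the molecule-local frame (see above)."""
    r = local_frame_rotation(c1_mean, c4_mean)
    return np.asarray(vectors, dtype=float) @ r.T


def vector_to_orientation(v) -> SphericalOrientation:
    """Unit vector -> (theta, phi) on the canonical quarter-sphere.

    The four intensities determine only sin(theta) and phi mod 180, so
    orientations are reported with theta in [0, 90] (fold z -> |z|) and phi
    in (-90, 90] (fold the in-plane component to x >= 0).
    """
    v = _normalize(np.asarray(v, dtype=float))
    x, y, z = v
    z = abs(z)
    if x < 0 or (x == 0 and y < 0):
        x, y = -x, -y
    theta = float(np.rad2deg(np.arccos(np.clip(z, 0.0, 1.0))))
    if np.hypot(x, y) < 1e-12:
        return SphericalOrientation(0.0, 0.0, degenerate=True)
    phi = float(np.rad2deg(np.arctan2(y, x)))
    if phi <= -90.0:
        phi += 180.0
    return SphericalOrientation(theta, phi)


def mean_orientation(vectors) -> np.ndarray:
    """Sign-coherent mean of dipole unit vectors (folded toward the first)."""
    v = np.asarray(vectors, dtype=float)
    if v.ndim == 1:
        return _normalize(v)
    ref = v[0]
    signs = np.where(v @ ref < 0, -1.0, 1.0)
    return _normalize((v * signs[:, None]).mean(axis=0))
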