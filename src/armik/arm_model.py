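"""Four-degree-of-freedom arm kinematics.

The arm is modelled as two rigid links (upper arm and forearm) joined at
the elbow, with a ball-and-socket shoulder (3 DOF) and a hinge elbow
(1 DOF); pronation/supination and wrist DOF are excluded.  Two equivalent
configuration representations are supported:

* **anatomical** ``(theta, eta, zeta, phi)`` — upper-arm elevation and
  yaw in an external frame plus humeral rotation ``zeta`` and elbow
  flexion ``phi`` (``phi = pi`` is full extension) in the frame of the
  upper arm;
* **absolute** ``(theta, eta, beta, alpha)`` — elevation and yaw of each
  segment in a single gravity-fixed external frame.

Coordinate convention: ``z`` is vertical up, azimuth is measured in the
horizontal plane from ``+x``, and elevation is measured from the downward
vertical, so ``theta = 0`` means the arm hangs at rest.  ``zeta = 0``
places the forearm in the vertical plane containing the upper arm, and a
positive ``zeta`` rotates it out of that plane by the right-hand rule
about the upper-arm axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AbsoluteAngles",
    "AnatomicalAngles",
    "GimbalDegenerateError",
    "MarkerFrame",
    "SegmentLengths",
    "absolute_to_anatomical",
    "anatomical_to_absolute",
    "estimate_joint_centre",
    "extract_joint_angles",
    "forward_kinematics",
    "numeric_jacobian",
]

_DOWN = np.array([0.0, 0.0, -1.0])


class GimbalDegenerateError(ValueError):
    """Raised when a configuration makes an angle decomposition undefined."""


@dataclass(frozen=True)
class SegmentLengths:
    """Lengths of the two arm links in metres."""

    upper_arm: float
    forearm: float

    def __post_init__(self) -> None:
        if not (self.upper_arm > 0 and self.forearm > 0):
            raise ValueError("segment lengths must be strictly positive")


@dataclass(frozen=True)
class AnatomicalAngles:
    """Anatomical (relative) representation ``(theta, eta, zeta, phi)`` in radians."""

    theta: float
    eta: float
    zeta: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= np.pi:
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")
        if not 0.0 < self.phi <= np.pi:
            raise ValueError(f"phi must lie in (0, pi], got {self.phi}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.eta, self.zeta, self.phi])


@dataclass(frozen=True)
class AbsoluteAngles:
    """Absolute (external) representation ``(theta, eta, beta, alpha)`` in radians."""

    theta: float
    eta: float
    beta: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= np.pi:
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")
        if not 0.0 <= self.beta <= np.pi:
            raise ValueError(f"beta must lie in [0, pi], got {self.beta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.eta, self.beta, self.alpha])


@dataclass(frozen=True)
class MarkerFrame:
    """Named marker positions (metres) at one time instant."""

    positions: Mapping[str, np.ndarray]
    time: float = 0.0

    def __post_init__(self) -> None:
        for name, p in self.positions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"marker {name!r} must be a finite 3-vector")


def _segment_direction(elevation: float, azimuth: float) -> np.ndarray:
    """Unit direction of a segment from its (elevation, azimuth).

    Elevation is measured from the downward vertical, azimuth from +x in
    the horizontal plane, so elevation 0 gives (0, 0, -1).
    """
    se, ce = np.sin(elevation), np.cos(elevation)
    return np.array([se * np.cos(azimuth), se * np.sin(azimuth), -ce])


def _spherical_of_direction(v: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`_segment_direction`: (elevation, azimuth) of a unit vector."""
    elevation = float(np.arccos(np.clip(-v[2], -1.0, 1.0)))
    if np.hypot(v[0], v[1]) < 1e-12:
        azimuth = 0.0  # vertical segment: azimuth unobservable, fixed to 0
    else:
        azimuth = float(np.arctan2(v[1], v[0]))
    return elevation, azimuth


def _flexion_plane_basis(u: np.ndarray) -> np.ndarray:
    """In-plane unit vector perpendicular to ``u`` pointing down-ish.

    This is the direction the forearm bends towards at ``zeta = 0``: the
    projection of the downward vertical onto the plane orthogonal to the
    upper-arm axis ``u``.
    """
    m = _DOWN - np.dot(_DOWN, u) * u
    n = np.linalg.norm(m)
    if n < 1e-10:
        raise GimbalDegenerateError(
            "upper arm is vertical (theta = 0 or pi): the zeta/flexion plane is undefined"
        )
    return m / n


def _forearm_direction(a: AnatomicalAngles) -> np.ndarray:
    u = _segment_direction(a.theta, a.eta)
    if abs(a.phi - np.pi) < 1e-12:
        return u  # fully extended: forearm collinear, zeta irrelevant
    m0 = _flexion_plane_basis(u)
    m = np.cos(a.zeta) * m0 + np.sin(a.zeta) * np.cross(u, m0)
    bend = np.pi - a.phi
    return np.cos(bend) * u + np.sin(bend) * m


def forward_kinematics(
    config: AnatomicalAngles | AbsoluteAngles, lengths: SegmentLengths
) -> tuple[np.ndarray, np.ndarray]:
    """Elbow and wrist positions (shoulder at the origin).

    Returns
    -------
    elbow, wrist : ndarray of shape (3,)
        ``elbow = L_u * u(theta, eta)`` and ``wrist = elbow + L_f * v``
        where ``v`` is the forearm direction implied by ``(zeta, phi)``
        or ``(beta, alpha)``.
    """
    u = _segment_direction(config.theta, config.eta)
    if isinstance(config, AnatomicalAngles):
        v = _forearm_direction(config)
    elif isinstance(config, AbsoluteAngles):
        v = _segment_direction(config.beta, config.alpha)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported configuration type {type(config)!r}")
    elbow = lengths.upper_arm * u
    wrist = elbow + lengths.forearm * v
    return elbow, wrist


def anatomical_to_absolute(a: AnatomicalAngles) -> AbsoluteAngles:
    """Convert ``(theta, eta, zeta, phi)`` to ``(theta, eta, beta, alpha)``.

    The upper-arm angles pass through unchanged; ``(beta, alpha)`` are the
    spherical elevation/azimuth of the forearm direction.
    """
    v = _forearm_direction(a)
    beta, alpha = _spherical_of_direction(v)
    return AbsoluteAngles(theta=a.theta, eta=a.eta, beta=beta, alpha=alpha)


def absolute_to_anatomical(b: AbsoluteAngles) -> AnatomicalAngles:
    """Convert ``(theta, eta, beta, alpha)`` to ``(theta, eta, zeta, phi)``.

    ``phi`` is the elbow angle between the (shoulder - elbow) and
    (wrist - elbow) directions, so collinear extension gives ``phi = pi``;
    ``zeta`` is the signed dihedral angle between the vertical plane
    through the upper arm and the arm plane.
    """
    u = _segment_direction(b.theta, b.eta)
    v = _segment_direction(b.beta, b.alpha)
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    phi = float(np.arccos(np.clip(-c, -1.0, 1.0)))
    if phi < 1e-9:
        raise ValueError("forearm antiparallel to upper arm: zeta undefined (phi = 0)")
    v_perp = v - c * u
    n = np.linalg.norm(v_perp)
    if n < 1e-9:
        zeta = 0.0  # full extension: zeta unobservable, zero by convention
    else:
        m0 = _flexion_plane_basis(u)
        zeta = float(np.arctan2(np.dot(np.cross(u, m0), v_perp / n), np.dot(m0, v_perp / n)))
    return AnatomicalAngles(theta=b.theta, eta=b.eta, zeta=zeta, phi=phi)


def numeric_jacobian(
    config: AnatomicalAngles, lengths: SegmentLengths, step: float = 1e-6
) -> np.ndarray:
    """3x4 Jacobian of the wrist position w.r.t. (theta, eta, zeta, phi).

    Central finite differences with configurable step (radians).
    """
    q0 = config.as_array()
    J = np.empty((3, 4))
    for j in range(4):
        qp, qm = q0.copy(), q0.copy()
        qp[j] += step
        qm[j] -= step
        # Clip to valid ranges so differencing at domain edges stays defined.
        qp[0] = min(qp[0], np.pi)
        qm[0] = max(qm[0], 0.0)
        qp[3] = min(qp[3], np.pi)
        qm[3] = max(qm[3], 1e-12)
        h = qp[j] - qm[j]
        _, wp = forward_kinematics(AnatomicalAngles(*qp), lengths)
        _, wm = forward_kinematics(AnatomicalAngles(*qm), lengths)
        J[:, j] = (wp - wm) / h
    return J


def estimate_joint_centre(
    frames: Sequence[MarkerFrame],
    marker_names: Iterable[str],
    bias_compensation: bool = True,
) -> np.ndarray:
    """Least-squares centre of rotation from markers rigid w.r.t. a joint.

    Solves the sphere-fit family problem: find the point ``m`` minimizing
    ``sum_k sum_t (|p_k(t) - m|^2 - r_k^2)^2`` via the closed-form linear
    system (each marker moves on its own sphere about the common centre).
    A bias-compensation pass subtracts the isotropic-noise bias from the
    right-hand side using the residual-based noise variance estimate.

    Parameters
    ----------
    frames : sequence of MarkerFrame
        At least ~50 frames with rotation diversity.
    marker_names : iterable of str
        Markers assumed rigidly attached to the rotating segment.

    Returns
    -------
    ndarray (3,) — centre of rotation in the frame of the input markers.
    """
    names = list(marker_names)
    P = {k: np.array([np.asarray(f.positions[k], dtype=float) for f in frames]) for k in names}

    def _solve(noise_var: float) -> tuple[np.ndarray, float]:
        A = np.zeros((3, 3))
        rhs = np.zeros(3)
        ss_res = 0.0
        n_obs = 0
        for k in names:
            p = P[k]
            pbar = p.mean(axis=0)
            d = 2.0 * (p - pbar)
            sq = np.einsum("ij,ij->i", p, p)
            # Isotropic noise inflates |p|^2 by 3*sigma^2 on average; the
            # mean-removed target y is unbiased, but the normal matrix picks
            # up a 4*sigma^2*I term from E[d d^T]; compensate both sides.
            y = sq - sq.mean()
            A += d.T @ d - 4.0 * noise_var * len(p) * np.eye(3)
            rhs += d.T @ y
            n_obs += len(p)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "centre-of-rotation system is rank deficient: insufficient rotation diversity"
            )
        m = np.linalg.solve(A, rhs)
        for k in names:
            p = P[k]
            r2 = np.mean(np.einsum("ij,ij->i", p - m, p - m))
            ss_res += float(np.sum((np.einsum("ij,ij->i", p - m, p - m) - r2) ** 2))
        return m, ss_res / max(n_obs - 4, 1)

    m, resid = _solve(0.0)
    if bias_compensation:
        # resid ~ E[(|e|^2-ish)^2]; for radius r >> sigma the dominant term is
        # 4 r^2 sigma^2 per observation. Use the mean squared radius to back
        # out sigma^2 and redo the solve with the debiased normal matrix.
        r2_mean = np.mean(
            [np.mean(np.einsum("ij,ij->i", P[k] - m, P[k] - m)) for k in names]
        )
        sigma2 = resid / (4.0 * r2_mean) if r2_mean > 0 else 0.0
        m, _ = _solve(sigma2)
    return m


def _angles_from_directions(u: np.ndarray, v: np.ndarray) -> tuple[AbsoluteAngles, AnatomicalAngles]:
    th, eta = _spherical_of_direction(u)
    be, al = _spherical_of_direction(v)
    b = AbsoluteAngles(theta=th, eta=eta, beta=be, alpha=al)
    return b, absolute_to_anatomical(b)


def extract_joint_angles(
    frames: Sequence[MarkerFrame],
    shoulder: str = "shoulder",
    elbow: str = "elbow",
    wrist: str = "wrist",
) -> tuple[np.ndarray, np.ndarray, "SegmentLengths"]:
    """Joint-angle trajectories and segment lengths from marker frames.

    Per-frame segment directions ``u = elbow - shoulder`` and ``v = wrist -
    elbow`` give the absolute angles directly; anatomical angles follow via
    :func:`absolute_to_anatomical`.  Segment lengths are the medians of the
    per-frame distances.  The three markers are taken to sit at the joint
    centres (use :func:`estimate_joint_centre` on a marker cluster first if
    they do not).

    Returns
    -------
    anatomical : ndarray (n_frames, 4) — columns (theta, eta, zeta, phi)
    absolute : ndarray (n_frames, 4) — columns (theta, eta, beta, alpha)
    lengths : SegmentLengths
    """
    anat = np.empty((len(frames), 4))
    absl = np.empty((len(frames), 4))
    lu, lf = np.empty(len(frames)), np.empty(len(frames))
    for i, f in enumerate(frames):
        s = np.asarray(f.positions[shoulder], dtype=float)
        e = np.asarray(f.positions[elbow], dtype=float)
        w = np.asarray(f.positions[wrist], dtype=float)
        lu[i] = np.linalg.norm(e - s)
        lf[i] = np.linalg.norm(w - e)
        b, a = _angles_from_directions((e - s) / lu[i], (w - e) / lf[i])
        absl[i] = b.as_array()
        anat[i] = a.as_array()
    return anat, absl, SegmentLengths(float(np.median(lu)), float(np.median(lf)))
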