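"""Shared-basis inverse kinematics.

If the task-space channels and the joint-space channels of a cyclic
movement are mixtures of the *same* periodic sources, the task mixture can
be inverted to recover the sources, and the joint trajectory re-composed
from them.  On the harmonic grid the task mixture is the per-frequency
linear system ``F[x](xi) = A(xi) F[s](xi)`` with the *symbol matrix*
``A_ij(xi) = a_ij exp(-2 pi i tau_ij xi)``; whenever ``det A(xi) != 0`` on
the retained band the system is solved harmonic by harmonic, conjugate
symmetry is enforced, and the recovered real sources are delayed/weighted
into joint angles.  With all delays zero the whole transform collapses to
the static linear map ``q = A B^{-1} x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .arm_model import AnatomicalAngles, SegmentLengths, numeric_jacobian
from .fada import AnechoicDemixing, _as_cycles

__all__ = [
    "LinearMaps",
    "SharedBasisIK",
    "SingularFrequencyError",
    "SymbolMatrix",
    "build_symbol_matrix",
    "invert_mixture",
    "task_to_joint_full",
    "task_to_joint_static",
    "velocity_map",
]


class SingularFrequencyError(np.linalg.LinAlgError):
    """The mixing operator is singular on at least one retained harmonic."""

    def __init__(self, harmonics: list[int]):
        self.harmonics = harmonics
        super().__init__(
            f"symbol matrix singular at harmonic(s) {harmonics}: "
            "the anechoic mixture cannot be inverted there (|A| = 0)"
        )


@dataclass
class SymbolMatrix:
    """Frequency-indexed mixing operator of a 3-source task mixture.

    ``entries[k]`` is the 3x3 complex matrix ``A_ij(xi_k) = a_ij *
    exp(-2 pi i tau_ij xi_k)`` on the cycle-locked harmonic grid
    ``xi_k = k / P`` for ``k = 1..K``.
    """

    weights: np.ndarray          # (3, 3) a_ij
    delays: np.ndarray           # (3, 3) tau_ij, samples
    P: int
    entries: np.ndarray          # (K, 3, 3) complex
    condition: np.ndarray        # (K,) per-harmonic condition numbers

    @property
    def harmonics(self) -> np.ndarray:
        return np.arange(1, self.entries.shape[0] + 1)


def build_symbol_matrix(
    weights: np.ndarray, delays: np.ndarray, K: int = 10, P: int = 200
) -> SymbolMatrix:
    """Evaluate ``A_ij(xi) = a_ij e^{-2 pi i tau_ij xi}`` on harmonics 1..K."""
    weights = np.asarray(weights, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if weights.shape != delays.shape or weights.shape[0] != weights.shape[1]:
        raise ValueError("weights and delays must be square matrices of equal shape")
    k = np.arange(1, K + 1)
    entries = weights[None] * np.exp(-2j * np.pi * delays[None] * k[:, None, None] / P)
    condition = np.array([np.linalg.cond(e) for e in entries])
    return SymbolMatrix(weights=weights, delays=delays, P=P, entries=entries, condition=condition)


def invert_mixture(
    x: np.ndarray,
    sm: SymbolMatrix,
    det_rtol: float = 1e-10,
    ridge: float | None = None,
) -> np.ndarray:
    """Recover sources from task cycles by per-harmonic inversion.

    ``x`` is ``(n_cycles, 3, P)`` or ``(3, P)``.  For each retained
    harmonic the 3x3 system ``F[x](k) = A(k) F[s](k)`` is solved; the
    channel means (harmonic 0) carry no source content and are dropped.
    Conjugate symmetry of the solved band is implicit in the inverse real
    FFT, so the recovered sources are real by construction.

    Raises :class:`SingularFrequencyError` when ``|det A(k)|`` falls below
    ``det_rtol * ||A||^3`` at any harmonic; warns (and optionally applies a
    Tikhonov ridge) when a harmonic is ill-conditioned.
    """
    squeeze = np.asarray(x).ndim == 2
    x = _as_cycles(x)
    L, M, P = x.shape
    if M != sm.weights.shape[0]:
        raise ValueError("task cycles and symbol matrix disagree on channel count")
    if P != sm.P:
        raise ValueError("cycle length differs from the symbol matrix P")
    K = sm.entries.shape[0]
    norm = np.linalg.norm(sm.weights)
    bad = [
        int(k)
        for k, e in zip(sm.harmonics, sm.entries)
        if abs(np.linalg.det(e)) < det_rtol * max(norm, 1e-300) ** 3
    ]
    if bad:
        raise SingularFrequencyError(bad)
    ill = sm.condition > 1e8
    if ill.any():
        warnings.warn(
            f"symbol matrix ill-conditioned at harmonics {list(sm.harmonics[ill])}"
            + ("; applying ridge" if ridge else ""),
            RuntimeWarning,
        )
    Xf = np.fft.rfft(x - x.mean(axis=2, keepdims=True), axis=2)
    Sf = np.zeros((L, M, P // 2 + 1), dtype=complex)
    for ki in range(K):
        Ak = sm.entries[ki]
        if ridge and ill[ki]:
            AH = Ak.conj().T
            solve_mat = AH @ Ak + ridge * np.eye(M)
            Sf[:, :, ki + 1] = np.linalg.solve(solve_mat, AH @ Xf[:, :, ki + 1].T).T
        else:
            Sf[:, :, ki + 1] = np.linalg.solve(Ak, Xf[:, :, ki + 1].T).T
    s = np.fft.irfft(Sf, n=P, axis=2)
    return s[0] if squeeze else s


def task_to_joint_static(x: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Zero-delay inverse map ``q = A B^{-1} x`` applied samplewise.

    ``A`` is the (n_joints, 3) joint weight matrix and ``B`` the (3, 3)
    task weight matrix; requires ``B`` invertible (three sources spanning
    the three task DOF).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.shape[0] != B.shape[1]:
        raise ValueError("task weight matrix B must be square")
    if abs(np.linalg.det(B)) < 1e-12 * max(np.linalg.norm(B), 1e-300) ** B.shape[0]:
        raise np.linalg.LinAlgError(
            "task weight matrix B is singular; the static inverse map q = A B^-1 x "
            "requires invertible task mixing"
        )
    squeeze = np.asarray(x).ndim == 2
    x = _as_cycles(x)
    K = A @ np.linalg.inv(B)
    q = np.einsum("jm,lmp->ljp", K, x)
    return q[0] if squeeze else q


def task_to_joint_full(
    x: np.ndarray,
    sm: SymbolMatrix,
    joint_weights: np.ndarray,
    joint_delays: np.ndarray,
    joint_means: np.ndarray | None = None,
    det_rtol: float = 1e-10,
) -> np.ndarray:
    """Full anechoic task-to-joint transform.

    Recovers the sources from the task cycles by per-harmonic inversion of
    the symbol matrix, then composes ``q_i(t) = sum_j beta_ij s_j((t -
    tau_ij) mod P)`` with the joint weights/delays (delays applied in the
    frequency domain, so fractional values are exact for band-limited
    sources).
    """
    squeeze = np.asarray(x).ndim == 2
    s = invert_mixture(x, sm, det_rtol=det_rtol)
    s = _as_cycles(s)
    L = s.shape[0]
    P = sm.P
    jw = np.asarray(joint_weights, dtype=float)
    jd = np.asarray(joint_delays, dtype=float)
    Sf = np.fft.rfft(s, axis=2)
    k = np.arange(Sf.shape[2])
    ramp = np.exp(-2j * np.pi * jd[:, :, None] * k[None, None, :] / P)  # (J, 3, K)
    Qf = np.einsum("ij,ijk,ljk->lik", jw, ramp, Sf)
    q = np.fft.irfft(Qf, n=P, axis=2)
    if joint_means is not None:
        q = q + np.asarray(joint_means, dtype=float)[None, :, None]
    return q[0] if squeeze else q


@dataclass
class LinearMaps:
    """Zero-delay linear maps between spaces at a configuration.

    ``F = J(q) A`` maps source velocities to task velocities and
    ``K = A B^{-1} F`` maps them to joint velocities.
    """

    A: np.ndarray   # (n_joints, n_src) joint weights
    B: np.ndarray   # (3, n_src) task weights
    J: np.ndarray   # (3, n_joints) Jacobian at the configuration
    F: np.ndarray
    K: np.ndarray


def velocity_map(
    config: AnatomicalAngles,
    A: np.ndarray,
    B: np.ndarray,
    s_dot: np.ndarray,
    lengths: SegmentLengths,
) -> tuple[np.ndarray, np.ndarray, LinearMaps]:
    """Velocity-level maps ``x_dot = F s_dot`` and ``q_dot = K s_dot``.

    ``s_dot`` is ``(n_src,)`` or ``(n_src, n_samples)``.  ``F = J(q) A``
    and ``K = A B^{-1} F`` with the numeric Jacobian evaluated at
    ``config``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.shape[0] != B.shape[1]:
        raise ValueError("B must be square")
    if abs(np.linalg.det(B)) < 1e-12:
        raise np.linalg.LinAlgError("task weight matrix B is singular")
    J = numeric_jacobian(config, lengths)
    F = J @ A
    K = A @ np.linalg.inv(B) @ F
    s_dot = np.asarray(s_dot, dtype=float)
    return F @ s_dot, K @ s_dot, LinearMaps(A=A, B=B, J=J, F=F, K=K)


class SharedBasisIK(RegressorMixin, BaseEstimator):
    """Task-to-joint transform learned from paired cyclic trajectories.

    ``fit`` demixes the task cycles (3 channels) into ``n_sources = 3``
    basis functions, builds the per-frequency symbol matrix from the
    fitted task weights/delays, and estimates the joint weights/delays by
    projecting the joint cycles on the same sources.  ``predict`` then
    maps new task cycles to joint cycles through per-harmonic inversion
    and re-composition.

    Parameters
    ----------
    n_harmonics : int, default 10
    max_iter, tol : demixing controls (see :class:`AnechoicDemixing`)
    random_state : seed for the demixing initialization.

    Attributes
    ----------
    demixer_ : AnechoicDemixing fitted on the task cycles
    symbol_matrix_ : SymbolMatrix of the mean task mixing
    joint_weights_, joint_delays_ : (n_joints, 3) mean joint mixing
    joint_means_ : (n_joints,)
    """

    def __init__(
        self,
        n_harmonics: int = 10,
        max_iter: int = 500,
        tol: float = 1e-8,
        random_state: int | None = None,
    ):
        self.n_harmonics = n_harmonics
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SharedBasisIK":
        """``X``: task cycles ``(L, 3, P)``; ``y``: joint cycles ``(L, J, P)``."""
        X = _as_cycles(X)
        y = _as_cycles(y)
        if X.shape[1] != 3:
            raise ValueError("task cycles must have exactly 3 channels")
        if X.shape[0] != y.shape[0] or X.shape[2] != y.shape[2]:
            raise ValueError("task and joint cycles must share n_cycles and P")
        self.demixer_ = AnechoicDemixing(
            n_sources=3,
            n_harmonics=self.n_harmonics,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(X)
        tw = self.demixer_.weights_.mean(axis=0)
        td = _circular_mean(self.demixer_.delays_, self.demixer_.P_)
        self.symbol_matrix_ = build_symbol_matrix(tw, td, K=self.n_harmonics, P=self.demixer_.P_)
        jw, jd, jm = self.demixer_.encode(y)
        self.joint_weights_ = jw.mean(axis=0)
        self.joint_delays_ = _circular_mean(jd, self.demixer_.P_)
        self.joint_means_ = jm.mean(axis=0)
        self.n_features_in_ = 3
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Joint cycles for new task cycles, same shape convention as fit."""
        check_is_fitted(self, "symbol_matrix_")
        return task_to_joint_full(
            X,
            self.symbol_matrix_,
            self.joint_weights_,
            self.joint_delays_,
            self.joint_means_,
        )


def _circular_mean(delays: np.ndarray, P: int) -> np.ndarray:
    """Circular mean over the leading (cycle) axis, in samples in [0, P)."""
    ang = 2 * np.pi * np.asarray(delays) / P
    m = np.angle(np.exp(1j * ang).mean(axis=0))
    return np.mod(m * P / (2 * np.pi), P)
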