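"""Synthetic cyclic drawing trials with known ground truth.

The generator emulates the statistical structure of recorded cyclic arm
drawing movements: ~20-25 s trials of repeated shape tracing, each cycle
representable as a weighted, circularly time-shifted superposition of a
small set of periodic basis functions ("sources") plus additive white
Gaussian measurement noise, with mild inter-cycle variability.  Cycles are
generated directly at the normalized length P = 200 samples.

Two generation modes are provided:

* ``exact_shared=True`` — the task-space channels are built from the same
  sources as the joint channels (both sides satisfy the anechoic mixture
  model exactly at zero noise), for exact-recovery tests;
* ``exact_shared=False`` (default) — the joint space is generative and the
  task trajectory is derived through forward kinematics, so the two spaces
  share sources only approximately, as in real movement data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .arm_model import (
    AbsoluteAngles,
    MarkerFrame,
    SegmentLengths,
    absolute_to_anatomical,
    forward_kinematics,
)

__all__ = [
    "GroundTruth",
    "dominant_mixture_weights",
    "ShapeSpec",
    "default_ground_truth",
    "generate_shape_trajectory",
    "generate_sources",
    "mix_channels",
    "synthesize_trial",
]

SHAPES = ("PE", "FE", "BE", "DBE", "UD")


@dataclass
class GroundTruth:
    """Generative parameters of a synthetic trial.

    ``sources`` are ``(n_src, P)`` unit-L2 periodic waveforms; weights and
    delays follow the anechoic mixture model per channel.  Delays are in
    samples, circular in ``[0, P)``.
    """

    sources: np.ndarray
    task_weights: np.ndarray       # (3, n_src)
    task_delays: np.ndarray        # (3, n_src)
    joint_weights: np.ndarray      # (4, n_src)
    joint_delays: np.ndarray       # (4, n_src)
    joint_offsets: np.ndarray      # (4,) mean absolute angles, radians
    noise_sd: float = 0.0
    n_cycles: int = 10
    seed: int = 0
    weight_jitter_sd: float = 0.05    # multiplicative, ~N(1, sd^2) per cycle
    delay_jitter_sd: float = 0.0      # additive samples per cycle

    @property
    def n_src(self) -> int:
        return self.sources.shape[0]

    @property
    def P(self) -> int:
        return self.sources.shape[1]


@dataclass
class ShapeSpec:
    """Geometric description of a drawn shape.

    ``shape`` is one of PE (planar ellipse), FE (figure eight, a 1:2
    Lissajous), BE (bent ellipse, one vertical lobe), DBE (double bent
    ellipse, two lobes) or UD (up-down oscillation).  ``plane_rotation``
    applies extrinsic rotations about x then y, in degrees.
    """

    shape: str = "PE"
    plane_rotation: tuple[float, float] = (0.0, 0.0)
    amplitude: float = 0.15
    centre: np.ndarray = field(default_factory=lambda: np.array([0.35, 0.0, -0.15]))
    cycle_period: float = 2.0
    sample_rate: float = 240.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.sample_rate < 60:
            raise ValueError("sample_rate must be at least 60 Hz")


def _max_circular_corr(f: np.ndarray, g: np.ndarray) -> float:
    """Maximum absolute circular cross-correlation of two waveforms."""
    f = f - f.mean()
    g = g - g.mean()
    r = np.fft.irfft(np.conj(np.fft.rfft(f)) * np.fft.rfft(g), n=len(f))
    return float(np.max(np.abs(r)) / (np.linalg.norm(f) * np.linalg.norm(g)))


def _max_autocorr_sidelobe(f: np.ndarray, guard: int) -> float:
    """Largest absolute circular autocorrelation beyond ``guard`` samples of lag 0."""
    f = f - f.mean()
    r = np.fft.irfft(np.abs(np.fft.rfft(f)) ** 2, n=len(f))
    r = r / r[0]
    mask = np.ones(len(f), dtype=bool)
    mask[:guard] = False
    mask[len(f) - guard + 1 :] = False
    return float(np.max(np.abs(r[mask])))


def generate_sources(
    n_src: int,
    P: int = 200,
    family: Literal["fourier-sparse", "sinusoid"] = "fourier-sparse",
    seed: int = 0,
    max_corr: float = 0.2,
    max_shift_corr: float = 0.55,
    max_sidelobe: float = 0.92,
    max_retries: int = 800,
) -> np.ndarray:
    """Periodic, zero-mean, unit-L2 source waveforms of shape ``(n_src, P)``.

    ``sinusoid`` gives cosines with 1..n_src cycles per period (mutually
    orthogonal).  ``fourier-sparse`` emulates the harmonic structure of
    cyclic drawing kinematics: source ``p`` is dominated by harmonic ``p``
    (the fundamental for the first source, the second harmonic for the
    next, and so on) plus weaker side harmonics with random phases.
    Candidates are redrawn until three identifiability conditions hold,
    all consequences of the free circular time shifts in the mixture
    model:

    * all pairwise Pearson correlations (lag 0) below ``max_corr``;
    * maximum circular cross-correlation over all lags below
      ``max_shift_corr`` (two sources that are near-copies under some
      shift are not separable);
    * each source's circular autocorrelation sidelobes (beyond 5% of the
      cycle) below ``max_sidelobe`` — a waveform that nearly reproduces
      itself under a shift, as a pure harmonic does every ``P/k``
      samples, has no well-defined delay.
    """
    if n_src < 1 or P < 8:
        raise ValueError("need n_src >= 1 and P >= 8")
    t = np.arange(P)
    if family == "sinusoid":
        S = np.stack([np.cos(2 * np.pi * (p + 1) * t / P) for p in range(n_src)])
        return S / np.linalg.norm(S, axis=1, keepdims=True)
    if family != "fourier-sparse":
        raise ValueError(f"unknown source family {family!r}")
    rng = np.random.default_rng(seed)
    side_pool = np.arange(1, max(7, n_src + 2))
    guard = max(2, P // 20)
    for _ in range(max_retries):
        S = np.zeros((n_src, P))
        for p in range(n_src):
            k_main = p + 1
            S[p] = np.cos(2 * np.pi * k_main * t / P + rng.uniform(0, 2 * np.pi))
            side = rng.choice(side_pool[side_pool != k_main], size=2, replace=False)
            for k in side:
                S[p] += rng.uniform(0.25, 0.55) * np.cos(
                    2 * np.pi * k * t / P + rng.uniform(0, 2 * np.pi)
                )
        S -= S.mean(axis=1, keepdims=True)
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        if any(_max_autocorr_sidelobe(S[p], guard) >= max_sidelobe for p in range(n_src)):
            continue
        if n_src == 1:
            return S
        C = np.corrcoef(S)
        if np.max(np.abs(C[np.triu_indices(n_src, 1)])) >= max_corr:
            continue
        shift_ok = all(
            _max_circular_corr(S[i], S[j]) < max_shift_corr
            for i in range(n_src)
            for j in range(i + 1, n_src)
        )
        if shift_ok:
            return S
    raise RuntimeError(f"could not decorrelate sources in {max_retries} tries")


def dominant_mixture_weights(n_channels: int, n_src: int, rng: np.random.Generator) -> np.ndarray:
    """Signed mixing weights with one dominant source per channel.

    Channel ``m`` is driven mainly by source ``m % n_src`` (|weight| in
    0.7..1.0) with weaker contributions (0.1..0.4) from the others and
    random signs, mirroring the empirical structure of drawing movements
    where, e.g., azimuth-related degrees of freedom follow one temporal
    generator and elevation-related ones another.
    """
    w = rng.uniform(0.1, 0.4, (n_channels, n_src)) * rng.choice([-1, 1], (n_channels, n_src))
    for m in range(n_channels):
        w[m, m % n_src] = rng.uniform(0.7, 1.0) * rng.choice([-1, 1])
    return w


def _rotation_xy(rot_x_deg: float, rot_y_deg: float) -> np.ndarray:
    ax, ay = np.deg2rad(rot_x_deg), np.deg2rad(rot_y_deg)
    Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    return Ry @ Rx


def generate_shape_trajectory(
    spec: ShapeSpec, n_cycles: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Task-space trajectory of a drawn shape.

    Returns ``(time, xyz)`` with ``xyz`` of shape ``(n_samples, 3)``.  Small
    per-cycle amplitude and phase jitter emulates the natural variability of
    repeated tracing.
    """
    rng = np.random.default_rng(seed)
    n_per = int(round(spec.cycle_period * spec.sample_rate))
    t = np.arange(n_cycles * n_per) / spec.sample_rate
    phase = 2 * np.pi * t / spec.cycle_period
    cyc = (np.arange(len(t)) // n_per).astype(int)
    amp_j = 1.0 + 0.03 * rng.standard_normal(n_cycles)
    ph_j = 0.05 * rng.standard_normal(n_cycles)
    a = spec.amplitude * amp_j[cyc]
    ph = phase + ph_j[cyc]
    z = np.zeros_like(t)
    if spec.shape == "PE":
        x, y = a * np.cos(ph), 0.6 * a * np.sin(ph)
    elif spec.shape == "FE":
        # 1:2 Lissajous: x at twice the fundamental of y.
        x, y = 0.5 * a * np.sin(2 * ph), a * np.sin(ph)
    elif spec.shape == "BE":
        x, y = a * np.cos(ph), 0.6 * a * np.sin(ph)
        z = 0.3 * a * np.cos(ph)**2  # one vertical lobe per cycle
    elif spec.shape == "DBE":
        x, y = a * np.cos(ph), 0.6 * a * np.sin(ph)
        z = 0.3 * a * np.cos(2 * ph)  # two lobes
    elif spec.shape == "UD":
        x, y = np.zeros_like(t), np.zeros_like(t)
        z = a * np.sin(ph)
    R = _rotation_xy(*spec.plane_rotation)
    xyz = np.stack([x, y, z], axis=1) @ R.T + np.asarray(spec.centre)
    return t, xyz


def mix_channels(
    sources: np.ndarray,
    weights: np.ndarray,
    delays: np.ndarray,
    offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Anechoic mixture: ``x_m(t) = sum_p c_mp * s_p((t - tau_mp) mod P) + offset_m``.

    Delays may be fractional; shifts are applied via Fourier phase ramps so
    the result is exact for band-limited sources.
    """
    n_src, P = sources.shape
    weights = np.asarray(weights, dtype=float)
    delays = np.asarray(delays, dtype=float)
    if weights.shape != delays.shape or weights.shape[1] != n_src:
        raise ValueError("weights/delays must both be (n_channels, n_src)")
    Sf = np.fft.rfft(sources, axis=1)           # (n_src, P//2+1)
    k = np.arange(Sf.shape[1])
    # (M, n_src, K) phase ramps
    ramp = np.exp(-2j * np.pi * delays[:, :, None] * k[None, None, :] / P)
    Xf = np.einsum("mp,mpk,pk->mk", weights, ramp, Sf)
    x = np.fft.irfft(Xf, n=P, axis=1)
    if offsets is not None:
        x = x + np.asarray(offsets, dtype=float)[:, None]
    return x


def default_ground_truth(
    n_src: int = 3,
    P: int = 200,
    n_cycles: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    family: Literal["fourier-sparse", "sinusoid"] = "fourier-sparse",
    delay_jitter_sd: float = 0.0,
) -> GroundTruth:
    """A realistic GroundTruth with random weights/delays in plausible ranges.

    Mixing weights follow :func:`dominant_mixture_weights`; base delays are
    uniform over the whole cycle.
    """
    rng = np.random.default_rng(seed)
    S = generate_sources(n_src, P, family=family, seed=seed)

    task_w = dominant_mixture_weights(3, n_src, rng)
    joint_w = 0.6 * dominant_mixture_weights(4, n_src, rng)
    task_d = rng.uniform(0, P, (3, n_src))
    joint_d = rng.uniform(0, P, (4, n_src))
    offsets = np.array([np.pi / 3, 0.3, np.pi / 2.5, 0.5])  # (theta, eta, beta, alpha)
    return GroundTruth(
        sources=S,
        task_weights=task_w,
        task_delays=task_d,
        joint_weights=joint_w,
        joint_delays=joint_d,
        joint_offsets=offsets,
        noise_sd=noise_sd,
        n_cycles=n_cycles,
        seed=seed,
        delay_jitter_sd=delay_jitter_sd,
    )


def synthesize_trial(
    gt: GroundTruth,
    lengths: SegmentLengths = SegmentLengths(0.3, 0.25),
    exact_shared: bool = False,
    joint_scale: float = 3.0,
    markers: bool = False,
) -> dict:
    """Synthesize one trial from ground truth.

    The absolute-angle joint channels are built exactly from the anechoic
    mixture model (per-cycle weights/delays with the configured jitter plus
    noise); anatomical angles follow by conversion and the task trajectory
    by forward kinematics of the joints, guaranteeing kinematic
    consistency.  With ``exact_shared=True`` the task channels are instead
    mixed directly from the same sources with ``gt.task_weights/delays``
    (exact model on both sides).

    Returns a dict with keys ``task``, ``joints_abs``, ``joints_anat``
    (each ``(n_cycles, n_channels, P)`` stacks), per-cycle generative
    ``cycle_weights``/``cycle_delays`` for the joint channels, and
    optionally ``markers``.
    """
    rng = np.random.default_rng(gt.seed)
    n_src, P, L = gt.n_src, gt.P, gt.n_cycles
    jw = np.empty((L, 4, n_src))
    jd = np.empty((L, 4, n_src))
    tw = np.empty((L, 3, n_src))
    td = np.empty((L, 3, n_src))
    joints_abs = np.empty((L, 4, P))
    task = np.empty((L, 3, P))
    for l in range(L):
        jw[l] = gt.joint_weights * (1 + gt.weight_jitter_sd * rng.standard_normal((4, n_src)))
        jd[l] = np.mod(gt.joint_delays + gt.delay_jitter_sd * rng.standard_normal((4, n_src)), P)
        tw[l] = gt.task_weights * (1 + gt.weight_jitter_sd * rng.standard_normal((3, n_src)))
        td[l] = np.mod(gt.task_delays + gt.delay_jitter_sd * rng.standard_normal((3, n_src)), P)
        joints_abs[l] = mix_channels(
            gt.sources, joint_scale * jw[l], jd[l], gt.joint_offsets
        )
        if exact_shared:
            task[l] = mix_channels(gt.sources, tw[l], td[l])
    joints_abs += gt.noise_sd * rng.standard_normal(joints_abs.shape)
    joints_anat = np.empty_like(joints_abs)
    marker_frames: list[MarkerFrame] = []
    for l in range(L):
        for i in range(P):
            th, eta, be, al = joints_abs[l, :, i]
            b = AbsoluteAngles(
                theta=float(np.clip(th, 1e-3, np.pi - 1e-3)),
                eta=float(eta),
                beta=float(np.clip(be, 1e-3, np.pi - 1e-3)),
                alpha=float(al),
            )
            a = absolute_to_anatomical(b)
            joints_anat[l, :, i] = a.as_array()
            if not exact_shared:
                elbow, wrist = forward_kinematics(b, lengths)
                task[l, :, i] = wrist
                if markers:
                    marker_frames.append(
                        MarkerFrame(
                            positions={
                                "shoulder": np.zeros(3),
                                "elbow": elbow,
                                "wrist": wrist,
                            },
                            time=(l * P + i) / P,
                        )
                    )
    if exact_shared:
        task += gt.noise_sd * rng.standard_normal(task.shape)
    out = {
        "task": task,
        "joints_abs": joints_abs,
        "joints_anat": joints_anat,
        "cycle_weights": jw,
        "cycle_delays": jd,
        "task_cycle_weights": tw,
        "task_cycle_delays": td,
    }
    if markers:
        out["markers"] = marker_frames
    return out
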