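"""Phase-shift (time-delay) structure of the demixed sources.

Each fitted cycle carries one delay per (degree of freedom, source).  Two
kinds of pairwise differences are informative: delays of two *sources*
within the same DOF (coordination at the level of the movement
generators) and delays of the same *source* across two DOF, possibly from
different spaces, e.g. upper-arm yaw against the lateral hand coordinate
(joint-task coordination).  Differences are circular in ``[0, P)`` and are
summarized per cycle as circular mean +/- circular s.d., also expressed
as a percentage of the cycle; pairs whose across-cycle s.d. stays below a
threshold are flagged as phase locked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fada import SourceSet

__all__ = [
    "PhaseShiftTable",
    "across_dof_shifts",
    "circular_mean_sd",
    "lock_detector",
    "summarize_shifts",
    "within_dof_shifts",
]


def _circ_diff(a: np.ndarray, b: np.ndarray, P: int) -> np.ndarray:
    """Circular difference mapped to [0, P)."""
    return np.mod(np.asarray(a) - np.asarray(b), P)


def circular_mean_sd(values: np.ndarray, P: int) -> tuple[float, float]:
    """Circular mean and circular standard deviation on a period-P circle.

    The mean is the argument of the resultant vector mapped back to
    samples in ``[0, P)``; the s.d. is ``sqrt(-2 ln R)`` (R the resultant
    length) scaled to samples, which reduces to the ordinary s.d. for
    tightly concentrated samples.
    """
    ang = 2 * np.pi * np.asarray(values, dtype=float) / P
    z = np.exp(1j * ang).mean()
    mean = np.mod(np.angle(z) * P / (2 * np.pi), P)
    R = np.abs(z)
    sd = np.sqrt(max(-2.0 * np.log(max(R, 1e-300)), 0.0)) * P / (2 * np.pi)
    return float(mean), float(sd)


@dataclass
class PhaseShiftTable:
    """Per-cycle pairwise delay differences and their circular summaries."""

    labels: list[str] = field(default_factory=list)
    per_cycle: list[np.ndarray] = field(default_factory=list)
    P: int = 200

    def add(self, label: str, shifts: np.ndarray) -> None:
        self.labels.append(label)
        self.per_cycle.append(np.asarray(shifts, dtype=float))

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for label, shifts in zip(self.labels, self.per_cycle):
            mean, sd = summarize_shifts(shifts, self.P)
            out[label] = {
                "mean_samples": mean,
                "sd_samples": sd,
                "mean_pct": mean / self.P * 100.0,
                "sd_pct": sd / self.P * 100.0,
                "n_cycles": int(len(shifts)),
            }
        return out


def _channel_index(ss: SourceSet, dof: int | str) -> int:
    if isinstance(dof, str):
        if not ss.channel_names:
            raise ValueError("SourceSet has no channel names; use integer indices")
        return ss.channel_names.index(dof)
    return int(dof)


def within_dof_shifts(ss: SourceSet, dof: int | str, sources: tuple[int, int]) -> np.ndarray:
    """Per-cycle ``tau_{i,j} - tau_{i,k}`` for one DOF ``i`` and sources ``(j, k)``.

    Returns circular differences in ``[0, P)``, one per cycle.
    """
    i = _channel_index(ss, dof)
    j, k = sources
    d = _circ_diff(ss.delays[:, i, j], ss.delays[:, i, k], ss.P)
    if ss.delays.shape[0] == 1:
        warnings.warn("only one delay set available (per-trial delays): single value", RuntimeWarning)
    return d


def across_dof_shifts(
    ss_a: SourceSet,
    ss_b: SourceSet | None,
    source: int,
    dofs: tuple[int | str, int | str],
) -> np.ndarray:
    """Per-cycle ``tau_{i,j} - tau_{k,j}`` for one source across two DOF.

    With ``ss_b`` given, the first DOF indexes ``ss_a`` and the second
    ``ss_b`` (a cross-space pair, e.g. a joint angle against a hand
    coordinate); the two SourceSets must share the source basis — align
    one to the other with :func:`armik.fada.align_sources` first.
    """
    if ss_b is None:
        ss_b = ss_a
    if ss_a.P != ss_b.P or ss_a.n_src != ss_b.n_src:
        raise ValueError("source sets must share P and n_src")
    if ss_a.delays.shape[0] != ss_b.delays.shape[0]:
        raise ValueError("source sets must have the same number of cycles")
    if ss_a is not ss_b:
        # a shared basis implies near-identical source waveforms
        corr = [
            float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
            for a, b in zip(ss_a.sources, ss_b.sources)
        ]
        if min(corr) < 0.4:
            raise ValueError(
                "source sets do not share a common basis (min waveform correlation "
                f"{min(corr):.2f}); align them with fada.align_sources first"
            )
    i = _channel_index(ss_a, dofs[0])
    k = _channel_index(ss_b, dofs[1])
    return _circ_diff(ss_a.delays[:, i, source], ss_b.delays[:, k, source], ss_a.P)


def summarize_shifts(shifts: np.ndarray, P: int = 200) -> tuple[float, float]:
    """Circular mean and s.d. of per-cycle shifts (samples in [0, P))."""
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size < 2:
        raise ValueError("need at least 2 cycles to summarize shifts")
    return circular_mean_sd(shifts, P)


def lock_detector(table: PhaseShiftTable, threshold_pct: float = 5.0) -> dict[str, dict]:
    """Flag pairs whose across-cycle circular s.d. is at most ``threshold_pct`` of a cycle."""
    locked = {}
    for label, stats in table.summary().items():
        if stats["sd_pct"] <= threshold_pct:
            locked[label] = stats
    return locked
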