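"""End-to-end orchestration of the analysis stages.

A run covers, per configured shape: synthetic-trial generation,
preprocessing (cycle segmentation + length normalization of the flat
trial), anechoic demixing of the task and both joint representations,
source comparison across representations, shared-basis inverse
kinematics, and phase-shift analysis.  Every stage writes its outputs
under the run directory and the manifest records seeds, versions and
stage completion so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .arm_model import SegmentLengths
from .evaluation import accuracy, correlation_difference_table, match_sources, sign_test
from .fada import SourceSet, align_sources, fit_fada
from .ik_transform import SharedBasisIK
from .phase_analysis import PhaseShiftTable, across_dof_shifts, lock_detector, within_dof_shifts
from .preprocessing import Trajectory, normalize_cycle_length, segment_cycles
from .synthetic_data import SHAPES, default_ground_truth, synthesize_trial

__all__ = ["RunConfig", "STAGES", "run_pipeline"]

STAGES = ("simulate", "preprocess", "decompose", "compare", "ik", "phase")

ABS_CHANNELS = ["theta", "eta", "beta", "alpha"]
ANAT_CHANNELS = ["theta", "eta", "zeta", "phi"]
TASK_CHANNELS = ["x", "y", "z"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    out_dir: str = "armik_run"
    shapes: list[str] = field(default_factory=lambda: ["PE", "BE"])
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    n_src: int = 3
    P: int = 200
    K: int = 10
    n_cycles: int = 10
    noise_sd: float = 0.01
    seed: int = 0
    lock_threshold_pct: float = 5.0
    exact_shared: bool = False
    delay_jitter_sd: float = 2.0

    def validate(self) -> None:
        unknown = set(self.shapes) - set(SHAPES)
        if unknown:
            raise ValueError(f"unknown shapes {sorted(unknown)}; choose from {SHAPES}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; choose from {STAGES}")
        if self.n_src > 3:
            raise ValueError(
                f"n_src={self.n_src} exceeds the 3 task channels; the shared-basis "
                "inversion needs a square task mixing"
            )
        if self.K > self.P // 2:
            raise ValueError("K must be at most P/2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _json_dump(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _shape_seed(base: int, shape: str) -> int:
    return int(np.random.SeedSequence([base, SHAPES.index(shape)]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    # expand prerequisite stages so any stage can be requested on its own
    deps = {
        "simulate": [],
        "preprocess": ["simulate"],
        "decompose": ["preprocess"],
        "compare": ["decompose"],
        "ik": ["preprocess"],
        "phase": ["decompose"],
    }
    wanted: set[str] = set()
    frontier = list(config.stages)
    while frontier:
        s = frontier.pop()
        if s not in wanted:
            wanted.add(s)
            frontier.extend(deps[s])

    state: dict = {}
    for stage in STAGES:
        if stage not in wanted:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as e:
            manifest["stages"][stage] = {"status": "failed", "error": str(e)}
            _json_dump(manifest, out / "manifest.json")
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest["stages"][stage] = {
            "status": "complete",
            "seconds": round(time.perf_counter() - t0, 3),
        }
    _json_dump(manifest, out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> None:
    lengths = SegmentLengths(0.3, 0.25)
    for shape in config.shapes:
        seed = _shape_seed(config.seed, shape)
        gt = default_ground_truth(
            n_src=config.n_src,
            P=config.P,
            n_cycles=config.n_cycles,
            noise_sd=config.noise_sd,
            seed=seed,
            delay_jitter_sd=config.delay_jitter_sd,
        )
        trial = synthesize_trial(gt, lengths, exact_shared=config.exact_shared)
        state.setdefault("trials", {})[shape] = trial
        state.setdefault("gt", {})[shape] = gt
        d = out / "trials"
        d.mkdir(exist_ok=True)
        for key, channels in (
            ("task", TASK_CHANNELS),
            ("joints_abs", ABS_CHANNELS),
            ("joints_anat", ANAT_CHANNELS),
        ):
            cyc = trial[key]  # (L, M, P)
            flat = cyc.transpose(0, 2, 1).reshape(-1, cyc.shape[1])
            traj = Trajectory(
                time=np.arange(flat.shape[0]) / config.P,
                data=flat,
                channels=channels,
                cycle_bounds=[
                    (l * config.P, (l + 1) * config.P) for l in range(cyc.shape[0])
                ],
                P=config.P,
            )
            traj.to_tsv(d / f"{shape}_{key}.tsv")
        _json_dump(
            {
                "seed": seed,
                "sources": gt.sources,
                "task_weights": gt.task_weights,
                "task_delays": gt.task_delays,
                "joint_weights": gt.joint_weights,
                "joint_delays": gt.joint_delays,
                "noise_sd": gt.noise_sd,
            },
            d / f"{shape}_ground_truth.json",
        )


def _stage_preprocess(config: RunConfig, out: Path, state: dict) -> None:
    state.setdefault("cycles", {})
    for shape in config.shapes:
        cycles = {}
        for key in ("task", "joints_abs", "joints_anat"):
            traj = Trajectory.from_tsv(out / "trials" / f"{shape}_{key}.tsv")
            if not traj.cycle_bounds:
                traj = segment_cycles(traj)
            cycles[key] = normalize_cycle_length(traj, P=config.P)
        state["cycles"][shape] = cycles


def _stage_decompose(config: RunConfig, out: Path, state: dict) -> None:
    state.setdefault("sourcesets", {})
    d = out / "sources"
    d.mkdir(exist_ok=True)
    names = {"task": TASK_CHANNELS, "joints_abs": ABS_CHANNELS, "joints_anat": ANAT_CHANNELS}
    for shape in config.shapes:
        sets = {}
        for key, cyc in state["cycles"][shape].items():
            ss = fit_fada(
                cyc,
                n_src=config.n_src,
                K=config.K,
                seed=_shape_seed(config.seed, shape),
            )
            ss.channel_names = names[key]
            sets[key] = ss
            _json_dump(ss.to_dict(), d / f"{shape}_{key}_sources.json")
        state["sourcesets"][shape] = sets


def _stage_compare(config: RunConfig, out: Path, state: dict) -> None:
    fitted = {
        shape: (
            sets["joints_anat"].sources,
            sets["joints_abs"].sources,
            sets["task"].sources,
        )
        for shape, sets in state["sourcesets"].items()
    }
    table = correlation_difference_table(fitted)
    deltas = table[[c for c in table.columns if c != "mean"]].to_numpy().ravel()
    report: dict = {"correlation_difference": json.loads(table.to_json(orient="index"))}
    try:
        report["sign_test"] = sign_test(deltas)
    except ValueError as e:
        report["sign_test"] = {"error": str(e)}
    _json_dump(report, out / "compare.json")
    (out / "compare.txt").write_text(table.to_string(float_format=lambda v: f"{v: .3f}") + "\n")
    state["compare"] = report


def _stage_ik(config: RunConfig, out: Path, state: dict) -> None:
    results = {}
    for shape in config.shapes:
        cyc = state["cycles"][shape]
        ik = SharedBasisIK(
            n_harmonics=config.K, random_state=_shape_seed(config.seed, shape)
        ).fit(cyc["task"], cyc["joints_abs"])
        q_hat = ik.predict(cyc["task"])
        q_ref = cyc["joints_abs"]
        results[shape] = {
            "joint_accuracy": accuracy(
                q_hat.reshape(-1, q_hat.shape[-1]), q_ref.reshape(-1, q_ref.shape[-1])
            ),
            "joint_rmse_rad": float(np.sqrt(np.mean((q_hat - q_ref) ** 2))),
        }
        state.setdefault("ik", {})[shape] = ik
    _json_dump(results, out / "ik.json")


def _stage_phase(config: RunConfig, out: Path, state: dict) -> None:
    report = {}
    for shape in config.shapes:
        sets = state["sourcesets"][shape]
        task_ss = sets["task"]
        joint_ss = align_sources(sets["joints_abs"], task_ss)
        table = PhaseShiftTable(P=config.P)
        # source pairs within each joint DOF
        for i, name in enumerate(joint_ss.channel_names or []):
            for j in range(config.n_src):
                for k in range(j + 1, config.n_src):
                    table.add(
                        f"{name}: s{j + 1}-s{k + 1}",
                        within_dof_shifts(joint_ss, i, (j, k)),
                    )
        # cross-space DOF pairs per source (joint angle vs task coordinate)
        for j in range(config.n_src):
            for jname, tname in (("eta", "x"), ("alpha", "x"), ("theta", "z"), ("beta", "z")):
                table.add(
                    f"s{j + 1}: {jname}-{tname}",
                    across_dof_shifts(joint_ss, task_ss, j, (jname, tname)),
                )
        locked = lock_detector(table, config.lock_threshold_pct)
        report[shape] = {"summary": table.summary(), "locked": sorted(locked)}
    _json_dump(report, out / "phase.json")
    state["phase"] = report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "decompose": _stage_decompose,
    "compare": _stage_compare,
    "ik": _stage_ik,
    "phase": _stage_phase,
}
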