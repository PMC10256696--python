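"""Readers, writers, run configuration and bundled fixture generation.

Behaviour-log CSV dialect (one row per elementary path):

    session,ordinal,origin,path_label,edge_sequence,edge_durations

with ``edge_sequence`` and ``edge_durations`` semicolon-separated and
durations printed at 6 decimal places, which makes the writer
bit-stable.  The reader validates chainability and classifiability and
reports errors with row numbers.

Neural CSV dialect: ``neuron,region,condition_pair,N1,N2,d1,d2``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .credit import Params
from .maze import (
    BehaviorLog,
    MazeError,
    PathRecord,
    classify_path,
    path_by_label,
)
from .neural import records_to_frame, frame_to_records, simulate_spike_records
from .simulate import (
    DEFAULT_PARAMS,
    SimulationDesign,
    reaches_learning_criterion,
    simulate_log_with_lc,
)
from .strategies import MODEL_NAMES

__all__ = [
    "write_behavior_log",
    "read_behavior_log",
    "write_neural_records",
    "read_neural_records",
    "RunConfig",
    "named_seed_streams",
    "make_fixtures",
]


def named_seed_streams(seed: int) -> dict:
    """Split one top-level seed into named independent sub-streams.

    All randomness in a run flows from these, so partial reruns (only the
    optimizer, only the neural simulation, ...) stay reproducible.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulation", "optimizer", "neural")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


# -- behaviour-log CSV -------------------------------------------------------


def write_behavior_log(log: BehaviorLog, path) -> None:
    rows = []
    for session in log.sessions:
        for rec in session:
            rows.append(
                {
                    "session": rec.session_index,
                    "ordinal": rec.ordinal_in_experiment,
                    "origin": rec.path.origin,
                    "path_label": rec.path.label,
                    "edge_sequence": ";".join(rec.path.edge_sequence),
                    "edge_durations": ";".join(
                        f"{d:.6f}" for d in rec.edge_durations
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_behavior_log(path) -> BehaviorLog:
    frame = pd.read_csv(path)
    required = {
        "session",
        "ordinal",
        "origin",
        "path_label",
        "edge_sequence",
        "edge_durations",
    }
    missing = required - set(frame.columns)
    if missing:
        raise MazeError(f"behaviour CSV is missing columns: {sorted(missing)}")
    sessions: dict = {}
    for i, row in enumerate(frame.itertuples(), start=2):  # 1-based + header
        try:
            edges = tuple(str(row.edge_sequence).split(";"))
            durations = tuple(float(x) for x in str(row.edge_durations).split(";"))
            elementary = classify_path(edges, str(row.origin))
            if elementary.label != str(row.path_label):
                raise MazeError(
                    f"edge sequence classifies as {elementary.label!r}, "
                    f"row says {row.path_label!r}"
                )
            record = PathRecord(
                int(row.session), int(row.ordinal), elementary, durations
            )
        except (MazeError, ValueError) as exc:
            raise MazeError(f"{path}, row {i}: {exc}") from exc
        sessions.setdefault(int(row.session), []).append(record)
    ordered = [sessions[k] for k in sorted(sessions)]
    try:
        return BehaviorLog(ordered)  # validates chainability per session
    except MazeError as exc:
        raise MazeError(f"{path}: {exc}") from exc


# -- neural CSV --------------------------------------------------------------


def write_neural_records(records, path) -> None:
    frame = records_to_frame(records).copy()
    frame["d1"] = frame["d1"].map(lambda v: f"{v:.6f}")
    frame["d2"] = frame["d2"].map(lambda v: f"{v:.6f}")
    frame.to_csv(path, index=False)


def read_neural_records(path) -> list:
    return frame_to_records(pd.read_csv(path))


# -- run configuration -------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Every run writes its resolved config next to its outputs, so a result
    directory is self-describing.
    """

    models: tuple = MODEL_NAMES
    cut: int = 800
    restarts: int = 20
    maxiter: int = 80
    tol: float = 1e-8
    seed: int = 0
    generating_model: str = "Hybrid3"
    alpha: float = DEFAULT_PARAMS.alpha
    gamma: float = DEFAULT_PARAMS.gamma
    n_sessions: int = 20
    paths_per_session: int = 75
    lc_threshold: float = 0.80
    replicates: int = 20
    output_dir: str = "."

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown model names: {sorted(unknown)}")
        if self.cut < 1:
            raise ValueError("cut must be positive")
        Params(self.alpha, self.gamma)  # bounds check
        if self.replicates < 1 or self.n_sessions < 1 or self.paths_per_session < 1:
            raise ValueError("counts must be positive")

    def design(self, seed: int | None = None) -> SimulationDesign:
        return SimulationDesign(
            model_name=self.generating_model,
            params=Params(self.alpha, self.gamma),
            n_sessions=self.n_sessions,
            paths_per_session=self.paths_per_session,
            seed=self.seed if seed is None else seed,
            lc_threshold=self.lc_threshold,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in payload:
            payload["models"] = tuple(payload["models"])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


# -- fixtures ----------------------------------------------------------------


def _worked_example_log(rng: np.random.Generator) -> BehaviorLog:
    """Three-episode toy session showing the three episode/reward types:
    good+loop+good (reward 2), good+wrong (reward 1), wrong+wrong (0)."""
    labels = [
        "SL:good",       # SL -> SR
        "SR:loop_low",   # SR -> SR
        "SR:good",       # SR -> SL   ... episode 1, reward 2
        "SL:good",       # SL -> SR
        "SR:cross_low",  # SR -> SL   ... episode 2, reward 1
        "SL:cross_top",  # SL -> SR
        "SR:reverse",    # SR -> SL   ... episode 3, reward 0
    ]
    records = []
    for i, label in enumerate(labels, start=1):
        p = path_by_label(label)
        durations = tuple(rng.lognormal(0.0, 0.2) for _ in p.edge_sequence)
        records.append(PathRecord(1, i, p, durations))
    return BehaviorLog([records])


def make_fixtures(seed: int, out_dir) -> dict:
    """Write the bundled small datasets; returns {name: path}.

    * ``worked_example.csv`` — the three canonical episode types with
      rewards (2, 1, 0);
    * ``hybrid3_learning.csv`` — a full synthetic Hybrid-3 learning log
      (20 sessions x 75 paths) that reaches the 80% learning criterion
      (asserted at generation);
    * ``neural_synthetic.csv`` — synthetic spike-count records for three
      regions with a known coding subpopulation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = named_seed_streams(seed)
    paths = {}

    worked = _worked_example_log(np.random.default_rng(streams["simulation"]))
    rewards = tuple(ep.reward for ep in worked.episodes_per_session[0])
    if rewards != (2, 1, 0):
        raise RuntimeError(f"worked example rewards {rewards} != (2, 1, 0)")
    paths["worked_example"] = out / "worked_example.csv"
    write_behavior_log(worked, paths["worked_example"])

    design = SimulationDesign(
        "Hybrid3", DEFAULT_PARAMS, 20, 75, seed=streams["simulation"]
    )
    learning, _ = simulate_log_with_lc(design)
    if not reaches_learning_criterion(learning, design.lc_threshold):
        raise RuntimeError("learning fixture failed the learning criterion")
    paths["hybrid3_learning"] = out / "hybrid3_learning.csv"
    write_behavior_log(learning, paths["hybrid3_learning"])

    records = []
    for i, region in enumerate(("lateral_descent", "central_stem", "first_straight")):
        records.extend(
            simulate_spike_records(
                n_neurons=60,
                coding_fraction=(0.05, 0.35, 0.15)[i],
                region_id=region,
                seed=streams["neural"] + i,
            )
        )
    paths["neural_synthetic"] = out / "neural_synthetic.csv"
    write_neural_records(records, paths["neural_synthetic"])

    sidecar = {
        "seed": seed,
        "streams": streams,
        "design": {
            "model_name": design.model_name,
            "alpha": design.params.alpha,
            "gamma": design.params.gamma,
            "n_sessions": design.n_sessions,
            "paths_per_session": design.paths_per_session,
            "lc_threshold": design.lc_threshold,
        },
    }
    with open(out / "fixtures.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    paths["sidecar"] = out / "fixtures.json"
    return paths
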