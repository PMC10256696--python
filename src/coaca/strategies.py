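"""The six chunking strategies as explicit state/action decision diagrams.

Each strategy is a different carving of the twelve elementary paths into
*actions* — contiguous edge chunks cut (or not) at the maze junctions —
together with the *states* at which those actions are chosen:

========  =============================================================
Paths     no cut: a whole elementary path is one action, chosen at the
          supplier (2 states x 6 actions).
Hybrid 1  cut at the *second* junction encountered within the path;
          paths passing a single junction stay whole.
Hybrid 2  cut at the *first* junction encountered.
Hybrid 3  cut at physical junction A whenever the path passes it.
Hybrid 4  cut at physical junction B whenever the path passes it.
Turns     cut at every junction passed: each action is a single decision
          leg (10 states x 2 actions).
========  =============================================================

A state is the animal's position plus the supplier it last visited —
without the latter, a loop and a rewarded alternation are
indistinguishable once the animal is on the central stem — plus the edge
it arrived by, which encodes the no-turn-back constraint and makes the
available-action sets at the junctions well defined.  Credits are never
pooled between left/right mirror states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .maze import (
    CANONICAL_MAZE,
    SUPPLIERS,
    BehaviorLog,
    ElementaryPath,
    MazeError,
    MazeGraph,
    PathRecord,
    enumerate_elementary_paths,
)

__all__ = [
    "MODEL_NAMES",
    "ModelState",
    "ModelAction",
    "StrategyModel",
    "EncodedStep",
    "build_model",
    "available_actions",
    "encode_trajectory",
    "decompose_path",
]

MODEL_NAMES = ("Paths", "Hybrid1", "Hybrid2", "Hybrid3", "Hybrid4", "Turns")


@dataclass(frozen=True)
class ModelState:
    """Position + arrival edge (``None`` at a supplier) + last supplier."""

    position: str
    incoming_edge: str | None
    last_supplier: str

    def __post_init__(self) -> None:
        if self.position in SUPPLIERS:
            if self.incoming_edge is not None or self.last_supplier != self.position:
                raise MazeError("at a supplier the state is (supplier, None, supplier)")

    @property
    def identifier(self) -> str:
        return f"{self.position}|{self.incoming_edge or '-'}|{self.last_supplier}"


@dataclass(frozen=True)
class ModelAction:
    """A contiguous edge chunk of an elementary path, ending in a state."""

    edge_chunk: tuple
    terminal_state: ModelState

    @property
    def identifier(self) -> str:
        return ";".join(self.edge_chunk)


class StrategyModel:
    """One chunking strategy: finite states, per-state ordered action lists,
    and the unique decomposition of every elementary path into actions."""

    def __init__(self, name: str, maze: MazeGraph = CANONICAL_MAZE):
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
        self.name = name
        self.maze = maze
        # label -> list of (start_state, action, (chunk_start, chunk_end))
        self._decompositions: dict = {}
        actions_by_state: dict = {}
        for path in enumerate_elementary_paths(maze):
            steps = []
            for state, chunk, span in self._chunk_path(path):
                action = ModelAction(
                    edge_chunk=chunk,
                    terminal_state=self._state_after(path, span[1]),
                )
                actions_by_state.setdefault(state, set()).add(action)
                steps.append((state, action, span))
            self._decompositions[path.label] = steps
        # canonical lexicographic action order fixes the softmax support
        self.actions_by_state = {
            s: tuple(sorted(acts, key=lambda a: a.edge_chunk))
            for s, acts in actions_by_state.items()
        }
        self.states = tuple(
            sorted(self.actions_by_state, key=lambda s: s.identifier)
        )
        self.state_index = {s: i for i, s in enumerate(self.states)}
        self.slot_index = {
            (s, a): j
            for s in self.states
            for j, a in enumerate(self.actions_by_state[s])
        }
        self.n_actions = tuple(len(self.actions_by_state[s]) for s in self.states)

    # -- construction ----------------------------------------------------

    def _cut_points(self, path: ElementaryPath) -> list:
        """Indices (between edges) at which this strategy cuts ``path``."""
        edges = path.edge_sequence
        # intermediate node reached after edge i+1 (always a junction)
        inner = []
        node = path.origin
        for i, e in enumerate(edges[:-1]):
            node = self.maze.other_end(e, node)
            inner.append((i + 1, node))
        if self.name == "Paths":
            return []
        if self.name == "Turns":
            return [i for i, _ in inner]
        if self.name == "Hybrid1":
            return [inner[1][0]] if len(inner) >= 2 else []
        if self.name == "Hybrid2":
            return [inner[0][0]]
        junction = "A" if self.name == "Hybrid3" else "B"
        return [i for i, n in inner if n == junction]

    def _state_after(self, path: ElementaryPath, edge_count: int) -> ModelState:
        """State occupied after traversing the first ``edge_count`` edges."""
        node = path.origin
        for e in path.edge_sequence[:edge_count]:
            node = self.maze.other_end(e, node)
        if node in SUPPLIERS:
            return ModelState(node, None, node)
        return ModelState(node, path.edge_sequence[edge_count - 1], path.origin)

    def _chunk_path(self, path: ElementaryPath):
        cuts = self._cut_points(path)
        bounds = [0] + cuts + [len(path.edge_sequence)]
        for lo, hi in zip(bounds, bounds[1:]):
            yield (
                self._state_after(path, lo),
                tuple(path.edge_sequence[lo:hi]),
                (lo, hi),
            )

    # -- queries ---------------------------------------------------------

    def decomposition(self, label: str) -> list:
        """``[(state, action, (chunk_start, chunk_end)), ...]`` for a path label."""
        try:
            return self._decompositions[label]
        except KeyError:
            raise MazeError(f"path label {label!r} unknown to model {self.name}") from None

    def available_actions(self, state: ModelState) -> tuple:
        try:
            return self.actions_by_state[state]
        except KeyError:
            raise MazeError(
                f"state {state.identifier!r} is not reachable in model {self.name}"
            ) from None

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_state_action_pairs(self) -> int:
        return sum(self.n_actions)

    # -- export ----------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "states": [
                {
                    "state": s.identifier,
                    "actions": [
                        {
                            "action": a.identifier,
                            "edge_chunk": list(a.edge_chunk),
                            "terminal_state": a.terminal_state.identifier,
                        }
                        for a in self.actions_by_state[s]
                    ],
                }
                for s in self.states
            ],
        }
        return json.dumps(payload, indent=2)

    def to_graphviz(self) -> str:
        lines = [f'digraph "{self.name}" {{']
        for s in self.states:
            for a in self.actions_by_state[s]:
                lines.append(
                    f'  "{s.identifier}" -> "{a.terminal_state.identifier}" '
                    f'[label="{a.identifier}"];'
                )
        lines.append("}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"StrategyModel({self.name!r}, {self.n_states} states)"


def build_model(name: str, maze: MazeGraph = CANONICAL_MAZE) -> StrategyModel:
    """Build the decision diagram of one of the six strategies."""
    return StrategyModel(name, maze)


def available_actions(model: StrategyModel, state: ModelState) -> tuple:
    return model.available_actions(state)


def decompose_path(model: StrategyModel, record: PathRecord) -> list:
    """Decompose one traversed path into ``(state, action, chunk_duration)``."""
    out = []
    for state, action, (lo, hi) in model.decomposition(record.path.label):
        out.append((state, action, float(sum(record.edge_durations[lo:hi]))))
    return out


@dataclass(frozen=True)
class EncodedStep:
    """One model-level decision with its activity numerator (seconds)."""

    state: ModelState
    action: ModelAction
    duration: float
    session_index: int
    path_ordinal: int
    episode_index: int | None  # None for trailing-fragment actions


def encode_trajectory(model: StrategyModel, log: BehaviorLog) -> list:
    """Map a behaviour log to the model's (state, action) decision sequence.

    Every elementary path maps to its unique action decomposition; the
    activity numerator of an action is the summed duration of its edge
    chunk.  Actions belonging to a session's trailing fragment carry
    ``episode_index=None``.
    """
    steps: list = []
    for session, episodes, fragment in zip(
        log.sessions, log.episodes_per_session, log.trailing_fragment_per_session
    ):
        for ep in episodes:
            for rec in ep.paths:
                for state, action, dur in decompose_path(model, rec):
                    steps.append(
                        EncodedStep(
                            state,
                            action,
                            dur,
                            rec.session_index,
                            rec.ordinal_in_experiment,
                            ep.episode_index_in_session,
                        )
                    )
        for rec in fragment:
            for state, action, dur in decompose_path(model, rec):
                steps.append(
                    EncodedStep(
                        state,
                        action,
                        dur,
                        rec.session_index,
                        rec.ordinal_in_experiment,
                        None,
                    )
                )
    return steps
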