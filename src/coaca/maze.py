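"""Continuous T-maze topology, elementary paths and episode segmentation.

The apparatus is a T-maze whose two choice arms are connected back to the
base of the central stem by return tracks, so the animal can run it
continuously without being handled.  Topologically it is a 4-node,
5-edge graph:

* ``SL``/``SR`` — the left and right reward suppliers (degree 2),
* ``A`` — the base junction where the two return tracks meet the stem,
* ``B`` — the top T-junction where the stem meets the two choice arms.

Behaviour is discretised into *elementary paths*: supplier-to-supplier
walks that never reverse along the edge just traversed (turn-backs are
excluded) and never pass through a supplier mid-walk.  Exactly twelve
such walks exist, six from each supplier; the two rewarded ("good")
paths descend the return track, run up the stem and exit through the
*opposite* arm — i.e. spatial alternation.

An *episode* is the minimal run starting at one supplier, visiting the
other at least once, and returning to the origin; the reward of an
episode is its number of good paths (0, 1 or 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "SL",
    "SR",
    "A",
    "B",
    "SUPPLIERS",
    "EDGES",
    "MazeGraph",
    "ElementaryPath",
    "PathRecord",
    "Episode",
    "BehaviorLog",
    "enumerate_elementary_paths",
    "classify_path",
    "path_by_label",
    "segment_episodes",
    "session_success_rate",
    "MazeError",
]

SL = "SL"
SR = "SR"
A = "A"
B = "B"
SUPPLIERS = (SL, SR)

#: edge name -> (endpoint, endpoint)
EDGES = {
    "left_return": (SL, A),
    "right_return": (SR, A),
    "stem": (A, B),
    "left_arm": (SL, B),
    "right_arm": (SR, B),
}


class MazeError(ValueError):
    """Structural error: malformed maze, path or path sequence."""


@dataclass(frozen=True)
class MazeGraph:
    """The T-maze as an undirected graph over named nodes and edges."""

    nodes: frozenset = frozenset((SL, SR, A, B))
    edges: dict = field(default_factory=lambda: dict(EDGES))

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if set(g.nodes) != {SL, SR, A, B} or g.number_of_edges() != 5:
            raise MazeError("maze must have exactly nodes {SL, SR, A, B} and 5 edges")
        if not nx.is_connected(g):
            raise MazeError("maze graph must be connected")
        degrees = dict(g.degree())
        if degrees[SL] != 2 or degrees[SR] != 2 or degrees[A] != 3 or degrees[B] != 3:
            raise MazeError("suppliers must have degree 2 and junctions degree 3")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for name, (u, v) in self.edges.items():
            g.add_edge(u, v, name=name)
        return g

    def other_end(self, edge: str, node: str) -> str:
        u, v = self.edges[edge]
        if node == u:
            return v
        if node == v:
            return u
        raise MazeError(f"node {node!r} is not an endpoint of edge {edge!r}")

    def incident_edges(self, node: str) -> tuple:
        """Edges touching ``node``, in canonical (sorted) order."""
        return tuple(sorted(e for e, (u, v) in self.edges.items() if node in (u, v)))


#: the default apparatus used throughout
CANONICAL_MAZE = MazeGraph()


@dataclass(frozen=True)
class ElementaryPath:
    """One of the 12 supplier-to-supplier walks, labelled ``origin:shape``."""

    label: str
    origin: str
    destination: str
    edge_sequence: tuple
    is_good: bool

    def __len__(self) -> int:
        return len(self.edge_sequence)


# Shape names keyed by the structural role of each walk, mirrored left/right:
#   good      return -> stem -> opposite arm   (rewarded alternation)
#   loop_low  return -> stem -> own arm        (loop entering the stem at A)
#   loop_top  arm -> stem -> own return        (loop entering the stem at B)
#   cross_low return -> opposite return        (below the stem)
#   cross_top arm -> opposite arm              (over the top, skipping the stem)
#   reverse   arm -> stem -> opposite return   (the opposite good path backwards)
_SHAPE_ORDER = ("good", "loop_low", "loop_top", "cross_low", "cross_top", "reverse")


def _shape_of(maze: MazeGraph, origin: str, edge_sequence: Sequence[str]) -> str:
    first = edge_sequence[0]
    via_return = first.endswith("_return")
    if "stem" not in edge_sequence:
        return "cross_low" if via_return else "cross_top"
    destination = _walk_destination(maze, origin, edge_sequence)
    if via_return:
        return "good" if destination != origin else "loop_low"
    return "reverse" if destination != origin else "loop_top"


def _walk_destination(maze: MazeGraph, origin: str, edges: Sequence[str]) -> str:
    node = origin
    for e in edges:
        node = maze.other_end(e, node)
    return node


def enumerate_elementary_paths(maze: MazeGraph = CANONICAL_MAZE) -> list:
    """Enumerate the 12 elementary paths of the maze in canonical order.

    A walk qualifies if it starts and ends at a supplier, never repeats the
    edge just traversed (no turn-back) and never touches a supplier at an
    intermediate step.  Order is by origin (``SL`` first) then shape.
    """
    found = {}
    for origin in SUPPLIERS:
        stack = [(origin, None, ())]
        while stack:
            node, last_edge, edges = stack.pop()
            for e in maze.incident_edges(node):
                if e == last_edge:
                    continue
                nxt = maze.other_end(e, node)
                walk = edges + (e,)
                if nxt in SUPPLIERS:
                    shape = _shape_of(maze, origin, walk)
                    label = f"{origin}:{shape}"
                    if label in found:
                        raise MazeError(f"ambiguous walk shape {label!r}")
                    found[label] = ElementaryPath(
                        label=label,
                        origin=origin,
                        destination=nxt,
                        edge_sequence=walk,
                        is_good=(shape == "good"),
                    )
                else:
                    stack.append((nxt, e, walk))
    paths = [
        found[f"{origin}:{shape}"]
        for origin in sorted(SUPPLIERS)
        for shape in _SHAPE_ORDER
    ]
    if len(paths) != 12:
        raise MazeError(f"expected 12 elementary paths, found {len(found)}")
    return paths


_PATHS = enumerate_elementary_paths()
_BY_LABEL = {p.label: p for p in _PATHS}
_BY_EDGES = {(p.origin, p.edge_sequence): p for p in _PATHS}


def path_by_label(label: str) -> ElementaryPath:
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise MazeError(f"unknown elementary-path label {label!r}") from None


def classify_path(edge_sequence: Sequence[str], origin: str) -> ElementaryPath:
    """Match an edge sequence from ``origin`` to its elementary path.

    Unclassifiable sequences raise :class:`MazeError`, mirroring the removal
    of unclassifiable track portions from the analysis.
    """
    key = (origin, tuple(edge_sequence))
    try:
        return _BY_EDGES[key]
    except KeyError:
        raise MazeError(
            f"edge sequence {tuple(edge_sequence)!r} from {origin!r} is not an "
            "elementary path"
        ) from None


@dataclass(frozen=True)
class PathRecord:
    """One traversed elementary path with per-edge durations (seconds)."""

    session_index: int
    ordinal_in_experiment: int
    path: ElementaryPath
    edge_durations: tuple

    def __post_init__(self) -> None:
        if len(self.edge_durations) != len(self.path.edge_sequence):
            raise MazeError("one duration per edge is required")
        if any(d <= 0 for d in self.edge_durations):
            raise MazeError("edge durations must be positive")

    @property
    def duration(self) -> float:
        return float(sum(self.edge_durations))


@dataclass(frozen=True)
class Episode:
    """Minimal origin->opposite->origin run; the unit of reward evaluation."""

    session_index: int
    episode_index_in_session: int
    paths: tuple
    origin: str

    @property
    def reward(self) -> int:
        return sum(1 for r in self.paths if r.path.is_good)

    @property
    def duration(self) -> float:
        return float(sum(r.duration for r in self.paths))


def _check_chainable(records: Sequence[PathRecord]) -> None:
    for prev, cur in zip(records, records[1:]):
        if cur.path.origin != prev.path.destination:
            raise MazeError(
                f"path sequence is not chainable at ordinal "
                f"{cur.ordinal_in_experiment}: {cur.path.origin!r} does not "
                f"follow {prev.path.destination!r}"
            )


def segment_episodes(session_paths: Sequence[PathRecord]):
    """Greedy left-to-right minimal segmentation of a session into episodes.

    Returns ``(episodes, trailing_fragment)``.  An episode closes at the
    first path after which the opposite supplier has been visited and the
    run is back at its origin; any paths left over at session end form the
    trailing fragment (their reward is never evaluated).
    """
    records = list(session_paths)
    _check_chainable(records)
    episodes = []
    start = 0
    while start < len(records):
        origin = records[start].path.origin
        opposite_seen = False
        end = None
        for i in range(start, len(records)):
            dest = records[i].path.destination
            if dest != origin:
                opposite_seen = True
            if opposite_seen and dest == origin:
                end = i + 1
                break
        if end is None:
            break
        episodes.append(
            Episode(
                session_index=records[start].session_index,
                episode_index_in_session=len(episodes) + 1,
                paths=tuple(records[start:end]),
                origin=origin,
            )
        )
        start = end
    return episodes, list(records[start:])


def session_success_rate(session_paths: Sequence[PathRecord]) -> float:
    """Fraction of good paths among all paths of one session."""
    records = list(session_paths)
    if not records:
        raise MazeError("success rate is undefined for an empty session")
    return sum(1 for r in records if r.path.is_good) / len(records)


@dataclass
class BehaviorLog:
    """Session-structured record of traversed elementary paths.

    ``sessions`` is an ordered list of sessions, each an ordered list of
    :class:`PathRecord`.  Episodes and per-session trailing fragments are
    derived once at construction; concatenating a session's episode paths
    and its trailing fragment reproduces the session exactly.
    """

    sessions: list

    def __post_init__(self) -> None:
        self.episodes_per_session = []
        self.trailing_fragment_per_session = []
        for paths in self.sessions:
            eps, frag = segment_episodes(paths)
            self.episodes_per_session.append(eps)
            self.trailing_fragment_per_session.append(frag)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def n_paths(self) -> int:
        return sum(len(s) for s in self.sessions)

    def all_records(self) -> Iterable[PathRecord]:
        for session in self.sessions:
            yield from session

    def success_rates(self) -> list:
        return [session_success_rate(s) for s in self.sessions]
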