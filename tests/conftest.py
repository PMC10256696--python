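import numpy as np
import pytest

from coaca.maze import BehaviorLog, PathRecord, path_by_label


def log_from_labels(session_labels, seed=0, unit_durations=False):
    """Build a BehaviorLog from lists of path labels, one list per session.

    Durations are lognormal draws (or exactly 1 s per edge when
    ``unit_durations``); ordinals run globally across sessions.
    """
    rng = np.random.default_rng(seed)
    sessions = []
    ordinal = 0
    for s, labels in enumerate(session_labels, start=1):
        records = []
        for label in labels:
            path = path_by_label(label)
            ordinal += 1
            durations = tuple(
                1.0 if unit_durations else float(rng.lognormal(0.0, 0.2))
                for _ in path.edge_sequence
            )
            records.append(PathRecord(s, ordinal, path, durations))
        sessions.append(records)
    return BehaviorLog(sessions)


@pytest.fixture
def toy_log():
    """Three-session toy log covering all three episode/reward types and a
    trailing fragment."""
    return log_from_labels(
        [
            ["SL:good", "SR:loop_low", "SR:good", "SL:good", "SR:cross_low"],
            ["SL:cross_top", "SR:reverse", "SL:good", "SR:good"],
            ["SL:good", "SR:loop_top", "SR:good", "SL:cross_top"],
        ],
        seed=42,
    )
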