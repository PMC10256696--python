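"""CoACA credit dynamics.

A credit table K(S, A) starts at zero for every state-action pair.  While
an episode unfolds, actions are chosen by a softmax of the credits over
the actions available in the current state:

    P(A | S) = exp(K(S, A)) / sum_{A' available from S} exp(K(S, A'))

At the end of each episode, every action performed in it gains

    dK(S, A) = alpha * a(A) * R

where ``alpha`` in [0, 1] is the learning parameter, ``R`` in {0, 1, 2}
the episode reward and ``a(A) = d(A) / d(episode)`` the *activity*, the
share of the episode's total locomotion time the action occupied.
Because activities within an episode sum to one, the total credit poured
into an episode is exactly ``alpha * R``.  Pairs not visited in the
episode are untouched, and probabilities during the episode are frozen
at the table as it stood when the episode began.

Between sessions every credit is multiplied by a forgetfulness
parameter ``gamma`` in [0, 1], modelling day-to-day forgetting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .strategies import ModelAction, ModelState, StrategyModel

__all__ = [
    "Params",
    "CreditTable",
    "action_probabilities",
    "apply_episode_update",
    "apply_session_decay",
]


@dataclass(frozen=True)
class Params:
    """Learning parameter ``alpha`` and forgetfulness ``gamma``, both in [0, 1]."""

    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.gamma <= 1.0):
            raise ValueError("alpha and gamma must lie in the closed unit interval")


class CreditTable:
    """Mutable map from (state, action) to credit, initialised to zero.

    Entries are materialised lazily; an absent pair reads as 0.  The table
    tracks its epoch (session, episode) for audit purposes only.
    """

    def __init__(self, model: StrategyModel):
        self.model = model
        self._credits: dict = {}
        self.session = 1
        self.episode = 1

    def get(self, state: ModelState, action: ModelAction) -> float:
        return self._credits.get((state, action), 0.0)

    def set(self, state: ModelState, action: ModelAction, value: float) -> None:
        self._credits[(state, action)] = value

    def items(self):
        """All (state, action, credit) triples, unvisited pairs included."""
        for s in self.model.states:
            for a in self.model.actions_by_state[s]:
                yield s, a, self.get(s, a)

    # -- serialisation ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "model": self.model.name,
            "session": self.session,
            "episode": self.episode,
            "credits": [
                {"state": s.identifier, "action": a.identifier, "credit": k}
                for s, a, k in self.items()
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, model: StrategyModel, text: str) -> "CreditTable":
        payload = json.loads(text)
        if payload["model"] != model.name:
            raise ValueError(
                f"snapshot is for model {payload['model']!r}, not {model.name!r}"
            )
        table = cls(model)
        table.session = payload["session"]
        table.episode = payload["episode"]
        by_id = {
            (s.identifier, a.identifier): (s, a)
            for s in model.states
            for a in model.actions_by_state[s]
        }
        for row in payload["credits"]:
            s, a = by_id[(row["state"], row["action"])]
            if row["credit"] != 0.0:
                table.set(s, a, row["credit"])
        return table


def action_probabilities(
    table: CreditTable, model: StrategyModel, state: ModelState
) -> np.ndarray:
    """Softmax of credits over the actions available from ``state``.

    Computed with max-subtraction so arbitrarily large credits cannot
    overflow; the value is unchanged by the shift.
    """
    actions = model.available_actions(state)
    credits = np.array([table.get(state, a) for a in actions], dtype=float)
    shifted = credits - credits.max()
    w = np.exp(shifted)
    return w / w.sum()


def apply_episode_update(
    table: CreditTable,
    episode_actions: Sequence[tuple],
    reward: int,
    params: Params,
) -> CreditTable:
    """Credit every action of a finished episode with ``alpha * activity * R``.

    ``episode_actions`` is a sequence of ``(state, action, activity)`` with
    activities in [0, 1] (their sum over the episode is 1 under the
    locomotion-only duration convention).  The update mutates and returns
    ``table``; pairs not visited in the episode are unchanged.
    """
    for _, _, activity in episode_actions:
        if not (0.0 <= activity <= 1.0):
            raise ValueError(f"activity {activity} outside [0, 1]")
    for state, action, activity in episode_actions:
        table.set(
            state, action, table.get(state, action) + params.alpha * activity * reward
        )
    table.episode += 1
    return table


def apply_session_decay(table: CreditTable, params: Params) -> CreditTable:
    """Multiply every credit by ``gamma`` at a session boundary."""
    for key, value in list(table._credits.items()):
        table._credits[key] = params.gamma * value
    table.session += 1
    table.episode = 1
    return table


def log_softmax(credits: Sequence[float]) -> list:
    """Log-probabilities of a softmax over raw credits (stable)."""
    m = max(credits)
    lse = m + math.log(sum(math.exp(k - m) for k in credits))
    return [k - lse for k in credits]
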