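"""Synthetic players: simulated participants with known ground truth.

The player model is a test fixture, not a cognitive model. It reproduces
the statistical structure the metrics pipeline assumes: positively skewed
(gamma) per-board search times whose mean rises linearly with set size
(``w*h``), falls with the number of tile types ``t``, and scales with a
per-group multiplier emulating age-group slowing; plus occasional false
moves and hint usage. Mean search time::

    mu = group_multiplier * max(eps, base_time
                                + set_size_effect * w * h
                                + tile_type_effect * t)

with gamma noise of shape ``k`` (scale ``mu / k``). Simulated moves are
played through the real session engine against real trials, so every log
satisfies the engine's replay property by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .board import Board, Move
from .generator import Trial
from .session import MoveLogEntry, Session, SessionLog

__all__ = [
    "PlayerModel",
    "simulate_board",
    "simulate_trial",
    "simulate_cohort",
    "load_player_model",
]

_EPS = 1e-3


@dataclass(frozen=True)
class PlayerModel:
    """Parameters of a simulated participant.

    Defaults emulate a young-adult-like player on desk-scale levels:
    roughly 1 s of base time plus 0.1 s per display item, slightly faster
    with more tile types (grouping makes the target easier to spot), with
    rare false moves and hints.
    """

    base_time: float = 1.0  # seconds
    set_size_effect: float = 0.1  # seconds per item, >= 0
    tile_type_effect: float = -0.05  # seconds per extra tile type, <= 0
    group_multiplier: float = 1.0
    shape: float = 4.0  # gamma shape k
    p_false: float = 0.05  # probability of one preceding false move
    p_hint: float = 0.02  # probability of hint use per board
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.group_multiplier <= 0:
            raise ValueError("shape and group_multiplier must be positive")
        for p in (self.p_false, self.p_hint):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    def mean_search_time(self, w: int, h: int, t: int) -> float:
        mu = self.base_time + self.set_size_effect * w * h + self.tile_type_effect * t
        return self.group_multiplier * max(_EPS, mu)


def _random_wrong_move(board: Board, solution: Move, rng: np.random.Generator) -> Move:
    """A uniformly random adjacent swap that is not the solution."""
    candidates = []
    for r in range(board.h):
        for c in range(board.w):
            if c + 1 < board.w:
                candidates.append(Move((r, c), (r, c + 1)))
            if r + 1 < board.h:
                candidates.append(Move((r, c), (r + 1, c)))
    candidates = [m for m in candidates if m != solution]
    return candidates[int(rng.integers(len(candidates)))]


def simulate_board(
    model: PlayerModel,
    session: Session,
    rng: np.random.Generator,
    clock: float,
) -> float:
    """Play the currently active board of ``session``; returns the new clock.

    Draws the board's total search time from a gamma distribution with mean
    ``mu(w, h, t)`` and shape ``k``; with probability ``p_false`` a random
    non-solution adjacent swap is submitted first, splitting the time at a
    uniform point; with probability ``p_hint`` the hint is requested before
    the correct move.
    """
    level = session.trial.level
    mu = model.mean_search_time(level.w, level.h, level.t)
    total = float(rng.gamma(model.shape, mu / model.shape))
    total = max(total, 2 * _EPS)
    solution = session.trial.matches[session.board_index - 1].solution_move
    if rng.random() < model.p_hint:
        session.request_hint(clock)
    if rng.random() < model.p_false:
        split = total * float(rng.uniform(0.2, 0.8))
        wrong = _random_wrong_move(session.active_board, solution, rng)
        session.submit_move(wrong, clock + split)
    session.submit_move(solution, clock + total)
    return clock + total


def simulate_trial(
    model: PlayerModel,
    trial: Trial,
    rng: np.random.Generator,
    participant_id: str = "sim",
    group: str = "none",
    clock: float = 0.0,
    rate_difficulty: bool = True,
    validate: bool = False,
) -> tuple[SessionLog, float]:
    """Simulate one full trial; returns the log and the advanced clock."""
    session = Session(trial, participant_id=participant_id, group=group, validate=validate)
    session.start(clock)
    while not session.finished:
        clock = simulate_board(model, session, rng, clock)
    if rate_difficulty:
        # crude difficulty impression: longer mean time -> higher rating
        mu = model.mean_search_time(trial.level.w, trial.level.h, trial.level.t)
        rating = int(np.clip(round(1 + 9 * (mu / model.group_multiplier) / 8.0), 1, 10))
        session.record_difficulty_rating(rating)
    return session.log, clock


def simulate_cohort(
    models: Mapping[str, PlayerModel],
    trials: Sequence[Trial],
    seed: int,
    n_participants: int = 1,
) -> list[SessionLog]:
    """Simulate ``n_participants`` per group playing every trial.

    ``models`` maps group labels to player models. Fully deterministic
    given ``seed``: each (group, participant) gets an independent
    deterministic substream.
    """
    if not models:
        raise ValueError("at least one player model is required")
    if not trials:
        raise ValueError("at least one trial is required")
    logs: list[SessionLog] = []
    for gi, (group, model) in enumerate(sorted(models.items())):
        for p in range(n_participants):
            rng = np.random.default_rng([seed, model.rng_seed, gi, p])
            pid = f"{group}-{p:03d}"
            full = SessionLog(metadata={"participant_id": pid, "group": group})
            clock = 0.0
            for trial in trials:
                log, clock = simulate_trial(
                    model, trial, rng, participant_id=pid, group=group, clock=clock
                )
                full.extend(log)
            logs.append(full)
    return logs


def load_player_model(path: str) -> PlayerModel:
    """Load a player model from a YAML/JSON mapping of field names."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("player config must be a mapping of PlayerModel fields")
    return PlayerModel(**data)
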