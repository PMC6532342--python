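"""Headless gameplay sessions with move-level logging.

A session plays one validated trial: the player submits adjacent swaps
against the active board; the unique valid move resolves the match and
advances to the next board (trials self-terminate after the fourth correct
move), while any other swap attempt "bounces" and is logged as a false
move. A hint discloses the unique valid move and flags the board's correct
move as hint-assisted. After completion the player may attach a 1-10
difficulty rating, which is propagated to every log entry of the trial.

Timing is injected: every call takes a caller-supplied timestamp (seconds,
monotonically increasing), so the engine is equally usable by a GUI front
end, scripted replays and the synthetic player. Elapsed time per move is
the time since the board became active or since the previous move attempt.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .board import Board, Move, apply_swap, resolve_match
from .generator import BOARDS_PER_TRIAL, Trial
from .trial_io import validate_trial

__all__ = [
    "MoveLogEntry",
    "SessionLog",
    "Session",
    "SessionError",
    "LOG_COLUMNS",
    "shuffle_level_order",
]

LOG_COLUMNS = [
    "participant_id",
    "group",
    "w",
    "h",
    "t",
    "trial_id",
    "board_index",
    "move_number",
    "move",
    "elapsed_time",
    "accuracy",
    "hint_used",
    "difficulty_rating",
]


class SessionError(RuntimeError):
    """Misuse of the session protocol (wrong phase, bad input)."""


@dataclass(frozen=True)
class MoveLogEntry:
    """One attempted swap, as recorded in the move-level summary file."""

    participant_id: str
    group: str
    w: int
    h: int
    t: int
    trial_id: str
    board_index: int  # 1-based, 1..4
    move_number: int  # 1-based within the board
    move: Move
    elapsed_time: float  # seconds since board onset or previous attempt
    accuracy: str  # "correct" | "false"
    hint_used: bool
    difficulty_rating: int | None = None

    def to_row(self) -> dict:
        (r1, c1), (r2, c2) = self.move.cells
        return {
            "participant_id": self.participant_id,
            "group": self.group,
            "w": self.w,
            "h": self.h,
            "t": self.t,
            "trial_id": self.trial_id,
            "board_index": self.board_index,
            "move_number": self.move_number,
            "move": f"{r1} {c1} {r2} {c2}",
            "elapsed_time": self.elapsed_time,
            "accuracy": self.accuracy,
            "hint_used": self.hint_used,
            "difficulty_rating": self.difficulty_rating,
        }


@dataclass
class SessionLog:
    """Ordered move entries plus session metadata."""

    entries: list[MoveLogEntry] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([e.to_row() for e in self.entries], columns=LOG_COLUMNS)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    def extend(self, other: "SessionLog") -> None:
        self.entries.extend(other.entries)


class Session:
    """Single-use playthrough of one trial.

    Protocol: ``start(t0)`` -> repeated ``submit_move(move, t)`` /
    ``request_hint(t)`` -> after the 4th correct move,
    ``record_difficulty_rating(r)``.
    """

    def __init__(
        self,
        trial: Trial,
        participant_id: str = "anonymous",
        group: str = "none",
        validate: bool = True,
    ):
        if validate:
            report = validate_trial(trial)
            if not report:
                raise SessionError(f"invalid trial: {report.first_violation}")
        self.trial = trial
        self.participant_id = participant_id
        self.group = group
        self.log = SessionLog(
            metadata={
                "participant_id": participant_id,
                "group": group,
                "trial_id": trial.trial_id,
                "level": (trial.level.w, trial.level.h, trial.level.t),
                "seed": trial.seed,
            }
        )
        self._started = False
        self._finished = False
        self._board: Board | None = None
        self._board_index = 0
        self._move_number = 0
        self._anchor: float | None = None
        self._hint_pending = False
        self._solution: Move | None = None

    # -- phase helpers -----------------------------------------------------

    @property
    def active_board(self) -> Board:
        if self._board is None:
            raise SessionError("no active board (session not started or finished)")
        return self._board

    @property
    def board_index(self) -> int:
        return self._board_index

    @property
    def finished(self) -> bool:
        return self._finished

    def _activate(self, board: Board, index: int) -> None:
        self._board = board
        self._board_index = index
        self._move_number = 0
        self._hint_pending = False
        self._solution = self.trial.matches[index - 1].solution_move

    # -- protocol ----------------------------------------------------------

    def start(self, timestamp: float = 0.0) -> Board:
        """Activate board 1 and anchor the clock."""
        if self._started:
            raise SessionError("session already started (single use)")
        self._started = True
        self._anchor = float(timestamp)
        self._activate(self.trial.initial_board, 1)
        return self.active_board

    def _elapsed(self, timestamp: float) -> float:
        assert self._anchor is not None
        elapsed = float(timestamp) - self._anchor
        if elapsed <= 0:
            raise SessionError(
                f"timestamps must strictly increase (elapsed {elapsed:.6g} <= 0)"
            )
        self._anchor = float(timestamp)
        return elapsed

    def submit_move(self, move: Move, timestamp: float) -> str:
        """Attempt a swap; returns "matched", "bounce" or "trial complete".

        Out-of-bounds cells are rejected as malformed input and not logged;
        an in-bounds adjacent swap that creates no match (including a swap
        of two identical tiles) bounces and is logged as a false move.
        """
        board = self.active_board
        if not (board.in_bounds(move.a) and board.in_bounds(move.b)):
            raise SessionError(f"move {move} out of bounds for {board.w}x{board.h} board")
        elapsed = self._elapsed(timestamp)
        self._move_number += 1
        correct = move == self._solution
        self.log.entries.append(
            MoveLogEntry(
                participant_id=self.participant_id,
                group=self.group,
                w=self.trial.level.w,
                h=self.trial.level.h,
                t=self.trial.level.t,
                trial_id=self.trial.trial_id,
                board_index=self._board_index,
                move_number=self._move_number,
                move=move,
                elapsed_time=elapsed,
                accuracy="correct" if correct else "false",
                hint_used=correct and self._hint_pending,
            )
        )
        if not correct:
            return "bounce"
        match = self.trial.matches[self._board_index - 1]
        resolved = resolve_match(apply_swap(board, move), match.refill)
        if self._board_index == BOARDS_PER_TRIAL:
            self._board = None
            self._finished = True
            return "trial complete"
        self._activate(resolved, self._board_index + 1)
        return "matched"

    def request_hint(self, timestamp: float | None = None) -> Move:
        """Disclose the unique valid move; the board's eventual correct move
        is logged with ``hint_used=True``. Does not advance the board or the
        clock anchor."""
        self.active_board
        self._hint_pending = True
        assert self._solution is not None
        return self._solution

    def record_difficulty_rating(self, rating: int) -> SessionLog:
        """Attach a 1-10 subjective difficulty rating to all trial entries."""
        if not self._finished:
            raise SessionError("difficulty rating only after trial completion")
        if not isinstance(rating, int) or not (1 <= rating <= 10):
            raise SessionError(f"rating must be an integer in 1..10, got {rating!r}")
        self.log.entries = [replace(e, difficulty_rating=rating) for e in self.log.entries]
        return self.log


def shuffle_level_order(levels: Sequence, seed: int) -> list:
    """Seed-deterministic randomized presentation order for a level list
    (random order avoids learning effects from incremental presentation)."""
    order = list(levels)
    random.Random(seed).shuffle(order)
    return order
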