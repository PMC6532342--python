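"""Difficulty-level space and constrained trial generation.

Difficulty is manipulated factorially through board width ``w``, height
``h`` (set size = ``w*h``) and the number of tile types ``t`` (distractor
heterogeneity): ``(w, h) in {4..8}^2`` with ``4 <= t <= max(w, h)``, giving
25 board sizes and 95 levels in total.

A *playable trial* is a sequence of 4 consecutive single-target boards: the
initial board and each refilled successor are stable and admit exactly one
valid move, and (by default) that move creates exactly one run of exactly
three tiles. Boards are found by rejection sampling; refills by rejection
sampling with backtracking across the four match stages. Everything is
deterministic given a seed.

Not every level is feasible: at large set sizes with few tile types a
random board almost never has exactly one target, so trial generation fails
within any practical budget — the board-acceptance rate falls steeply with
set size at fixed ``t``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .board import Board, Move, apply_swap, find_runs, resolve_match
from .patterns import _grid_stable, _unique_move_scan, template_moves

__all__ = [
    "LevelSpec",
    "GeneratorConfig",
    "MatchRecord",
    "Trial",
    "GenerationFailure",
    "enumerate_level_specs",
    "generate_stable_single_target_board",
    "generate_trial",
    "estimate_acceptance_rate",
    "survey_playability",
    "split_parallel_versions",
]

BOARDS_PER_TRIAL = 4

W_RANGE = range(4, 9)
H_RANGE = range(4, 9)
T_MIN = 4


@dataclass(frozen=True, order=True)
class LevelSpec:
    """One difficulty cell: board width, height and number of tile types."""

    w: int
    h: int
    t: int

    def __post_init__(self) -> None:
        if not (self.w >= 1 and self.h >= 1 and self.t >= 2):
            raise ValueError(f"degenerate level spec {self}")

    @property
    def set_size(self) -> int:
        return self.w * self.h

    @property
    def level_id(self) -> str:
        return f"w{self.w}h{self.h}t{self.t}"

    @property
    def sort_key(self) -> tuple[int, int, int, int]:
        # Levels are ordered by (set size, w, h, t) everywhere: "sorted by
        # set size" with deterministic tie-breaking.
        return (self.set_size, self.w, self.h, self.t)


@dataclass(frozen=True)
class GeneratorConfig:
    """Budgets and acceptance flags for trial generation.

    ``forbid_runs_gt3`` additionally requires the unique move to create
    exactly one run of exactly three tiles, so a hint and a per-board search
    time are unambiguous.
    """

    rng_seed: int = 0
    max_board_attempts: int = 10_000
    max_refill_attempts: int = 2_000
    max_restarts: int = 25
    forbid_runs_gt3: bool = True
    trials_required: int = 47

    def __post_init__(self) -> None:
        if min(self.max_board_attempts, self.max_refill_attempts, self.max_restarts) < 1:
            raise ValueError("generation budgets must be positive")


@dataclass(frozen=True)
class MatchRecord:
    """Solution move for one board plus the refill that builds the next."""

    solution_move: Move
    refill: tuple[tuple[int, ...], ...]  # one stream per column


@dataclass(frozen=True)
class Trial:
    """A pregenerated playable trial: initial board plus 4 match records.

    The 4th match needs no refill for gameplay (trials self-terminate after
    the 4th correct move) but one is stored for uniformity; the board it
    produces is generated stable so nothing would auto-eliminate.
    """

    level: LevelSpec
    trial_id: str
    seed: int
    initial_board: Board
    matches: tuple[MatchRecord, MatchRecord, MatchRecord, MatchRecord]

    def boards(self) -> list[Board]:
        """The four played boards (replayed from the stored moves/refills)."""
        out = [self.initial_board]
        b = self.initial_board
        for m in self.matches[:-1]:
            b = resolve_match(apply_swap(b, m.solution_move), m.refill)
            out.append(b)
        return out


@dataclass(frozen=True)
class GenerationFailure:
    """Explicit failure value from an exhausted generation budget."""

    level: LevelSpec
    stage: str  # "board" | "refill"
    attempts: int
    detail: str = ""

    def __bool__(self) -> bool:
        return False


def enumerate_level_specs() -> list[LevelSpec]:
    """All levels of the restricted factorial space, sorted by
    (set size, w, h, t)."""
    specs = [
        LevelSpec(w, h, t)
        for w, h in itertools.product(W_RANGE, H_RANGE)
        for t in range(T_MIN, max(w, h) + 1)
    ]
    return sorted(specs, key=lambda s: s.sort_key)


def _single_target_grid(grid: np.ndarray, forbid_runs_gt3: bool) -> Move | None:
    """The unique valid move if the (stable) grid passes single-target
    acceptance, else None.

    With ``forbid_runs_gt3`` a single template hit plus a one-run-of-three
    check decides acceptance (early-exit fast path); without it, any board
    with exactly one distinct valid move is accepted regardless of what the
    move creates, which requires full move deduplication.
    """
    if forbid_runs_gt3:
        mv = _unique_move_scan(grid)
        if mv is None:
            return None
        runs = find_runs(apply_swap(Board(grid), mv))
        if len(runs) != 1 or len(runs[0]) != 3:
            return None
        return mv
    moves = template_moves(Board(grid))
    if len(moves) != 1:
        return None
    return next(iter(moves))


def _single_target_move(board: Board, forbid_runs_gt3: bool) -> Move | None:
    """The unique valid move if the board passes single-target acceptance,
    else None. The board must already be stable."""
    return _single_target_grid(np.asarray(board.grid), forbid_runs_gt3)


def generate_stable_single_target_board(
    level: LevelSpec,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> Board | GenerationFailure:
    """Rejection-sample a board that is stable and has exactly one target.

    Boards are filled uniformly from the level's tile alphabet and accepted
    iff (a) no run exists, (b) exactly one valid move exists, and (c) with
    ``forbid_runs_gt3`` that move creates exactly one run of exactly three.
    Returns a :class:`GenerationFailure` (not an exception) when the attempt
    budget is exhausted — the normal outcome for levels like (8, 8, 4) where
    random boards contain many targets.
    """
    config = config or GeneratorConfig()
    for attempt in range(1, config.max_board_attempts + 1):
        grid = rng.integers(0, level.t, size=(level.h, level.w), dtype=np.int16)
        if not _grid_stable(grid):
            continue
        if _single_target_grid(grid, config.forbid_runs_gt3) is not None:
            return Board(grid)
    return GenerationFailure(
        level, "board", config.max_board_attempts, "no single-target board accepted"
    )


def _search_refill(
    board: Board,
    move: Move,
    level: LevelSpec,
    rng: np.random.Generator,
    config: GeneratorConfig,
    require_single_target: bool,
) -> tuple[tuple[tuple[int, ...], ...], Board, Move | None] | None:
    """Sample refill streams until the refilled board is acceptable.

    For intermediate stages the refilled board must pass full single-target
    acceptance; for the final stored refill it must only be stable.
    """
    swapped = apply_swap(board, move)
    removed: set[tuple[int, int]] = set()
    for run in find_runs(swapped):
        removed.update(run.cells)
    need = [sum(1 for r, c in removed if c == col) for col in range(level.w)]
    total = sum(need)
    # Precompute the post-gravity grid with holes at the top of each column;
    # each attempt only writes the freshly drawn tiles into the holes.
    rows = swapped.rows()
    base = np.empty((level.h, level.w), dtype=np.int16)
    for col in range(level.w):
        survivors = [rows[r][col] for r in range(level.h) if (r, col) not in removed]
        base[need[col] :, col] = survivors
    hole_rows = [r for col in range(level.w) for r in range(need[col])]
    hole_cols = [col for col in range(level.w) for _ in range(need[col])]
    for _ in range(config.max_refill_attempts):
        draw = rng.integers(0, level.t, size=total, dtype=np.int16)
        grid = base.copy()
        grid[hole_rows, hole_cols] = draw
        if not _grid_stable(grid):
            continue
        if not require_single_target:
            nxt_move = None
        else:
            nxt_move = _single_target_grid(grid, config.forbid_runs_gt3)
            if nxt_move is None:
                continue
        streams: list[tuple[int, ...]] = []
        k = 0
        for col in range(level.w):
            streams.append(tuple(int(v) for v in draw[k : k + need[col]]))
            k += need[col]
        return tuple(streams), Board(grid), nxt_move
    return None


def generate_trial(
    level: LevelSpec,
    seed: int,
    config: GeneratorConfig | None = None,
) -> Trial | GenerationFailure:
    """Generate one playable trial, deterministically from ``seed``.

    Structure: rejection-sample the initial single-target board, then for
    each of the four matches search a refill whose successor board again
    passes acceptance (the final refill only needs a stable successor).
    When a stage exhausts its refill budget, backtrack one stage and
    resample; when backtracking falls below the first stage, restart from a
    fresh initial board, up to ``config.max_restarts`` restarts.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    board_attempts = 0
    for _restart in range(config.max_restarts):
        b0 = generate_stable_single_target_board(level, rng, config)
        if isinstance(b0, GenerationFailure):
            return GenerationFailure(
                level, "board", board_attempts + b0.attempts, b0.detail
            )
        board_attempts += config.max_board_attempts
        mv0 = _single_target_move(b0, config.forbid_runs_gt3)
        assert mv0 is not None
        # DFS over the 4 match stages with one-stage backtracking.
        boards: list[Board] = [b0]
        moves: list[Move] = [mv0]
        records: list[MatchRecord] = []
        stage_retries = [0] * BOARDS_PER_TRIAL
        stage = 0
        dead = False
        while stage < BOARDS_PER_TRIAL:
            last = stage == BOARDS_PER_TRIAL - 1
            found = _search_refill(
                boards[stage], moves[stage], level, rng, config,
                require_single_target=not last,
            )
            if found is not None:
                refill, nxt, nxt_move = found
                records.append(MatchRecord(moves[stage], refill))
                if not last:
                    boards.append(nxt)
                    moves.append(nxt_move)  # type: ignore[arg-type]
                stage += 1
                continue
            stage_retries[stage] += 1
            if stage == 0 or stage_retries[stage] > 2:
                dead = True
                break
            # backtrack one stage: discard its record and resample its refill
            stage -= 1
            records.pop()
            if stage < len(boards) - 1:
                boards.pop()
                moves.pop()
        if dead:
            continue
        trial_id = f"{level.level_id}-s{seed}"
        return Trial(level, trial_id, seed, b0, tuple(records))  # type: ignore[arg-type]
    return GenerationFailure(
        level, "refill", config.max_restarts, "refill search exhausted all restarts"
    )


def estimate_acceptance_rate(
    level: LevelSpec,
    n_boards: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> float:
    """Monte-Carlo estimate of the probability a uniformly random board
    passes single-target acceptance."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    accepted = 0
    for _ in range(n_boards):
        grid = rng.integers(0, level.t, size=(level.h, level.w), dtype=np.int16)
        if _grid_stable(grid) and _single_target_grid(grid, config.forbid_runs_gt3) is not None:
            accepted += 1
    return accepted / n_boards


def survey_playability(
    levels: Sequence[LevelSpec],
    config: GeneratorConfig | None = None,
    seed: int = 0,
    attempts_per_level: int | None = None,
    cache_path: str | Path | None = None,
) -> pd.DataFrame:
    """Count distinct playable trials per level within budget.

    Tries ``attempts_per_level`` independent trial generations per level
    (default: 2x ``trials_required``) with seeds derived deterministically
    from ``seed``; trials are distinct when their initial boards differ.
    ``feasible`` flags levels reaching ``trials_required`` distinct trials.
    """
    config = config or GeneratorConfig()
    if attempts_per_level is None:
        attempts_per_level = 2 * config.trials_required
    rows = []
    for i, level in enumerate(sorted(levels, key=lambda s: s.sort_key)):
        boards_seen: set[Board] = set()
        for j in range(attempts_per_level):
            trial = generate_trial(level, seed + 100_003 * i + j, config)
            if isinstance(trial, Trial):
                boards_seen.add(trial.initial_board)
            if len(boards_seen) >= config.trials_required:
                break
        n = len(boards_seen)
        rows.append(
            {
                "level_id": level.level_id,
                "w": level.w,
                "h": level.h,
                "t": level.t,
                "set_size": level.set_size,
                "n_playable": n,
                "feasible": n >= config.trials_required,
            }
        )
    df = pd.DataFrame(rows)
    if cache_path is not None:
        df.to_csv(cache_path, index=False)
    return df


def split_parallel_versions(
    feasible_levels: Sequence[LevelSpec],
) -> tuple[list[LevelSpec], list[LevelSpec]]:
    """Split feasible levels into two parallel versions.

    Square levels (w == h) go into both versions; rectangular levels are
    sorted by (set size, w, h, t) and dealt out alternately. Both versions
    are returned sorted by set size (with the same tie-breaking).
    """
    squares = sorted((s for s in feasible_levels if s.w == s.h), key=lambda s: s.sort_key)
    rects = sorted((s for s in feasible_levels if s.w != s.h), key=lambda s: s.sort_key)
    version_a = list(squares)
    version_b = list(squares)
    for i, lvl in enumerate(rects):
        (version_a if i % 2 == 0 else version_b).append(lvl)
    version_a.sort(key=lambda s: s.sort_key)
    version_b.sort(key=lambda s: s.sort_key)
    return version_a, version_b
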