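"""Reader/writer/validator for pregenerated trial files.

Trials are stored as line-oriented UTF-8 text with LF line endings so they
can be inspected, diffed and regression-hashed. The canonical layout::

    SEARCHMATCH-TRIAL 1
    level <w> <h> <t>
    trial <trial_id>
    seed <seed>
    board
    <h lines of w space-separated tile ids>
    match 1
    move <r1> <c1> <r2> <c2>
    refill 0: <ids...>
    ...
    refill <w-1>: <ids...>
    match 2
    ...

Serialization is canonical: identical trials always produce identical
bytes, and ``read_trial(write_trial(t)) == t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .board import Board, BoardError, Move, apply_swap, find_runs, resolve_match
from .board import enumerate_valid_moves, is_stable
from .generator import BOARDS_PER_TRIAL, LevelSpec, MatchRecord, Trial

__all__ = [
    "FORMAT_VERSION",
    "TrialParseError",
    "ValidationReport",
    "write_trial",
    "trial_to_text",
    "read_trial",
    "trial_from_text",
    "validate_trial",
]

FORMAT_VERSION = 1
_MAGIC = "SEARCHMATCH-TRIAL"


class TrialParseError(ValueError):
    """Malformed trial file; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class ValidationReport:
    """Outcome of replaying a trial against the brute-force move oracle."""

    passed: bool
    failures: list[str] = field(default_factory=list)

    @property
    def first_violation(self) -> str | None:
        return self.failures[0] if self.failures else None

    def __bool__(self) -> bool:
        return self.passed


def trial_to_text(trial: Trial) -> str:
    """Canonical serialization of a trial (validated first)."""
    report = validate_trial(trial)
    if not report:
        raise BoardError(f"refusing to serialize invalid trial: {report.first_violation}")
    lines = [
        f"{_MAGIC} {FORMAT_VERSION}",
        f"level {trial.level.w} {trial.level.h} {trial.level.t}",
        f"trial {trial.trial_id}",
        f"seed {trial.seed}",
        "board",
        *trial.initial_board.to_lines(),
    ]
    for i, match in enumerate(trial.matches, start=1):
        (r1, c1), (r2, c2) = match.solution_move.cells
        lines.append(f"match {i}")
        lines.append(f"move {r1} {c1} {r2} {c2}")
        for col, stream in enumerate(match.refill):
            ids = " ".join(str(v) for v in stream)
            lines.append(f"refill {col}:" + (f" {ids}" if ids else ""))
    return "\n".join(lines) + "\n"


def write_trial(trial: Trial, path: str | Path) -> Path:
    """Write a trial to ``path``; identical trials produce identical bytes."""
    path = Path(path)
    path.write_text(trial_to_text(trial), encoding="utf-8", newline="\n")
    return path


class _Cursor:
    def __init__(self, text: str):
        self.lines = text.splitlines()
        self.i = 0

    @property
    def lineno(self) -> int:
        return self.i  # 1-based number of the line just consumed

    def next(self, expect: str | None = None) -> str:
        if self.i >= len(self.lines):
            raise TrialParseError(
                f"unexpected end of file (expected {expect or 'more data'})",
                len(self.lines) + 1,
            )
        line = self.lines[self.i]
        self.i += 1
        return line

    def expect_prefix(self, prefix: str) -> list[str]:
        line = self.next(expect=prefix)
        parts = line.split()
        if not parts or parts[0] != prefix:
            raise TrialParseError(f"expected '{prefix} ...', got {line!r}", self.lineno)
        return parts[1:]


def _ints(parts: list[str], what: str, lineno: int) -> list[int]:
    try:
        return [int(p) for p in parts]
    except ValueError as exc:
        raise TrialParseError(f"non-integer {what}: {exc}", lineno) from None


def trial_from_text(text: str) -> Trial:
    """Parse a canonical trial file, re-checking structural invariants."""
    cur = _Cursor(text)
    head = cur.next(expect="header").split()
    if len(head) != 2 or head[0] != _MAGIC:
        raise TrialParseError(f"bad magic, expected '{_MAGIC} <version>'", cur.lineno)
    if int(head[1]) != FORMAT_VERSION:
        raise TrialParseError(f"unsupported format version {head[1]}", cur.lineno)
    w, h, t = _ints(cur.expect_prefix("level"), "level spec", cur.lineno)
    level = LevelSpec(w, h, t)
    trial_parts = cur.expect_prefix("trial")
    if len(trial_parts) != 1:
        raise TrialParseError("trial id must be a single token", cur.lineno)
    trial_id = trial_parts[0]
    (seed,) = _ints(cur.expect_prefix("seed"), "seed", cur.lineno)
    if cur.next(expect="'board'").strip() != "board":
        raise TrialParseError("expected 'board'", cur.lineno)
    board_lines = []
    for r in range(h):
        row = _ints(cur.next(expect="board row").split(), "tile id", cur.lineno)
        if len(row) != w:
            raise TrialParseError(f"board row has {len(row)} tiles, expected {w}", cur.lineno)
        board_lines.append(row)
    board = Board(board_lines)
    try:
        board.validate_tiles(t)
    except BoardError as exc:
        raise TrialParseError(str(exc), cur.lineno) from None

    matches: list[MatchRecord] = []
    for i in range(1, BOARDS_PER_TRIAL + 1):
        try:
            idx_parts = cur.expect_prefix("match")
        except TrialParseError:
            raise TrialParseError(
                f"expected {BOARDS_PER_TRIAL} match blocks, found {i - 1}", cur.lineno
            ) from None
        if _ints(idx_parts, "match index", cur.lineno) != [i]:
            raise TrialParseError(f"expected 'match {i}'", cur.lineno)
        mv = _ints(cur.expect_prefix("move"), "move coordinates", cur.lineno)
        if len(mv) != 4:
            raise TrialParseError("move needs 4 coordinates 'r1 c1 r2 c2'", cur.lineno)
        try:
            move = Move((mv[0], mv[1]), (mv[2], mv[3]))
        except BoardError as exc:
            raise TrialParseError(str(exc), cur.lineno) from None
        streams: list[tuple[int, ...]] = []
        for col in range(w):
            parts = cur.expect_prefix("refill")
            if not parts or not parts[0].endswith(":"):
                raise TrialParseError(f"expected 'refill {col}: ...'", cur.lineno)
            got_col = _ints([parts[0][:-1]], "refill column", cur.lineno)[0]
            if got_col != col:
                raise TrialParseError(
                    f"refill column {got_col} out of order (expected {col})", cur.lineno
                )
            ids = _ints(parts[1:], "refill tile id", cur.lineno)
            if any(v < 0 or v >= t for v in ids):
                raise TrialParseError(
                    f"refill column {col}: tile id out of range for t={t}", cur.lineno
                )
            streams.append(tuple(ids))
        matches.append(MatchRecord(move, tuple(streams)))
    if cur.i < len(cur.lines) and any(l.strip() for l in cur.lines[cur.i :]):
        raise TrialParseError("trailing content after 4th match block", cur.i + 1)
    return Trial(level, trial_id, seed, board, tuple(matches))  # type: ignore[arg-type]


def read_trial(path: str | Path) -> Trial:
    """Read and structurally re-check a trial file."""
    return trial_from_text(Path(path).read_text(encoding="utf-8"))


def validate_trial(trial: Trial, check_single_run3: bool = True) -> ValidationReport:
    """Replay a trial using only the core mechanics and the brute-force
    swap oracle (independent of the template code the generator uses).

    Per board: stability, exactly one valid move, agreement with the stored
    solution, and (optionally) that the move creates exactly one run of
    exactly three tiles; resolution with the stored refill must produce the
    next full, stable board. Reports the first violation instead of raising.
    """
    failures: list[str] = []
    if len(trial.matches) != BOARDS_PER_TRIAL:
        failures.append(
            f"trial has {len(trial.matches)} match blocks, expected {BOARDS_PER_TRIAL}"
        )
        return ValidationReport(False, failures)
    board = trial.initial_board
    for i, match in enumerate(trial.matches, start=1):
        if board.h != trial.level.h or board.w != trial.level.w:
            failures.append(f"board {i}: dimensions {board.w}x{board.h} != level")
            break
        try:
            board.validate_tiles(trial.level.t)
        except BoardError as exc:
            failures.append(f"board {i}: {exc}")
            break
        if not is_stable(board):
            failures.append(f"board {i}: unstable (contains a run)")
            break
        moves = enumerate_valid_moves(board)
        if len(moves) != 1:
            failures.append(f"board {i}: {len(moves)} valid moves")
            break
        if moves != {match.solution_move}:
            failures.append(
                f"board {i}: stored solution {match.solution_move} is not the valid move"
            )
            break
        after = apply_swap(board, match.solution_move)
        runs = find_runs(after)
        if check_single_run3 and (len(runs) != 1 or len(runs[0]) != 3):
            failures.append(
                f"board {i}: solution creates {len(runs)} runs "
                f"(lengths {[len(r) for r in runs]}), expected one run of three"
            )
            break
        try:
            board = resolve_match(after, match.refill)
        except BoardError as exc:
            failures.append(f"board {i}: refill rejected: {exc}")
            break
        if i == BOARDS_PER_TRIAL and not is_stable(board):
            failures.append("post-trial board: unstable after final stored refill")
    return ValidationReport(not failures, failures)
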