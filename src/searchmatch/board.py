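"""Match-3 board mechanics.

A board is a dense ``h x w`` grid of integer tile identifiers. Coordinates
are 0-based ``(row, col)`` with row 0 at the top; gravity pulls tiles toward
higher row indices, so refill tiles enter at row 0.

A *run* is a maximal horizontal or vertical sequence of at least three
identical tiles. A *move* swaps two orthogonally adjacent tiles and is valid
only when it creates at least one run. Resolving a match removes every cell
that belongs to a run, lets the survivors fall, and fills the vacated top
cells from per-column refill streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

Cell = tuple[int, int]

__all__ = [
    "Cell",
    "Move",
    "Run",
    "Board",
    "BoardError",
    "StabilityError",
    "RefillError",
    "find_runs",
    "is_stable",
    "enumerate_valid_moves",
    "apply_swap",
    "resolve_match",
]


class BoardError(ValueError):
    """Malformed board, move or refill input."""


class StabilityError(BoardError):
    """An operation that requires a stable (run-free) board was given an
    unstable one, or vice versa."""


class RefillError(BoardError):
    """Refill stream does not match the number of removed cells per column."""


@dataclass(frozen=True, order=True)
class Move:
    """An unordered swap of two orthogonally adjacent cells.

    Stored in canonical form: ``a`` precedes ``b`` in ``(row, col)`` order,
    so ``Move(x, y) == Move(y, x)``.
    """

    a: Cell
    b: Cell

    def __post_init__(self) -> None:
        a = (int(self.a[0]), int(self.a[1]))
        b = (int(self.b[0]), int(self.b[1]))
        if a == b:
            raise BoardError(f"move cells must differ, got {a} twice")
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
            raise BoardError(f"move cells must be orthogonally adjacent: {a}, {b}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def cells(self) -> tuple[Cell, Cell]:
        return (self.a, self.b)

    def translate(self, dr: int, dc: int) -> "Move":
        return Move((self.a[0] + dr, self.a[1] + dc), (self.b[0] + dr, self.b[1] + dc))


@dataclass(frozen=True)
class Run:
    """A maximal straight line of >= 3 identical tiles."""

    cells: tuple[Cell, ...]
    tile: int
    orientation: str  # "horizontal" | "vertical"

    def __len__(self) -> int:
        return len(self.cells)


class Board:
    """Immutable rectangular grid of tile identifiers (value semantics)."""

    __slots__ = ("_grid",)

    def __init__(self, grid: Iterable[Iterable[int]] | np.ndarray):
        try:
            arr = np.array(grid, dtype=np.int16)
        except ValueError as exc:
            raise BoardError(f"malformed board grid: {exc}") from None
        if arr.ndim != 2:
            raise BoardError(f"board grid must be 2-dimensional, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise BoardError(f"board must be non-empty, got shape {arr.shape}")
        if (arr < 0).any():
            raise BoardError("tile identifiers must be non-negative")
        arr.flags.writeable = False
        self._grid = arr

    @property
    def grid(self) -> np.ndarray:
        """Read-only ``h x w`` array view of the tiles."""
        return self._grid

    @property
    def h(self) -> int:
        return self._grid.shape[0]

    @property
    def w(self) -> int:
        return self._grid.shape[1]

    def tile(self, cell: Cell) -> int:
        return int(self._grid[cell])

    def validate_tiles(self, t: int) -> None:
        """Check every tile id lies in ``[0, t)``."""
        if (self._grid >= t).any():
            bad = int(self._grid.max())
            raise BoardError(f"tile id {bad} out of range for t={t}")

    def in_bounds(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.h and 0 <= c < self.w

    def rows(self) -> list[list[int]]:
        return self._grid.tolist()

    def to_lines(self) -> list[str]:
        """Serialize as ``h`` lines of ``w`` space-separated integers."""
        return [" ".join(str(v) for v in row) for row in self.rows()]

    @classmethod
    def from_lines(cls, lines: Sequence[str]) -> "Board":
        rows = [[int(v) for v in line.split()] for line in lines]
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise BoardError(f"ragged board: row widths {sorted(widths)}")
        return cls(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Board):
            return NotImplemented
        return self._grid.shape == other._grid.shape and bool(
            (self._grid == other._grid).all()
        )

    def __hash__(self) -> int:
        return hash((self._grid.shape, self._grid.tobytes()))

    def __repr__(self) -> str:
        body = "/".join(" ".join(str(v) for v in row) for row in self.rows())
        return f"Board({self.w}x{self.h}: {body})"


def find_runs(board: Board) -> list[Run]:
    """Return every maximal horizontal/vertical run of length >= 3.

    An empty result means the board is *stable*: no tiles would
    auto-eliminate.
    """
    rows = board.rows()
    h, w = board.h, board.w
    runs: list[Run] = []
    for r in range(h):
        row = rows[r]
        c = 0
        while c < w:
            c2 = c + 1
            while c2 < w and row[c2] == row[c]:
                c2 += 1
            if c2 - c >= 3:
                runs.append(
                    Run(tuple((r, cc) for cc in range(c, c2)), row[c], "horizontal")
                )
            c = c2
    for c in range(w):
        r = 0
        while r < h:
            r2 = r + 1
            while r2 < h and rows[r2][c] == rows[r][c]:
                r2 += 1
            if r2 - r >= 3:
                runs.append(
                    Run(tuple((rr, c) for rr in range(r, r2)), rows[r][c], "vertical")
                )
            r = r2
    return runs


def is_stable(board: Board) -> bool:
    """True iff the board contains no run (nothing would auto-eliminate)."""
    g = board.grid
    if g.shape[1] >= 3:
        h3 = (g[:, 2:] == g[:, 1:-1]) & (g[:, 1:-1] == g[:, :-2])
        if h3.any():
            return False
    if g.shape[0] >= 3:
        v3 = (g[2:, :] == g[1:-1, :]) & (g[1:-1, :] == g[:-2, :])
        if v3.any():
            return False
    return True


def _has_any_run(rows: list[list[int]], h: int, w: int) -> bool:
    for r in range(h):
        row = rows[r]
        for c in range(w - 2):
            if row[c] == row[c + 1] == row[c + 2]:
                return True
    for c in range(w):
        for r in range(h - 2):
            if rows[r][c] == rows[r + 1][c] == rows[r + 2][c]:
                return True
    return False


def enumerate_valid_moves(board: Board) -> set[Move]:
    """Brute-force enumeration of all valid moves on a stable board.

    Tries every orthogonally adjacent swap and keeps those that create at
    least one run. Swapping two identical tiles changes nothing and is never
    valid. Raises :class:`StabilityError` on an unstable board, where "the
    swap created this run" is ill-defined.
    """
    if not is_stable(board):
        raise StabilityError("enumerate_valid_moves requires a stable board")
    rows = board.rows()
    h, w = board.h, board.w
    moves: set[Move] = set()
    for r in range(h):
        for c in range(w):
            for r2, c2 in ((r, c + 1), (r + 1, c)):
                if r2 >= h or c2 >= w:
                    continue
                if rows[r][c] == rows[r2][c2]:
                    continue
                rows[r][c], rows[r2][c2] = rows[r2][c2], rows[r][c]
                if _has_any_run(rows, h, w):
                    moves.add(Move((r, c), (r2, c2)))
                rows[r][c], rows[r2][c2] = rows[r2][c2], rows[r][c]
    return moves


def apply_swap(board: Board, move: Move) -> Board:
    """Return a new board with the two tiles of ``move`` exchanged."""
    if not (board.in_bounds(move.a) and board.in_bounds(move.b)):
        raise BoardError(f"move {move} out of bounds for {board.w}x{board.h} board")
    g = board.grid.copy()
    g[move.a], g[move.b] = g[move.b], g[move.a]
    return Board(g)


def _normalize_refill(refill: Sequence[Sequence[int]], w: int) -> tuple[tuple[int, ...], ...]:
    streams = tuple(tuple(int(v) for v in col) for col in refill)
    if len(streams) != w:
        raise RefillError(f"refill must provide {w} column streams, got {len(streams)}")
    return streams


def resolve_match(board: Board, refill: Sequence[Sequence[int]]) -> Board:
    """Remove all run cells, apply gravity, and refill from the top.

    ``refill`` holds one stream per column (index 0 = leftmost); the first
    element of a stream ends up highest. Each stream must contain exactly as
    many tiles as that column loses. The resolution itself may leave new
    runs on the result; callers that need a stable outcome must check.
    """
    runs = find_runs(board)
    if not runs:
        raise StabilityError("resolve_match requires at least one run")
    streams = _normalize_refill(refill, board.w)
    removed: set[Cell] = set()
    for run in runs:
        removed.update(run.cells)
    rows = board.rows()
    new_cols: list[list[int]] = []
    for c in range(board.w):
        survivors = [rows[r][c] for r in range(board.h) if (r, c) not in removed]
        need = board.h - len(survivors)
        if len(streams[c]) != need:
            raise RefillError(
                f"column {c}: refill stream has {len(streams[c])} tiles, needs {need}"
            )
        new_cols.append(list(streams[c]) + survivors)
    grid = [[new_cols[c][r] for c in range(board.w)] for r in range(board.h)]
    return Board(grid)
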