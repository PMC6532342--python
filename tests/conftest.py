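import numpy as np
import pytest
from hypothesis import settings

from searchmatch import Board, LevelSpec, generate_trial

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# A 4x4 stable board with exactly one valid move: swap (3,2)<->(3,3) turns
# the bottom row into 0 0 0 1.
BOARD_W_ROWS = [
    [0, 1, 2, 3],
    [1, 2, 3, 0],
    [2, 3, 1, 1],
    [0, 0, 1, 0],
]


@pytest.fixture
def board_w() -> Board:
    return Board(BOARD_W_ROWS)


@pytest.fixture
def latin_board() -> Board:
    return Board([[0, 1, 2, 3], [1, 2, 3, 0], [2, 3, 0, 1], [3, 0, 1, 2]])


@pytest.fixture(scope="session")
def trial_bank():
    """A few pregenerated trials per square level, shared across tests."""
    bank = {}
    for w in (4, 5, 6, 7, 8):
        level = LevelSpec(w, w, w)
        trials = []
        seed = 0
        while len(trials) < 2:
            t = generate_trial(level, seed)
            seed += 1
            if hasattr(t, "matches"):
                trials.append(t)
        bank[(w, w, w)] = trials
    return bank


# ---------------------------------------------------------------------------
# Independent oracles (no shared code with the package internals beyond the
# Board container): exhaustive run scan and swap-everything move search.
# ---------------------------------------------------------------------------

def oracle_runs(rows):
    """All maximal runs >= 3 as (frozenset of cells, tile, orientation)."""
    h, w = len(rows), len(rows[0])
    found = []
    for r in range(h):
        c = 0
        while c < w:
            c2 = c
            while c2 < w and rows[r][c2] == rows[r][c]:
                c2 += 1
            if c2 - c >= 3:
                found.append(
                    (frozenset((r, cc) for cc in range(c, c2)), rows[r][c], "horizontal")
                )
            c = c2
    for c in range(w):
        r = 0
        while r < h:
            r2 = r
            while r2 < h and rows[r2][c] == rows[r][c]:
                r2 += 1
            if r2 - r >= 3:
                found.append(
                    (frozenset((rr, c) for rr in range(r, r2)), rows[r][c], "vertical")
                )
            r = r2
    return found


def oracle_valid_moves(rows):
    """Every adjacent swap that creates a run, as canonical frozen pairs."""
    h, w = len(rows), len(rows[0])
    moves = set()
    for r in range(h):
        for c in range(w):
            for r2, c2 in ((r, c + 1), (r + 1, c)):
                if r2 >= h or c2 >= w:
                    continue
                rows[r][c], rows[r2][c2] = rows[r2][c2], rows[r][c]
                if oracle_runs(rows):
                    moves.add(frozenset({(r, c), (r2, c2)}))
                rows[r][c], rows[r2][c2] = rows[r2][c2], rows[r][c]
    return moves


def random_stable_rows(rng, h, w, t):
    """Rejection-sample a stable board as plain lists."""
    while True:
        rows = rng.integers(0, t, size=(h, w)).tolist()
        if not oracle_runs(rows):
            return rows
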