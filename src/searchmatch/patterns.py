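"""Target and distractor pattern taxonomy.

A *target pattern* is a configuration of three identical tiles that a single
swap of two orthogonally adjacent cells turns into a horizontal or vertical
line of three. Enumerated up to translation (orientations and reflections
counted separately) there are 16 such configurations, which collapse into
3 families under the symmetries of the square:

* ``J`` — a pair of adjacent identical tiles plus a third tile diagonal to
  one end of the pair (8 templates),
* ``V`` — two identical tiles separated by one cell, with the third tile
  orthogonally beside the gap (4 templates),
* ``i`` — two adjacent identical tiles plus a third collinear tile one cell
  beyond the gap (4 templates).

*Distractor patterns* are near-targets: a pair of adjacent identical tiles
plus a third tile displaced by one cell from a target's third-tile position,
such that no adjacent swap creates a line. The displacement rule is
documented best-effort (see :func:`enumerate_distractor_templates`).

Template scanning doubles as a fast, independent route to counting valid
moves on a board, cross-checkable against the brute-force swap enumeration
in :mod:`searchmatch.board`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .board import Board, Cell, Move, StabilityError, apply_swap, find_runs, is_stable

__all__ = [
    "PatternTemplate",
    "DistractorTemplate",
    "enumerate_target_templates",
    "classify_symmetry_families",
    "template_moves",
    "count_target_moves",
    "enumerate_distractor_templates",
    "templates_to_json",
]


@dataclass(frozen=True)
class PatternTemplate:
    """A 3-tile pre-swap configuration with its unique completing swap.

    ``offsets`` are relative cells normalized so the lexicographically
    smallest is ``(0, 0)``; ``completing_move`` is expressed in the same
    relative frame. ``orientation`` is that of the line the move completes.
    """

    offsets: tuple[Cell, Cell, Cell]
    completing_move: Move
    family: str  # "J" | "V" | "i"
    orientation: str  # "horizontal" | "vertical"


@dataclass(frozen=True)
class DistractorTemplate:
    """A near-target 3-tile configuration admitting no match-creating swap."""

    offsets: tuple[Cell, Cell, Cell]
    derived_from: str  # family of the target template it deviates from
    type_label: str  # "A" | "B" | "C"


def _normalize(cells: Iterable[Cell]) -> tuple[tuple[Cell, ...], Cell]:
    """Translate so the lexicographically smallest cell is (0, 0).

    Returns the sorted offsets and the shift that was subtracted.
    """
    cs = sorted(cells)
    dr, dc = cs[0]
    return tuple((r - dr, c - dc) for r, c in cs), (dr, dc)


def _has_adjacent_pair(cells: Iterable[Cell]) -> bool:
    cs = list(cells)
    for i in range(len(cs)):
        for j in range(i + 1, len(cs)):
            if abs(cs[i][0] - cs[j][0]) + abs(cs[i][1] - cs[j][1]) == 1:
                return True
    return False


def _is_collinear(cells: Iterable[Cell]) -> bool:
    cs = list(cells)
    return len({r for r, _ in cs}) == 1 or len({c for _, c in cs}) == 1


def _classify_family(offsets: tuple[Cell, ...]) -> str:
    if not _has_adjacent_pair(offsets):
        return "V"
    if _is_collinear(offsets):
        return "i"
    return "J"


def enumerate_target_templates() -> list[PatternTemplate]:
    """Brute-force enumeration of all 3-tile configurations completable by
    one adjacent swap.

    For each line orientation, every outside cell adjacent to a line cell is
    a position from which a tile can be swapped into the line; the pre-swap
    configuration is the line with that cell substituted for the swap
    target. Configurations are deduplicated up to translation; rotations and
    reflections remain distinct. Deterministic, sorted by normalized
    offsets.
    """
    seen: dict[tuple[Cell, ...], PatternTemplate] = {}
    for orientation, line in (
        ("horizontal", ((0, 0), (0, 1), (0, 2))),
        ("vertical", ((0, 0), (1, 0), (2, 0))),
    ):
        line_set = set(line)
        for dest in line:
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                origin = (dest[0] + dr, dest[1] + dc)
                if origin in line_set:
                    continue
                config = (line_set - {dest}) | {origin}
                offsets, (sr, sc) = _normalize(config)
                if offsets in seen:
                    continue
                move = Move(dest, origin).translate(-sr, -sc)
                seen[offsets] = PatternTemplate(
                    offsets=offsets,  # type: ignore[arg-type]
                    completing_move=move,
                    family=_classify_family(offsets),
                    orientation=orientation,
                )
    return [seen[k] for k in sorted(seen)]


_D4 = (
    lambda r, c: (r, c),
    lambda r, c: (c, -r),
    lambda r, c: (-r, -c),
    lambda r, c: (-c, r),
    lambda r, c: (r, -c),
    lambda r, c: (-r, c),
    lambda r, c: (c, r),
    lambda r, c: (-c, -r),
)


def _orbit_key(offsets: Iterable[Cell]) -> tuple[Cell, ...]:
    """Canonical representative of a configuration's orbit under the
    8 symmetries of the square (4 rotations x reflection)."""
    images = []
    for f in _D4:
        cells = [f(r, c) for r, c in offsets]
        dr = min(r for r, _ in cells)
        dc = min(c for _, c in cells)
        images.append(tuple(sorted((r - dr, c - dc) for r, c in cells)))
    return min(images)


def classify_symmetry_families(
    templates: list[PatternTemplate],
) -> dict[str, list[PatternTemplate]]:
    """Partition templates into orbits under the dihedral symmetries of the
    square; orbits are labelled by the shared family (J/V/i) of their
    members."""
    orbits: dict[tuple[Cell, ...], list[PatternTemplate]] = {}
    for tpl in templates:
        orbits.setdefault(_orbit_key(tpl.offsets), []).append(tpl)
    partition: dict[str, list[PatternTemplate]] = {}
    for members in orbits.values():
        families = {m.family for m in members}
        if len(families) != 1:
            raise ValueError(f"orbit mixes families {families}")
        label = families.pop()
        if label in partition:
            raise ValueError(f"two distinct orbits share family label {label}")
        partition[label] = sorted(members, key=lambda m: m.offsets)
    return partition


# Precomputed sliding-scan data: offsets shifted to a non-negative bounding
# box, with the completing move in the same frame.
def _scan_data() -> list[tuple[tuple[Cell, Cell, Cell], Move, int, int]]:
    data = []
    for tpl in enumerate_target_templates():
        dr = min(r for r, _ in tpl.offsets)
        dc = min(c for _, c in tpl.offsets)
        offs = tuple((r - dr, c - dc) for r, c in tpl.offsets)
        move = tpl.completing_move.translate(-dr, -dc)
        bh = max(r for r, _ in offs) + 1
        bw = max(c for _, c in offs) + 1
        for r, c in move.cells:
            assert 0 <= r < bh and 0 <= c < bw
        data.append((offs, move, bh, bw))
    return data


_SCAN: list[tuple[tuple[Cell, Cell, Cell], Move, int, int]] | None = None


def template_moves(board: Board) -> set[Move]:
    """All valid moves on a stable board, found by sliding every target
    template over the grid and collecting the completing swaps.

    On a stable board this is exactly the set of match-creating swaps: every
    run a swap creates passes through a swapped cell, and the run's other
    two tiles plus the moved tile form a target configuration pre-swap.
    """
    global _SCAN
    if _SCAN is None:
        _SCAN = _scan_data()
    if not is_stable(board):
        raise StabilityError("template_moves requires a stable board")
    g = board.grid
    h, w = g.shape
    moves: set[Move] = set()
    for offs, move, bh, bw in _SCAN:
        if bh > h or bw > w:
            continue
        (r0, c0), (r1, c1), (r2, c2) = offs
        v0 = g[r0 : r0 + h - bh + 1, c0 : c0 + w - bw + 1]
        v1 = g[r1 : r1 + h - bh + 1, c1 : c1 + w - bw + 1]
        v2 = g[r2 : r2 + h - bh + 1, c2 : c2 + w - bw + 1]
        hits = np.argwhere((v0 == v1) & (v0 == v2))
        for rr, cc in hits:
            moves.add(move.translate(int(rr), int(cc)))
    return moves


def _grid_stable(g: np.ndarray) -> bool:
    if g.shape[1] >= 3 and ((g[:, 2:] == g[:, 1:-1]) & (g[:, 1:-1] == g[:, :-2])).any():
        return False
    if g.shape[0] >= 3 and ((g[2:, :] == g[1:-1, :]) & (g[1:-1, :] == g[:-2, :])).any():
        return False
    return True


def _unique_move_scan(g: np.ndarray) -> Move | None:
    """Early-exit scan on a raw (stable) grid.

    Returns the unique valid move iff the template scan produces exactly one
    hit overall, else None. A single created run of exactly three tiles
    corresponds to exactly one template hit, so together with a
    one-run-of-three check on the returned move this decides single-target
    acceptance; two or more hits always mean either several distinct moves
    or a move creating a longer/multiple run.
    """
    global _SCAN
    if _SCAN is None:
        _SCAN = _scan_data()
    h, w = g.shape
    total = 0
    found: Move | None = None
    for offs, move, bh, bw in _SCAN:
        if bh > h or bw > w:
            continue
        (r0, c0), (r1, c1), (r2, c2) = offs
        v0 = g[r0 : r0 + h - bh + 1, c0 : c0 + w - bw + 1]
        v1 = g[r1 : r1 + h - bh + 1, c1 : c1 + w - bw + 1]
        mask = v0 == v1
        if not mask.any():
            continue
        v2 = g[r2 : r2 + h - bh + 1, c2 : c2 + w - bw + 1]
        mask &= v0 == v2
        n = int(np.count_nonzero(mask))
        if n == 0:
            continue
        total += n
        if total > 1:
            return None
        rr, cc = np.argwhere(mask)[0]
        found = move.translate(int(rr), int(cc))
    return found


def count_target_moves(board: Board) -> int:
    """Number of canonical valid moves, via the template scan.

    Interchangeable with ``len(enumerate_valid_moves(board))``; the two
    routes are independent and cross-checked in the test suite.
    """
    return len(template_moves(board))


def _isolated_board(offsets: Iterable[Cell]) -> Board:
    """Place the 3-tile configuration (tile 0) on a large board whose other
    cells hold pairwise-distinct filler tiles, so only the configuration can
    participate in any run."""
    cells = list(offsets)
    pad = 3
    h = max(r for r, _ in cells) + 1 + 2 * pad
    w = max(c for _, c in cells) + 1 + 2 * pad
    grid = np.arange(1, h * w + 1, dtype=np.int64).reshape(h, w)
    for r, c in cells:
        grid[r + pad, c + pad] = 0
    return Board(grid)


def _isolated_valid_moves(offsets: Iterable[Cell]) -> set[Move]:
    from .board import enumerate_valid_moves

    return enumerate_valid_moves(_isolated_board(offsets))


_FAMILY_TO_DISTRACTOR_LABEL = {"J": "A", "i": "B", "V": "C"}


def enumerate_distractor_templates() -> list[DistractorTemplate]:
    """Best-effort enumeration of distractor (false-target) patterns.

    Rule: starting from each target template, displace the to-be-moved third
    tile by one orthogonal cell; keep configurations that still contain an
    orthogonally adjacent identical pair, are not a complete line of three,
    are not themselves target templates, and admit no match-creating
    adjacent swap in isolation (verified with the brute-force swap oracle).
    The displacement rule that yields the canonical count is under-specified,
    so the count produced here is reported, not asserted, and nothing in the
    trial generator depends on it.
    """
    targets = {tpl.offsets for tpl in enumerate_target_templates()}
    seen: dict[tuple[Cell, ...], DistractorTemplate] = {}
    for tpl in enumerate_target_templates():
        third = tpl.completing_move.b  # origin of the moved tile in most frames
        # completing_move is canonical (sorted), so identify the origin as
        # the move cell that is part of the configuration.
        in_config = [c for c in tpl.completing_move.cells if c in tpl.offsets]
        if len(in_config) != 1:
            continue
        third = in_config[0]
        pair = [c for c in tpl.offsets if c != third]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            moved = (third[0] + dr, third[1] + dc)
            if moved in pair:
                continue
            config = (*pair, moved)
            offsets, _ = _normalize(config)
            if offsets in seen or offsets in targets:
                continue
            if not _has_adjacent_pair(offsets):
                continue
            if _is_collinear(offsets) and _has_adjacent_pair(
                [offsets[0], offsets[1]]
            ) and _has_adjacent_pair([offsets[1], offsets[2]]):
                continue  # complete line of three
            if _isolated_valid_moves(offsets):
                continue
            seen[offsets] = DistractorTemplate(
                offsets=offsets,  # type: ignore[arg-type]
                derived_from=tpl.family,
                type_label=_FAMILY_TO_DISTRACTOR_LABEL[tpl.family],
            )
    return [seen[k] for k in sorted(seen)]


def templates_to_json(templates: list[PatternTemplate] | None = None) -> str:
    """Export target templates (offsets, completing move, family) as JSON."""
    if templates is None:
        templates = enumerate_target_templates()
    doc = [
        {
            "offsets": [list(c) for c in tpl.offsets],
            "completing_move": [list(tpl.completing_move.a), list(tpl.completing_move.b)],
            "family": tpl.family,
            "orientation": tpl.orientation,
        }
        for tpl in templates
    ]
    return json.dumps(doc, indent=2)


def _verify_template(tpl: PatternTemplate) -> bool:
    """A template's completing move, applied to the isolated configuration,
    must yield exactly one run of exactly three tiles."""
    b = _isolated_board(tpl.offsets)
    pad = 3
    mv = tpl.completing_move.translate(pad, pad)
    runs = find_runs(apply_swap(b, mv))
    return len(runs) == 1 and len(runs[0]) == 3
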