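# Methods

## Task model

The task is a single-target variant of tile-matching match-3 gameplay, cast
as a controlled visual-search paradigm. A board is an `h × w` grid of tile
identifiers drawn from an alphabet of `t` types (cosmetically, up to 8
uniquely colored regular polygons; the engine works on integer ids). A
*run* is a maximal horizontal or vertical line of ≥3 identical tiles; a
*move* swaps two orthogonally adjacent tiles and is valid only when it
creates a run; invalid swaps bounce. Resolving a match removes all run
cells, drops the survivors (gravity toward higher row indices), and fills
the vacated top cells from per-column refill streams, first stream element
ending highest.

Coordinates are 0-based `(row, col)` with row 0 at the top. Moves are
canonical unordered pairs, so a swap and its reverse are the same move.
Swapping two identical tiles changes nothing and is never valid; at the
session level such attempts are logged as false moves, like any other
non-matching swap.

Difficulty is manipulated factorially: set size `w·h` (items to scan) and
the number of tile types `t` (distractor heterogeneity). The level space is
`(w, h) ∈ {4..8}²` with `4 ≤ t ≤ max(w, h)`: 25 board sizes, 95 levels.
With fewer tile types, identical triples are denser, so random boards hold
*more* targets — which is exactly why low-`t`, large-board levels cannot
satisfy the single-target constraint (see feasibility below).

## Target-pattern taxonomy

A target pattern is a 3-tile configuration from which exactly one adjacent
swap produces a line of three. Enumeration is constructive: for each line
orientation, each line cell can be vacated and filled from any orthogonal
neighbour outside the line; the pre-swap configuration is deduplicated up
to translation only, with rotations and reflections counted separately.
This yields 16 templates. Under the 8 symmetries of the square they fall
into 3 orbits, which coincide with the intuitive families: J (pair plus
diagonal third, 8), V (split pair plus flanking third, 4), i (pair plus
collinear third one cell away, 4).

Template scanning provides a second, independent route to move counting: on
a stable board, every run a swap creates passes through a swapped cell, so
the run's two other tiles plus the moved tile form a template placement.
The test suite cross-checks template counting against exhaustive swap
enumeration on tens of thousands of random stable boards; the generator
uses the (faster) template route while the trial validator deliberately
uses only the brute-force oracle.

Distractor (false-target) patterns are enumerated under a documented
best-effort rule — displace a target's to-be-moved tile by one orthogonal
cell, keep configurations with an adjacent identical pair that admit no
match-creating swap — because the canonical displacement rule behind the
published count is under-specified. Our rule yields 32 configurations; the
catalogue is exposed for inspection but nothing in the generator depends on
it, and the count is reported rather than asserted.

## Trial generation

A playable trial is 4 consecutive single-target boards. Acceptance for a
board: stable (no pre-existing run, which would auto-eliminate before any
search), exactly one valid move, and — with the default
`forbid_runs_gt3=True` — that move creates exactly one run of exactly three
tiles. The strict form makes the hint and the per-board search time
unambiguous; the flag exists because longer or double runs are mechanically
representable and some deployments may want them.

Generation is rejection sampling: boards are filled uniformly from the
level alphabet and tested (default budget 10,000 attempts); refills are
sampled uniformly per vacated cell and tested against the successor board's
acceptance (default 2,000 attempts per stage), with one-stage backtracking
and a full restart from a fresh initial board after repeated stage failure
(default 25 restarts). The stored 4th refill only needs a stable successor,
since the trial self-terminates after the 4th correct move. Everything is
driven by `numpy.random.default_rng(seed)`, so a (level, seed, config)
triple maps to a byte-identical trial file.

Feasibility is an empirical property of this constraint system: the
acceptance probability falls steeply with set size at fixed `t` (at
`(8, 8, 4)` effectively zero — random boards contain many targets), so the
playability survey counts distinct playable trials per level within budget
and flags levels reaching the 47-trial selection threshold. The exact
feasible set depends on the search budget and is surveyed, not hard-coded.
Parallel test versions duplicate all square levels and deal rectangular
levels out alternately after sorting by (set size, w, h, t); that sort key
is used everywhere a total order on levels is needed.

## Sessions and logging

The engine is headless and clock-agnostic: every call takes a
caller-supplied timestamp, and elapsed time per move is time since board
onset or since the previous attempt. This makes the engine equally usable
under a GUI, scripted replay, or simulation, and keeps timing out of the
engine's trust boundary. Malformed input (out-of-bounds cells) is rejected
without logging; only genuine swap attempts enter the log, one row per
attempt with level metadata, move number, elapsed time, accuracy, and a
hint flag attached to the correct move it assisted. Difficulty ratings
(1–10) are accepted only after trial completion and propagate to all rows
of the trial.

## Performance metrics

Per-board search time sums the elapsed times of all false moves leading up
to the correct move, plus the correct move itself. Outlier filtering uses
Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` with linearly interpolated
quartiles (the common statistics-package default; no convention was
prescribed), applied once, per grouping, before hint exclusion; groups
under 4 observations pass through with a warning. The filter operates on
board-level search times — the unit in which search time is defined — and
excludes the whole trial containing an outlying board, which is what the
summary's `n_trials_excluded_outlier` counts. Trial-level exclusion needs a
distribution of trials to be meaningful, so the summary applies it only
when a log holds at least 4 trials; shorter logs pass through unfiltered.

Hint-assisted boards are excluded from the without-hints average, the
geometric mean, processing time per item, and the slope. Processing time
per item is search time divided by `w·h`. The search slope (s/item) is
estimated by OLS on per-board search times against set size — simple,
dependency-light, and unbiased for the linear mean structure — with an
optional gamma-family GLM (set size × group interaction) as a
distributional cross-check for the positively skewed times; the GLM
defaults to a log link for numerical stability, with the canonical inverse
link available.

## Synthetic players

The player model is a fixture with known ground truth, not a cognitive
model. Mean search time is linear in set size and tile types, scaled per
group:

```
μ = group_multiplier · max(ε, β₀ + β_s·(w·h) + β_t·t),   ε = 10⁻³ s
```

with gamma noise of shape `k` (scale `μ/k`), matching the positively
skewed response-time distributions the metrics assume. Defaults emulate a
young-adult-like player: `β₀ = 1 s`, `β_s = 0.1 s/item`,
`β_t = −0.05 s/type` (more tile types → easier grouping → faster),
`k = 4`, one false move with probability 0.05 (splitting the drawn time at
a uniform point), hint probability 0.02. Cohort simulations emulating
young/older/oldest age groups use multipliers near 1 / 1.6 / 3.1, the
approximate ratios of the groups' mean search times in the study this task
design targets. Simulated moves are played through the real session engine
against real trials, so every simulated log satisfies the replay property
by construction.

What the simulator does *not* emulate: learning across trials, fatigue,
strategic scan paths, target-location effects, or any fitted human
parameters. Passing recovery tests therefore shows the pipeline measures
what the model injects (effect directions and magnitudes), not that humans
behave like the model.

## Problem sizes and numerical choices

Test-suite simulations are desk-scale by design: oracle-equivalence checks
use ~10,000 random stable boards across mixed level specs; trial-structure
checks replay 100 generated trials across (4,4,4), (5,5,5), (6,6,6); slope
recovery uses 2,000 simulated boards over set sizes 16–64 (50 simulated
participants × 10 trials over the five square levels with `t = w`); group
ordering uses 50 participants per group. Acceptance-rate comparisons use
1,500–2,000 sampled boards per level. Floating-point identities are
asserted to 1e-9; slope recovery to ±0.03 around the injected 0.1 s/item.

Determinism: all randomness flows through seeded `numpy` generators (cohort
simulation derives per-participant substreams from a seed sequence);
template and level enumerations are sorted; trial serialization is
canonical LF-terminated UTF-8, so regression tests can hash files.

## Known limitations

* The distractor-pattern rule is a documented approximation (32 patterns,
  not the canonical 20); only the target taxonomy is load-bearing.
* Feasibility surveys depend on the configured budgets; the shipped
  defaults reproduce the qualitative pattern (small levels comfortably
  exceed 47 trials, large low-`t` levels fail), not any specific published
  level list, and the parallel-version split is computed from whatever
  survey it is given.
* The gamma GLM cross-check is reported with a log link by default; with
  strongly non-linear mean structure the OLS slope and GLM coefficients
  answer different questions.
* No graphical front end, cascade scoring, or timed "classic" match-3 mode.
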