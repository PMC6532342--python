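# searchmatch

An experimentally controlled **single-target match-3 visual-search task**
engine, for researchers who want match-3 ("tile-matching") gameplay with the
measurement properties of a classical visual-search paradigm: every puzzle
board contains exactly one target, so the time to the correct move is an
unambiguous per-display search time.

The package provides, headlessly and fully scripted:

* **Board mechanics** — run detection, swap legality (a move is valid only
  if it creates a horizontal/vertical line of ≥3 identical tiles), match
  resolution with gravity and deterministic refill.
* **Pattern taxonomy** — brute-force enumeration of the 16 three-tile
  *target patterns* (configurations one adjacent swap turns into a line of
  three), their 3 symmetry families (J, V, i with 8/4/4 members), and a
  best-effort catalogue of near-target *distractor patterns*.
* **Difficulty space & trial generator** — the factorial space
  `(w, h) ∈ {4..8}², 4 ≤ t ≤ max(w, h)` (25 board sizes, 95 levels), where
  set size `w·h` and distractor heterogeneity `t` drive difficulty, and a
  constrained generator that rejection-samples *playable trials*: 4
  consecutive single-target boards linked by solved matches and searched
  refills. Levels like (8, 8, 4) are infeasible — random boards hold too
  many targets for single-target acceptance — and the playability survey
  quantifies this.
* **Trial files** — a canonical line-oriented text format with a replay
  validator that uses only the brute-force swap oracle.
* **Session engine** — move submission with bounce-on-invalid, hints that
  disclose the unique move, 1–10 difficulty ratings, and a move-level CSV
  log (elapsed time, accuracy, hint flag per attempted swap).
* **Performance metrics** — per-board search time (false moves summed into
  the correct move), single-pass Tukey-fence outlier filtering
  (`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`), processing time per item
  (search time / `w·h`), search slope (s/item via OLS, optional gamma-GLM
  cross-check), arithmetic and geometric mean search times, false-move and
  hint counts.
* **Synthetic players** — gamma-noise simulated participants with known
  set-size, tile-type and group effects, played through the real engine, so
  the whole pipeline is testable without human data.

## Worked example

```python
import numpy as np
from searchmatch import (LevelSpec, PlayerModel, generate_trial,
                         simulate_trial, summarize_session, trial_to_text)

trial = generate_trial(LevelSpec(4, 4, 4), seed=11)
print(trial_to_text(trial).splitlines()[4:9])   # the initial board block

log, _ = simulate_trial(PlayerModel(p_false=0.5, p_hint=0.2), trial,
                        np.random.default_rng(5))
print(summarize_session(log))
```

prints the 4×4 initial board and a summary such as

```
PerformanceSummary(task_completion_time=0.133, avg_search_time_with_hints=1.999,
    avg_search_time_without_hints=2.124, geometric_mean_search_time=2.053,
    processing_time_per_item=0.133, search_slope=None, n_false_moves=2,
    n_hints=1, n_trials_excluded_outlier=0)
```

i.e. the simulated player took ~0.13 min for the trial, averaged ~2.0 s of
search per board (~2.1 s over hint-free boards; geometric mean 2.05 s),
spent ~0.13 s per display item, made 2 false moves and used 1 hint. The
slope is `None` because a single level has only one set size.

A command-line interface wraps the same functions:

```bash
searchmatch generate-levels
searchmatch generate-trials --w 4 --h 4 --t 4 --n 5 --seed 0 --out trials/
searchmatch validate trials/*.txt
searchmatch simulate --trial trials/w4h4t4-s0.txt --seed 1 --out log.csv
searchmatch metrics log.csv
```

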