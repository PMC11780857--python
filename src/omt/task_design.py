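"""Session schedules for the "What was where?" memory task.

The task shows 1 or 3 fractal stimuli at random screen locations; after a
1 s or 4 s delay the participant identifies the studied item (target vs a
foil not shown that trial) and drags it back to its remembered location.
A session is a practice block of 8 trials followed by three test blocks of
40 trials, 10 trials per (set size x delay) condition per block, giving
120 test trials.

Locations live in a normalised [0, 1]^2 screen space (origin top-left).
Items are placed by rejection sampling subject to an edge margin and a
minimum pairwise separation so that three items never visually overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

N_SHAPES = 49
N_COLOURS = 4

#: (set_size, delay_s) cells of the 2x2 design.
CONDITIONS: tuple[tuple[int, float], ...] = ((1, 1.0), (1, 4.0), (3, 1.0), (3, 4.0))

DEFAULT_MIN_SEPARATION = 0.15
DEFAULT_MARGIN = 0.10
_PLACEMENT_BUDGET = 10_000


@dataclass(frozen=True)
class Stimulus:
    """One fractal: a shape identity in one of four colour variants."""

    shape_id: int
    colour_id: int

    def __post_init__(self) -> None:
        if not (0 <= self.shape_id < N_SHAPES):
            raise ValueError(f"shape_id {self.shape_id} outside [0, {N_SHAPES - 1}]")
        if not (0 <= self.colour_id < N_COLOURS):
            raise ValueError(f"colour_id {self.colour_id} outside [0, {N_COLOURS - 1}]")


@dataclass(frozen=True)
class TrialSpec:
    """Design of a single trial: what was shown where, and the probe pair."""

    trial_id: int
    block: int
    set_size: int
    delay_s: float
    items: tuple[tuple[Stimulus, tuple[float, float]], ...]
    target_index: int
    foil: Stimulus

    def __post_init__(self) -> None:
        if len(self.items) != self.set_size:
            raise ValueError("items length must equal set_size")
        if not (0 <= self.target_index < self.set_size):
            raise ValueError("target_index out of range")
        stimuli = [s for s, _ in self.items]
        if self.foil in stimuli:
            raise ValueError("foil must not appear among the trial's items")
        if len(set(stimuli)) != len(stimuli):
            raise ValueError("duplicate stimulus within trial")

    @property
    def target_location(self) -> tuple[float, float]:
        return self.items[self.target_index][1]

    @property
    def distractor_locations(self) -> tuple[tuple[float, float], ...]:
        """Locations of the non-probed in-trial items (empty at set size 1)."""
        return tuple(
            loc for i, (_, loc) in enumerate(self.items) if i != self.target_index
        )


@dataclass(frozen=True)
class ScheduleConfig:
    blocks: int = 3
    trials_per_condition_per_block: int = 10
    practice_trials: int = 8
    min_separation: float = DEFAULT_MIN_SEPARATION
    margin: float = DEFAULT_MARGIN


def build_stimulus_library() -> list[Stimulus]:
    """All 196 distinct (shape, colour) fractals, in deterministic order."""
    return [Stimulus(s, c) for s, c in product(range(N_SHAPES), range(N_COLOURS))]


def sample_locations(
    set_size: int,
    rng: np.random.Generator,
    *,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    margin: float = DEFAULT_MARGIN,
    budget: int = _PLACEMENT_BUDGET,
) -> np.ndarray:
    """Rejection-sample `set_size` locations with pairwise separation.

    Returns an (set_size, 2) array inside [margin, 1 - margin]^2 with all
    pairwise Euclidean distances >= min_separation. Raises RuntimeError when
    the budget is exhausted (separation infeasible for the region).
    """
    lo, hi = margin, 1.0 - margin
    if hi <= lo:
        raise ValueError("margin leaves no placement region")
    for _ in range(budget):
        pts = rng.uniform(lo, hi, size=(set_size, 2))
        if set_size == 1:
            return pts
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        if d[np.triu_indices(set_size, k=1)].min() >= min_separation:
            return pts
    raise RuntimeError(
        f"placement budget ({budget}) exhausted: min_separation={min_separation} "
        f"infeasible for {set_size} items in [{lo}, {hi}]^2"
    )


def _draw_trial(
    trial_id: int,
    block: int,
    set_size: int,
    delay_s: float,
    library: list[Stimulus],
    rng: np.random.Generator,
    cfg: ScheduleConfig,
) -> TrialSpec:
    idx = rng.choice(len(library), size=set_size, replace=False)
    stimuli = [library[i] for i in idx]
    locs = sample_locations(
        set_size, rng, min_separation=cfg.min_separation, margin=cfg.margin
    )
    target_index = int(rng.integers(set_size))
    # Foil: uniform over the library minus this trial's items.
    while True:
        foil = library[int(rng.integers(len(library)))]
        if foil not in stimuli:
            break
    return TrialSpec(
        trial_id=trial_id,
        block=block,
        set_size=set_size,
        delay_s=delay_s,
        items=tuple((s, (float(x), float(y))) for s, (x, y) in zip(stimuli, locs)),
        target_index=target_index,
        foil=foil,
    )


def make_session_schedule(
    seed: int | np.random.Generator,
    blocks: int = 3,
    trials_per_condition_per_block: int = 10,
    practice_trials: int = 8,
    *,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    margin: float = DEFAULT_MARGIN,
) -> tuple[list[TrialSpec], list[TrialSpec]]:
    """Build (practice, test) trial lists for one session.

    Within each test block every (set size, delay) condition appears exactly
    `trials_per_condition_per_block` times, in a freshly permuted order per
    block. Identical seeds give bit-identical schedules.
    """
    if blocks < 1 or trials_per_condition_per_block < 1:
        raise ValueError("blocks and trials_per_condition_per_block must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cfg = ScheduleConfig(
        blocks, trials_per_condition_per_block, practice_trials, min_separation, margin
    )
    library = build_stimulus_library()

    practice: list[TrialSpec] = []
    for t in range(practice_trials):
        ss, dl = CONDITIONS[int(rng.integers(len(CONDITIONS)))]
        practice.append(_draw_trial(-(t + 1), 0, ss, dl, library, rng, cfg))

    test: list[TrialSpec] = []
    trial_id = 0
    for block in range(1, blocks + 1):
        cells = [c for c in CONDITIONS for _ in range(trials_per_condition_per_block)]
        order = rng.permutation(len(cells))
        for k in order:
            ss, dl = cells[k]
            test.append(_draw_trial(trial_id, block, ss, dl, library, rng, cfg))
            trial_id += 1
    return practice, test


def validate_schedule(test: list[TrialSpec], cfg: ScheduleConfig | None = None) -> None:
    """Assert the schedule invariants (condition balance, geometry, foils)."""
    cfg = cfg or ScheduleConfig()
    per_block: dict[tuple[int, tuple[int, float]], int] = {}
    for tr in test:
        per_block[(tr.block, (tr.set_size, tr.delay_s))] = (
            per_block.get((tr.block, (tr.set_size, tr.delay_s)), 0) + 1
        )
        locs = np.array([loc for _, loc in tr.items])
        if np.any(locs < cfg.margin - 1e-12) or np.any(locs > 1 - cfg.margin + 1e-12):
            raise AssertionError(f"trial {tr.trial_id}: item outside placement region")
        for a, b in combinations(range(len(locs)), 2):
            if np.linalg.norm(locs[a] - locs[b]) < cfg.min_separation - 1e-12:
                raise AssertionError(f"trial {tr.trial_id}: items too close")
        if tr.foil in [s for s, _ in tr.items]:
            raise AssertionError(f"trial {tr.trial_id}: foil collides with items")
    counts = set(per_block.values())
    if len(counts) != 1:
        raise AssertionError(f"unbalanced conditions per block: {per_block}")


def schedule_to_records(trials: list[TrialSpec]) -> list[dict]:
    """Flatten trials to CSV/JSON-ready dicts (one row per trial)."""
    rows = []
    for tr in trials:
        row: dict = {
            "trial_id": tr.trial_id,
            "block": tr.block,
            "set_size": tr.set_size,
            "delay_s": tr.delay_s,
            "target_index": tr.target_index,
            "foil_shape": tr.foil.shape_id,
            "foil_colour": tr.foil.colour_id,
        }
        for i in range(3):
            if i < len(tr.items):
                s, (x, y) = tr.items[i]
                row |= {
                    f"item{i}_shape": s.shape_id,
                    f"item{i}_colour": s.colour_id,
                    f"item{i}_x": x,
                    f"item{i}_y": y,
                }
            else:
                row |= {
                    f"item{i}_shape": np.nan,
                    f"item{i}_colour": np.nan,
                    f"item{i}_x": np.nan,
                    f"item{i}_y": np.nan,
                }
        rows.append(row)
    return rows


def records_to_schedule(rows: list[dict]) -> list[TrialSpec]:
    """Inverse of :func:`schedule_to_records`."""
    trials = []
    for row in rows:
        items = []
        for i in range(3):
            shape = row.get(f"item{i}_shape")
            if shape is None or (isinstance(shape, float) and np.isnan(shape)):
                break
            items.append(
                (
                    Stimulus(int(shape), int(row[f"item{i}_colour"])),
                    (float(row[f"item{i}_x"]), float(row[f"item{i}_y"])),
                )
            )
        trials.append(
            TrialSpec(
                trial_id=int(row["trial_id"]),
                block=int(row["block"]),
                set_size=int(row["set_size"]),
                delay_s=float(row["delay_s"]),
                items=tuple(items),
                target_index=int(row["target_index"]),
                foil=Stimulus(int(row["foil_shape"]), int(row["foil_colour"])),
            )
        )
    return trials
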