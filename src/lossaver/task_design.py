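"""Mixed-gamble task design: the 16 x 16 gain/loss grid and trial sampling.

The task presents sequential 50/50 mixed gambles (win ``gain`` or lose
``loss``, versus a certain status quo of $0).  Gains run $10-$40 in $2
steps, losses $5-$20 in $1 steps, yielding a 256-cell grid from which the
default 128-trial design is drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GAIN_LEVELS",
    "LOSS_LEVELS",
    "N_TRIALS_DEFAULT",
    "P_WIN",
    "Gamble",
    "TaskDesign",
    "enumerate_grid",
    "generate_design",
    "read_design",
    "write_design",
]

GAIN_LEVELS: tuple[int, ...] = tuple(range(10, 41, 2))  # $10-$40 step $2
LOSS_LEVELS: tuple[int, ...] = tuple(range(5, 21, 1))  # $5-$20 step $1
N_TRIALS_DEFAULT: int = 128
P_WIN: float = 0.5


@dataclass(frozen=True)
class Gamble:
    """One 50/50 mixed gamble: win ``gain`` dollars or lose ``loss`` dollars.

    ``loss`` is stored as a positive magnitude.
    """

    gain: int
    loss: int
    p_win: float = P_WIN

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.loss <= 0:
            raise ValueError(
                f"gain and loss must be positive magnitudes, got {self.gain}, {self.loss}"
            )
        if self.p_win != P_WIN:
            raise ValueError(f"p_win is fixed at {P_WIN}, got {self.p_win}")

    @property
    def expected_value(self) -> float:
        return self.p_win * self.gain - (1.0 - self.p_win) * self.loss


@dataclass
class TaskDesign:
    """An ordered sequence of gambles presented to one or more subjects."""

    trials: list[Gamble]
    seed: int | None = None
    stratified: bool = field(default=True, repr=False)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(1, len(self.trials) + 1),
                "gain": [g.gain for g in self.trials],
                "loss": [g.loss for g in self.trials],
            }
        )


def enumerate_grid() -> list[Gamble]:
    """Full Cartesian grid of gain levels x loss levels (256 gambles)."""
    return [Gamble(gain=g, loss=l) for g in GAIN_LEVELS for l in LOSS_LEVELS]


def _latin_rectangle(n_rounds: int, rng: np.random.Generator) -> np.ndarray:
    """Rows of a randomized cyclic Latin square on 16 symbols.

    Row r maps gain slot j to loss slot pi[(sigma[j] + offset_r) % 16],
    so within each row every gain level and every loss level appears once,
    and no (gain, loss) pair repeats across rows.
    """
    k = len(GAIN_LEVELS)
    pi = rng.permutation(k)
    sigma = rng.permutation(k)
    offsets = rng.permutation(k)[:n_rounds]
    return np.stack([pi[(sigma + off) % k] for off in offsets])


def generate_design(
    n_trials: int = N_TRIALS_DEFAULT,
    seed: int | None = None,
    stratified: bool = True,
) -> TaskDesign:
    """Sample a seed-reproducible design of ``n_trials`` unique gambles.

    With ``stratified=True`` (default) and ``n_trials`` a multiple of 16,
    every gain level and every loss level appears exactly ``n_trials // 16``
    times (8 times each in the default 128-trial design).  Otherwise gambles
    are drawn uniformly without replacement from the grid.

    Raises
    ------
    ValueError
        If ``n_trials`` exceeds the 256-cell grid.
    """
    grid = enumerate_grid()
    if n_trials > len(grid):
        raise ValueError(
            f"n_trials={n_trials} exceeds the {len(grid)}-cell gain/loss grid"
        )
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)

    k = len(GAIN_LEVELS)
    if stratified and n_trials % k == 0:
        rows = _latin_rectangle(n_trials // k, rng)
        gambles = [
            Gamble(gain=GAIN_LEVELS[j], loss=LOSS_LEVELS[rows[r, j]])
            for r in range(rows.shape[0])
            for j in range(k)
        ]
    else:
        idx = rng.choice(len(grid), size=n_trials, replace=False)
        gambles = [grid[i] for i in idx]

    order = rng.permutation(len(gambles))
    return TaskDesign(
        trials=[gambles[i] for i in order], seed=seed, stratified=stratified
    )


def write_design(design: TaskDesign, path) -> None:
    """Write a trial-list CSV with columns trial_index, gain, loss."""
    design.to_frame().to_csv(path, index=False)


def read_design(path) -> TaskDesign:
    """Read a trial-list CSV written by :func:`write_design`."""
    df = pd.read_csv(path)
    missing = {"gain", "loss"} - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    if "trial_index" in df.columns:
        df = df.sort_values("trial_index")
    trials = [Gamble(gain=int(r.gain), loss=int(r.loss)) for r in df.itertuples()]
    return TaskDesign(trials=trials, seed=None)
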