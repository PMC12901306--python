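"""Colour-bandit task: stimulus statistics and experiment generation.

The task presents sequences of choices between two options (shapes).  Each
option is tied to one of two outcome-generating categories — *orange-dominant*
or *blue-dominant* — and every choice reveals a colour shade drawn from the
chosen option's category.  Shades live on a continuum from −1 (saturated blue)
to +1 (saturated orange) and are constructed so that the log likelihood ratio
(logLR) between the two categories is linear in the shade:

    logLR(c) = log(p(c | orange) / p(c | blue)) = k * c

with ``k`` fixed so that the most saturated shade carries 1.4 logLR units.
A dominant-colour category produces a dominant-side shade with probability
2/3.  Per trial the *magnitude* of the shade is shared between the two
options ("yoked" information), so the information available from either
option is identical; only the sides (signs) differ according to each
option's category.

Three instruction conditions reuse identical stimuli: MATCH (maximise
target-coloured outcomes, immediate reward), GUESS (report each option's
dominant colour at an unpredictable final question) and FIND (identify an
option of a pre-announced target colour at the end).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

ORANGE = 1
BLUE = -1

MATCH = "MATCH"
GUESS = "GUESS"
FIND = "FIND"

SEQUENCE_LENGTHS = (8, 12, 16, 20)
N_SHAPES = 8
SHAPE_PAIRS = tuple(itertools.combinations(range(N_SHAPES), 2))

#: retry cap for the pseudo-randomisation rejection sampler
MAX_RANDOMISATION_RETRIES = 10_000


class ConstraintInfeasibleError(ValueError):
    """No parameter of the outcome distribution meets the requested constraint."""


class GenerationError(RuntimeError):
    """Pseudo-randomisation failed within the retry budget."""


class ConfigError(ValueError):
    """Invalid experiment layout."""


# ---------------------------------------------------------------------------
# Colour space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColourSpace:
    """Discrete shade continuum with per-category outcome distributions.

    Attributes
    ----------
    shades : ndarray
        Ordered shade values in [−1, 1], symmetric about 0, 0 excluded.
    loglr_scale : float
        ``k``, logLR units per unit shade; ``logLR(c) = k*c``.
    pmf_orange, pmf_blue : ndarray
        Outcome probability of each shade under each dominant category.
    p_dominant : float
        Probability of a dominant-side outcome (2/3 in the task).
    """

    shades: np.ndarray
    loglr_scale: float
    pmf_orange: np.ndarray
    pmf_blue: np.ndarray
    p_dominant: float

    @property
    def max_loglr(self) -> float:
        return float(self.loglr_scale * np.max(np.abs(self.shades)))

    @property
    def magnitudes(self) -> np.ndarray:
        """Distinct |shade| values, ascending."""
        return np.unique(np.abs(self.shades))

    def magnitude_pmf(self) -> np.ndarray:
        """Marginal pmf over magnitudes; identical for both categories."""
        cached = getattr(self, "_magnitude_pmf", None)
        if cached is None:
            mags = self.magnitudes
            cached = np.zeros_like(mags)
            for i, m in enumerate(mags):
                cached[i] = self.pmf_orange[np.isclose(np.abs(self.shades), m)].sum()
            object.__setattr__(self, "_magnitude_pmf", cached)
        return cached

    def shade_index(self, c: float) -> int:
        idx = np.flatnonzero(np.isclose(self.shades, c))
        if idx.size != 1:
            raise ValueError(f"shade {c!r} is not in the colour space grid")
        return int(idx[0])


def build_colour_space(
    n_magnitudes: int = 4,
    max_loglr: float = 1.4,
    p_dominant: float = 2.0 / 3.0,
) -> ColourSpace:
    """Construct the shade grid and the two category pmfs.

    The grid holds ``n_magnitudes`` equally spaced magnitudes in (0, 1],
    mirrored to negative shades (0 excluded so every outcome has a dominant
    side).  The orange-category pmf takes the exponential-tilt form

        pmf_orange(c) ∝ base(|c|) * exp(k*c/2),   base(m) ∝ exp(−λ*m)

    which makes ``log(pmf_orange(c)/pmf_blue(c)) = k*c`` hold exactly by
    mirror symmetry; λ is solved numerically so the dominant-side mass equals
    ``p_dominant``.
    """
    if n_magnitudes < 2:
        raise ValueError("n_magnitudes must be ≥ 2")
    if not (0.5 < p_dominant < 1.0):
        raise ValueError("p_dominant must lie in (0.5, 1)")
    if max_loglr <= 0:
        raise ValueError("max_loglr must be positive")

    mags = np.arange(1, n_magnitudes + 1) / n_magnitudes  # (0, 1]
    shades = np.concatenate([-mags[::-1], mags])
    k = max_loglr / mags[-1]

    def dominant_mass(lam: float) -> float:
        base = np.exp(-lam * mags)
        up = base * np.exp(k * mags / 2.0)        # orange-side shades
        down = base * np.exp(-k * mags / 2.0)     # blue-side shades
        return float(up.sum() / (up.sum() + down.sum()))

    lo, hi = -60.0, 60.0
    f_lo, f_hi = dominant_mass(lo) - p_dominant, dominant_mass(hi) - p_dominant
    if f_lo * f_hi > 0:
        raise ConstraintInfeasibleError(
            f"no magnitude tilt achieves p_dominant={p_dominant} with "
            f"{n_magnitudes} magnitudes and max_loglr={max_loglr}"
        )
    lam = brentq(lambda x: dominant_mass(x) - p_dominant, lo, hi, xtol=1e-12)

    base = np.exp(-lam * np.abs(shades))
    pmf_orange = base * np.exp(k * shades / 2.0)
    pmf_orange /= pmf_orange.sum()
    pmf_blue = pmf_orange[::-1].copy()  # mirror symmetry

    return ColourSpace(
        shades=shades,
        loglr_scale=k,
        pmf_orange=pmf_orange,
        pmf_blue=pmf_blue,
        p_dominant=p_dominant,
    )


def shade_loglr(space: ColourSpace, c) -> float | np.ndarray:
    """logLR carried by shade ``c``: ``k*c`` (odd in ``c``).

    Positive values are evidence for the orange category.
    """
    c_arr = np.asarray(c, dtype=float)
    on_grid = np.isclose(np.abs(c_arr)[..., None], np.abs(space.shades)).any(-1)
    if not np.all(on_grid):
        raise ValueError(f"shade(s) {c!r} not in the colour space grid")
    out = space.loglr_scale * c_arr
    return float(out) if np.isscalar(c) or out.ndim == 0 else out


def sample_trial_outcomes(
    space: ColourSpace,
    categories: TypingSequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one trial's yoked outcome shades for a pair of options.

    A single magnitude is drawn from the category-independent magnitude
    distribution and shared by both options; each option's side is then
    sampled independently given its category: an orange-dominant option shows
    the orange side with probability σ(k·m).
    """
    cats = np.asarray(categories)
    if not np.all(np.isin(cats, (ORANGE, BLUE))):
        raise ValueError("categories must be ORANGE (+1) or BLUE (−1)")
    mags = space.magnitudes
    m = rng.choice(mags, p=space.magnitude_pmf())
    p_orange_side = expit(space.loglr_scale * m)
    # dominant-side probability is σ(k·m) toward each option's own category
    p_plus = np.where(cats == ORANGE, p_orange_side, 1.0 - p_orange_side)
    signs = np.where(rng.random(cats.shape) < p_plus, 1.0, -1.0)
    return signs * m


# ---------------------------------------------------------------------------
# Sequences and experiment designs
# ---------------------------------------------------------------------------

@dataclass
class SequenceStimuli:
    """One sequence of a given condition: pre-defined outcomes for both options."""

    sequence_id: int
    condition: str
    length: int
    option_categories: tuple[int, int]
    target_colour: int                      # +1 orange, −1 blue, 0 undefined
    shape_pair: tuple[int, int]
    outcomes: np.ndarray                    # (length, 2) shades
    sides: np.ndarray                       # (length,) side of option 1: 0=left, 1=right
    final_question: tuple[str, int] | None  # ("option", 0|1) or ("colour", ±1)


@dataclass
class DatasetConfig:
    """Layout of one experiment (counts, conditions, block structure)."""

    name: str
    conditions: tuple[str, ...]
    sequences_per_condition: int
    n_blocks: int
    final_question_style: str  # "option" (datasets 1–2) or "colour" (dataset 3)

    @property
    def n_sequences(self) -> int:
        return self.sequences_per_condition * len(self.conditions)

    @property
    def block_size(self) -> int:
        if self.n_sequences % self.n_blocks:
            raise ConfigError(
                f"{self.n_sequences} sequences do not divide into "
                f"{self.n_blocks} blocks"
            )
        size = self.n_sequences // self.n_blocks
        if size % len(self.conditions):
            raise ConfigError(
                f"block size {size} not divisible by {len(self.conditions)} conditions"
            )
        return size


DATASET_CONFIGS = {
    # 48 sequences per condition, 96 total in 8 blocks of 12
    "discovery": DatasetConfig("discovery", (MATCH, GUESS), 48, 8, "option"),
    # 64 per condition, 128 total in 8 blocks of 16
    "replication": DatasetConfig("replication", (MATCH, GUESS), 64, 8, "option"),
    # 32 per condition × 3 conditions, 96 total in 4 blocks of 24
    "third": DatasetConfig("third", (MATCH, GUESS, FIND), 32, 4, "colour"),
}


@dataclass
class ExperimentDesign:
    name: str
    space: ColourSpace
    sequences: list[SequenceStimuli] = field(default_factory=list)  # presentation order
    blocks: list[list[int]] = field(default_factory=list)           # indices into sequences
    seed: int | None = None

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s.condition for s in self.sequences))

    def per_condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sequences:
            counts[s.condition] = counts.get(s.condition, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Tidy stimuli table: one row per (sequence, trial, option)."""
        rows = []
        for pos, s in enumerate(self.sequences):
            block = next(b for b, idxs in enumerate(self.blocks) if pos in idxs)
            for t in range(s.length):
                for o in range(2):
                    rows.append(
                        dict(
                            dataset=self.name,
                            position=pos,
                            block=block,
                            condition=s.condition,
                            sequence_id=s.sequence_id,
                            trial=t + 1,
                            option=o + 1,
                            shade=s.outcomes[t, o],
                            category=s.option_categories[o],
                            target_colour=s.target_colour,
                            length=s.length,
                            side_option1=int(s.sides[t]),
                        )
                    )
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        return dict(
            name=self.name,
            seed=self.seed,
            n_sequences=len(self.sequences),
            n_blocks=len(self.blocks),
            conditions=list(self.conditions),
            per_condition=self.per_condition_counts(),
            loglr_scale=self.space.loglr_scale,
            p_dominant=self.space.p_dominant,
        )

    def write(self, stimuli_csv, meta_json=None) -> None:
        self.to_frame().to_csv(stimuli_csv, index=False)
        if meta_json is not None:
            with open(meta_json, "w") as fh:
                json.dump(self.metadata(), fh, indent=2)


def _balanced_lengths(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random uniform lengths: balanced multiset of {8,12,16,20}, shuffled."""
    reps = -(-n // len(SEQUENCE_LENGTHS))
    lengths = np.tile(SEQUENCE_LENGTHS, reps)[:n]
    rng.shuffle(lengths)
    return lengths


def _order_conditions(
    config: DatasetConfig, rng: np.random.Generator
) -> list[list[str]]:
    """Condition labels per block: balanced within block, ≤3 consecutive repeats."""
    per_block = config.block_size // len(config.conditions)
    if len(config.conditions) == 1:  # run-length rule needs ≥2 conditions
        return [list(config.conditions) * per_block for _ in range(config.n_blocks)]
    blocks: list[list[str]] = []
    prev_tail: list[str] = []
    for _ in range(config.n_blocks):
        pool = list(config.conditions) * per_block
        for attempt in range(MAX_RANDOMISATION_RETRIES):
            rng.shuffle(pool)
            run = prev_tail + pool
            ok = True
            streak = 1
            for a, b in zip(run, run[1:]):
                streak = streak + 1 if a == b else 1
                if streak > 3:
                    ok = False
                    break
            if ok:
                break
        else:
            raise GenerationError(
                "condition pseudo-randomisation exceeded retry cap"
            )
        blocks.append(list(pool))
        prev_tail = run[-3:]
    return blocks


def generate_experiment(
    config: DatasetConfig | str,
    rng: np.random.Generator | int,
    space: ColourSpace | None = None,
) -> ExperimentDesign:
    """Generate a full experiment design (stimuli only; choices come from agents).

    Each unique stimulus sequence (lengths drawn balanced from {8,12,16,20},
    option categories independent, outcomes yoked, target colours
    counterbalanced) is duplicated once per condition so that the conditions
    are stimulus-matched.  Conditions are pseudo-randomised into blocks with
    equal per-condition counts, no more than 3 consecutive sequences of a
    condition, and no immediate repetition of the same shape pair or the same
    first-trial response sides.
    """
    if isinstance(config, str):
        try:
            config = DATASET_CONFIGS[config]
        except KeyError:
            raise ConfigError(f"unknown dataset config {config!r}") from None
    config.block_size  # validates divisibility
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(rng)
    if space is None:
        space = build_colour_space()

    n_unique = config.sequences_per_condition
    lengths = _balanced_lengths(n_unique, rng)
    # counterbalanced target colours
    targets = np.tile([ORANGE, BLUE], -(-n_unique // 2))[:n_unique]
    rng.shuffle(targets)
    cat_choices = np.array([ORANGE, BLUE])

    uniques = []
    for uid in range(n_unique):
        cats = (int(rng.choice(cat_choices)), int(rng.choice(cat_choices)))
        L = int(lengths[uid])
        outcomes = np.stack(
            [sample_trial_outcomes(space, cats, rng) for _ in range(L)]
        )
        uniques.append(dict(
            sequence_id=uid, length=L, option_categories=cats,
            target_colour=int(targets[uid]), outcomes=outcomes,
        ))

    cond_blocks = _order_conditions(config, rng)
    # deal the unique sequences into per-condition presentation slots
    per_cond_order = {
        cond: list(rng.permutation(n_unique)) for cond in config.conditions
    }

    # counterbalanced queried colours for the "colour"-style final question
    q_colours = {}
    for cond in config.conditions:
        cols = np.tile([ORANGE, BLUE], -(-n_unique // 2))[:n_unique]
        rng.shuffle(cols)
        q_colours[cond] = cols

    sequences: list[SequenceStimuli] = []
    blocks: list[list[int]] = []
    prev_pair: tuple[int, int] | None = None
    prev_first_side: int | None = None
    seen_per_cond = {cond: 0 for cond in config.conditions}
    for cond_block in cond_blocks:
        block_idxs = []
        for cond in cond_block:
            u = uniques[per_cond_order[cond][seen_per_cond[cond]]]
            seen_per_cond[cond] += 1
            # shape pair differs from the immediately preceding sequence
            for _ in range(MAX_RANDOMISATION_RETRIES):
                pair = SHAPE_PAIRS[rng.integers(len(SHAPE_PAIRS))]
                if pair != prev_pair:
                    break
            sides = rng.integers(0, 2, size=u["length"])
            if prev_first_side is not None and sides[0] == prev_first_side:
                sides[0] = 1 - sides[0]
            if cond == MATCH:
                fq = None
                target = u["target_colour"]
            elif cond == FIND:
                fq = ("colour", u["target_colour"])
                target = u["target_colour"]
            else:  # GUESS: no target during sampling
                target = 0
                if config.final_question_style == "option":
                    fq = ("option", int(rng.integers(2)))
                else:
                    fq = ("colour", int(q_colours[cond][seen_per_cond[cond] - 1]))
            sequences.append(SequenceStimuli(
                sequence_id=u["sequence_id"],
                condition=cond,
                length=u["length"],
                option_categories=u["option_categories"],
                target_colour=target,
                shape_pair=pair,
                outcomes=u["outcomes"].copy(),
                sides=sides,
                final_question=fq,
            ))
            block_idxs.append(len(sequences) - 1)
            prev_pair = pair
            prev_first_side = int(sides[0])
        blocks.append(block_idxs)

    return ExperimentDesign(
        name=config.name, space=space, sequences=sequences, blocks=blocks,
        seed=seed,
    )
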