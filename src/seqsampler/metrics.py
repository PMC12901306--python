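"""Behavioural indices of sampling patterns.

All metrics operate on tidy ChoiceDataset trial tables and are aggregated
per participant × condition:

* **performance** — fraction of last sampling choices directed at the option
  truly associated with the target colour (single-target sequences only),
  and accuracy at the final question;
* **fraction repeat** — overall probability of re-sampling the previous
  option, and as a function of familiarity (how many times the previous
  option had already been sampled, 1..10);
* **choice similarity** — position × position agreement matrix of choices
  within sequences;
* **choice direction** — per-position fraction of choices toward the
  *target* option (highest accumulated evidence toward the target colour)
  and toward the *uncertain* option (lowest |accumulated evidence|), both
  computed from each participant's own sampling history;
* **stereotypy flags** — the participant-exclusion rule: full-sequence
  side alternation, option alternation, or single-option sampling; a
  participant is excluded when more than half the sequences of any
  condition are stereotyped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import ChoiceDataset
from .task import ColourSpace

MAX_FAMILIARITY = 10
MAX_TRIALS = 20


@dataclass
class BehaviourSummary:
    """Per participant × condition behavioural indices (wide tables)."""

    performance: pd.DataFrame
    repeat_overall: pd.DataFrame
    repeat_by_familiarity: pd.DataFrame
    similarity: dict
    direction_target: pd.DataFrame
    direction_uncertainty: pd.DataFrame

    def write(self, prefix) -> None:
        self.performance.to_csv(f"{prefix}_performance.csv")
        self.repeat_overall.to_csv(f"{prefix}_repeat_overall.csv")
        self.repeat_by_familiarity.to_csv(f"{prefix}_repeat_by_familiarity.csv")
        self.direction_target.to_csv(f"{prefix}_direction_target.csv")
        self.direction_uncertainty.to_csv(f"{prefix}_direction_uncertainty.csv")


def _iter_sequences(trials: pd.DataFrame):
    for (pid, cond, pos), grp in trials.groupby(
        ["participant", "condition", "position"], sort=True
    ):
        yield pid, cond, pos, grp.sort_values("trial")


# ---------------------------------------------------------------------------
# Performance
# ---------------------------------------------------------------------------

def performance(dataset: ChoiceDataset) -> pd.DataFrame:
    """Last-choice target fraction (single-target sequences) and final accuracy.

    Rows indexed by (participant, condition); either column is NaN when the
    metric is undefined for that cell (e.g. no single-target sequences, or no
    final question in that condition).
    """
    rows = {}
    for pid, cond, pos, grp in _iter_sequences(dataset.trials):
        target = int(grp["target_colour"].iloc[0])
        cats = (int(grp["category1"].iloc[0]), int(grp["category2"].iloc[0]))
        key = (pid, cond)
        rec = rows.setdefault(key, dict(last_hits=0, last_n=0, fq_hits=0, fq_n=0))
        if target != 0:
            is_target = [c == target for c in cats]
            if sum(is_target) == 1:
                target_opt = 1 + is_target.index(True)
                last_choice = int(grp["choice"].iloc[-1])
                rec["last_hits"] += int(last_choice == target_opt)
                rec["last_n"] += 1
    if len(dataset.finals):
        for (pid, cond), grp in dataset.finals.groupby(["participant", "condition"]):
            rec = rows.setdefault(
                (pid, cond), dict(last_hits=0, last_n=0, fq_hits=0, fq_n=0)
            )
            rec["fq_hits"] += int(grp["correct"].sum())
            rec["fq_n"] += len(grp)
    out = []
    for (pid, cond), rec in rows.items():
        out.append(dict(
            participant=pid, condition=cond,
            last_choice_target_fraction=(
                rec["last_hits"] / rec["last_n"] if rec["last_n"] else np.nan
            ),
            final_accuracy=(
                rec["fq_hits"] / rec["fq_n"] if rec["fq_n"] else np.nan
            ),
            n_single_target=rec["last_n"],
            n_final_questions=rec["fq_n"],
        ))
    return pd.DataFrame(out).set_index(["participant", "condition"]).sort_index()


# ---------------------------------------------------------------------------
# Repetition
# ---------------------------------------------------------------------------

def sequence_repeat_counts(choices) -> tuple[np.ndarray, np.ndarray]:
    """Per-familiarity (1..10) repeat and opportunity counts for one sequence.

    A trial t ≥ 2 is a repeat iff choice_t == choice_{t−1}; its familiarity
    is the number of samples already taken from the option chosen at t−1
    (including the t−1 sample itself).
    """
    choices = np.asarray(choices)
    # index MAX_FAMILIARITY collects everything beyond the reported curve so
    # the overall fraction covers every trial t ≥ 2
    hits = np.zeros(MAX_FAMILIARITY + 1)
    opps = np.zeros(MAX_FAMILIARITY + 1)
    counts = {1: 0, 2: 0}
    for t, ch in enumerate(choices):
        if t >= 1:
            fam = min(counts[choices[t - 1]], MAX_FAMILIARITY + 1)
            opps[fam - 1] += 1
            hits[fam - 1] += ch == choices[t - 1]
        counts[ch] += 1
    return hits, opps


def fraction_repeat(dataset: ChoiceDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overall repeat fraction and by-familiarity curve per participant × condition."""
    acc: dict = {}
    for pid, cond, pos, grp in _iter_sequences(dataset.trials):
        h, o = sequence_repeat_counts(grp["choice"].to_numpy())
        rec = acc.setdefault(
            (pid, cond),
            dict(h=np.zeros(MAX_FAMILIARITY + 1), o=np.zeros(MAX_FAMILIARITY + 1)),
        )
        rec["h"] += h
        rec["o"] += o
    overall_rows, curve_rows = [], []
    for (pid, cond), rec in acc.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            curve = np.where(rec["o"] > 0, rec["h"] / rec["o"], np.nan)
        total_o = rec["o"].sum()
        overall_rows.append(dict(
            participant=pid, condition=cond,
            fraction_repeat=rec["h"].sum() / total_o if total_o else np.nan,
        ))
        for fam in range(MAX_FAMILIARITY):
            curve_rows.append(dict(
                participant=pid, condition=cond, familiarity=fam + 1,
                fraction_repeat=curve[fam], n=rec["o"][fam],
            ))
    overall = (
        pd.DataFrame(overall_rows).set_index(["participant", "condition"]).sort_index()
    )
    curve = (
        pd.DataFrame(curve_rows)
        .set_index(["participant", "condition", "familiarity"])
        .sort_index()
    )
    return overall, curve


# ---------------------------------------------------------------------------
# Choice similarity
# ---------------------------------------------------------------------------

def sequence_similarity(choices) -> np.ndarray:
    """(MAX_TRIALS × MAX_TRIALS) matrix for one sequence: 1 same option,
    0 different, NaN outside the sequence or on/below the diagonal."""
    choices = np.asarray(choices)
    L = len(choices)
    m = np.full((MAX_TRIALS, MAX_TRIALS), np.nan)
    same = choices[:, None] == choices[None, :]
    iu = np.triu_indices(L, k=1)
    m[iu[0], iu[1]] = same[iu].astype(float)
    return m


def choice_similarity(dataset: ChoiceDataset) -> dict:
    """Position × position similarity per condition, averaged over sequences
    within participants (positions beyond a sequence's length excluded),
    then over participants."""
    per_participant: dict = {}
    for pid, cond, pos, grp in _iter_sequences(dataset.trials):
        rec = per_participant.setdefault(
            (pid, cond),
            dict(sum=np.zeros((MAX_TRIALS, MAX_TRIALS)),
                 n=np.zeros((MAX_TRIALS, MAX_TRIALS))),
        )
        m = sequence_similarity(grp["choice"].to_numpy())
        ok = np.isfinite(m)
        rec["sum"][ok] += m[ok]
        rec["n"][ok] += 1
    by_cond: dict = {}
    for (pid, cond), rec in per_participant.items():
        with np.errstate(invalid="ignore"):
            mat = np.where(rec["n"] > 0, rec["sum"] / rec["n"], np.nan)
        by_cond.setdefault(cond, []).append(mat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {cond: np.nanmean(mats, axis=0) for cond, mats in by_cond.items()}


# ---------------------------------------------------------------------------
# Choice direction
# ---------------------------------------------------------------------------

def _direction_scores(grp: pd.DataFrame, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (target-directed, uncertainty-directed) scores for one
    sequence; NaN where undefined (trial 1, or no target colour)."""
    choices = grp["choice"].to_numpy()
    shades = grp["shade"].to_numpy()
    c_tar = int(grp["target_colour"].iloc[0])
    L = len(choices)
    tgt = np.full(MAX_TRIALS, np.nan)
    unc = np.full(MAX_TRIALS, np.nan)
    xhat = np.zeros(2)
    for t in range(L):
        if t >= 1:
            if c_tar != 0:
                scores = xhat * c_tar
                if scores[0] == scores[1]:
                    tgt[t] = 0.5
                else:
                    tgt[t] = float(np.argmax(scores) + 1 == choices[t])
            a = np.abs(xhat)
            if a[0] == a[1]:
                unc[t] = 0.5
            else:
                unc[t] = float(np.argmin(a) + 1 == choices[t])
        xhat[choices[t] - 1] += k * shades[t]
    return tgt, unc


def choice_direction(
    dataset: ChoiceDataset, space: ColourSpace
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Target- and uncertainty-directed fractions per trial position.

    Both fractions are defined for trials ≥ 2 (ties credit 0.5), based on
    evidence accumulated from each participant's own choice history.  Rows
    indexed by (participant, condition); columns are trial positions.
    """
    acc: dict = {}
    for pid, cond, pos, grp in _iter_sequences(dataset.trials):
        tgt, unc = _direction_scores(grp, space.loglr_scale)
        rec = acc.setdefault(
            (pid, cond),
            dict(tsum=np.zeros(MAX_TRIALS), tn=np.zeros(MAX_TRIALS),
                 usum=np.zeros(MAX_TRIALS), un=np.zeros(MAX_TRIALS)),
        )
        ok = np.isfinite(tgt)
        rec["tsum"][ok] += tgt[ok]
        rec["tn"][ok] += 1
        ok = np.isfinite(unc)
        rec["usum"][ok] += unc[ok]
        rec["un"][ok] += 1
    t_rows, u_rows = {}, {}
    for key, rec in acc.items():
        with np.errstate(invalid="ignore"):
            t_rows[key] = np.where(rec["tn"] > 0, rec["tsum"] / rec["tn"], np.nan)
            u_rows[key] = np.where(rec["un"] > 0, rec["usum"] / rec["un"], np.nan)
    idx = pd.MultiIndex.from_tuples(t_rows.keys(), names=["participant", "condition"])
    cols = [f"trial_{t + 1}" for t in range(MAX_TRIALS)]
    target = pd.DataFrame(list(t_rows.values()), index=idx, columns=cols).sort_index()
    uncertainty = pd.DataFrame(
        list(u_rows.values()), index=idx, columns=cols
    ).sort_index()
    return target, uncertainty


# ---------------------------------------------------------------------------
# Stereotypy / exclusion
# ---------------------------------------------------------------------------

def sequence_is_stereotyped(choices, sides=None) -> dict:
    """Flags for one sequence: strict option alternation over the whole
    sequence, single-option sampling, and (when sides are known) strict
    side alternation."""
    choices = np.asarray(choices)
    flags = dict(
        single_option=bool(np.all(choices == choices[0])),
        option_alternation=bool(np.all(choices[1:] != choices[:-1])),
    )
    if sides is not None:
        sides = np.asarray(sides)
        flags["side_alternation"] = bool(np.all(sides[1:] != sides[:-1]))
    else:
        flags["side_alternation"] = False
    return flags


def flag_stereotyped(dataset: ChoiceDataset) -> pd.DataFrame:
    """Per-participant exclusion decision.

    A participant is excluded iff the fraction of stereotyped sequences
    exceeds 0.5 in at least one condition.
    """
    has_sides = "side" in dataset.trials.columns
    if not has_sides:
        warnings.warn("no side information: side-alternation rule skipped")
    frac: dict = {}
    for pid, cond, pos, grp in _iter_sequences(dataset.trials):
        flags = sequence_is_stereotyped(
            grp["choice"].to_numpy(),
            grp["side"].to_numpy() if has_sides else None,
        )
        rec = frac.setdefault((pid, cond), [0, 0])
        rec[0] += int(any(flags.values()))
        rec[1] += 1
    rows: dict = {}
    for (pid, cond), (n_st, n) in frac.items():
        rows.setdefault(pid, {})[cond] = n_st / n
    out = []
    for pid, per_cond in rows.items():
        out.append(dict(
            participant=pid,
            max_stereotyped_fraction=max(per_cond.values()),
            excluded=any(v > 0.5 for v in per_cond.values()),
            **{f"frac_{c}": v for c, v in per_cond.items()},
        ))
    return pd.DataFrame(out).set_index("participant").sort_index()


def uncertainty_direction_random_cohort(
    design,
    n_participants: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uncertainty-directed choice curves for a cohort of uniform-random agents.

    Vectorised equivalent of simulating the ``random`` policy on ``design``
    and running :func:`choice_direction`; used as the null generator of the
    cluster permutation tests, where many thousands of random cohorts are
    needed.  Returns (n_participants, MAX_TRIALS) with NaN at trial 1.
    """
    seqs = design.sequences
    n_seq = len(seqs)
    N = n_participants * n_seq
    k = design.space.loglr_scale
    lengths = np.array([s.length for s in seqs])
    out_pad = np.zeros((n_seq, MAX_TRIALS, 2))
    for i, s in enumerate(seqs):
        out_pad[i, : s.length] = s.outcomes
    outcomes = np.tile(out_pad, (n_participants, 1, 1))
    lengths_all = np.tile(lengths, n_participants)
    choices = rng.integers(0, 2, size=(N, MAX_TRIALS))  # 0 = option 1
    xhat = np.zeros((N, 2))
    score_sum = np.zeros((n_participants, MAX_TRIALS))
    score_n = np.zeros((n_participants, MAX_TRIALS))
    pid = np.repeat(np.arange(n_participants), n_seq)
    for t in range(MAX_TRIALS):
        alive = lengths_all > t
        if t >= 1:
            a = np.abs(xhat)
            tie = a[:, 0] == a[:, 1]
            directed = (np.argmin(a, axis=1) == choices[:, t]).astype(float)
            score = np.where(tie, 0.5, directed)
            np.add.at(score_sum[:, t], pid[alive], score[alive])
            np.add.at(score_n[:, t], pid[alive], 1.0)
        ch = choices[:, t]
        shade = outcomes[np.arange(N), t, ch]
        upd = np.where(alive, k * shade, 0.0)
        xhat[np.arange(N), ch] += upd
    with np.errstate(invalid="ignore"):
        return np.where(score_n > 0, score_sum / score_n, np.nan)


def behaviour_summary(dataset: ChoiceDataset, space: ColourSpace) -> BehaviourSummary:
    """Compute every behavioural index in one pass."""
    overall, curve = fraction_repeat(dataset)
    target, uncertainty = choice_direction(dataset, space)
    return BehaviourSummary(
        performance=performance(dataset),
        repeat_overall=overall,
        repeat_by_familiarity=curve,
        similarity=choice_similarity(dataset),
        direction_target=target,
        direction_uncertainty=uncertainty,
    )
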