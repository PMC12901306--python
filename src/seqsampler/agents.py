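"""Choice models for the colour-bandit task.

Evidence for each option is accumulated perfectly as the sum of observed
shades scaled to logLR units, x̂_o = k·Σc (only the chosen option updates).
Each trial's decision variable combines three components, oriented toward
option 1:

    DV = β_tar · (x̂₁ − x̂₂) · c_tar  +  β_unc · (|x̂₂| − |x̂₁|)  +  b_rep · r

where c_tar ∈ {−1, 0, +1} is the announced target colour (0 in GUESS
sampling), and r is +1/−1 after choosing option 1/2 (0 on the first trial).
The probability of choosing option 1 is logistic(DV).

The ini+ variant adds an *initial sampling phase*: when an option is being
sampled for the first time and its accumulated |x̂| is still below a
threshold θ, the model simply repeats the previous choice with probability ε
instead of consulting the decision variable.  An option's phase dies
permanently on the first switch away from it.  The ini− variant has no phase
(θ = 0).

Optimal agents are the β→∞ limits: MATCH picks argmax (x̂₁−x̂₂)·c_tar, GUESS
picks the option with the smaller |x̂| (the most uncertain one).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import (
    BLUE,
    FIND,
    GUESS,
    MATCH,
    ORANGE,
    ColourSpace,
    ExperimentDesign,
    SequenceStimuli,
)

INI_PLUS = "ini+"
INI_MINUS = "ini-"

PARAM_NAMES = ("beta_tar", "beta_unc", "b_rep", "theta", "epsilon")


@dataclass(frozen=True)
class ParameterSet:
    """Parameters of the ini+/ini− choice model."""

    beta_tar: float = 0.0
    beta_unc: float = 0.0
    b_rep: float = 0.0
    theta: float = 0.0     # initial-phase evidence threshold, logLR units, ≥0
    epsilon: float = 0.0   # initial-phase repeat probability, in [0,1]
    variant: str = INI_PLUS

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be ≥ 0")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.variant not in (INI_PLUS, INI_MINUS):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == INI_MINUS and self.theta != 0.0:
            object.__setattr__(self, "theta", 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def with_lesion(self, lesion: str) -> "ParameterSet":
        """Knock-out copies: 'none', 'phase_off' (θ=0), 'rep_off' (b_rep=0), 'both'."""
        if lesion == "none":
            return self
        if lesion == "phase_off":
            return replace(self, theta=0.0)
        if lesion == "rep_off":
            return replace(self, b_rep=0.0)
        if lesion == "both":
            return replace(self, theta=0.0, b_rep=0.0)
        raise ValueError(f"unknown lesion {lesion!r}")


@dataclass
class AgentState:
    """Within-sequence bookkeeping (option indices 0/1 internally)."""

    xhat: np.ndarray             # per-option accumulated logLR
    phase_active: np.ndarray     # per-option initial-phase flag
    prev_choice: int = 0         # +1 option 1, −1 option 2, 0 none yet
    samples: np.ndarray | None = None

    @classmethod
    def fresh(cls) -> "AgentState":
        return cls(
            xhat=np.zeros(2),
            phase_active=np.array([True, True]),
            prev_choice=0,
            samples=np.zeros(2, dtype=int),
        )


def accumulate(space: ColourSpace, shades_per_option) -> np.ndarray:
    """Accumulated logLR per option: x̂_o = k · Σ(shades chosen from o)."""
    return np.array(
        [space.loglr_scale * float(np.sum(sh)) for sh in shades_per_option]
    )


def decision_variable(state: AgentState, params: ParameterSet, c_tar: int) -> float:
    """DV oriented toward option 1; repetition term is 0 before any choice."""
    if c_tar not in (-1, 0, 1):
        raise ValueError("c_tar must be −1, 0 or +1")
    x1, x2 = state.xhat
    return (
        params.beta_tar * (x1 - x2) * c_tar
        + params.beta_unc * (abs(x2) - abs(x1))
        + params.b_rep * state.prev_choice
    )


def _in_phase(state: AgentState, params: ParameterSet, theta_draw: float) -> bool:
    if params.variant == INI_MINUS or state.prev_choice == 0:
        return False
    prev_opt = 0 if state.prev_choice == 1 else 1
    return bool(
        state.phase_active[prev_opt] and abs(state.xhat[prev_opt]) < theta_draw
    )


def choice_probability(
    state: AgentState,
    params: ParameterSet,
    c_tar: int,
    theta_draw: float | None = None,
) -> tuple[float, float | None]:
    """Probability of choosing option 1 (and of repeating, when defined).

    ``theta_draw`` is a realised threshold value (the likelihood module
    marginalises over the smoothed threshold); defaults to ``params.theta``.
    """
    if theta_draw is None:
        theta_draw = params.theta
    if theta_draw < 0:
        raise ValueError("theta_draw must be ≥ 0")
    if _in_phase(state, params, theta_draw):
        p_rep = params.epsilon
        p1 = p_rep if state.prev_choice == 1 else 1.0 - p_rep
        return p1, p_rep
    p1 = float(expit(decision_variable(state, params, c_tar)))
    if state.prev_choice == 0:
        return p1, None
    return p1, p1 if state.prev_choice == 1 else 1.0 - p1


def step(state: AgentState, choice: int, shade: float, space: ColourSpace) -> AgentState:
    """Advance the state after sampling option ``choice`` (1 or 2).

    On a switch the abandoned option's phase dies permanently.
    """
    if choice not in (1, 2):
        raise ValueError("choice must be 1 or 2")
    opt = choice - 1
    xhat = state.xhat.copy()
    xhat[opt] += space.loglr_scale * shade
    phase = state.phase_active.copy()
    r = 1 if choice == 1 else -1
    if state.prev_choice != 0 and r != state.prev_choice:
        prev_opt = 0 if state.prev_choice == 1 else 1
        phase[prev_opt] = False
    samples = None if state.samples is None else state.samples.copy()
    if samples is not None:
        samples[opt] += 1
    return AgentState(xhat=xhat, phase_active=phase, prev_choice=r, samples=samples)


def optimal_policy(state: AgentState, condition: str, c_tar: int = 0) -> float:
    """Optimal agent's probability of choosing option 1 (ties → 0.5)."""
    if condition == MATCH:
        score = (state.xhat[0] - state.xhat[1]) * c_tar
    elif condition == GUESS:
        score = abs(state.xhat[1]) - abs(state.xhat[0])
    else:
        raise ValueError(f"no optimal agent is defined for condition {condition!r}")
    if score > 0:
        return 1.0
    if score < 0:
        return 0.0
    return 0.5


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class ChoiceDataset:
    """Tidy per-trial choice records for many participants.

    ``trials``: one row per (participant, condition, position, trial) with the
    chosen option, the observed shade and side.  ``finals``: one row per
    sequence with a final question and its response.
    """

    def __init__(self, trials: pd.DataFrame, finals: pd.DataFrame):
        self.trials = trials
        self.finals = finals

    def participants(self) -> np.ndarray:
        return self.trials["participant"].unique()

    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.trials["condition"]))

    def subset(self, participant=None, condition=None) -> "ChoiceDataset":
        t, f = self.trials, self.finals
        if participant is not None:
            t = t[t["participant"] == participant]
            f = f[f["participant"] == participant] if len(f) else f
        if condition is not None:
            t = t[t["condition"] == condition]
            f = f[f["condition"] == condition] if len(f) else f
        return ChoiceDataset(t.reset_index(drop=True), f.reset_index(drop=True))

    def write(self, trials_csv, finals_csv=None) -> None:
        self.trials.to_csv(trials_csv, index=False)
        if finals_csv is not None:
            self.finals.to_csv(finals_csv, index=False)

    @classmethod
    def read(cls, trials_csv, finals_csv=None) -> "ChoiceDataset":
        trials = pd.read_csv(trials_csv)
        finals = pd.read_csv(finals_csv) if finals_csv else pd.DataFrame()
        return cls(trials, finals)


def _answer_final_question(
    question: tuple[str, int], state: AgentState, rng: np.random.Generator
) -> int:
    """Sign-readout responder.

    Queried option → report sign(x̂) as the colour (+1 orange / −1 blue).
    Queried colour → pick the option maximising x̂·c_query.  Ties random.
    """
    kind, arg = question
    if kind == "option":
        x = state.xhat[arg]
        if x == 0:
            return int(rng.choice([ORANGE, BLUE]))
        return ORANGE if x > 0 else BLUE
    # kind == "colour": respond with an option index (1 or 2)
    scores = state.xhat * arg
    if scores[0] == scores[1]:
        return int(rng.integers(1, 3))
    return int(np.argmax(scores) + 1)


def _final_correct(question: tuple[str, int], response: int, seq: SequenceStimuli) -> int:
    kind, arg = question
    if kind == "option":
        return int(response == seq.option_categories[arg])
    match = [c == arg for c in seq.option_categories]
    if not any(match):
        # no option of the queried colour: either response scores 0
        return 0
    return int(match[response - 1])


def simulate_sequence(
    seq: SequenceStimuli,
    params: ParameterSet | None,
    space: ColourSpace,
    rng: np.random.Generator,
    policy: str = "model",
) -> tuple[np.ndarray, AgentState]:
    """Simulate the choices of one agent on one sequence; returns (choices, state)."""
    state = AgentState.fresh()
    if policy == "model":
        theta_draw = params.theta
    choices = np.zeros(seq.length, dtype=int)
    c_tar = seq.target_colour
    for t in range(seq.length):
        if policy == "random":
            p1 = 0.5
        elif policy == "optimal":
            p1 = optimal_policy(state, seq.condition, c_tar)
        else:
            p1, _ = choice_probability(state, params, c_tar, theta_draw)
        choice = 1 if rng.random() < p1 else 2
        choices[t] = choice
        state = step(state, choice, seq.outcomes[t, choice - 1], space)
    return choices, state


def simulate_dataset(
    design: ExperimentDesign,
    params,
    rng: np.random.Generator | int,
    policy: str = "model",
    n_participants: int | None = None,
) -> ChoiceDataset:
    """Simulate a cohort of agents on an experiment design.

    Parameters
    ----------
    params
        For the ``model`` policy: a mapping participant → {condition →
        ParameterSet}, or a single ParameterSet applied everywhere (then
        ``n_participants`` is required).  Ignored for ``optimal`` and
        ``random`` policies (pass ``n_participants``).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if isinstance(params, ParameterSet):
        if n_participants is None:
            raise ValueError("n_participants required with a single ParameterSet")
        params = {
            p: {cond: params for cond in design.conditions}
            for p in range(n_participants)
        }
    elif params is None:
        if policy == "model":
            raise ValueError("model policy requires parameters")
        if n_participants is None:
            raise ValueError("n_participants required")
        params = {p: {} for p in range(n_participants)}

    trial_rows, final_rows = [], []
    for pid in params:
        for pos, seq in enumerate(design.sequences):
            if policy == "model":
                try:
                    pset = params[pid][seq.condition]
                except KeyError:
                    raise ValueError(
                        f"missing parameters for participant {pid!r}, "
                        f"condition {seq.condition}"
                    ) from None
            else:
                pset = None
            choices, state = simulate_sequence(seq, pset, design.space, rng, policy)
            for t, choice in enumerate(choices):
                side1 = seq.sides[t]
                trial_rows.append((
                    pid, seq.condition, pos, seq.sequence_id, t + 1,
                    int(choice),
                    seq.outcomes[t, choice - 1],
                    int(side1 if choice == 1 else 1 - side1),
                    seq.target_colour, seq.length,
                    seq.option_categories[0], seq.option_categories[1],
                ))
            if seq.final_question is not None:
                resp = _answer_final_question(seq.final_question, state, rng)
                final_rows.append((
                    pid, seq.condition, pos, seq.sequence_id,
                    seq.final_question[0], seq.final_question[1], resp,
                    _final_correct(seq.final_question, resp, seq),
                ))
    trials = pd.DataFrame(
        trial_rows,
        columns=[
            "participant", "condition", "position", "sequence_id", "trial",
            "choice", "shade", "side", "target_colour", "length",
            "category1", "category2",
        ],
    )
    finals = pd.DataFrame(
        final_rows,
        columns=[
            "participant", "condition", "position", "sequence_id",
            "question_kind", "question_arg", "response", "correct",
        ],
    )
    return ChoiceDataset(trials, finals)
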