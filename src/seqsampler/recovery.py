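"""Validation suites: model recovery, parameter recovery, knock-out simulations.

*Model recovery* simulates cohorts of agents with (ini+) and without (ini−)
the initial sampling phase at group-regime parameters, fits both variants
with cross-validation, runs Bayesian model selection per simulated cohort,
and reports a confusion matrix (simulated model × expected fitted-model
frequency) and its Bayes-inverted counterpart (probability of the simulated
model given the selected one, uniform prior).

*Parameter recovery* first decorrelates the simulating parameter values by
permuting each parameter column until all pairwise |Spearman ρ| fall below a
cap (preserving every marginal exactly), then simulates, refits, and scores
each parameter by the Spearman correlation between simulated and recovered
values weighted by the goodness of each agent's recovery fit, along with the
recovery bias and the cross-correlations among recovered parameters.

*Knock-out* re-simulates fitted cohorts after silencing the initial phase
(θ=0), the repetition bias (b_rep=0), both, or neither, and returns the full
behavioural summary per lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .agents import INI_MINUS, INI_PLUS, ParameterSet, simulate_dataset
from .bms import BMSResult, vb_dirichlet
from .likelihood import (
    FitConfig,
    crossvalidate_prepared,
    fit_prepared,
    prepare_dataset,
)
from .metrics import BehaviourSummary, behaviour_summary
from .task import ExperimentDesign

LESIONS = ("none", "phase_off", "rep_off", "both")

#: Group-regime parameters used by default in the recovery and knock-out
#: suites (approximately the best-fitting group means in the GUESS condition;
#: MATCH ini+ agents borrow the GUESS phase parameters, since MATCH fits do
#: not constrain the phase).
GROUP_REGIME = ParameterSet(
    beta_tar=2.0, beta_unc=1.5, b_rep=1.0, theta=1.5, epsilon=0.95,
    variant=INI_PLUS,
)

PARAM_COLUMNS = ("beta_tar", "beta_unc", "b_rep", "theta", "epsilon")


@dataclass
class ModelRecoveryResult:
    confusion: np.ndarray     # rows: simulated (ini+, ini−); cols: fitted
    inversion: np.ndarray     # P(simulated | fitted), uniform prior
    bms_ini_plus: BMSResult
    bms_ini_minus: BMSResult
    evidence: pd.DataFrame    # agent × (simulated, cv_ini_plus, cv_ini_minus)


def _params_to_set(row, variant: str) -> ParameterSet:
    if variant == INI_MINUS:
        return ParameterSet(
            row["beta_tar"], row["beta_unc"], row["b_rep"], 0.0, 0.0,
            variant=INI_MINUS,
        )
    return ParameterSet(
        row["beta_tar"], row["beta_unc"], row["b_rep"], row["theta"],
        row["epsilon"], variant=INI_PLUS,
    )


def _fit_both_with_cv(data, config, rng_seq):
    out = {}
    for variant, seed in zip((INI_PLUS, INI_MINUS), rng_seq):
        out[variant] = crossvalidate_prepared(data, variant, config, seed)
    return out


def model_recovery(
    design: ExperimentDesign,
    params_ini_plus: ParameterSet,
    params_ini_minus: ParameterSet,
    n_agents: int = 27,
    fit_config: FitConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ModelRecoveryResult:
    """Confusion and inversion matrices of the ini+/ini− comparison."""
    fit_config = fit_config or FitConfig()
    ss = np.random.SeedSequence(
        int(rng) if isinstance(rng, (int, np.integer)) else None
    )
    rows = []
    for sim_variant, pset in ((INI_PLUS, params_ini_plus), (INI_MINUS, params_ini_minus)):
        for a in range(n_agents):
            s_sim, s_fit1, s_fit2 = ss.spawn(3)
            ds = simulate_dataset(
                design, pset, np.random.default_rng(s_sim), n_participants=1
            )
            data = prepare_dataset(ds, design.space)
            fits = _fit_both_with_cv(
                data, fit_config,
                (np.random.default_rng(s_fit1), np.random.default_rng(s_fit2)),
            )
            rows.append(dict(
                simulated=sim_variant, agent=a,
                cv_ini_plus=fits[INI_PLUS].cv_loglik,
                cv_ini_minus=fits[INI_MINUS].cv_loglik,
            ))
    evidence = pd.DataFrame(rows)
    confusion = np.zeros((2, 2))
    bms_results = {}
    for i, sim_variant in enumerate((INI_PLUS, INI_MINUS)):
        sub = evidence[evidence["simulated"] == sim_variant]
        L = sub[["cv_ini_plus", "cv_ini_minus"]].to_numpy()
        res = vb_dirichlet(L)
        bms_results[sim_variant] = res
        confusion[i] = res.freq_mean
    col_sums = confusion.sum(axis=0)
    inversion = confusion / np.where(col_sums > 0, col_sums, 1.0)
    return ModelRecoveryResult(
        confusion=confusion, inversion=inversion,
        bms_ini_plus=bms_results[INI_PLUS], bms_ini_minus=bms_results[INI_MINUS],
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def _max_abs_spearman(matrix: np.ndarray) -> float:
    ranks = np.apply_along_axis(rankdata, 0, matrix)
    c = np.corrcoef(ranks, rowvar=False)
    iu = np.triu_indices(matrix.shape[1], k=1)
    return float(np.max(np.abs(c[iu]))) if iu[0].size else 0.0


def decorrelate_params(
    param_matrix,
    max_abs_rho: float = 0.07,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 10_000,
) -> np.ndarray:
    """Permute each parameter column independently until every pairwise
    |Spearman ρ| is below ``max_abs_rho``; marginals are preserved exactly."""
    m = np.asarray(param_matrix, float).copy()
    if m.shape[0] < 10:
        raise ValueError("need at least 10 rows to decorrelate meaningfully")
    if m.shape[1] < 2:
        return m
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for _ in range(max_retries):
        out = np.column_stack([
            col[rng.permutation(m.shape[0])] for col in m.T
        ])
        if _max_abs_spearman(out) < max_abs_rho:
            return out
    raise RuntimeError(
        f"could not reach |rho| < {max_abs_rho} within {max_retries} permutations; "
        "consider a looser threshold"
    )


def weighted_spearman(x, y, w) -> float:
    """Weighted Pearson correlation of the ranks of x and y."""
    rx, ry = rankdata(x), rankdata(y)
    w = np.asarray(w, float)
    w = w / w.sum()
    mx, my = np.sum(w * rx), np.sum(w * ry)
    cov = np.sum(w * (rx - mx) * (ry - my))
    sx = np.sqrt(np.sum(w * (rx - mx) ** 2))
    sy = np.sqrt(np.sum(w * (ry - my) ** 2))
    if sx == 0 or sy == 0:
        return np.nan
    return float(cov / (sx * sy))


@dataclass
class ParameterRecoveryResult:
    simulated: pd.DataFrame        # agents × parameters
    recovered: pd.DataFrame
    weights: np.ndarray            # goodness-of-fit weights per agent
    weighted_rho: dict             # parameter → weighted Spearman ρ
    bias: dict                     # parameter → mean(recovered − simulated)
    recovered_correlations: pd.DataFrame


def parameter_recovery(
    design: ExperimentDesign,
    simulated_params: pd.DataFrame,
    fit_config: FitConfig | None = None,
    rng: np.random.Generator | int | None = None,
    sim_variant: str = INI_PLUS,
    fit_variant: str = INI_PLUS,
    param_names=None,
) -> ParameterRecoveryResult:
    """Simulate agents at given parameter rows, refit, and score recovery.

    ``simulated_params``: DataFrame with columns among PARAM_COLUMNS, one row
    per agent (decorrelate first with :func:`decorrelate_params`).  Weights
    are each agent's exp(mean per-trial log-likelihood) of the recovery fit,
    normalised across agents.
    """
    fit_config = fit_config or FitConfig()
    ss = np.random.SeedSequence(
        int(rng) if isinstance(rng, (int, np.integer)) else None
    )
    if param_names is None:
        param_names = [c for c in PARAM_COLUMNS if c in simulated_params.columns]
    rec_rows, weights = [], []
    for _, row in simulated_params.iterrows():
        s_sim, s_fit = ss.spawn(2)
        pset = _params_to_set(row, sim_variant)
        ds = simulate_dataset(
            design, pset, np.random.default_rng(s_sim), n_participants=1
        )
        data = prepare_dataset(ds, design.space)
        fit = fit_prepared(data, fit_variant, fit_config, np.random.default_rng(s_fit))
        rec_rows.append({c: getattr(fit.params, c) for c in PARAM_COLUMNS})
        weights.append(np.exp(fit.loglik_total / fit.n_trials))
    recovered = pd.DataFrame(rec_rows)
    weights = np.asarray(weights)
    weights = weights / weights.sum()
    rho = {
        c: weighted_spearman(simulated_params[c], recovered[c], weights)
        for c in param_names
    }
    bias = {
        c: float(np.mean(recovered[c].to_numpy() - simulated_params[c].to_numpy()))
        for c in param_names
    }
    ranks = recovered[list(param_names)].rank()
    rec_corr = ranks.corr()
    return ParameterRecoveryResult(
        simulated=simulated_params.reset_index(drop=True),
        recovered=recovered,
        weights=weights,
        weighted_rho=rho,
        bias=bias,
        recovered_correlations=rec_corr,
    )


# ---------------------------------------------------------------------------
# Knock-out simulations
# ---------------------------------------------------------------------------

def knockout(
    fitted_params: dict,
    design: ExperimentDesign,
    lesions=LESIONS,
    n_sims: int = 1,
    rng: np.random.Generator | int | None = None,
) -> dict[str, list[BehaviourSummary]]:
    """Simulate lesioned cohorts and return behavioural summaries per lesion.

    ``fitted_params``: participant → {condition → ParameterSet}.  For every
    lesion, ``n_sims`` cohort simulations are run; the identity lesion
    ("none") reproduces :func:`simulate_dataset` with the same seed exactly.
    """
    seed0 = int(rng) if isinstance(rng, (int, np.integer)) else None
    ss = np.random.SeedSequence(seed0)
    cohort_seeds = ss.spawn(n_sims)
    out: dict[str, list[BehaviourSummary]] = {}
    for lesion in lesions:
        lesioned = {
            pid: {cond: ps.with_lesion(lesion) for cond, ps in conds.items()}
            for pid, conds in fitted_params.items()
        }
        summaries = []
        for s in cohort_seeds:
            ds = simulate_dataset(design, lesioned, np.random.default_rng(s))
            summaries.append(behaviour_summary(ds, design.space))
        out[lesion] = summaries
    return out
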