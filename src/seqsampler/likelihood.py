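"""Likelihood, maximum-likelihood fitting and cross-validation.

The sequence likelihood of the ini+ model marginalises the initial-phase
threshold over its smoothing distribution, θ' ~ Normal(θ, 0.1 logLR units):

    L = log ∫ p(θ') Π_t p(choice_t | θ') dθ'

Given a realised θ' the phase dynamics are deterministic functions of the
observed choices, so the inner product is exact.  The support is truncated
to [max(0, θ−3σ), θ+3σ] with renormalised weights; because the per-trial
gate ``|x̂| < θ'`` makes the integrand piecewise constant in θ', the
quadrature splits the support at the accumulated-evidence breakpoints and
applies Gauss–Legendre within each piece, which integrates the normal weight
essentially exactly.  A consequence of the truncated support: once θ falls
3σ below the smallest reachable |x̂| the phase can never trigger and the
ini+ likelihood coincides with ini−, mirroring the model definition in which
θ = 0 disables the phase.

Fitting is two-pass: a multi-start bounded quasi-Newton pass over a grid of
threshold initialisations crossed with random decision-variable starts,
then a derivative-free (Nelder–Mead) refinement from the pass-1 optimum.
Model evidence for model selection comes from leave-one-sequence-out
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .agents import INI_MINUS, INI_PLUS, ChoiceDataset, ParameterSet
from .task import ColourSpace

THETA_SMOOTHING_SD = 0.1   # logLR units
PROB_FLOOR = 1e-12
_LOG_FLOOR = np.log(PROB_FLOOR)


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    """Per-trial arrays, padded over sequences, from which the likelihood of
    any parameter set is a closed-form array expression.

    All arrays are (n_sequences, T_max); invalid cells are masked.
    """

    valid: np.ndarray        # bool
    sign: np.ndarray         # +1 chose option 1, −1 chose option 2
    repeat: np.ndarray       # bool, choice_t == choice_{t−1} (False at t=1)
    f_tar: np.ndarray        # (x̂₁−x̂₂)·c_tar before trial t
    f_unc: np.ndarray        # |x̂₂|−|x̂₁| before trial t
    f_rep: np.ndarray        # r_{t−1} (0 at t=1)
    phase_prev: np.ndarray   # bool, previous option's phase still alive at t
    xprev_abs: np.ndarray    # |x̂| of the previously chosen option before t
    n_sequences: int = 0
    n_trials_total: int = 0

    def subset(self, keep: np.ndarray) -> "PreparedData":
        return PreparedData(
            valid=self.valid[keep], sign=self.sign[keep],
            repeat=self.repeat[keep], f_tar=self.f_tar[keep],
            f_unc=self.f_unc[keep], f_rep=self.f_rep[keep],
            phase_prev=self.phase_prev[keep], xprev_abs=self.xprev_abs[keep],
            n_sequences=int(np.sum(keep)),
            n_trials_total=int(self.valid[keep].sum()),
        )


def prepare_sequences(sequences, space: ColourSpace) -> PreparedData:
    """Build likelihood arrays from per-sequence (choices, shades, c_tar).

    ``sequences``: iterable of tuples ``(choices, shades, c_tar)`` where
    ``choices`` are 1/2 and ``shades`` are the observed outcome shades of the
    chosen options.
    """
    seqs = list(sequences)
    S = len(seqs)
    T = max(len(ch) for ch, _, _ in seqs)
    k = space.loglr_scale
    valid = np.zeros((S, T), bool)
    sign = np.zeros((S, T))
    rep = np.zeros((S, T), bool)
    f_tar = np.zeros((S, T))
    f_unc = np.zeros((S, T))
    f_rep = np.zeros((S, T))
    phase_prev = np.zeros((S, T), bool)
    xprev = np.full((S, T), np.inf)
    for s, (choices, shades, c_tar) in enumerate(seqs):
        xhat = np.zeros(2)
        alive = [True, True]
        prev = 0  # +1/−1/0
        for t, (ch, sh) in enumerate(zip(choices, shades)):
            valid[s, t] = True
            sign[s, t] = 1.0 if ch == 1 else -1.0
            f_tar[s, t] = (xhat[0] - xhat[1]) * c_tar
            f_unc[s, t] = abs(xhat[1]) - abs(xhat[0])
            f_rep[s, t] = prev
            if prev != 0:
                prev_opt = 0 if prev == 1 else 1
                rep[s, t] = (ch == 1) == (prev == 1)
                phase_prev[s, t] = alive[prev_opt]
                xprev[s, t] = abs(xhat[prev_opt])
            r = 1 if ch == 1 else -1
            if prev != 0 and r != prev:
                alive[0 if prev == 1 else 1] = False
            xhat[ch - 1] += k * sh
            prev = r
    return PreparedData(
        valid=valid, sign=sign, repeat=rep, f_tar=f_tar, f_unc=f_unc,
        f_rep=f_rep, phase_prev=phase_prev, xprev_abs=xprev,
        n_sequences=S, n_trials_total=int(valid.sum()),
    )


def prepare_dataset(dataset: ChoiceDataset, space: ColourSpace) -> PreparedData:
    """Prepare one participant × condition slice of a ChoiceDataset."""
    seqs = []
    for _, grp in dataset.trials.groupby("position", sort=True):
        grp = grp.sort_values("trial")
        seqs.append((
            grp["choice"].to_numpy(),
            grp["shade"].to_numpy(),
            int(grp["target_colour"].iloc[0]),
        ))
    return prepare_sequences(seqs, space)


# ---------------------------------------------------------------------------
# Threshold quadrature
# ---------------------------------------------------------------------------

def threshold_nodes(
    theta: float,
    n_nodes: int = 21,
    sd: float = THETA_SMOOTHING_SD,
    breakpoints: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and log-weights for θ' ~ N(θ, sd) on [max(0,θ−3sd), θ+3sd].

    The support is split at ``breakpoints`` (the accumulated-evidence values
    where the phase gate flips) so Gauss–Legendre only ever integrates the
    smooth normal density within a piece.  Weights are renormalised to sum
    to one over the truncated support.
    """
    a, b = max(0.0, theta - 3.0 * sd), theta + 3.0 * sd
    edges = [a, b]
    if breakpoints is not None:
        inner = np.asarray(breakpoints, float)
        edges += list(inner[(inner > a) & (inner < b)])
    edges = np.unique(edges)
    n_pieces = len(edges) - 1
    per_piece = max(2, int(np.ceil(n_nodes / n_pieces)))
    gl_x, gl_w = np.polynomial.legendre.leggauss(per_piece)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = 0.5 * (hi - lo)
        mid = 0.5 * (hi + lo)
        x = mid + half * gl_x
        w = half * gl_w * norm.pdf(x, loc=theta, scale=sd)
        nodes.append(x)
        weights.append(w)
    nodes = np.concatenate(nodes)
    weights = np.concatenate(weights)
    weights = np.maximum(weights, 0.0) / weights.sum()
    with np.errstate(divide="ignore"):
        return nodes, np.log(weights)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _per_sequence_loglik(
    data: PreparedData, params: ParameterSet, n_nodes: int
) -> np.ndarray:
    """Log-likelihood per sequence, marginalised over the threshold."""
    if not np.all(np.isfinite(params.as_array())):
        raise ValueError("non-finite parameters")
    dv = (
        params.beta_tar * data.f_tar
        + params.beta_unc * data.f_unc
        + params.b_rep * data.f_rep
    )
    # log σ(±dv) via the numerically stable log-ndtr-free form
    z = data.sign * dv
    log_soft = np.where(z > 0, -np.log1p(np.exp(-np.abs(z))),
                        z - np.log1p(np.exp(-np.abs(z))))
    log_soft = np.maximum(log_soft, _LOG_FLOOR)
    # θ = 0 disables the initial phase outright (the smoothing is a device
    # for θ > 0, not a change of model class), so ini+ at the boundary is
    # exactly the nested ini− model
    if params.variant == INI_MINUS or params.theta == 0.0:
        ll = np.where(data.valid, log_soft, 0.0).sum(axis=1)
        return ll
    p_rep = np.clip(np.where(data.repeat, params.epsilon, 1.0 - params.epsilon),
                    PROB_FLOOR, 1.0)
    log_phase = np.log(p_rep)
    bps = data.xprev_abs[np.isfinite(data.xprev_abs)]
    nodes, log_w = threshold_nodes(params.theta, n_nodes,
                                   breakpoints=np.unique(bps))
    # gate: (S, T, J)
    gate = data.phase_prev[:, :, None] & (
        data.xprev_abs[:, :, None] < nodes[None, None, :]
    )
    logp = np.where(gate, log_phase[:, :, None], log_soft[:, :, None])
    logp = np.where(data.valid[:, :, None], logp, 0.0)
    return logsumexp(logp.sum(axis=1) + log_w[None, :], axis=1)


def dataset_loglik(
    data: PreparedData, params: ParameterSet, n_nodes: int = 21
) -> float:
    return float(_per_sequence_loglik(data, params, n_nodes).sum())


def sequence_loglik(
    choices,
    shades,
    c_tar: int,
    params: ParameterSet,
    space: ColourSpace,
    quadrature_nodes: int = 21,
) -> float:
    """Marginal log-likelihood of one sequence of observed choices."""
    if quadrature_nodes < 1:
        raise ValueError("quadrature_nodes must be ≥ 1")
    data = prepare_sequences([(choices, shades, c_tar)], space)
    return dataset_loglik(data, params, quadrature_nodes)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimisation settings.

    Defaults mirror the reference fitting procedure: 100 threshold
    initialisations in [0.05, 5] crossed with random decision-variable starts
    (β in [−2,2], b_rep in [−4,4]), followed by a derivative-free refinement.
    Reduce ``n_theta_grid``/``n_beta_starts`` for quick runs.
    """

    n_theta_grid: int = 100
    theta_grid_range: tuple[float, float] = (0.05, 5.0)
    n_beta_starts: int = 10
    quadrature_nodes: int = 21
    bounds_beta: tuple[float, float] = (-10.0, 10.0)
    bounds_b_rep: tuple[float, float] = (-10.0, 10.0)
    bounds_theta: tuple[float, float] = (0.0, 5.0)
    maxiter_pass1: int = 200
    maxiter_pass2: int = 500
    cv_extra_starts: int = 1   # random restarts per CV fold beyond the warm start
    cv_refine_only: bool = False  # folds: derivative-free refinement from the
                                  # full-data optimum only (fast, for large suites)


@dataclass
class FitResult:
    params: ParameterSet
    loglik_total: float
    n_sequences: int
    n_trials: int
    variant: str
    n_starts: int
    n_converged: int
    seed: int | None = None
    cv_loglik: float | None = None
    cv_per_fold: np.ndarray | None = None
    floored: bool = False

    @property
    def theta_as_probability(self) -> float:
        """θ re-expressed as the category probability logistic(θ) reached
        before the phase ends."""
        return float(1.0 / (1.0 + np.exp(-self.params.theta)))

    def to_dict(self) -> dict:
        d = {n: getattr(self.params, n) for n in
             ("beta_tar", "beta_unc", "b_rep", "theta", "epsilon")}
        d.update(
            variant=self.variant, loglik=self.loglik_total,
            cv_loglik=self.cv_loglik, n_sequences=self.n_sequences,
            n_trials=self.n_trials, n_starts=self.n_starts,
            n_converged=self.n_converged, seed=self.seed,
            theta_prob=self.theta_as_probability,
        )
        return d


def _unpack(x: np.ndarray, variant: str) -> ParameterSet:
    if variant == INI_MINUS:
        return ParameterSet(x[0], x[1], x[2], 0.0, 0.0, variant=INI_MINUS)
    return ParameterSet(x[0], x[1], x[2], x[3], x[4], variant=INI_PLUS)


def _bounds(config: FitConfig, variant: str):
    b = [config.bounds_beta, config.bounds_beta, config.bounds_b_rep]
    if variant == INI_PLUS:
        b += [config.bounds_theta, (0.0, 1.0)]
    return b


def _starts(config: FitConfig, variant: str, rng: np.random.Generator):
    """Pass-1 start points: θ grid × random β draws (random β only for ini−)."""
    out = []
    if variant == INI_PLUS:
        thetas = np.linspace(*config.theta_grid_range, config.n_theta_grid)
        for th in thetas:
            for _ in range(config.n_beta_starts):
                out.append(np.array([
                    rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(-4, 4),
                    th, rng.uniform(0, 1),
                ]))
    else:
        n = config.n_theta_grid * config.n_beta_starts // 10 or 1
        for _ in range(max(n, config.n_beta_starts)):
            out.append(np.array([
                rng.uniform(-2, 2), rng.uniform(-2, 2), rng.uniform(-4, 4),
            ]))
    return out


def fit_prepared(
    data: PreparedData,
    variant: str,
    config: FitConfig | None = None,
    rng: np.random.Generator | int | None = None,
    warm_starts=None,
) -> FitResult:
    """Two-pass MLE on prepared arrays.

    ``warm_starts``: optional list of parameter vectors prepended to the
    pass-1 start list (used by cross-validation folds).
    """
    config = config or FitConfig()
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nodes = config.quadrature_nodes

    def nll(x):
        return -dataset_loglik(data, _unpack(x, variant), nodes)

    bounds = _bounds(config, variant)
    starts = list(warm_starts or []) + _starts(config, variant, rng)
    best_x, best_f, n_conv = None, np.inf, 0
    for x0 in starts:
        res = minimize(
            nll, np.asarray(x0, float), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter_pass1},
        )
        n_conv += bool(res.success)
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_x is None or not np.isfinite(best_f):
        raise FitError("all optimisation starts failed")
    # pass 2: derivative-free robust refinement
    res = minimize(
        nll, best_x, method="Nelder-Mead", bounds=bounds,
        options={"maxiter": config.maxiter_pass2, "xatol": 1e-5, "fatol": 1e-7},
    )
    if res.fun < best_f:
        best_x, best_f = res.x, res.fun
    # θ=0 is a boundary face where the phase is disabled outright, which the
    # smoothed objective reaches discontinuously; optimise that face (the
    # nested phase-free model) separately and keep the better optimum
    if variant == INI_PLUS:
        nested = fit_prepared(data, INI_MINUS, config, rng)
        if nested.loglik_total > -best_f:
            best_x = np.array([
                nested.params.beta_tar, nested.params.beta_unc,
                nested.params.b_rep, 0.0, 0.5,
            ])
            best_f = -nested.loglik_total
    params = _unpack(best_x, variant)
    return FitResult(
        params=params, loglik_total=-best_f, n_sequences=data.n_sequences,
        n_trials=data.n_trials_total, variant=variant, n_starts=len(starts),
        n_converged=n_conv, seed=seed,
    )


def fit_participant(
    dataset: ChoiceDataset,
    variant: str,
    space: ColourSpace,
    config: FitConfig | None = None,
    rng=None,
) -> FitResult:
    """Fit one participant × condition dataset (see :func:`fit_prepared`)."""
    data = prepare_dataset(dataset, space)
    if data.n_sequences < 1 or data.n_trials_total < 2:
        raise ValueError("need at least one sequence with ≥2 trials")
    return fit_prepared(data, variant, config, rng)


def crossvalidate_prepared(
    data: PreparedData,
    variant: str,
    config: FitConfig | None = None,
    rng: np.random.Generator | int | None = None,
    full_fit: FitResult | None = None,
) -> FitResult:
    """Leave-one-sequence-out cross-validation.

    Each fold refits on the remaining sequences (warm-started from the
    full-data optimum plus fresh random starts) and evaluates the held-out
    sequence; ``cv_loglik`` is the summed held-out log-likelihood.  The
    returned FitResult carries the full-data point estimates.
    """
    config = config or FitConfig()
    if data.n_sequences < 2:
        raise ValueError("cross-validation needs ≥2 sequences")
    ss = np.random.SeedSequence(
        int(rng) if isinstance(rng, (int, np.integer)) else None
    )
    child_seeds = ss.spawn(data.n_sequences + 1)
    if full_fit is None:
        full_fit = fit_prepared(
            data, variant, config, np.random.default_rng(child_seeds[-1])
        )
    fold_config = replace(
        config,
        n_theta_grid=max(1, config.cv_extra_starts),
        n_beta_starts=1,
    )
    warm = [full_fit.params.as_array()[: 3 if variant == INI_MINUS else 5]]
    bounds = _bounds(config, variant)
    fold_ll = np.full(data.n_sequences, np.nan)
    n_failed = 0
    for i in range(data.n_sequences):
        keep = np.ones(data.n_sequences, bool)
        keep[i] = False
        train = data.subset(keep)
        try:
            if config.cv_refine_only:
                res = minimize(
                    lambda x: -dataset_loglik(
                        train, _unpack(x, variant), config.quadrature_nodes
                    ),
                    warm[0], method="Nelder-Mead", bounds=bounds,
                    options={"maxfev": 200, "xatol": 1e-4, "fatol": 1e-5},
                )
                fit_params = _unpack(res.x, variant)
            else:
                fit_i = fit_prepared(
                    train, variant, fold_config,
                    np.random.default_rng(child_seeds[i]), warm_starts=warm,
                )
                fit_params = fit_i.params
            held = data.subset(~keep)
            fold_ll[i] = dataset_loglik(held, fit_params, config.quadrature_nodes)
        except FitError:
            n_failed += 1
    if n_failed > 0.1 * data.n_sequences:
        raise FitError(f"{n_failed}/{data.n_sequences} CV folds failed")
    out = replace(
        full_fit,
        cv_loglik=float(np.nansum(fold_ll)),
        cv_per_fold=fold_ll,
    )
    return out


def crossvalidate(
    dataset: ChoiceDataset,
    variant: str,
    space: ColourSpace,
    config: FitConfig | None = None,
    rng=None,
) -> FitResult:
    data = prepare_dataset(dataset, space)
    return crossvalidate_prepared(data, variant, config, rng)
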