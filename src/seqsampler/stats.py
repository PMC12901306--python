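"""Cluster-level permutation tests on trialwise curves, and effect sizes.

Trialwise curves (e.g. the fraction of uncertainty-directed choices per
trial position, one row per participant) are tested point-by-point with
t-tests; contiguous runs of significant points (two-sided p < 0.05) form
clusters whose statistic is the sum of t-values.  Cluster-level inference
compares each observed cluster statistic against the distribution of the
*largest* absolute cluster statistic obtained under the null — either from
simulated random-choice cohorts run through the same metric pipeline
(tests against chance) or from shuffling condition labels of individual
sequences within participants and recomputing the curves (between-condition
tests).  Empirical p-values use the add-one correction (b+1)/(N+1) so they
are never exactly zero.

Effect sizes follow the formulas used for this task battery:
``r = z/sqrt(n)`` for rank tests, Cohen's d_z for paired t-tests, and
generalized eta squared ``SS_effect / (SS_effect + Σ SS_residuals)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

CLUSTER_ALPHA = 0.05


@dataclass
class Cluster:
    start: int           # first point index (0-based, into the tested columns)
    end: int             # last point index, inclusive
    sum_t: float
    p_value: float | None = None


@dataclass
class ClusterTestResult:
    clusters: list[Cluster] = field(default_factory=list)
    t_values: np.ndarray | None = None
    tested_points: np.ndarray | None = None  # indices of columns actually tested
    n_null: int = 0
    null_max_stat: np.ndarray | None = None
    alpha: float = CLUSTER_ALPHA

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < 0.05]

    def to_dict(self) -> dict:
        return dict(
            clusters=[
                dict(start=c.start, end=c.end, sum_t=c.sum_t, p=c.p_value)
                for c in self.clusters
            ],
            n_null=self.n_null,
            alpha=self.alpha,
        )


def _find_clusters(t_vals: np.ndarray, p_vals: np.ndarray, alpha: float):
    """Contiguous runs of significant points; same-sign split is not imposed
    (runs are defined by threshold crossing, as in the curve analyses)."""
    sig = p_vals < alpha
    clusters = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            clusters.append(Cluster(i, j, float(np.sum(t_vals[i : j + 1]))))
            i = j + 1
        else:
            i += 1
    return clusters


def _curve_tests(curves: np.ndarray, chance: float):
    """Columnwise one-sample t-tests vs chance; returns (t, p, tested columns)."""
    curves = np.asarray(curves, float)
    n_per_col = np.sum(np.isfinite(curves), axis=0)
    ok = n_per_col >= 2
    t = np.full(curves.shape[1], np.nan)
    p = np.full(curves.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_1samp(
            curves[:, ok], popmean=chance, nan_policy="omit", axis=0
        )
    t[ok], p[ok] = res.statistic, res.pvalue
    # degenerate columns (zero variance) give nan t; treat as not significant
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    return t, p, np.flatnonzero(ok)


def _max_cluster_stat(curves: np.ndarray, chance: float, alpha: float) -> float:
    t, p, ok = _curve_tests(curves, chance)
    cl = _find_clusters(t[ok], p[ok], alpha)
    return max((abs(c.sum_t) for c in cl), default=0.0)


def cluster_test_vs_chance(
    curves,
    chance: float,
    null_generator,
    n_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = CLUSTER_ALPHA,
) -> ClusterTestResult:
    """Cluster-level test of trialwise curves against a chance level.

    ``null_generator(rng)`` must return a matched-size participants × points
    curve array computed from simulated random choices through the same
    metric pipeline.
    """
    curves = np.asarray(curves, float)
    if curves.shape[0] < 2:
        raise ValueError("need at least two participants")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t, p, ok = _curve_tests(curves, chance)
    clusters = _find_clusters(t[ok], p[ok], alpha)
    null_stats = np.array([
        _max_cluster_stat(np.asarray(null_generator(rng), float), chance, alpha)
        for _ in range(n_sims)
    ])
    for c in clusters:
        b = int(np.sum(null_stats >= abs(c.sum_t)))
        c.p_value = (b + 1) / (n_sims + 1)
    return ClusterTestResult(
        clusters=clusters, t_values=t, tested_points=ok,
        n_null=n_sims, null_max_stat=null_stats, alpha=alpha,
    )


def _paired_curve_tests(diff: np.ndarray, alpha: float):
    return _curve_tests(diff, 0.0)


def cluster_test_between(
    seq_values: np.ndarray,
    participants: np.ndarray,
    condition_labels: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = CLUSTER_ALPHA,
    conditions: tuple | None = None,
) -> ClusterTestResult:
    """Between-condition cluster test with sequence-label permutation.

    Parameters
    ----------
    seq_values : (n_sequences, n_points)
        Per-sequence curve contributions (NaN where undefined); the
        participant × condition curve is the NaN-mean over its sequences.
    participants, condition_labels : (n_sequences,)
        Sequence-level identifiers.  Exactly two condition labels must be
        present, paired within every participant.

    The null shuffles the condition labels of individual sequences within
    each participant and recomputes the paired-difference curves in full.
    """
    seq_values = np.asarray(seq_values, float)
    participants = np.asarray(participants)
    condition_labels = np.asarray(condition_labels)
    if conditions is None:
        conditions = tuple(pd_unique(condition_labels))
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    pids = pd_unique(participants)
    for pid in pids:
        labs = set(condition_labels[participants == pid])
        if set(conditions) - labs:
            raise ValueError(f"participant {pid!r} lacks one of the conditions")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def diff_curves(labels):
        out = np.full((len(pids), seq_values.shape[1]), np.nan)
        for i, pid in enumerate(pids):
            mask = participants == pid
            a = nanmean_rows(seq_values[mask & (labels == conditions[0])])
            b = nanmean_rows(seq_values[mask & (labels == conditions[1])])
            out[i] = a - b
        return out

    observed = diff_curves(condition_labels)
    t, p, ok = _curve_tests(observed, 0.0)
    clusters = _find_clusters(t[ok], p[ok], alpha)
    null_stats = np.empty(n_permutations)
    labels = condition_labels.copy()
    for s in range(n_permutations):
        for pid in pids:
            mask = np.flatnonzero(participants == pid)
            labels[mask] = condition_labels[mask][rng.permutation(mask.size)]
        null_stats[s] = _max_cluster_stat(diff_curves(labels), 0.0, alpha)
    for c in clusters:
        b = int(np.sum(null_stats >= abs(c.sum_t)))
        c.p_value = (b + 1) / (n_permutations + 1)
    return ClusterTestResult(
        clusters=clusters, t_values=t, tested_points=ok,
        n_null=n_permutations, null_max_stat=null_stats, alpha=alpha,
    )


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def nanmean_rows(rows: np.ndarray) -> np.ndarray:
    if rows.size == 0:
        return np.full(rows.shape[-1], np.nan)
    with np.errstate(invalid="ignore"):
        counts = np.sum(np.isfinite(rows), axis=0)
        sums = np.nansum(rows, axis=0)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def effect_size_r(z: float, n: int) -> float:
    """Rank-test effect size r = z / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return float(z / np.sqrt(n))


def cohens_dz(differences) -> float:
    """Paired-sample Cohen's d_z: mean(diff) / sd(diff)."""
    d = np.asarray(differences, float)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero variance in differences")
    return float(d.mean() / sd)


def generalized_eta_squared(ss_effect: float, ss_residuals) -> float:
    """η²_G = SS_effect / (SS_effect + Σ SS_residuals)."""
    ss_res = float(np.sum(ss_residuals))
    if ss_effect < 0 or ss_res < 0:
        raise ValueError("sums of squares must be ≥ 0")
    denom = ss_effect + ss_res
    if denom == 0:
        raise ZeroDivisionError("undefined: all sums of squares are zero")
    return float(ss_effect / denom)
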