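"""Pre/post treatment outcome testing and cohort score summaries.

The paired comparison is the Wilcoxon signed-rank test on post - pre
differences: zero differences are dropped (Wilcoxon's original rule), ties
among the absolute differences receive average ranks, and the statistic is
``W+``, the rank sum of the positive differences.  For up to 25 non-zero
pairs the p-value is exact — the full null distribution of ``W+`` under
random signs is built by dynamic programming over the (tie-aware) rank
values — and a normal approximation with tie correction and a continuity
correction is used above that.  Both p-values are reported in the outcome
summary so the exact/approximate choice is transparent.

By convention the cognitive score (MMSE, higher = better) is tested
one-tailed for an increase and the behavioral score (DBD-13, higher = more
disturbance) one-tailed for a decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedTestError
from .tables import ParameterTable

__all__ = ["WilcoxonResult", "ScoreOutcome", "OutcomeSummary",
           "wilcoxon_signed_rank", "outcome_report"]

EXACT_LIMIT = 25  # switch to the normal approximation above this many non-zero pairs


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+: rank sum of positive (post - pre) differences
    p_value: float
    method: str  # "exact" or "approx"
    n_nonzero: int


@dataclass(frozen=True)
class ScoreOutcome:
    score: str
    direction: str  # alternative tested, e.g. "greater" for an improvement
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    statistic: float
    p_value: float
    p_exact: float | None
    p_approx: float


@dataclass(frozen=True)
class OutcomeSummary:
    scores: tuple[ScoreOutcome, ...]

    def __str__(self) -> str:
        lines = []
        for s in self.scores:
            lines.append(
                f"{s.score}: pre {s.pre_mean:.2f} +/- {s.pre_sd:.2f}, "
                f"post {s.post_mean:.2f} +/- {s.post_sd:.2f}; "
                f"one-tailed ({s.direction}) Wilcoxon W+={s.statistic:.1f}, "
                f"p={s.p_value:.4f}"
            )
        return "\n".join(lines)


def _signed_rank_parts(pre: np.ndarray, post: np.ndarray):
    d = post - pre
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return d, ranks, w_plus


def _exact_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ over all 2^n sign assignments.

    Average ranks may be half-integers, so everything is doubled to stay on
    an integer lattice; returns (support in doubled units, probabilities).
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    probs = counts / counts.sum()
    return np.arange(total + 1), probs


def _exact_p(ranks: np.ndarray, w_plus: float, alternative: str) -> float:
    support, probs = _exact_distribution(ranks)
    w2 = int(round(w_plus * 2))
    p_greater = float(probs[support >= w2].sum())
    p_less = float(probs[support <= w2].sum())
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def _approx_p(d: np.ndarray, ranks: np.ndarray, w_plus: float,
              alternative: str) -> float:
    n = d.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        raise UndefinedTestError("zero variance in the signed-rank statistic")
    sd = np.sqrt(var)
    # continuity correction of 0.5 toward the mean
    z_greater = (w_plus - mean - 0.5) / sd
    z_less = (w_plus - mean + 0.5) / sd
    p_greater = float(stats.norm.sf(z_greater))
    p_less = float(stats.norm.cdf(z_less))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def wilcoxon_signed_rank(
    pre,
    post,
    alternative: str = "two-sided",
    method: str = "auto",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on post - pre paired differences.

    ``alternative="greater"`` tests for post > pre.  ``method`` is ``auto``
    (exact up to 25 non-zero pairs, normal approximation beyond), ``exact``
    or ``approx``.
    """
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.shape != post.shape:
        raise InputError("pre and post must have equal length")
    if alternative not in ("greater", "less", "two-sided"):
        raise InputError(f"unknown alternative {alternative!r}")
    d, ranks, w_plus = _signed_rank_parts(pre, post)
    if d.size < 5:
        raise InputError(
            f"need at least 5 non-zero paired differences (got {d.size})"
        )
    if method == "auto":
        method = "exact" if d.size <= EXACT_LIMIT else "approx"
    if method == "exact":
        p = _exact_p(ranks, w_plus, alternative)
    elif method == "approx":
        p = _approx_p(d, ranks, w_plus, alternative)
    else:
        raise InputError(f"unknown method {method!r}")
    return WilcoxonResult(w_plus, p, method, d.size)


def _score_outcome(table: ParameterTable, score: str, direction: str) -> ScoreOutcome:
    pre = table.session_values("pre")[score].to_numpy()
    post = table.session_values("post")[score].to_numpy()
    d = (post - pre)[post != pre]
    res = wilcoxon_signed_rank(pre, post, alternative=direction, method="auto")
    p_exact = None
    if d.size <= EXACT_LIMIT:
        p_exact = wilcoxon_signed_rank(pre, post, direction, method="exact").p_value
    p_approx = wilcoxon_signed_rank(pre, post, direction, method="approx").p_value
    return ScoreOutcome(
        score=score,
        direction=direction,
        pre_mean=float(pre.mean()),
        pre_sd=float(pre.std(ddof=1)),
        post_mean=float(post.mean()),
        post_sd=float(post.std(ddof=1)),
        statistic=res.statistic,
        p_value=res.p_value,
        p_exact=p_exact,
        p_approx=p_approx,
    )


def outcome_report(table: ParameterTable) -> OutcomeSummary:
    """Cohort score summary: MMSE tested for increase, DBD-13 for decrease."""
    return OutcomeSummary(
        scores=(
            _score_outcome(table, "MMSE", "greater"),
            _score_outcome(table, "DBD-13", "less"),
        )
    )
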