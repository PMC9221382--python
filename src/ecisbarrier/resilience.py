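"""Case-level aggregation of damage fits and the resilience-threshold analysis.

Culture conditions (seeding density x culture time) define cases; each case
contributes per-node values of the Phase-1 length N_P1, the Phase-2 decay
constant lambda, and the initial barrier resistance Rb_init. This module
computes Table-style case summaries (mean, sample sd), pairwise two-tailed
t-tests between cases (paired by node index, or Welch when pairing is
unavailable), and the sigmoid fit of N_P1 against Rb_init whose midpoint x0
is the resilience threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "CaseSpec",
    "CaseSummary",
    "SigmoidFit",
    "SigmoidThreshold",
    "summarize_cases",
    "compare_cases",
    "fit_resilience_sigmoid",
]


@dataclass
class CaseSpec:
    """One culture condition: seeding density (cells/cm^2) and culture time (h)."""

    case_id: int
    seeding_density: float
    culture_time_h: float
    n_nodes: int = 7

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("a case needs at least 2 nodes")


@dataclass
class CaseSummary:
    case_id: int
    n_nodes: int
    mean_np1: float
    sd_np1: float
    mean_lambda: float
    sd_lambda: float
    mean_rb_init: float
    sd_rb_init: float
    flagged: bool = False


@dataclass
class SigmoidFit:
    n_max: float
    x0: float
    k: float
    residual: float
    degenerate: bool = False


def summarize_cases(per_node: pd.DataFrame) -> list[CaseSummary]:
    """Per-case means and sample standard deviations (n-1 denominator).

    ``per_node`` must have columns ``case_id``, ``node_id``, ``n_p1``,
    ``lam``; ``rb_init`` is optional. Cases with fewer than 2 nodes are
    returned flagged with NaN standard deviations.
    """
    required = {"case_id", "node_id", "n_p1", "lam"}
    missing = required - set(per_node.columns)
    if missing:
        raise ValueError(f"per_node table missing columns {sorted(missing)}")
    has_rb = "rb_init" in per_node.columns
    out = []
    for case_id, sub in per_node.groupby("case_id", sort=True):
        n = len(sub)
        flagged = n < 2
        if flagged:
            warnings.warn(f"case {case_id} has {n} node(s); sd undefined")

        def mean_sd(col):
            if col is None:
                return float("nan"), float("nan")
            vals = sub[col].to_numpy(float)
            return float(np.mean(vals)), (float(np.std(vals, ddof=1)) if n >= 2 else float("nan"))

        m_np1, s_np1 = mean_sd("n_p1")
        m_lam, s_lam = mean_sd("lam")
        m_rb, s_rb = mean_sd("rb_init" if has_rb else None)
        out.append(
            CaseSummary(
                case_id=int(case_id),
                n_nodes=n,
                mean_np1=m_np1,
                sd_np1=s_np1,
                mean_lambda=m_lam,
                sd_lambda=s_lam,
                mean_rb_init=m_rb,
                sd_rb_init=s_rb,
                flagged=flagged,
            )
        )
    return out


def _pair_p(x: np.ndarray, y: np.ndarray, paired: bool) -> float:
    if paired:
        d = x - y
        if np.allclose(d, 0.0):
            return 1.0
        if np.std(d, ddof=1) == 0.0:
            # constant nonzero shift: the t statistic diverges
            warnings.warn("zero-variance paired differences; p -> 0 limit reported")
            return 0.0
        return float(stats.ttest_rel(x, y).pvalue)
    if np.std(x, ddof=1) == 0.0 and np.std(y, ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            return 1.0
        warnings.warn("zero-variance groups with unequal means; p -> 0 limit reported")
        return 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def compare_cases(
    per_node: pd.DataFrame,
    value: str = "n_p1",
    mode: str = "paired",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Pairwise two-tailed t-test p-value matrix between cases.

    ``mode='paired'`` pairs node-for-node by node_id (falling back to Welch
    with a warning when node counts differ); ``mode='welch'`` uses the
    unequal-variance two-sample test. With ``bh_adjust`` the matrix holds
    Benjamini-Hochberg adjusted p-values instead of raw ones.
    """
    if mode not in ("paired", "welch"):
        raise ValueError("mode must be 'paired' or 'welch'")
    cases = sorted(per_node["case_id"].unique())
    groups = {
        c: per_node[per_node["case_id"] == c].sort_values("node_id")[value].to_numpy(float)
        for c in cases
    }
    mat = pd.DataFrame(np.ones((len(cases), len(cases))), index=cases, columns=cases)
    raw = []
    pairs = list(combinations(cases, 2))
    for a, b in pairs:
        x, y = groups[a], groups[b]
        paired = mode == "paired"
        if paired and len(x) != len(y):
            warnings.warn(
                f"cases {a} and {b} have unequal node counts; falling back to Welch"
            )
            paired = False
        raw.append(_pair_p(x, y, paired))
    pvals = raw
    if bh_adjust:
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, raw[i] * m / (rank_pos + 1))
            adj[i] = running
        pvals = adj.tolist()
    for (a, b), p in zip(pairs, pvals):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


class SigmoidThreshold(BaseEstimator):
    """Three-parameter logistic fit of N_P1 against Rb_init.

    N_P1(x) = N_max / (1 + exp(-(x - x0)/k)); the midpoint x0 is reported as
    the resilience threshold: layers with Rb_init above x0 withstand on the
    order of N_max RD cycles before disintegration, layers below fail almost
    immediately.

    Attributes
    ----------
    n_max_, x0_, k_ : fitted parameters (k > 0).
    residual_ : root-mean-square fit residual, cycles.
    degenerate_ : flag set when the response carries no transition (all y
        equal) or all x lie on one side of the fitted midpoint.
    """

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SigmoidThreshold":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if len(x) < self.min_points:
            raise ValueError(f"need at least {self.min_points} points")
        if np.ptp(y) == 0.0:
            self.n_max_ = float(y[0]) if y[0] > 0 else float("nan")
            self.x0_ = float("nan")
            self.k_ = float("nan")
            self.residual_ = 0.0
            self.degenerate_ = True
            warnings.warn("degenerate sigmoid fit: response has no spread")
            return self

        order = np.argsort(x)
        xs, ys = x[order], y[order]
        # midpoint initialized at the largest jump of the sorted response
        jumps = np.abs(np.diff(ys))
        j = int(np.argmax(jumps))
        x0_init = 0.5 * (xs[j] + xs[j + 1])
        span = max(np.ptp(x), 1e-6)

        def resid(p):
            n_max, x0, log_k = p
            return n_max / (1.0 + np.exp(-(x - x0) / np.exp(log_k))) - y

        sol = optimize.least_squares(
            resid,
            [max(y.max(), 1e-6), x0_init, np.log(span / 20.0)],
            bounds=(
                [0.0, x.min() - span, np.log(span * 1e-4)],
                [np.inf, x.max() + span, np.log(span * 10.0)],
            ),
            x_scale=[max(y.max(), 1.0), span, 1.0],
        )
        self.n_max_, self.x0_ = float(sol.x[0]), float(sol.x[1])
        self.k_ = float(np.exp(sol.x[2]))
        self.residual_ = float(np.sqrt(2.0 * sol.cost / len(x)))
        one_sided = bool(np.all(x < self.x0_) or np.all(x > self.x0_))
        self.degenerate_ = one_sided
        if one_sided:
            warnings.warn("sigmoid fit flagged: all points on one side of the midpoint")
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return self.n_max_ / (1.0 + np.exp(-(x - self.x0_) / self.k_))


def fit_resilience_sigmoid(x: np.ndarray, y: np.ndarray, **options) -> SigmoidFit:
    """Functional wrapper over :class:`SigmoidThreshold`."""
    est = SigmoidThreshold(**options).fit(x, y)
    return SigmoidFit(
        n_max=est.n_max_,
        x0=est.x0_,
        k=est.k_,
        residual=est.residual_,
        degenerate=est.degenerate_,
    )
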