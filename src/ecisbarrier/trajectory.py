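"""Two-phase segmentation and fitting of RD damage trajectories.

A damage trajectory records the surrogate signals against the cumulative
number N of recruitment/derecruitment cycles. Phase 1 is the interval over
which the layer stays confluent — C(64K) holds a flat baseline while R(1K)
stays high; its length N_P1 is the resilience statistic. In Phase 2 each
further RD cycle removes a fixed fraction of the remaining layer, so R(1K)
follows dR/dN = -lambda R, i.e.

    R(N) = R0 exp(-lambda (N - N_P1)) + R_F

with R_F the cell-free resistance and R0 + R_F the resistance at the end of
Phase 1 (R0 is the decaying amplitude; the pre-insult level R_init is reported
separately).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .io import SurrogateTrace

__all__ = [
    "PhaseSegmentation",
    "DamageFit",
    "Phase1Trend",
    "PhaseSegmenter",
    "DecayFitter",
    "Phase1TrendFitter",
    "segment_phases",
    "fit_decay",
    "fit_phase1_trends",
]


@dataclass
class PhaseSegmentation:
    node_id: int
    n_p1: float
    method: str  # 'joint-fit' | 'threshold'
    baseline_c64k: float
    margin: float
    no_phase2: bool = False


@dataclass
class DamageFit:
    """Phase-2 decay summary: R(N) = r0 exp(-lam (N - n_p1)) + rf."""

    node_id: int
    n_p1: float
    lam: float
    r0: float
    rf: float
    r2: float
    r_init: float
    no_decay: bool = False


@dataclass
class Phase1Trend:
    node_id: int
    rb_slope: float
    rb_intercept: float
    rb_zero_crossing: float
    alpha_slope: float
    alpha_intercept: float


class PhaseSegmenter(BaseEstimator):
    """Locate the Phase-1/Phase-2 changepoint N_P1 on a C(64K) trace.

    Methods
    -------
    ``joint-fit`` (default): for every candidate changepoint c on the observed
    epoch grid, fit a constant plateau for N <= c joined continuously to an
    exponential departure for N > c, and return the candidate minimizing total
    squared error. A changepoint is accepted only if it beats the
    no-changepoint (constant) model by ``detect_ratio`` in SSE; otherwise the
    trace is flagged "no Phase 2" and N_P1 = max(N).

    ``threshold``: baseline is the median of the first ``baseline_epochs``
    observations; N_P1 is the first N where C(64K) exceeds
    baseline*(1+delta) for ``consecutive`` consecutive epochs.

    Measurements only happen between RD epochs, so N_P1 is always one of the
    observed cycle counts.
    """

    def __init__(
        self,
        method: str = "joint-fit",
        delta: float = 0.05,
        consecutive: int = 2,
        baseline_epochs: int = 3,
        detect_ratio: float = 2.0,
    ):
        self.method = method
        self.delta = delta
        self.consecutive = consecutive
        self.baseline_epochs = baseline_epochs
        self.detect_ratio = detect_ratio

    def fit(self, n: np.ndarray, c64k: np.ndarray) -> "PhaseSegmenter":
        n = np.asarray(n, float)
        c = np.asarray(c64k, float)
        if len(n) < 5:
            raise ValueError("need at least 5 epochs to segment")
        if self.method == "joint-fit":
            self._fit_joint(n, c)
        elif self.method == "threshold":
            self._fit_threshold(n, c)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    # -- joint plateau + exponential-departure changepoint ------------------
    @staticmethod
    def _candidate_sse(n, c, idx):
        """SSE of [plateau up to index idx] + [exponential departure after]."""
        plateau = float(np.mean(c[: idx + 1]))
        left_sse = float(np.sum((c[: idx + 1] - plateau) ** 2))
        nr, cr = n[idx + 1 :], c[idx + 1 :]
        if len(nr) == 0:
            return left_sse, plateau
        dn = nr - n[idx]
        a0 = max(float(cr[-1] - plateau), 1e-12)
        span = max(float(dn[-1]), 1.0)

        def resid(x):
            a, log_k = x
            return plateau + a * (1.0 - np.exp(-np.exp(log_k) * dn)) - cr

        best = None
        for k0 in (1.0 / span, 10.0 / span):
            sol = optimize.least_squares(
                resid, [a0, np.log(k0)], bounds=([0.0, np.log(1e-6 / span)], [np.inf, np.log(1e3)])
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return left_sse + 2.0 * best.cost, plateau

    def _fit_joint(self, n, c):
        const_sse = float(np.sum((c - np.mean(c)) ** 2))
        best_sse, best_idx, best_plateau = np.inf, None, np.mean(c)
        # keep >= 2 points in the plateau and >= 3 in the departure
        for idx in range(1, len(n) - 3):
            sse, plateau = self._candidate_sse(n, c, idx)
            if sse < best_sse:
                best_sse, best_idx, best_plateau = sse, idx, plateau
        detected = (
            best_idx is not None
            and best_sse > 0
            and const_sse / best_sse >= self.detect_ratio
        )
        if best_idx is not None and best_sse == 0 and const_sse > 0:
            detected = True
        self.method_ = "joint-fit"
        self.margin_ = float(self.detect_ratio)
        if detected:
            self.n_p1_ = float(n[best_idx])
            self.baseline_ = float(best_plateau)
            self.no_phase2_ = False
        else:
            self.n_p1_ = float(n[-1])
            self.baseline_ = float(np.mean(c))
            self.no_phase2_ = True

    # -- baseline-threshold rule --------------------------------------------
    def _fit_threshold(self, n, c):
        baseline = float(np.median(c[: self.baseline_epochs]))
        above = c > baseline * (1.0 + self.delta)
        self.method_ = "threshold"
        self.baseline_ = baseline
        self.margin_ = float(self.delta)
        run = 0
        for i, flag in enumerate(above):
            run = run + 1 if flag else 0
            if run >= self.consecutive:
                first = i - self.consecutive + 1
                self.n_p1_ = float(n[first])
                self.no_phase2_ = False
                return
        self.n_p1_ = float(n[-1])
        self.no_phase2_ = True


class DecayFitter(BaseEstimator):
    """Fit the Phase-2 exponential decay R(N) = R0 exp(-lambda (N-N_P1)) + R_F.

    Bounded nonlinear least squares on the observations with N >= N_P1;
    lambda, R0 and R_F are constrained non-negative. Initialization follows
    the geometry of the model: R_F from the trace minimum, R0 from the level
    at the changepoint, lambda from a log-linear regression of the
    baseline-subtracted trace.

    Attributes
    ----------
    lambda_ : per-cycle decay constant (>= 0).
    r0_ : decaying amplitude at N = N_P1, ohm.
    rf_ : asymptotic cell-free resistance, ohm.
    r2_ : coefficient of determination of the Phase-2 fit.
    r_init_ : mean pre-insult R(1K) (observations with N < N_P1); NaN if none.
    no_decay_ : fit pinned at lambda = 0 (flat trace).
    """

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def fit(self, n: np.ndarray, r: np.ndarray, n_p1: float) -> "DecayFitter":
        n = np.asarray(n, float)
        r = np.asarray(r, float)
        mask = n >= n_p1
        if mask.sum() < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} observations with N >= N_P1, got {mask.sum()}"
            )
        n2, r2 = n[mask], r[mask]
        pre = n < n_p1
        self.r_init_ = float(np.mean(r[pre])) if pre.any() else float("nan")

        rf0 = float(np.min(r2))
        r00 = max(float(r2[0] - rf0), 1e-9)
        lam0 = self._init_lambda(n2, r2, n_p1, rf0)

        def resid(x):
            lam, r0, rf = x
            return r0 * np.exp(-lam * (n2 - n_p1)) + rf - r2

        sol = optimize.least_squares(
            resid,
            [lam0, r00, rf0],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            x_scale=[max(lam0, 1e-4), max(r00, 1.0), max(rf0, 1.0)],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        lam, r0, rf = sol.x
        ss_res = float(np.sum(sol.fun**2))
        ss_tot = float(np.sum((r2 - np.mean(r2)) ** 2))
        if ss_tot > 0:
            self.r2_ = max(0.0, 1.0 - ss_res / ss_tot)
        else:
            self.r2_ = 1.0 if ss_res < 1e-12 else 0.0
        self.no_decay_ = bool(lam < 1e-10 or r0 < 1e-9)
        if self.no_decay_:
            lam, r0 = 0.0, 0.0
            rf = float(np.mean(r2))
            warnings.warn("decay fit pinned at lambda = 0: no Phase-2 decay in trace")
        self.lambda_ = float(lam)
        self.r0_ = float(r0)
        self.rf_ = float(rf)
        self.n_p1_ = float(n_p1)
        return self

    @staticmethod
    def _init_lambda(n2, r2, n_p1, rf0):
        y = r2 - 0.95 * rf0
        ok = y > 0
        if ok.sum() >= 2 and np.ptp(n2[ok]) > 0:
            slope = np.polyfit(n2[ok] - n_p1, np.log(y[ok]), 1)[0]
            return max(-slope, 1e-6)
        return 1e-3

    def predict(self, n: np.ndarray) -> np.ndarray:
        n = np.asarray(n, float)
        return self.r0_ * np.exp(-self.lambda_ * (n - self.n_p1_)) + self.rf_


class Phase1TrendFitter(BaseEstimator):
    """OLS trends of Rb and alpha against normalized cycle count N/N_P1.

    Regressing on the normalized axis lets trends pool across nodes whose
    Phase-1 lengths differ. The Rb intercept estimates the initial barrier
    resistance Rb_init; the zero crossing of the Rb line (in N/N_P1 units)
    marks where tight-junction resistance is eliminated.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    def fit(self, n_frac: np.ndarray, rb: np.ndarray, alpha: np.ndarray | None = None):
        x = np.asarray(n_frac, float)
        rb = np.asarray(rb, float)
        if len(x) < self.min_points:
            raise ValueError(f"need at least {self.min_points} Phase-1 points, got {len(x)}")
        if np.any(x > 1.0 + 1e-9):
            raise ValueError("Phase-1 trends only use observations with N <= N_P1")
        self.rb_slope_, self.rb_intercept_ = (float(v) for v in np.polyfit(x, rb, 1))
        if self.rb_slope_ != 0.0:
            self.rb_zero_crossing_ = -self.rb_intercept_ / self.rb_slope_
        else:
            self.rb_zero_crossing_ = float("inf")
        if alpha is not None:
            alpha = np.asarray(alpha, float)
            self.alpha_slope_, self.alpha_intercept_ = (
                float(v) for v in np.polyfit(x, alpha, 1)
            )
        else:
            self.alpha_slope_ = self.alpha_intercept_ = float("nan")
        return self


# -- functional wrappers over SurrogateTrace ---------------------------------

def segment_phases(trace: SurrogateTrace, **options) -> PhaseSegmentation:
    """Segment a surrogate trace into Phase 1 / Phase 2 via its C(64K) signal."""
    seg = PhaseSegmenter(**options).fit(trace.n, trace.c64k)
    return PhaseSegmentation(
        node_id=trace.node_id,
        n_p1=seg.n_p1_,
        method=seg.method_,
        baseline_c64k=seg.baseline_,
        margin=seg.margin_,
        no_phase2=seg.no_phase2_,
    )


def fit_decay(trace: SurrogateTrace, n_p1: float, **options) -> DamageFit:
    """Fit the Phase-2 exponential decay of R(1K) for a segmented trace."""
    fitter = DecayFitter(**options).fit(trace.n, trace.r1k, n_p1)
    return DamageFit(
        node_id=trace.node_id,
        n_p1=float(n_p1),
        lam=fitter.lambda_,
        r0=fitter.r0_,
        rf=fitter.rf_,
        r2=fitter.r2_,
        r_init=fitter.r_init_,
        no_decay=fitter.no_decay_,
    )


def fit_phase1_trends(
    node_id: int,
    n_frac: np.ndarray,
    rb: np.ndarray,
    alpha: np.ndarray | None = None,
) -> Phase1Trend:
    """Linear Phase-1 trends of inverted GK parameters vs N/N_P1."""
    f = Phase1TrendFitter().fit(n_frac, rb, alpha)
    return Phase1Trend(
        node_id=node_id,
        rb_slope=f.rb_slope_,
        rb_intercept=f.rb_intercept_,
        rb_zero_crossing=f.rb_zero_crossing_,
        alpha_slope=f.alpha_slope_,
        alpha_intercept=f.alpha_intercept_,
    )
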