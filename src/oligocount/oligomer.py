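"""Dual Poisson monomer + K-mer mixture: fitting, scoring, model selection.

A cluster holding j K-mers and i monomers shows N = i + K*j copies. With
independent Poisson counts (means k and m respectively) the predicted copy
number distribution is the superposition

    P_Total(N) = sum_{j=0}^{floor(N/K)} Poisson(j; k) * Poisson(N - K*j; m).

m is fitted on the sub-K part of the histogram (clusters with N < K cannot
contain a K-mer) and k follows without any fit from the observed mean via
k = (mean_N - m) / K. Candidate oligomer sizes K are scored against the
observed histogram with two goodness-of-fit statistics,

    V = 1 / sum_{N=1}^{Nmax} (P_obs(N) - P_Total(N))^2
    O = 1 / sum_{N=1}^{Nmax} (P_obs(N) - P_Total(N))^2 / P_obs(N),

both of which increase as the prediction approaches the observation; the
selected K maximizes them (ties break toward smaller K). The O sum runs over
bins with P_obs(N) > 0 only, so a large relative error on a rare event
cannot dominate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

from ._util import FitError
from .synthetic import ClusterObservation

__all__ = [
    "CopyNumberDistribution",
    "DualPoissonFit",
    "ModelSelectionResult",
    "build_distribution",
    "predict_dual_poisson",
    "fit_monomer_mean",
    "oligomer_mean_from_totals",
    "score_V",
    "score_O",
    "select_oligomer_size",
    "fit_dual_poisson",
]

log = logging.getLogger(__name__)

DEFAULT_NMAX = 10  # scoring cutoff for V and O


@dataclass
class CopyNumberDistribution:
    """Observed copy-number histogram over N >= 1."""

    counts: dict[int, int]
    n_total: int
    mean_N: float

    def p_obs(self, n: int) -> float:
        return self.counts.get(n, 0) / self.n_total

    def p_obs_vector(self, n_max: int) -> np.ndarray:
        """P_obs(0..n_max); P_obs(0) is 0 by construction."""
        out = np.zeros(n_max + 1)
        for n, c in self.counts.items():
            if n <= n_max:
                out[n] = c / self.n_total
        return out


@dataclass
class DualPoissonFit:
    K: int
    m: float
    k: float
    predicted: np.ndarray  # P_Total(N) for N = 0..N_pred_max
    V: float = math.nan
    O: float = math.nan
    nmax_scored: int = DEFAULT_NMAX
    fit_residual: float = math.nan


@dataclass
class ModelSelectionResult:
    table: pd.DataFrame  # columns K, m, k, V, O
    best_K_by_V: int
    best_K_by_O: int
    fits: dict[int, DualPoissonFit] = field(default_factory=dict)

    @property
    def best_fit(self) -> DualPoissonFit:
        return self.fits[self.best_K_by_O]


def build_distribution(
    clusters: Sequence[ClusterObservation] | Iterable[int],
) -> CopyNumberDistribution:
    """Histogram of copy numbers over observable (N >= 1) clusters."""
    values = [
        c.copy_number if isinstance(c, ClusterObservation) else int(c)
        for c in clusters
    ]
    values = [v for v in values if v >= 1]
    if not values:
        raise FitError("no observable clusters (N >= 1)")
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    n_total = len(values)
    mean = sum(n * c for n, c in counts.items()) / n_total
    return CopyNumberDistribution(counts=counts, n_total=n_total, mean_N=mean)


def _default_pred_max(K: int, m: float, k: float) -> int:
    # mean + 12 SD keeps the truncated tail below 1e-9 (10 SD leaves ~1e-9)
    mean = m + K * k
    sd = math.sqrt(m + K * K * k)
    return max(int(math.ceil(mean + 12 * sd)), K + 1, DEFAULT_NMAX + 1)


def predict_dual_poisson(
    K: int, m: float, k: float, n_pred_max: Optional[int] = None
) -> np.ndarray:
    """P_Total(N) for N = 0..n_pred_max under the monomer + K-mer mixture.

    The default n_pred_max is mean + 12 SD, so the truncated tail mass is
    below 1e-9.
    """
    if K < 1:
        raise FitError("K must be >= 1")
    if m < 0 or k < 0:
        raise FitError("Poisson means must be non-negative")
    if n_pred_max is None:
        n_pred_max = _default_pred_max(K, m, k)
    n = np.arange(n_pred_max + 1)
    j_max = n_pred_max // K
    j = np.arange(j_max + 1)
    pj = poisson.pmf(j, k)  # K-mer count probabilities
    out = np.zeros(n_pred_max + 1)
    for jj, p in zip(j, pj):
        rest = n - K * jj
        valid = rest >= 0
        out[valid] += p * poisson.pmf(rest[valid], m)
    return out


def fit_monomer_mean(
    dist: CopyNumberDistribution, K: int, n_grid: int = 256
) -> tuple[float, float]:
    """Monomer mean from the sub-K bins of the histogram.

    For N < K the mixture reduces to e^{-k} * Poisson(N; m) (a cluster below
    K copies cannot contain a K-mer), with k tied to the observed mean via
    k(m) = max(0, (mean_N - m)/K). m minimizes the squared deviation of that
    prediction from P_obs over N = 1..K-1, searched on (0, mean_N] by a
    coarse grid plus a bounded local polish. Returns (m, residual).

    K = 1 returns mean_N by convention (single-Poisson null model).
    """
    if K < 1:
        raise FitError("K must be >= 1")
    if K == 1:
        return dist.mean_N, 0.0
    sub_bins = np.arange(1, K)
    p_obs = np.array([dist.p_obs(int(n)) for n in sub_bins])
    if not np.any(p_obs > 0):
        raise FitError(f"no observed counts below K={K}; monomer fit impossible")
    mean_n = dist.mean_N

    def objective(m: float) -> float:
        kk = max(0.0, (mean_n - m) / K)
        pred = math.exp(-kk) * poisson.pmf(sub_bins, m)
        return float(np.sum((p_obs - pred) ** 2))

    grid = np.linspace(mean_n / n_grid, mean_n, n_grid)
    values = np.array([objective(m) for m in grid])
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    m_hat = float(res.x)
    if res.fun > values[i]:  # keep the grid point if the polish regressed
        m_hat = float(grid[i])
    return m_hat, float(objective(m_hat))


def oligomer_mean_from_totals(mean_N: float, m: float, K: int) -> float:
    """k = (mean_N - m)/K, clamped at 0 (no fit involved)."""
    if K < 1:
        raise FitError("K must be >= 1")
    k = (mean_N - m) / K
    if k < 0:
        warnings.warn(
            f"observed mean {mean_N:.4g} below monomer mean {m:.4g}; "
            "oligomer mean clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return k


def score_V(
    dist: CopyNumberDistribution, pred: np.ndarray, n_max: int = DEFAULT_NMAX
) -> float:
    """Inverse summed squared error over N = 1..n_max (+inf on perfect fit)."""
    if n_max < 1:
        raise FitError("n_max must be >= 1")
    p_obs = dist.p_obs_vector(n_max)[1:]
    p_pred = _pad(pred, n_max)[1:]
    s = float(np.sum((p_obs - p_pred) ** 2))
    return math.inf if s == 0 else 1.0 / s


def score_O(
    dist: CopyNumberDistribution, pred: np.ndarray, n_max: int = DEFAULT_NMAX
) -> float:
    """Inverse summed relative squared error, weighted by P_obs.

    Bins with P_obs(N) = 0 are excluded so that rare/empty bins cannot
    dominate. Raises if every scored bin is empty.
    """
    if n_max < 1:
        raise FitError("n_max must be >= 1")
    p_obs = dist.p_obs_vector(n_max)[1:]
    p_pred = _pad(pred, n_max)[1:]
    occupied = p_obs > 0
    if not np.any(occupied):
        raise FitError("all scored bins empty; O undefined")
    s = float(np.sum((p_obs[occupied] - p_pred[occupied]) ** 2 / p_obs[occupied]))
    return math.inf if s == 0 else 1.0 / s


def _pad(pred: np.ndarray, n_max: int) -> np.ndarray:
    pred = np.asarray(pred, dtype=float)
    if pred.size >= n_max + 1:
        return pred[: n_max + 1]
    return np.concatenate([pred, np.zeros(n_max + 1 - pred.size)])


def fit_dual_poisson(
    dist: CopyNumberDistribution, K: int, n_max: int = DEFAULT_NMAX
) -> DualPoissonFit:
    """Fit m and k for one candidate K and score the prediction."""
    if K == 1:
        m, k = dist.mean_N, 0.0
        resid = 0.0
        pred = predict_dual_poisson(1, m, 0.0)
    else:
        m, resid = fit_monomer_mean(dist, K)
        k = oligomer_mean_from_totals(dist.mean_N, m, K)
        pred = predict_dual_poisson(K, m, k)
    fit = DualPoissonFit(K=K, m=m, k=k, predicted=pred, nmax_scored=n_max,
                         fit_residual=resid)
    fit.V = score_V(dist, pred, n_max)
    fit.O = score_O(dist, pred, n_max)
    return fit


def select_oligomer_size(
    dist: CopyNumberDistribution,
    k_min: int = 1,
    k_max: int = 10,
    n_max: int = DEFAULT_NMAX,
) -> ModelSelectionResult:
    """Scan candidate oligomer sizes and select the best by V and O.

    K = 1 is the single-Poisson null (mean = mean_N). Ties break toward the
    smaller K (parsimony). A K whose sub-K bins are all empty cannot be
    fitted and is recorded with NaN scores.
    """
    rows = []
    fits: dict[int, DualPoissonFit] = {}
    for K in range(k_min, k_max + 1):
        try:
            fit = fit_dual_poisson(dist, K, n_max)
        except FitError as exc:
            log.warning("K=%d skipped: %s", K, exc)
            rows.append({"K": K, "m": math.nan, "k": math.nan,
                         "V": math.nan, "O": math.nan})
            continue
        fits[K] = fit
        rows.append({"K": K, "m": fit.m, "k": fit.k, "V": fit.V, "O": fit.O})
    table = pd.DataFrame(rows)
    if not fits:
        raise FitError("no candidate K could be fitted")

    def argmax_ties_small(col: str) -> int:
        valid = table.dropna(subset=[col])
        best = valid[col].max()
        return int(valid.loc[valid[col] >= best, "K"].min())

    return ModelSelectionResult(
        table=table,
        best_K_by_V=argmax_ties_small("V"),
        best_K_by_O=argmax_ties_small("O"),
        fits=fits,
    )
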