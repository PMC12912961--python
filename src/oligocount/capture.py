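"""Cooperative vesicle-capture model.

Given the fitted monomer + K-mer mixture, a cluster of N copies contains a
latent number n of oligomers with posterior

    P_n(N) = Poisson(n; k) Poisson(N - K n; m) / sum_j Poisson(j; k) Poisson(N - K j; m)

for n = 0..floor(N/K). If n oligomers capture a vesicle with probability
p_n (p_0 = 0; p_n saturates at p_{n_max} beyond n_max), the per-cluster
capture probability is P_bind(N) = sum_{n>=1} p_n P_n(N). The p_n are fitted
from (N, bound) observations by maximizing the Bernoulli likelihood under
box constraints (a least-squares-on-curve mode is available).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import poisson

from ._util import ConfigError, FitError
from .oligomer import DualPoissonFit
from .synthetic import ClusterObservation

__all__ = [
    "OligomerPosterior",
    "CaptureModel",
    "CaptureCurve",
    "oligomer_posterior",
    "predict_bind_probability",
    "empirical_bind_curve",
    "fit_capture_probabilities",
]

log = logging.getLogger(__name__)

_EPS = 1e-10  # probability clip inside the log-likelihood


@dataclass
class OligomerPosterior:
    N: int
    K: int
    probabilities: np.ndarray  # P_n(N) for n = 0..floor(N/K)


@dataclass
class CaptureModel:
    """Per-oligomer-count capture probabilities with saturation.

    ``capture_probs[n]`` is the probability that a cluster holding exactly n
    oligomers captures a vesicle; entry 0 is fixed at 0 and counts beyond
    ``n_max`` use the last entry.
    """

    K: int
    capture_probs: np.ndarray  # index 0..n_max, entry 0 == 0
    log_likelihood: float = math.nan

    def __post_init__(self) -> None:
        self.capture_probs = np.asarray(self.capture_probs, dtype=float)
        if self.capture_probs.ndim != 1 or self.capture_probs.size < 2:
            raise ConfigError("capture_probs must cover at least n = 0 and 1")
        if self.capture_probs[0] != 0:
            raise ConfigError("p0 (zero oligomers) must be 0")
        if np.any(self.capture_probs < 0) or np.any(self.capture_probs > 1):
            raise ConfigError("capture probabilities must lie in [0, 1]")

    @property
    def n_max(self) -> int:
        return self.capture_probs.size - 1

    def p(self, n: int) -> float:
        return float(self.capture_probs[min(n, self.n_max)])


@dataclass
class CaptureCurve:
    """Per-N empirical bound fraction, optionally with model prediction."""

    table: pd.DataFrame  # columns N, n_clusters, n_bound, fraction_bound[, predicted]


def oligomer_posterior(N: int, fit: DualPoissonFit) -> OligomerPosterior:
    """Posterior over the number of oligomers in a cluster of N copies."""
    if N < 1:
        raise FitError("N must be >= 1")
    K, m, k = fit.K, fit.m, fit.k
    n = np.arange(N // K + 1)
    weights = poisson.pmf(n, k) * poisson.pmf(N - K * n, m)
    total = weights.sum()
    if total <= 0:
        raise FitError(
            f"degenerate posterior at N={N}: no composition has positive probability"
        )
    return OligomerPosterior(N=N, K=K, probabilities=weights / total)


def _saturated_coefficients(
    N: int, fit: DualPoissonFit, n_max: int
) -> np.ndarray:
    """Coefficients c_j (j = 1..n_max) such that P_bind(N) = sum_j p_j c_j.

    Posterior mass at oligomer counts beyond n_max is folded onto the
    saturating entry n_max.
    """
    post = oligomer_posterior(N, fit).probabilities
    c = np.zeros(n_max)
    for n in range(1, post.size):
        c[min(n, n_max) - 1] += post[n]
    return c


def predict_bind_probability(N: int, fit: DualPoissonFit, model: CaptureModel) -> float:
    """P_bind(N) = sum_{n>=1} p_n P_n(N); zero when N < K."""
    if model.K != fit.K:
        raise ConfigError("capture model and Poisson fit disagree on K")
    if N < fit.K:
        return 0.0
    post = oligomer_posterior(N, fit).probabilities
    p = np.array([model.p(n) for n in range(post.size)])
    return float(np.clip(np.dot(p, post), 0.0, 1.0))


def empirical_bind_curve(clusters: Sequence[ClusterObservation]) -> CaptureCurve:
    """Fraction of clusters bound, per copy number N."""
    unknown = [c.cluster_id for c in clusters if c.vesicle_bound is None]
    if unknown:
        raise FitError(
            f"vesicle_bound unknown for cluster ids {unknown[:10]}"
            + ("..." if len(unknown) > 10 else "")
        )
    rows: dict[int, list[int]] = {}
    for c in clusters:
        if c.copy_number < 1:
            continue
        tot, bound = rows.setdefault(c.copy_number, [0, 0])
        rows[c.copy_number] = [tot + 1, bound + int(c.vesicle_bound)]
    table = pd.DataFrame(
        [
            {
                "N": n,
                "n_clusters": tot,
                "n_bound": bnd,
                "fraction_bound": bnd / tot,
            }
            for n, (tot, bnd) in sorted(rows.items())
        ]
    )
    return CaptureCurve(table=table)


def attach_prediction(
    curve: CaptureCurve, fit: DualPoissonFit, model: CaptureModel
) -> CaptureCurve:
    """Add the model's P_bind(N) column to an empirical curve."""
    table = curve.table.copy()
    table["predicted"] = [
        predict_bind_probability(int(n), fit, model) for n in table["N"]
    ]
    return CaptureCurve(table=table)


def fit_capture_probabilities(
    clusters: Sequence[ClusterObservation],
    fit: DualPoissonFit,
    n_max: int,
    method: str = "likelihood",
    n_restarts: int = 8,
    seed: int = 0,
) -> CaptureModel:
    """Fit p_1..p_{n_max} from per-cluster (N, bound) observations.

    The default maximizes the Bernoulli log-likelihood
    sum_i [b_i ln P_bind(N_i) + (1 - b_i) ln(1 - P_bind(N_i))] over
    [0, 1]^{n_max} with p_0 = 0 and saturation beyond n_max, using
    multistart L-BFGS-B. ``method="curve"`` instead minimizes the
    count-weighted squared error between the empirical per-N bound fraction
    and P_bind(N).
    """
    if n_max < 1:
        raise FitError("n_max must be >= 1")
    if method not in ("likelihood", "curve"):
        raise ConfigError(f"unknown fitting method {method!r}")
    curve = empirical_bind_curve(clusters)
    tbl = curve.table
    eligible = tbl[tbl["N"] >= fit.K]
    if eligible.empty:
        raise FitError(
            f"no clusters with N >= K={fit.K}; capture probabilities unidentifiable"
        )
    n_vals = eligible["N"].to_numpy(dtype=int)
    coeff = np.stack([_saturated_coefficients(int(n), fit, n_max) for n in n_vals])
    n_tot = eligible["n_clusters"].to_numpy(dtype=float)
    n_bound = eligible["n_bound"].to_numpy(dtype=float)

    if method == "likelihood":

        def objective(p: np.ndarray) -> tuple[float, np.ndarray]:
            pb = np.clip(coeff @ p, _EPS, 1.0 - _EPS)
            nll = -float(
                np.sum(n_bound * np.log(pb) + (n_tot - n_bound) * np.log1p(-pb))
            )
            grad = -coeff.T @ (n_bound / pb - (n_tot - n_bound) / (1.0 - pb))
            return nll, grad

    else:
        frac = n_bound / n_tot

        def objective(p: np.ndarray) -> tuple[float, np.ndarray]:
            pb = coeff @ p
            resid = pb - frac
            return float(np.sum(n_tot * resid**2)), 2.0 * coeff.T @ (n_tot * resid)

    rng = np.random.default_rng(seed)
    starts = [np.full(n_max, 0.5), np.linspace(0.1, 0.9, n_max)]
    starts += [rng.random(n_max) for _ in range(max(0, n_restarts - len(starts)))]
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * n_max,
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    probs = np.concatenate([[0.0], np.clip(best.x, 0.0, 1.0)])
    loglik = -float(best.fun) if method == "likelihood" else math.nan
    return CaptureModel(K=fit.K, capture_probs=probs, log_likelihood=loglik)
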