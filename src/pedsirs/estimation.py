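"""Proportion estimation for clustered binary diagnostic outcomes.

Sensitivity and specificity are marginal proportions of repeated binary
outcomes (assessment units, patient-days) clustered within patients. The
GEE route fits an intercept-only logistic marginal model with an
exchangeable working correlation:

    logit P(Y_ij = 1) = beta,     Corr(Y_ij, Y_ik) = alpha   (j != k)

For this model the estimating equation has the closed form

    expit(beta) = sum_i w_i Ybar_i / sum_i w_i,
    w_i = n_i / (1 + (n_i - 1) alpha),

so estimation is a fixed-point iteration: solve for beta given alpha, then
re-estimate alpha from Pearson residual cross-products, until beta is
stable. The robust (sandwich) variance of beta reduces to

    Var(beta) = sum_i w_i^2 (Ybar_i - mu)^2 / (mu (1 - mu) sum_i w_i)^2.

Wald 95% intervals are symmetric on the logit scale and back-transformed
(a linear-scale variant is available for comparison). With all cluster
sizes equal the weights cancel and the GEE estimate is the pooled mean;
with singleton clusters the sandwich SE is the binomial SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

Z95 = 1.96  # conventional two-sided 95% normal quantile


class EstimationError(RuntimeError):
    pass


@dataclass
class GeeFit:
    beta: float
    alpha: float
    sandwich_se: float
    converged: bool
    iterations: int
    n_units: int
    n_clusters: int
    degenerate: bool = False
    ee_residual: float = float("nan")  # scaled estimating-equation residual at beta


@dataclass
class AccuracyEstimate:
    measure: str  # 'sensitivity' | 'specificity' | 'proportion'
    estimate: float
    se: float
    ci: tuple[float, float]
    method: str  # 'crude' | 'gee'
    n_units: int
    n_clusters: int
    degenerate: bool = False
    fit: GeeFit | None = None

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "method": self.method,
            "n_units": self.n_units,
            "n_clusters": self.n_clusters,
            "degenerate": self.degenerate,
        }


def wald_ci(beta: float, se: float, scale: str = "logit") -> tuple[float, float]:
    """95% Wald interval for a proportion.

    On the default logit scale ``beta`` is the log-odds and the interval is
    expit(beta +/- 1.96 se); on the linear scale ``beta`` is the proportion
    itself and the interval is clipped to [0, 1].
    """
    if not (math.isfinite(beta) and math.isfinite(se)):
        raise ValueError("beta and se must be finite")
    lo, hi = beta - Z95 * se, beta + Z95 * se
    if scale == "logit":
        return (float(expit(lo)), float(expit(hi)))
    if scale == "linear":
        return (float(max(0.0, lo)), float(min(1.0, hi)))
    raise ValueError(f"unknown CI scale {scale!r}")


def crude_estimate(
    successes: int, failures: int, measure: str = "proportion", ci_scale: str = "logit"
) -> AccuracyEstimate:
    """Binomial proportion with Wald CI; baseline for the GEE route."""
    n = successes + failures
    if n <= 0:
        raise EstimationError("zero denominator")
    p = successes / n
    se_lin = math.sqrt(p * (1 - p) / n)
    if p in (0.0, 1.0):
        return AccuracyEstimate(measure, p, 0.0, (p, p), "crude", n, n, degenerate=True)
    if ci_scale == "logit":
        beta = float(logit(p))
        se_logit = se_lin / (p * (1 - p))
        ci = wald_ci(beta, se_logit, "logit")
    else:
        ci = wald_ci(p, se_lin, "linear")
    return AccuracyEstimate(measure, p, se_lin, ci, "crude", n, n)


def _alpha_moment(ybar: np.ndarray, n: np.ndarray, mu: float) -> float:
    """Exchangeable correlation from Pearson residual cross-products."""
    v = mu * (1 - mu)
    # per-cluster residual sum and sum of squares from Ybar and n (binary data)
    s1 = n * (ybar - mu) / math.sqrt(v)  # sum of residuals
    # y_ij^2 = y_ij for binary, so sum r^2 = (n ybar (1-mu)^2 + n (1-ybar) mu^2)/v
    s2 = (n * ybar * (1 - mu) ** 2 + n * (1 - ybar) * mu**2) / v
    cross = 0.5 * float(np.sum(s1**2 - s2))
    n_total = int(np.sum(n))
    n_pairs = float(np.sum(n * (n - 1) / 2))
    if n_pairs <= 1:
        return 0.0
    phi = float(np.sum(s2)) / max(n_total - 1, 1)
    alpha = cross / ((n_pairs - 1) * phi)
    return float(np.clip(alpha, -0.99, 0.99))


def gee_estimate(
    outcomes: Sequence[int],
    clusters: Sequence,
    measure: str = "proportion",
    ci_scale: str = "logit",
    tol: float = 1e-12,
    max_iter: int = 200,
) -> AccuracyEstimate:
    """Intercept-only logistic GEE with exchangeable working correlation.

    ``outcomes`` are 0/1 assessment units; ``clusters`` their cluster labels
    (patients). All-identical outcomes return a boundary estimate with a
    degenerate, flagged CI rather than raising.
    """
    y = np.asarray(outcomes, dtype=float)
    if y.size < 1 or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be non-empty binary 0/1")
    labels, inv = np.unique(np.asarray(clusters), return_inverse=True)
    n = np.bincount(inv).astype(float)
    ybar = np.bincount(inv, weights=y) / n
    n_units, n_clusters = int(y.size), int(labels.size)

    if y.min() == y.max():  # degenerate stratum: estimate pinned at 0 or 1
        p = float(y[0])
        fit = GeeFit(
            beta=math.inf if p == 1.0 else -math.inf, alpha=0.0, sandwich_se=math.nan,
            converged=True, iterations=0, n_units=n_units, n_clusters=n_clusters,
            degenerate=True, ee_residual=0.0,
        )
        return AccuracyEstimate(
            measure, p, 0.0, (p, p), "gee", n_units, n_clusters, degenerate=True, fit=fit
        )

    alpha = 0.0
    mu = float(np.mean(y))
    beta = float(logit(mu))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = n / (1.0 + (n - 1.0) * alpha)
        mu = float(np.sum(w * ybar) / np.sum(w))
        new_beta = float(logit(mu))
        alpha = _alpha_moment(ybar, n, mu)
        if abs(new_beta - beta) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    if not converged:
        raise EstimationError(
            f"GEE fixed point did not converge in {max_iter} iterations "
            f"(last beta={beta:.6g}, alpha={alpha:.4g})"
        )
    # polish: re-solve the estimating equation exactly at the final alpha
    w = n / (1.0 + (n - 1.0) * alpha)
    mu = float(np.sum(w * ybar) / np.sum(w))
    beta = float(logit(mu))
    v = mu * (1 - mu)
    ee_resid = float(np.sum(w * (ybar - mu)))  # estimating equation at beta
    var_beta = float(np.sum(w**2 * (ybar - mu) ** 2)) / (v * np.sum(w)) ** 2
    se_beta = math.sqrt(var_beta)
    fit = GeeFit(
        beta=beta, alpha=alpha, sandwich_se=se_beta, converged=True, iterations=it,
        n_units=n_units, n_clusters=n_clusters, ee_residual=ee_resid,
    )
    if ci_scale == "logit":
        ci = wald_ci(beta, se_beta, "logit")
    else:
        ci = wald_ci(mu, v * se_beta, "linear")
    return AccuracyEstimate(
        measure, mu, v * se_beta, ci, "gee", n_units, n_clusters, fit=fit
    )


def sample_size_one_proportion(
    p0: float, p1: float, alpha: float = 0.05, power: float = 0.90
) -> int:
    """One-sample normal-approximation sample size (chi-square equivalent).

    n = ceil( (z_{1-a/2} sqrt(p0 q0) + z_{power} sqrt(p1 q1))^2 / (p1-p0)^2 ),
    without continuity correction.
    """
    for name, v in (("p0", p0), ("p1", p1), ("alpha", alpha), ("power", power)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if p0 == p1:
        raise ValueError("p0 and p1 must differ")
    za = norm.ppf(1 - alpha / 2)
    zb = norm.ppf(power)
    num = (za * math.sqrt(p0 * (1 - p0)) + zb * math.sqrt(p1 * (1 - p1))) ** 2
    return int(math.ceil(num / (p1 - p0) ** 2))
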