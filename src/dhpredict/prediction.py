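"""RR-BLUP estimation of genome-wide marker effects and genomic prediction.

Model: p = 1*mu + X a + e with a ~ N(0, s_a2 I) over all markers and
e ~ N(0, s_e2 I).  The ridge solution

    a_hat = (X'X + lambda I)^-1 X'(p - 1 mu_hat),   lambda = s_e2 / s_a2,

is computed either in the marker space (primal, via the mixed-model
equations) or in the n-dimensional line space (dual) through the kernel
K = XX', which is the GBLUP formulation with the realized relationship
matrix; both give identical predictions.  lambda is set by REML by
default, using the spectral decomposition of the centred kernel and a
one-dimensional search over the variance ratio.

Predictions are for the phenotyped lines themselves: y = mu_hat + X a_hat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, helmert
from scipy.optimize import minimize_scalar

from .breeding_sim import DHPopulation
from .trial_sim import PhenotypeSet

__all__ = ["RRBLUPModel", "Predictions", "fit_rrblup", "predict", "gblup_predict", "reml_lambda"]


@dataclass(frozen=True)
class RRBLUPModel:
    """Fitted RR-BLUP model: intercept, shrunken effects, variance ratio."""

    mu: float
    effects: np.ndarray
    lam: float
    sigma_a2: float | None = None
    sigma_e2: float | None = None
    mode: str = "reml"
    flagged: bool = False  # degenerate fit (zero phenotypic variance)
    converged: bool = True

    def __post_init__(self):
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass(frozen=True)
class Predictions:
    """Per-line genomic predictions y, in trait units."""

    values: np.ndarray
    line_ids: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _as_matrix(genotypes) -> tuple[np.ndarray, tuple | None]:
    if isinstance(genotypes, DHPopulation):
        return genotypes.genotypes.astype(float), genotypes.line_ids
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2:
        raise ValueError("genotypes must be 2-D")
    return X, None


def _as_phenotype(phenotypes) -> np.ndarray:
    if isinstance(phenotypes, PhenotypeSet):
        return phenotypes.values
    return np.asarray(phenotypes, dtype=float)


def reml_lambda(K: np.ndarray, p: np.ndarray) -> tuple[float, float, float, bool]:
    """REML variance ratio for the kernel model p = 1 mu + g + e, g ~ N(0, s_a2 K).

    Returns ``(lam, sigma_a2, sigma_e2, converged)``.  The intercept is
    projected out with an orthonormal contrast basis; the restricted
    likelihood is profiled over s_a2 and maximized over
    ``delta = s_e2/s_a2`` on a log grid refined by bounded Brent search.
    """
    n = p.size
    Q = helmert(n)  # (n-1, n), rows orthonormal, orthogonal to 1
    B = Q @ K @ Q.T
    lam_eig, V = np.linalg.eigh(B)
    lam_eig = np.clip(lam_eig, 0.0, None)
    eta2 = (V.T @ (Q @ p)) ** 2

    def neg_restricted_ll(log_delta: float) -> float:
        d = math.exp(log_delta)
        denom = lam_eig + d
        s2 = float(np.sum(eta2 / denom)) / (n - 1)
        if not np.isfinite(s2) or s2 <= 0:
            return np.inf
        return (n - 1) * math.log(s2) + float(np.log(denom).sum())

    res = minimize_scalar(neg_restricted_ll, bounds=(-14.0, 14.0), method="bounded")
    converged = bool(res.success) and np.isfinite(res.fun)
    if converged:
        delta = math.exp(res.x)
    else:  # pragma: no cover - bounded Brent essentially always succeeds
        delta = float(np.trace(K)) / n
        warnings.warn("REML did not converge; falling back to heuristic lambda", RuntimeWarning)
    sigma_a2 = float(np.sum(eta2 / (lam_eig + delta))) / (n - 1)
    sigma_e2 = delta * sigma_a2
    return delta, sigma_a2, sigma_e2, converged


def fit_rrblup(genotypes, phenotypes, mode: str = "reml", lam: float | None = None, solver: str = "auto") -> RRBLUPModel:
    """Fit RR-BLUP marker effects from phenotypes of genotyped lines.

    ``mode`` is ``"reml"`` (estimate lambda from the data) or
    ``"fixed_lambda"`` (use the supplied ``lam``).  ``solver`` picks the
    marker-space (``"primal"``) or kernel-space (``"dual"``) solve;
    ``"auto"`` uses the dual whenever markers outnumber lines, and always
    above 2,000 markers.
    """
    X, _ = _as_matrix(genotypes)
    p = _as_phenotype(phenotypes)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two lines")
    if p.shape != (n,):
        raise ValueError("phenotype length does not match genotype rows")
    if not np.isfinite(X).all() or not np.isfinite(p).all():
        raise ValueError("non-finite inputs")

    if float(np.var(p)) == 0.0:
        return RRBLUPModel(mu=float(p[0]), effects=np.zeros(m), lam=1.0, mode=mode, flagged=True)

    sigma_a2 = sigma_e2 = None
    converged = True
    if mode == "reml":
        K = X @ X.T
        lam, sigma_a2, sigma_e2, converged = reml_lambda(K, p)
    elif mode == "fixed_lambda":
        if lam is None or lam <= 0:
            raise ValueError("fixed_lambda mode needs lam > 0")
        K = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if solver == "auto":
        solver = "dual" if (m > n or m > 2000) else "primal"

    if solver == "dual":
        if K is None:
            K = X @ X.T
        mu, alpha = _dual_solve(K, p, lam)
        effects = X.T @ alpha
    elif solver == "primal":
        mu, effects = _primal_solve(X, p, lam)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    return RRBLUPModel(
        mu=mu, effects=effects, lam=lam, sigma_a2=sigma_a2, sigma_e2=sigma_e2,
        mode=mode, converged=converged,
    )


def _dual_solve(K: np.ndarray, p: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """GLS intercept and dual coefficients alpha = (K + lam I)^-1 (p - 1 mu)."""
    n = p.size
    C = cho_factor(K + lam * np.eye(n))
    ones = np.ones(n)
    vi1 = cho_solve(C, ones)
    mu = float(vi1 @ p) / float(vi1 @ ones)
    alpha = cho_solve(C, p - mu)
    return mu, alpha


def _primal_solve(X: np.ndarray, p: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Mixed-model equations for (mu, a) in marker space."""
    n, m = X.shape
    ones = np.ones(n)
    A = np.empty((m + 1, m + 1))
    A[0, 0] = n
    A[0, 1:] = ones @ X
    A[1:, 0] = A[0, 1:]
    A[1:, 1:] = X.T @ X + lam * np.eye(m)
    rhs = np.concatenate(([ones @ p], X.T @ p))
    sol = np.linalg.solve(A, rhs)
    return float(sol[0]), sol[1:]


def predict(model: RRBLUPModel, genotypes) -> Predictions:
    """y = mu_hat + X a_hat for the supplied genotypes."""
    X, line_ids = _as_matrix(genotypes)
    if X.shape[1] != model.effects.size:
        raise ValueError("genotype marker count does not match the fitted model")
    return Predictions(model.mu + X @ model.effects, line_ids)


def gblup_predict(K: np.ndarray, p: np.ndarray, lam: float) -> np.ndarray:
    """GBLUP line values from a relationship kernel: mu + K(K+lam I)^-1 (p-mu).

    Independent of the marker-effect route; with K = XX' and matched
    lambda it must reproduce :func:`predict` exactly.
    """
    mu, alpha = _dual_solve(np.asarray(K, dtype=float), np.asarray(p, dtype=float), lam)
    return mu + K @ alpha
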