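"""Additive marker effects, genotypic values, and genetic-variance calibration.

The trait model is purely additive: the genotypic value of a DH line is the
intercept plus the dot product of its -1/+1 marker genotype with the true
per-marker effects.  Because the experimental effect estimates these
simulations emulate are not available, raw effects are drawn from a chosen
distribution and then rescaled so that the genetic variance of the progeny
of a given mating scheme matches a target value; the population-level
variance (not the effect distribution) is what the downstream correlations
depend on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_rng
from .breeding_sim import CrossPlan, DHPopulation, simulate_population
from .genome_founders import FounderPanel, GeneticMap

__all__ = [
    "MarkerEffects",
    "GeneticValues",
    "UncalibratableError",
    "draw_effects",
    "apply_donor_penalty",
    "reestimated_effects",
    "genotypic_values",
    "calibrate_sigma_g",
]

#: default intercept, the centre of a plausible winter-barley yield range
#: (dt/ha); purely cosmetic since every correlation is location-invariant.
DEFAULT_INTERCEPT = 85.0


class UncalibratableError(ValueError):
    """Raised when raw effects produce (near-)zero genetic variance."""


@dataclass(frozen=True)
class MarkerEffects:
    """True additive marker effects (trait units per allele-coding unit)."""

    effects: np.ndarray
    intercept: float = DEFAULT_INTERCEPT
    calibration: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))
        if self.effects.ndim != 1:
            raise ValueError("effects must be a 1-D vector")

    @property
    def n_markers(self) -> int:
        return self.effects.size

    def scaled(self, factor: float, calibration: dict | None = None) -> "MarkerEffects":
        return MarkerEffects(self.effects * factor, self.intercept, calibration)

    def to_frame(self, gmap: GeneticMap) -> pd.DataFrame:
        if gmap.n_markers != self.n_markers:
            raise ValueError("map does not match effect vector")
        frame = gmap.to_frame()
        frame["effect"] = self.effects
        return frame


@dataclass(frozen=True)
class GeneticValues:
    """True genotypic values g of a population, in trait units."""

    values: np.ndarray
    line_ids: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")


def draw_effects(
    gmap: GeneticMap,
    distribution: str = "gaussian",
    seed=None,
    scale: float = 1.0,
    k: int | None = None,
) -> MarkerEffects:
    """Draw i.i.d. raw marker effects for every marker of the map.

    ``distribution`` is one of ``gaussian``, ``laplace`` or ``sparse``;
    sparse draws gaussian effects at ``k`` randomly chosen markers and sets
    all others to zero (``sparse(0)`` gives a flat, zero-variance trait).
    """
    rng = as_rng(seed)
    m = gmap.n_markers
    if distribution == "gaussian":
        eff = rng.normal(0.0, scale, size=m)
    elif distribution == "laplace":
        eff = rng.laplace(0.0, scale, size=m)
    elif distribution == "sparse":
        if k is None:
            raise ValueError("sparse effects need k")
        if k > m:
            raise ValueError(f"k={k} exceeds marker count {m}")
        eff = np.zeros(m)
        if k > 0:
            idx = rng.choice(m, size=k, replace=False)
            eff[idx] = rng.normal(0.0, scale, size=k)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return MarkerEffects(eff)


def apply_donor_penalty(effects: MarkerEffects, panel: FounderPanel) -> MarkerEffects:
    """Align effect signs at pool-differentiated markers against the donor allele.

    In elite x donor material the donor pool contributes resistance but a
    systematic yield penalty, so at markers that separate the pools the
    donor allele (coded 1, i.e. +1 in line coding) is made trait-decreasing
    by flipping signs to ``-|a|``.  This directional pool contrast is what
    makes the genetic variance of pool-crossing progeny several-fold larger
    than that of a within-pool diallel; effect magnitudes are untouched.
    """
    if panel.pool_differentiated is None:
        return effects
    eff = effects.effects.copy()
    mask = np.asarray(panel.pool_differentiated, dtype=bool)
    if mask.shape != eff.shape:
        raise ValueError("panel markers do not match effect vector")
    eff[mask] = -np.abs(eff[mask])
    return MarkerEffects(eff, effects.intercept, effects.calibration)


def reestimated_effects(
    panel: FounderPanel,
    plan: CrossPlan,
    effects: MarkerEffects,
    seed=None,
) -> MarkerEffects:
    """Error-free ridge re-estimation of effects through a reference population.

    Simulates one reference DH population under ``plan``, computes its true
    genotypic values from ``effects``, and returns the marker effects a
    ridge regression with vanishing shrinkage would recover from those
    values — the minimum-norm effect vector reproducing the reference
    population's genotypic values exactly.  This emulates a study whose
    "true" effects are themselves genome-wide estimates obtained from an
    experimental panel, assumed free of estimation error: the resulting
    truth is confined to the genetic contrasts the reference population
    actually displays, which is what makes re-prediction of related
    material from the same parents so accurate.
    """
    rng = as_rng(seed)
    pop = simulate_population(panel, plan, rng)
    X = pop.genotypes.astype(float)
    g0 = X @ effects.effects
    K = X @ X.T
    n = X.shape[0]
    eps = 1e-8 * float(np.trace(K)) / n  # scale-free jitter for the solve
    alpha = np.linalg.solve(K + eps * np.eye(n), g0 - g0.mean())
    return MarkerEffects(X.T @ alpha, effects.intercept)


def genotypic_values(pop: DHPopulation, effects: MarkerEffects) -> GeneticValues:
    """g = intercept + X @ a for the -1/+1 genotype matrix X."""
    if effects.n_markers != pop.map.n_markers:
        raise ValueError("effects and population marker sets differ")
    g = effects.intercept + pop.genotypes.astype(float) @ effects.effects
    return GeneticValues(g, pop.line_ids)


def calibrate_sigma_g(
    panel: FounderPanel,
    plan: CrossPlan,
    raw_effects: MarkerEffects,
    target_sigma_g2: float,
    n_calibration_lines: int = 5000,
    seed=None,
) -> MarkerEffects:
    """Rescale raw effects so progeny genetic variance matches a target.

    A large calibration population (default 5,000 DH lines) is simulated
    under ``plan``; the effects are multiplied by
    ``sqrt(target / realized)`` so the calibration population's genetic
    variance equals the target exactly.  A second, fresh calibration draw
    re-checks the realized variance against a generous relative tolerance
    sized for clustered DH populations, whose variance estimates are
    noisier than the iid rate because lines within a cross share parental
    segments.
    """
    if target_sigma_g2 <= 0:
        raise ValueError("target variance must be positive")
    rng = as_rng(seed)
    n_l = max(1, math.ceil(n_calibration_lines / plan.n_crosses))
    cal_plan = plan.with_family_size(n_l)

    pop = simulate_population(panel, cal_plan, rng)
    g_raw = pop.genotypes.astype(float) @ raw_effects.effects
    realized_raw = float(np.var(g_raw, ddof=1))
    if realized_raw < 1e-12 * max(1.0, float(np.abs(raw_effects.effects).sum()) ** 2):
        raise UncalibratableError(
            "raw effects give (near-)zero genetic variance under this plan; "
            "cannot calibrate"
        )
    factor = math.sqrt(target_sigma_g2 / realized_raw)

    # independent re-check on a fresh draw
    check_pop = simulate_population(panel, cal_plan, rng)
    g_check = factor * (check_pop.genotypes.astype(float) @ raw_effects.effects)
    realized_check = float(np.var(g_check, ddof=1))
    # lines of one cross share parental segments, so the variance estimate
    # is noisier than the iid sqrt(2/(n-1)) rate (~3% relative SD at 5,000
    # clustered lines); the guard is meant to catch scale bugs, not noise
    n = cal_plan.n_lines
    rel_tol = max(0.15, 4.0 * math.sqrt(2.0 / (n - 1)))
    if abs(realized_check / target_sigma_g2 - 1.0) > rel_tol:
        raise RuntimeError(
            f"calibration re-check failed: realized {realized_check:.4g} vs "
            f"target {target_sigma_g2:.4g} (rel tol {rel_tol:.3g})"
        )

    record = {
        "target_sigma_g2": target_sigma_g2,
        "realized_raw_sigma_g2": realized_raw,
        "realized_check_sigma_g2": realized_check,
        "scaling_factor": factor,
        "scheme": plan.scheme,
        "n_calibration_lines": n,
    }
    return raw_effects.scaled(factor, record)
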