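"""Virtual field evaluation: masking effects and phenotypes.

A trial with E environments and R replications per environment is reduced
to line-mean level: averaging a variance component over its replications
divides its variance by the replication count, so the masking effect of
line l in cross c is

    m_cl = u_c + v_l + w,   u ~ N(0, s_ce2/E),  v ~ N(0, s_le2/E),
                            w ~ N(0, s_eps2/(E*R)),

with u drawn once per cross (shared by all its lines) and v, w per line.
The phenotype is p_cl = g_cl + m_cl.  No plot-level values are simulated;
the line-mean reduction is algebraically identical for every correlation
studied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_rng
from .breeding_sim import DHPopulation
from .quantgen import GeneticValues

__all__ = [
    "TrialDesign",
    "PhenotypeSet",
    "simulate_masking",
    "simulate_phenotypes",
    "expected_r_pg",
]


@dataclass(frozen=True)
class TrialDesign:
    """Trial dimensions and plot-level masking variance components.

    ``sigma_ce2``: cross-by-environment variance; ``sigma_le2``:
    line-by-environment variance; ``sigma_eps2``: residual plot error.
    All in squared trait units at plot level; the design scales them.
    """

    n_environments: int
    n_replications: int
    sigma_ce2: float
    sigma_le2: float
    sigma_eps2: float

    def __post_init__(self):
        if self.n_environments < 1 or self.n_replications < 1:
            raise ValueError("E and R must be >= 1")
        if min(self.sigma_ce2, self.sigma_le2, self.sigma_eps2) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def var_u(self) -> float:
        return self.sigma_ce2 / self.n_environments

    @property
    def var_v(self) -> float:
        return self.sigma_le2 / self.n_environments

    @property
    def var_w(self) -> float:
        return self.sigma_eps2 / (self.n_environments * self.n_replications)

    @property
    def masking_variance(self) -> float:
        """Total line-mean masking variance s_m2."""
        return self.var_u + self.var_v + self.var_w


@dataclass(frozen=True)
class PhenotypeSet:
    """Per-line phenotypes, optionally retaining the masking components."""

    values: np.ndarray
    line_ids: tuple | None = None
    components: dict | None = None  # {"g", "u", "v", "w"} per line

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("phenotypes must be 1-D")
        if self.components is not None:
            total = sum(self.components[k] for k in ("g", "u", "v", "w"))
            if not np.allclose(total, self.values):
                raise ValueError("components do not sum to the phenotypes")

    def to_frame(self, cross_of_origin=None) -> pd.DataFrame:
        data = {"p": self.values}
        if cross_of_origin is not None:
            data["cross"] = np.asarray(cross_of_origin)
        if self.components:
            data.update(self.components)
        frame = pd.DataFrame(data)
        if self.line_ids is not None:
            frame.index = pd.Index(self.line_ids, name="line_id")
        return frame


def simulate_masking(pop, design: TrialDesign, rng, return_components: bool = False):
    """Draw the masking vector m = u + v + w for a population.

    ``pop`` may be a :class:`DHPopulation` or a plain array of cross
    indices.  u is drawn once per cross and broadcast to its lines.
    """
    rng = as_rng(rng)
    cross = pop.cross_of_origin if isinstance(pop, DHPopulation) else np.asarray(pop, dtype=int)
    n = cross.size
    crosses, inverse = np.unique(cross, return_inverse=True)
    u = rng.normal(0.0, math.sqrt(design.var_u), size=crosses.size)[inverse]
    v = rng.normal(0.0, math.sqrt(design.var_v), size=n)
    w = rng.normal(0.0, math.sqrt(design.var_w), size=n)
    m = u + v + w
    if return_components:
        return m, {"u": u, "v": v, "w": w}
    return m


def simulate_phenotypes(
    g,
    pop,
    design: TrialDesign,
    rng,
    keep_components: bool = False,
) -> PhenotypeSet:
    """p = g + m with m from :func:`simulate_masking`."""
    gv = g.values if isinstance(g, GeneticValues) else np.asarray(g, dtype=float)
    cross = pop.cross_of_origin if isinstance(pop, DHPopulation) else np.asarray(pop, dtype=int)
    if gv.shape != cross.shape:
        raise ValueError("genotypic values and population sizes differ")
    m, comps = simulate_masking(cross, design, rng, return_components=True)
    line_ids = pop.line_ids if isinstance(pop, DHPopulation) else None
    components = {"g": gv, **comps} if keep_components else None
    return PhenotypeSet(gv + m, line_ids, components)


def expected_r_pg(sigma_g2: float, design: TrialDesign) -> float:
    """Plug-in expectation of corr(p, g): sqrt(s_g2 / (s_g2 + s_m2)).

    This treats sample moments as population moments; the mean *sample*
    correlation over a cross-structured population deviates from it by a
    few thousandths (downward for high correlations via ordinary finite-n
    bias amplified by the cross-shared u term, upward for designs with
    very few crosses, whose sample variance of p is volatile).
    """
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be non-negative")
    denom = sigma_g2 + design.masking_variance
    if denom == 0:
        raise ValueError("total variance is zero")
    return math.sqrt(sigma_g2 / denom)
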