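"""Meiosis simulation and mating schemes for doubled-haploid populations.

Crossing scheme: two homozygous parents are crossed to give an F1; a single
gamete is drawn from the F1 by simulated meiosis and its genome doubled,
yielding a fully homozygous DH line in one step.  Recombination follows the
Haldane model — per chromosome the crossover count is Poisson with mean
equal to the map length in Morgan, crossover positions are uniform, and
there is no interference.

Two standard mating schemes are provided: the 5 x 5 elite x donor factorial
(25 crosses) and the all-pairs diallel of the 5 elite lines (10 crosses,
no selfs or reciprocals).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._rng import as_rng
from .genome_founders import DONOR, ELITE, FounderPanel, GeneticMap

__all__ = [
    "CrossPlan",
    "DHPopulation",
    "factorial_plan",
    "diallel_plan",
    "simulate_gamete",
    "simulate_gametes",
    "make_dh_line",
    "make_dh_lines",
    "simulate_population",
]


@dataclass(frozen=True)
class CrossPlan:
    """Ordered list of crosses plus the family size per cross."""

    scheme: str
    crosses: tuple
    n_lines_per_cross: int

    def __post_init__(self):
        if self.n_lines_per_cross < 1:
            raise ValueError("n_lines_per_cross must be >= 1")
        if not self.crosses:
            raise ValueError("plan contains no crosses")

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    @property
    def n_lines(self) -> int:
        return self.n_crosses * self.n_lines_per_cross

    def with_family_size(self, n_lines_per_cross: int) -> "CrossPlan":
        return CrossPlan(self.scheme, self.crosses, n_lines_per_cross)


def factorial_plan(panel: FounderPanel, n_lines_per_cross: int = 10) -> CrossPlan:
    """Every elite founder crossed to every donor founder (5 x 5 -> 25)."""
    elite = panel.pool_members(ELITE)
    donor = panel.pool_members(DONOR)
    if not elite or not donor:
        raise ValueError("factorial plan needs founders in both pools")
    crosses = tuple((e, d) for e in elite for d in donor)
    return CrossPlan("factorial", crosses, n_lines_per_cross)


def diallel_plan(panel: FounderPanel, n_lines_per_cross: int = 25, pool: str = ELITE) -> CrossPlan:
    """All unordered pairs within one pool, no selfs (5 parents -> 10)."""
    members = panel.pool_members(pool)
    if len(members) < 2:
        raise ValueError("diallel plan needs at least two parents")
    crosses = tuple(combinations(members, 2))
    return CrossPlan("diallel", crosses, n_lines_per_cross)


@dataclass(frozen=True)
class DHPopulation:
    """Simulated DH lines: genotypes coded -1/+1, with cross of origin."""

    map: GeneticMap
    genotypes: np.ndarray
    cross_of_origin: np.ndarray
    line_ids: tuple
    plan: CrossPlan | None = None

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=np.int8)
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "cross_of_origin", np.asarray(self.cross_of_origin, dtype=int))
        if g.ndim != 2 or g.shape[1] != self.map.n_markers:
            raise ValueError("genotypes must be (n_lines, n_markers)")
        if not np.isin(g, (-1, 1)).all():
            raise ValueError("DH genotypes must be -1/+1 (fully homozygous)")
        if self.cross_of_origin.shape != (g.shape[0],):
            raise ValueError("cross_of_origin must have one entry per line")

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    def allele1_freq(self) -> np.ndarray:
        """Per-line frequency of allele 1 (0 or 1 for homozygous lines)."""
        return (self.genotypes.astype(float) + 1.0) / 2.0


def _check_haplotype(hap: np.ndarray, gmap: GeneticMap, name: str) -> np.ndarray:
    hap = np.asarray(hap)
    if hap.shape != (gmap.n_markers,):
        raise ValueError(f"{name} must have one allele per marker")
    if not np.isin(hap, (0, 1)).all():
        raise ValueError(f"{name} must be a 0/1 haplotype of a fully homozygous parent")
    return hap.astype(np.int8)


def simulate_gametes(hap_a, hap_b, gmap: GeneticMap, rng, n: int) -> np.ndarray:
    """Draw ``n`` gametes from the heterozygote formed by two haplotypes.

    For each chromosome and gamete: crossover count ~ Poisson(length in
    Morgan), crossover positions uniform on the chromosome, no
    interference; the gamete copies alternate between the two parental
    haplotypes at crossovers, the starting haplotype chosen by fair coin.
    """
    rng = as_rng(rng)
    hap_a = _check_haplotype(hap_a, gmap, "hap_a")
    hap_b = _check_haplotype(hap_b, gmap, "hap_b")
    out = np.empty((n, gmap.n_markers), dtype=np.int8)
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_slice(c)
        pos = gmap.marker_pos[sl]
        length = gmap.chrom_lengths[c]
        counts = rng.poisson(length, size=n)
        start = rng.integers(0, 2, size=n)
        kmax = int(counts.max()) if n else 0
        if kmax == 0:
            origin = np.broadcast_to(start[:, None], (n, pos.size)).copy()
        else:
            xo = rng.uniform(0.0, length, size=(n, kmax))
            xo[np.arange(kmax)[None, :] >= counts[:, None]] = np.inf
            crossings = (xo[:, None, :] < pos[None, :, None]).sum(axis=2)
            origin = (start[:, None] + crossings) % 2
        out[:, sl] = np.where(origin == 0, hap_a[sl][None, :], hap_b[sl][None, :])
    return out


def simulate_gamete(hap_a, hap_b, gmap: GeneticMap, rng) -> np.ndarray:
    """Single-gamete convenience wrapper around :func:`simulate_gametes`."""
    return simulate_gametes(hap_a, hap_b, gmap, rng, 1)[0]


def make_dh_lines(parent_a_hap, parent_b_hap, gmap: GeneticMap, rng, n: int) -> np.ndarray:
    """DH genotypes (-1/+1) of ``n`` lines from one cross of homozygous parents.

    The F1 carries one haplotype from each parent; one meiosis gives the
    gamete whose doubling fixes the line, so the DH genotype equals twice
    the gamete and is homozygous at every locus by construction.
    """
    gametes = simulate_gametes(parent_a_hap, parent_b_hap, gmap, rng, n)
    return (2 * gametes.astype(np.int8) - 1).astype(np.int8)


def make_dh_line(parent_a_hap, parent_b_hap, gmap: GeneticMap, rng) -> np.ndarray:
    return make_dh_lines(parent_a_hap, parent_b_hap, gmap, rng, 1)[0]


def simulate_population(panel: FounderPanel, plan: CrossPlan, rng) -> DHPopulation:
    """Simulate the DH population of a cross plan, cross by cross in plan order."""
    rng = as_rng(rng)
    unknown = {p for cross in plan.crosses for p in cross} - set(panel.founder_ids)
    if unknown:
        raise ValueError(f"unknown parent ids in plan: {sorted(unknown)}")

    n_l = plan.n_lines_per_cross
    blocks, origin, line_ids = [], [], []
    for ci, (pa, pb) in enumerate(plan.crosses):
        blocks.append(make_dh_lines(panel.haplotype_of(pa), panel.haplotype_of(pb), panel.map, rng, n_l))
        origin.append(np.full(n_l, ci))
        line_ids.extend(f"C{ci + 1:02d}_L{i + 1:03d}" for i in range(n_l))
    return DHPopulation(
        map=panel.map,
        genotypes=np.vstack(blocks),
        cross_of_origin=np.concatenate(origin),
        line_ids=tuple(line_ids),
        plan=plan,
    )
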