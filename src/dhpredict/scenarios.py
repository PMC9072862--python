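"""Replicated simulation experiments and correlation summaries.

One replicate of a scenario runs the full pipeline: founder panel ->
DH population -> true genotypic values g -> virtual-trial phenotypes p ->
RR-BLUP -> genomic predictions y, then records the Pearson and Spearman
correlations r(p,g), r(y,p), r(y,g).  A scenario averages these over many
replicates; the 30-row study grid crosses three mating schemes (factorial
25 x 10, factorial 25 x 6, elite diallel 10 x 25), two trial designs
(E=1,R=1 and E=3,R=2), and five masking-variance component sets, with the
genetic variance calibrated to 20 (factorial) or 2 (diallel).

The founder panel and the calibrated true effects are built once per
scenario from the master seed and held fixed across replicates, mirroring
a study anchored to one experimental panel; each replicate re-draws the
population and the trial noise from its own substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for
from .breeding_sim import CrossPlan, DHPopulation, diallel_plan, factorial_plan, simulate_population
from .genome_founders import FounderPanel, GeneticMap, build_map, simulate_founders
from .prediction import fit_rrblup, predict
from .quantgen import (
    MarkerEffects,
    apply_donor_penalty,
    calibrate_sigma_g,
    draw_effects,
    genotypic_values,
    reestimated_effects,
)
from .trial_sim import TrialDesign, expected_r_pg, simulate_phenotypes

__all__ = [
    "GenomeSpec",
    "FounderSpec",
    "EffectSpec",
    "ScenarioConfig",
    "ScenarioContext",
    "ScenarioResult",
    "CorrelationComparison",
    "build_context",
    "run_replicate",
    "run_scenario",
    "table1_configs",
    "run_table1",
    "pearson_filon_z",
    "compare_dependent_correlations",
    "illustration_runs",
]

METRICS = ("r_pg", "r_yp", "r_yg", "rho_pg", "rho_yp", "rho_yg")

# masking-variance component sets of the study grid: (s_ce2, s_le2, s_eps2)
COMPONENT_SETS = ((10, 10, 30), (2, 18, 30), (18, 2, 30), (10, 10, 60), (20, 20, 120))


@dataclass(frozen=True)
class GenomeSpec:
    n_chrom: int = 7
    chrom_length_morgan: float = 1.5
    n_markers: int = 700
    spacing: str = "uniform"


@dataclass(frozen=True)
class FounderSpec:
    n_elite: int = 5
    n_donor: int = 5
    pool_divergence: float = 1 / 3
    min_maf: float = 0.1
    within_pool_relatedness: float = 0.6


@dataclass(frozen=True)
class EffectSpec:
    """True-effect architecture of a scenario.

    ``donor_penalty`` aligns differentiated-marker effects against the
    donor allele (directional pool contrast); ``reestimate`` replaces the
    raw draw by its error-free ridge re-estimate through a reference
    factorial population, emulating truths that were themselves estimated
    genome-wide from an experimental panel.  Both default on; switch them
    off for sensitivity runs with purely random architectures.
    """

    distribution: str = "gaussian"
    k: int | None = None  # only for sparse effects
    donor_penalty: bool = True
    reestimate: bool = True
    reference_lines_per_cross: int = 10


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that determines one simulated scenario."""

    scheme: str = "factorial"  # or "diallel"
    n_lines_per_cross: int = 10
    design: TrialDesign = field(default_factory=lambda: TrialDesign(1, 1, 10.0, 10.0, 30.0))
    sigma_g2: float = 20.0
    n_reps: int = 2000
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    founders: FounderSpec = field(default_factory=FounderSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    rrblup_mode: str = "reml"
    include_prediction: bool = True
    n_calibration_lines: int = 5000
    label: str = ""

    def __post_init__(self):
        if self.scheme not in ("factorial", "diallel"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class ScenarioContext:
    """Fixed per-scenario objects shared by all replicates."""

    map: GeneticMap
    panel: FounderPanel
    plan: CrossPlan
    effects: MarkerEffects


def build_context(config: ScenarioConfig) -> ScenarioContext:
    """Build map, founders, cross plan, and calibrated effects for a scenario."""
    g = config.genome
    gmap = build_map(
        g.n_chrom, g.chrom_length_morgan, g.n_markers, g.spacing,
        seed=rng_for(config.seed, 1),
    )
    f = config.founders
    panel = simulate_founders(
        gmap, f.n_elite, f.n_donor, f.pool_divergence, f.min_maf,
        f.within_pool_relatedness, seed=rng_for(config.seed, 2),
    )
    if config.scheme == "factorial":
        plan = factorial_plan(panel, config.n_lines_per_cross)
    else:
        plan = diallel_plan(panel, config.n_lines_per_cross)
    e = config.effects
    raw = draw_effects(gmap, e.distribution, seed=rng_for(config.seed, 3), k=e.k)
    if e.donor_penalty:
        raw = apply_donor_penalty(raw, panel)
    if e.reestimate:
        # the reference panel is the flagship factorial experiment whenever
        # both pools exist; a pure one-pool panel falls back to its own plan
        try:
            ref_plan = factorial_plan(panel, e.reference_lines_per_cross)
        except ValueError:
            ref_plan = plan
        raw = reestimated_effects(panel, ref_plan, raw, seed=rng_for(config.seed, 5))
    effects = calibrate_sigma_g(
        panel, plan, raw, config.sigma_g2,
        n_calibration_lines=config.n_calibration_lines,
        seed=rng_for(config.seed, 4),
    )
    return ScenarioContext(gmap, panel, plan, effects)


@dataclass
class ReplicateResult:
    rep_index: int
    correlations: dict  # metric -> float (NaN if prediction skipped)
    flagged: bool = False


def _corr_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    return float(stats.pearsonr(a, b).statistic), float(stats.spearmanr(a, b).statistic)


def run_replicate(
    config: ScenarioConfig, rep_index: int, context: ScenarioContext | None = None
) -> ReplicateResult:
    """Run one full pipeline replicate; deterministic in (config.seed, rep_index)."""
    if context is None:
        context = build_context(config)
    rng = rng_for(config.seed, 10, rep_index)
    pop = simulate_population(context.panel, context.plan, rng)
    g = genotypic_values(pop, context.effects)
    phen = simulate_phenotypes(g, pop, config.design, rng)

    if np.var(g.values) == 0.0 or np.var(phen.values) == 0.0:
        return ReplicateResult(rep_index, {m: float("nan") for m in METRICS}, flagged=True)

    r_pg, rho_pg = _corr_pair(phen.values, g.values)
    out = {"r_pg": r_pg, "rho_pg": rho_pg}
    if config.include_prediction:
        model = fit_rrblup(pop, phen, mode=config.rrblup_mode)
        y = predict(model, pop)
        if np.var(y.values) == 0.0:
            return ReplicateResult(rep_index, {m: float("nan") for m in METRICS}, flagged=True)
        out["r_yp"], out["rho_yp"] = _corr_pair(y.values, phen.values)
        out["r_yg"], out["rho_yg"] = _corr_pair(y.values, g.values)
    else:
        out.update({k: float("nan") for k in ("r_yp", "rho_yp", "r_yg", "rho_yg")})
    return ReplicateResult(rep_index, out)


@dataclass
class ScenarioResult:
    """Per-replicate correlations of one scenario plus summary statistics."""

    config: ScenarioConfig
    per_rep: pd.DataFrame  # one row per non-flagged replicate
    n_flagged: int

    @property
    def n_reps(self) -> int:
        return len(self.per_rep)

    @property
    def unreliable(self) -> bool:
        total = self.n_reps + self.n_flagged
        return self.n_flagged > 0.01 * total

    def mean(self, metric: str) -> float:
        return float(self.per_rep[metric].mean())

    def se(self, metric: str) -> float:
        return float(self.per_rep[metric].std(ddof=1) / math.sqrt(self.n_reps))

    def summary(self) -> dict:
        out = {"label": self.config.label, "n_reps": self.n_reps, "n_flagged": self.n_flagged}
        for m in METRICS:
            out[f"mean_{m}"] = self.mean(m)
            out[f"se_{m}"] = self.se(m)
        return out

    def to_row(self) -> dict:
        """One study-table-style row (design columns plus mean correlations)."""
        c, d = self.config, self.config.design
        return {
            "label": c.label,
            "scheme": c.scheme,
            "n_c": _n_crosses(c),
            "n_l": c.n_lines_per_cross,
            "E": d.n_environments,
            "R": d.n_replications,
            "sigma_ce2": d.sigma_ce2,
            "sigma_le2": d.sigma_le2,
            "sigma_eps2": d.sigma_eps2,
            "sigma_g2": c.sigma_g2,
            "r_pg": self.mean("r_pg"),
            "r_yp": self.mean("r_yp"),
            "r_yg": self.mean("r_yg"),
        }


def _n_crosses(config: ScenarioConfig) -> int:
    if config.scheme == "factorial":
        return config.founders.n_elite * config.founders.n_donor
    k = config.founders.n_elite
    return k * (k - 1) // 2


def run_scenario(
    config: ScenarioConfig, context: ScenarioContext | None = None, progress: bool = False
) -> ScenarioResult:
    """Run all replicates of a scenario and summarise the correlations."""
    if context is None:
        context = build_context(config)
    rows, flagged = [], 0
    for rep in range(config.n_reps):
        res = run_replicate(config, rep, context)
        if res.flagged:
            flagged += 1
            continue
        rows.append({"rep": res.rep_index, **res.correlations})
        if progress and (rep + 1) % 100 == 0:
            print(f"  [{config.label or config.scheme}] {rep + 1}/{config.n_reps} replicates")
    per_rep = pd.DataFrame(rows, columns=["rep", *METRICS])
    return ScenarioResult(config, per_rep, flagged)


# ---------------------------------------------------------------------------
# the 30-scenario study grid
# ---------------------------------------------------------------------------


def table1_configs(
    n_reps: int = 2000,
    seed: int = 0,
    include_prediction: bool = True,
    **overrides,
) -> list[ScenarioConfig]:
    """The 30 study scenarios, in table order (rows 1-30).

    Rows 1-10: factorial 25 x 10 (sigma_g2 = 20); rows 11-20: factorial
    25 x 6; rows 21-30: diallel 10 x 25 (sigma_g2 = 2).  Within each block
    of ten, rows 1-5 use the unreplicated design (E=1, R=1) and rows 6-10
    the replicated design (E=3, R=2), each crossed with the five masking
    component sets.  Each row gets its own derived sub-seed of ``seed``.
    """
    schemes = [("factorial", 10, 20.0), ("factorial", 6, 20.0), ("diallel", 25, 2.0)]
    designs = [(1, 1), (3, 2)]
    configs = []
    row = 0
    for scheme, n_l, sg2 in schemes:
        for E, R in designs:
            for ce, le, eps in COMPONENT_SETS:
                row += 1
                row_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(row,)).generate_state(1)[0] % (2**31))
                configs.append(
                    ScenarioConfig(
                        scheme=scheme,
                        n_lines_per_cross=n_l,
                        design=TrialDesign(E, R, float(ce), float(le), float(eps)),
                        sigma_g2=sg2,
                        n_reps=n_reps,
                        seed=row_seed,
                        include_prediction=include_prediction,
                        label=f"row{row}",
                        **overrides,
                    )
                )
    return configs


def run_table1(
    n_reps: int = 2000, seed: int = 0, include_prediction: bool = True, progress: bool = False,
    **overrides,
) -> pd.DataFrame:
    """Run the whole 30-scenario grid; one summary row per scenario."""
    rows = []
    for config in table1_configs(n_reps, seed, include_prediction, **overrides):
        result = run_scenario(config, progress=progress)
        row = result.to_row()
        row["se_r_pg"] = result.se("r_pg")
        row["expected_r_pg"] = expected_r_pg(config.sigma_g2, config.design)
        row["n_flagged"] = result.n_flagged
        rows.append(row)
        if progress:
            print(f"{row['label']}: r(p,g)={row['r_pg']:.3f} r(y,p)={row['r_yp']:.3f} r(y,g)={row['r_yg']:.3f}")
    frame = pd.DataFrame(rows)
    frame.index = pd.RangeIndex(1, len(rows) + 1, name="row")
    return frame


# ---------------------------------------------------------------------------
# dependent-correlation comparison (Pearson-Filon 1898)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationComparison:
    """Comparison of two overlapping dependent correlations sharing ghat."""

    r1: float  # corr(p, ghat)
    r2: float  # corr(y, ghat)
    r12: float  # corr(p, y)
    n: int
    z: float
    p_value: float  # one-sided, H_A: r2 > r1


def pearson_filon_z(r1: float, r2: float, r12: float, n: int) -> float:
    """Pearson-Filon (1898) z for two overlapping dependent correlations.

    ``r1`` and ``r2`` share one variable; ``r12`` is the correlation of
    the two non-shared variables.  The statistic is antisymmetric in
    (r1, r2) and asymptotically standard normal under r1 = r2.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if max(abs(r1), abs(r2)) >= 1.0 - 1e-12:
        raise ValueError("degenerate correlation (|r| = 1)")
    k = r12 * (1 - r1**2 - r2**2) - 0.5 * r1 * r2 * (1 - r1**2 - r2**2 - r12**2)
    denom = (1 - r1**2) ** 2 + (1 - r2**2) ** 2 - 2 * k
    if denom <= 1e-12:
        # the asymptotic variance vanishes when the two predictors coincide
        # (r12 -> 1 with r1 = r2); the statistic is 0 there by antisymmetry
        if abs(r1 - r2) < 1e-12:
            return 0.0
        raise ValueError("degenerate variance in Pearson-Filon statistic")
    return math.sqrt(n) * (r1 - r2) / math.sqrt(denom)


def compare_dependent_correlations(p, y, ghat) -> CorrelationComparison:
    """One-sided test of H_A: corr(y, ghat) > corr(p, ghat).

    All three vectors are observed on the same lines; the z statistic
    accounts for the dependence through corr(p, y).  Small p-values mean
    the genomic predictions track ghat more closely than the phenotypes.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    ghat = np.asarray(ghat, dtype=float)
    if not (p.shape == y.shape == ghat.shape) or p.ndim != 1:
        raise ValueError("p, y, ghat must be equal-length 1-D vectors")
    n = p.size
    if n < 4:
        raise ValueError("need n >= 4")
    r1 = float(stats.pearsonr(p, ghat).statistic)
    r2 = float(stats.pearsonr(y, ghat).statistic)
    r12 = float(stats.pearsonr(p, y).statistic)
    z = pearson_filon_z(r1, r2, r12, n)
    p_value = float(stats.norm.cdf(z))  # z < 0 when r2 > r1
    return CorrelationComparison(r1, r2, r12, n, z, p_value)


# ---------------------------------------------------------------------------
# single-run illustration (unreplicated vs replicated trial)
# ---------------------------------------------------------------------------


def single_run_vectors(config: ScenarioConfig, rep_index: int = 0, context: ScenarioContext | None = None) -> dict:
    """Raw (g, p, y) vectors of one replicate, for scatter illustrations."""
    if context is None:
        context = build_context(config)
    rng = rng_for(config.seed, 10, rep_index)
    pop = simulate_population(context.panel, context.plan, rng)
    g = genotypic_values(pop, context.effects)
    phen = simulate_phenotypes(g, pop, config.design, rng)
    model = fit_rrblup(pop, phen, mode=config.rrblup_mode)
    y = predict(model, pop)
    return {"g": g.values, "p": phen.values, "y": y.values, "cross": pop.cross_of_origin}


def illustration_runs(seed: int = 0, n_reps: int = 1) -> dict:
    """Single seeded runs of the flagship factorial scenario under both designs.

    Returns ``{"unreplicated": {...}, "replicated": {...}}`` with the six
    correlations of (the mean over) ``n_reps`` run(s) each, ready for the
    two-design, six-panel correlation illustration.
    """
    out = {}
    for name, (E, R) in (("unreplicated", (1, 1)), ("replicated", (3, 2))):
        config = ScenarioConfig(
            scheme="factorial",
            n_lines_per_cross=10,
            design=TrialDesign(E, R, 10.0, 10.0, 30.0),
            sigma_g2=20.0,
            n_reps=n_reps,
            seed=seed,
            label=name,
        )
        result = run_scenario(config)
        out[name] = {m: result.mean(m) for m in METRICS}
    return out
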