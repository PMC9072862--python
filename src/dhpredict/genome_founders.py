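"""Synthetic genome, founder panel, and marker quality control.

This module provides the synthetic stand-in for the experimental panel the
simulations are anchored to: 10 fully homozygous barley parents in two pools
(5 elite lines and 5 resistance donors) genotyped at biallelic SNPs on a
7-chromosome genetic map.  It also implements the standard marker-QC filters
used for such panels (missingness, gene diversity, line missingness) and the
modified Rogers' distance used to summarise relatedness.

Coordinates are genetic (Morgan).  Founders are inbred lines, so a single
haplotype per founder fully defines its genotype; alleles are coded 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import as_rng

__all__ = [
    "GeneticMap",
    "FounderPanel",
    "MarkerQCReport",
    "build_map",
    "simulate_founders",
    "filter_markers",
    "gene_diversity",
    "modified_rogers_distance",
    "EmptyPanelError",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_plink_map",
    "write_vcf",
]

ELITE = "elite"
DONOR = "donor"


class EmptyPanelError(ValueError):
    """Raised when marker filtering removes every marker."""


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Genetic map: chromosome lengths and marker positions in Morgan.

    Parameters
    ----------
    chrom_ids
        Ordered chromosome identifiers (e.g. ``("1H", ..., "7H")``).
    chrom_lengths
        Length of each chromosome in Morgan.
    marker_ids
        Marker identifiers, ordered by (chromosome, position).
    marker_chrom
        Index of each marker's chromosome into ``chrom_ids``.
    marker_pos
        Map position of each marker in Morgan, within ``[0, length]``.
    """

    chrom_ids: tuple
    chrom_lengths: np.ndarray
    marker_ids: tuple
    marker_chrom: np.ndarray
    marker_pos: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chrom_lengths", np.asarray(self.chrom_lengths, dtype=float))
        object.__setattr__(self, "marker_chrom", np.asarray(self.marker_chrom, dtype=int))
        object.__setattr__(self, "marker_pos", np.asarray(self.marker_pos, dtype=float))
        if np.any(self.chrom_lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if len(self.marker_ids) != len(set(self.marker_ids)):
            raise ValueError("marker ids must be unique")
        if len(self.marker_ids) != self.marker_pos.size or self.marker_pos.size != self.marker_chrom.size:
            raise ValueError("marker arrays must have equal length")
        lengths = self.chrom_lengths[self.marker_chrom]
        if np.any(self.marker_pos < 0) or np.any(self.marker_pos > lengths):
            raise ValueError("marker positions must lie within their chromosome")
        order = np.lexsort((self.marker_pos, self.marker_chrom))
        if not np.array_equal(order, np.arange(order.size)):
            raise ValueError("markers must be sorted by (chromosome, position)")
        counts = np.bincount(self.marker_chrom, minlength=len(self.chrom_ids))
        if np.any(counts < 2):
            raise ValueError("every chromosome needs at least 2 markers")

    @property
    def n_markers(self) -> int:
        return self.marker_pos.size

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_ids)

    def chrom_slice(self, c: int) -> slice:
        """Contiguous marker slice of chromosome index ``c``."""
        start = int(np.searchsorted(self.marker_chrom, c, side="left"))
        stop = int(np.searchsorted(self.marker_chrom, c, side="right"))
        return slice(start, stop)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": list(self.marker_ids),
                "chrom": [self.chrom_ids[c] for c in self.marker_chrom],
                "pos_morgan": self.marker_pos,
            }
        )


def build_map(
    n_chrom: int,
    chrom_length_morgan: float | Sequence[float],
    n_markers: int,
    spacing: str = "uniform",
    seed=None,
) -> GeneticMap:
    """Build a synthetic genetic map.

    Markers are distributed across chromosomes as evenly as possible (the
    first ``n_markers % n_chrom`` chromosomes receive one extra marker).
    With ``spacing="uniform"`` markers sit at equal intervals spanning the
    whole chromosome; with ``spacing="random"`` positions are drawn
    uniformly and sorted (deterministic given ``seed``).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if n_markers < 2 * n_chrom:
        raise ValueError("need at least 2 markers per chromosome")
    if spacing not in ("uniform", "random"):
        raise ValueError(f"unknown spacing {spacing!r}")
    lengths = np.broadcast_to(np.asarray(chrom_length_morgan, dtype=float), (n_chrom,)).copy()
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")

    rng = as_rng(seed)
    base, extra = divmod(n_markers, n_chrom)
    per_chrom = [base + (1 if c < extra else 0) for c in range(n_chrom)]

    chrom_ids = tuple(f"{c + 1}H" for c in range(n_chrom))
    ids, chrom_idx, pos = [], [], []
    for c, k in enumerate(per_chrom):
        if spacing == "uniform":
            p = np.linspace(0.0, lengths[c], k)
        else:
            p = np.sort(rng.uniform(0.0, lengths[c], size=k))
        pos.append(p)
        chrom_idx.append(np.full(k, c))
        ids.extend(f"M{c + 1}_{i + 1}" for i in range(k))
    return GeneticMap(
        chrom_ids=chrom_ids,
        chrom_lengths=lengths,
        marker_ids=tuple(ids),
        marker_chrom=np.concatenate(chrom_idx),
        marker_pos=np.concatenate(pos),
    )


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderPanel:
    """Fully homozygous founder lines with pool labels.

    ``haplotypes`` is an ``(n_founders, n_markers)`` 0/1 array; one
    haplotype per founder suffices because founders are inbred.
    ``pool_differentiated`` flags markers at which the two pools were
    constructed to carry opposite alleles.
    """

    map: GeneticMap
    founder_ids: tuple
    haplotypes: np.ndarray
    pools: tuple
    pool_differentiated: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        object.__setattr__(self, "haplotypes", hap)
        if hap.shape != (len(self.founder_ids), self.map.n_markers):
            raise ValueError("haplotypes must be (n_founders, n_markers)")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1")
        if any(p not in (ELITE, DONOR) for p in self.pools):
            raise ValueError(f"pools must be '{ELITE}' or '{DONOR}'")

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    def pool_members(self, pool: str) -> list:
        return [fid for fid, p in zip(self.founder_ids, self.pools) if p == pool]

    def haplotype_of(self, founder_id: str) -> np.ndarray:
        return self.haplotypes[self.founder_ids.index(founder_id)]


def simulate_founders(
    gmap: GeneticMap,
    n_elite: int = 5,
    n_donor: int = 5,
    pool_divergence: float = 1 / 3,
    min_maf: float = 0.1,
    within_pool_relatedness: float = 0.6,
    seed=None,
) -> FounderPanel:
    """Simulate a two-pool panel of fully homozygous founders.

    A fraction ``pool_divergence`` of markers (count rounded to nearest
    integer, positions drawn at random) is fixed for opposite alleles in
    the two pools — elite founders carry allele 0, donors allele 1 — which
    creates the between-pool contrast that inflates genetic variance in
    pool-crossing (factorial) progeny.  At the remaining markers each
    founder copies a hidden pool-ancestor allele with probability
    ``within_pool_relatedness`` and otherwise draws a fair coin, which
    emulates the family structure of real breeding pools (founders of one
    pool share much of their genome).  Free markers are redrawn until the
    panel minor-allele frequency is at least ``min_maf`` and until no
    free marker is accidentally fixed for opposite alleles between the
    pools (only the ``pool_divergence`` fraction separates them).
    """
    if not 0.0 <= pool_divergence <= 1.0:
        raise ValueError("pool_divergence must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if not 0.0 <= within_pool_relatedness <= 1.0:
        raise ValueError("within_pool_relatedness must be in [0, 1]")
    n = n_elite + n_donor
    if n < 2:
        raise ValueError("need at least two founders")

    rng = as_rng(seed)
    m = gmap.n_markers
    n_div = int(round(pool_divergence * m))
    differentiated = np.zeros(m, dtype=bool)
    differentiated[rng.choice(m, size=n_div, replace=False)] = True

    hap = np.empty((n, m), dtype=np.int8)
    pools = (ELITE,) * n_elite + (DONOR,) * n_donor
    pool_rows = (np.arange(n_elite), np.arange(n_elite, n))
    hap[np.ix_(pool_rows[0], np.flatnonzero(differentiated))] = 0
    hap[np.ix_(pool_rows[1], np.flatnonzero(differentiated))] = 1

    def draw_free(k: int) -> np.ndarray:
        cols = np.empty((n, k), dtype=np.int8)
        for rows in pool_rows:
            if rows.size == 0:
                continue
            ancestor = rng.integers(0, 2, size=k, dtype=np.int8)
            copy = rng.random((rows.size, k)) < within_pool_relatedness
            fresh = rng.integers(0, 2, size=(rows.size, k), dtype=np.int8)
            cols[rows] = np.where(copy, ancestor[None, :], fresh)
        return cols

    def violates(cols: np.ndarray) -> np.ndarray:
        freq = cols.mean(axis=0)
        bad = np.minimum(freq, 1 - freq) < min_maf
        if n_elite > 0 and n_donor > 0:
            e, d = cols[pool_rows[0]], cols[pool_rows[1]]
            fixed_opposite = (np.ptp(e, axis=0) == 0) & (np.ptp(d, axis=0) == 0) & (e[0] != d[0])
            bad |= fixed_opposite
        return bad

    free = np.flatnonzero(~differentiated)
    draw = draw_free(free.size)
    for _ in range(10_000):
        bad = violates(draw)
        if not bad.any():
            break
        draw[:, bad] = draw_free(int(bad.sum()))
    else:  # pragma: no cover - unreachable for sane min_maf
        raise RuntimeError("could not satisfy panel marker constraints")
    hap[:, free] = draw

    founder_ids = tuple(f"E{i + 1}" for i in range(n_elite)) + tuple(f"D{i + 1}" for i in range(n_donor))
    return FounderPanel(
        map=gmap,
        founder_ids=founder_ids,
        haplotypes=hap,
        pools=pools,
        pool_differentiated=differentiated,
    )


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


@dataclass
class MarkerQCReport:
    """Counts and per-marker diagnostics from :func:`filter_markers`."""

    n_markers_in: int
    n_markers_kept: int
    n_lines_in: int
    n_lines_kept: int
    marker_missing_fraction: np.ndarray
    marker_gene_diversity: np.ndarray
    marker_kept: np.ndarray
    line_missing_fraction: np.ndarray
    line_kept: np.ndarray

    def __post_init__(self):
        if self.n_markers_kept > self.n_markers_in or self.n_lines_kept > self.n_lines_in:
            raise ValueError("kept counts cannot exceed input counts")

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "missing_fraction": self.marker_missing_fraction,
                "gene_diversity": self.marker_gene_diversity,
                "kept": self.marker_kept,
            }
        )

    def to_tsv(self, path) -> None:
        self.marker_frame().to_csv(path, sep="\t", index_label="marker")


def gene_diversity(column: np.ndarray) -> float:
    """Expected heterozygosity ``1 - sum(freq^2)`` over non-missing calls."""
    vals = column[~_missing_mask(column)]
    if vals.size == 0:
        return 0.0
    _, counts = np.unique(vals, return_counts=True)
    freq = counts / counts.sum()
    return float(1.0 - np.square(freq).sum())


def _missing_mask(a: np.ndarray) -> np.ndarray:
    return np.isnan(a) if a.dtype.kind == "f" else np.zeros(a.shape, dtype=bool)


def filter_markers(
    genotypes,
    max_missing_marker: float = 0.10,
    min_diversity: float = 0.10,
    max_missing_line: float = 0.15,
):
    """Apply panel marker/line QC filters; return (filtered, report).

    ``genotypes`` is a lines × markers matrix (ndarray or DataFrame) of
    numeric allele codes for homozygous material, with ``NaN`` marking
    missing calls.  Markers are removed first: those with more than two
    recorded alleles, a missing fraction strictly above
    ``max_missing_marker``, or gene diversity strictly below
    ``min_diversity``.  Lines with a missing fraction strictly above
    ``max_missing_line`` *on the retained markers* are removed second.
    Thresholds are strict inequalities, so e.g. exactly 10% missing is kept.
    """
    is_frame = isinstance(genotypes, pd.DataFrame)
    mat = genotypes.to_numpy(dtype=float) if is_frame else np.asarray(genotypes, dtype=float)
    if mat.ndim != 2:
        raise ValueError("genotypes must be 2-D (lines x markers)")
    n_lines, n_markers = mat.shape

    missing = np.isnan(mat)
    miss_frac = missing.mean(axis=0)
    diversity = np.array([gene_diversity(mat[:, j]) for j in range(n_markers)])
    n_alleles = np.array([np.unique(mat[~missing[:, j], j]).size for j in range(n_markers)])
    keep_marker = (
        (miss_frac <= max_missing_marker) & (diversity >= min_diversity) & (n_alleles <= 2)
    )
    if not keep_marker.any():
        raise EmptyPanelError("all markers removed by QC filters")

    kept = mat[:, keep_marker]
    line_miss = np.isnan(kept).mean(axis=1)
    keep_line = line_miss <= max_missing_line

    out = kept[keep_line]
    report = MarkerQCReport(
        n_markers_in=n_markers,
        n_markers_kept=int(keep_marker.sum()),
        n_lines_in=n_lines,
        n_lines_kept=int(keep_line.sum()),
        marker_missing_fraction=miss_frac,
        marker_gene_diversity=diversity,
        marker_kept=keep_marker,
        line_missing_fraction=line_miss,
        line_kept=keep_line,
    )
    if is_frame:
        out = pd.DataFrame(
            out,
            index=genotypes.index[keep_line],
            columns=genotypes.columns[keep_marker],
        )
    return out, report


# ---------------------------------------------------------------------------
# modified Rogers' distance
# ---------------------------------------------------------------------------


def modified_rogers_distance(obj) -> np.ndarray:
    """Pairwise modified Rogers' distance between homozygous lines.

    ``MRD(i, j) = sqrt( (1 / 2m) * sum_markers sum_alleles (f_a,i - f_a,j)^2 )``

    where ``f_a,i`` is the frequency of allele ``a`` in line ``i``.  For
    fully homozygous biallelic material the per-line allele frequency is 0
    or 1 and the distance reduces to the square root of the fraction of
    markers at which two lines differ, hence values lie in [0, 1].

    Accepts a :class:`FounderPanel`, a population with ``allele1_freq``,
    or a lines × markers allele-frequency matrix.  Missing values are
    rejected — run :func:`filter_markers` first.
    """
    freq = _allele1_freq(obj)
    if np.isnan(freq).any():
        raise ValueError("missing genotypes present; filter markers first")
    diff2 = ((freq[:, None, :] - freq[None, :, :]) ** 2).mean(axis=2)
    return np.sqrt(diff2)


def _allele1_freq(obj) -> np.ndarray:
    if isinstance(obj, FounderPanel):
        return obj.haplotypes.astype(float)
    if hasattr(obj, "allele1_freq"):
        return np.asarray(obj.allele1_freq(), dtype=float)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D allele-frequency matrix")
    return arr


# ---------------------------------------------------------------------------
# I/O: TSV, PLINK-style map, VCF
# ---------------------------------------------------------------------------


def _genotype_frame(obj) -> tuple[pd.DataFrame, GeneticMap]:
    """Lines x markers {0,2} dosage frame plus the map, from panel or population."""
    if isinstance(obj, FounderPanel):
        mat = 2 * obj.haplotypes.astype(int)
        index = list(obj.founder_ids)
        gmap = obj.map
    elif hasattr(obj, "genotypes") and hasattr(obj, "map"):
        mat = (np.asarray(obj.genotypes) + 1).astype(int)  # -1/+1 -> 0/2
        index = list(getattr(obj, "line_ids", range(mat.shape[0])))
        gmap = obj.map
    else:
        raise TypeError("expected a FounderPanel or DHPopulation")
    return pd.DataFrame(mat, index=index, columns=list(gmap.marker_ids)), gmap


def write_genotypes_tsv(obj, path) -> None:
    """Write genotypes as TSV, lines x markers, {0, 2} allele-dosage coding."""
    frame, _ = _genotype_frame(obj)
    frame.to_csv(path, sep="\t", index_label="line_id")


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Read a genotype TSV written by :func:`write_genotypes_tsv`."""
    return pd.read_csv(path, sep="\t", index_col="line_id")


def _bp_position(pos_morgan: float) -> int:
    # pseudo physical coordinate: 1 cM == 1e5 bp
    return int(round(pos_morgan * 100 * 1e5))


def write_plink_map(gmap: GeneticMap, path) -> None:
    """Write the map as PLINK .map-style TSV (chrom, id, cM, bp)."""
    frame = pd.DataFrame(
        {
            "chrom": [gmap.chrom_ids[c] for c in gmap.marker_chrom],
            "marker_id": list(gmap.marker_ids),
            "pos_cM": gmap.marker_pos * 100,
            "pos_bp": [_bp_position(p) for p in gmap.marker_pos],
        }
    )
    frame.to_csv(path, sep="\t", index=False, header=False)


def write_vcf(obj, path) -> None:
    """Write genotypes as an uncompressed VCF (one pseudo-contig per chromosome).

    Homozygous calls only (0/0 or 1/1); REF/ALT are placeholder A/T since
    the markers are synthetic biallelic SNPs.
    """
    frame, gmap = _genotype_frame(obj)
    samples = list(frame.index.astype(str))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dhpredict\n")
        for c, length in zip(gmap.chrom_ids, gmap.chrom_lengths):
            fh.write(f"##contig=<ID={c},length={_bp_position(length) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        dosage = frame.to_numpy()
        for j, mid in enumerate(gmap.marker_ids):
            chrom = gmap.chrom_ids[gmap.marker_chrom[j]]
            pos = max(1, _bp_position(gmap.marker_pos[j]))
            calls = "\t".join("1/1" if d == 2 else "0/0" for d in dosage[:, j])
            fh.write(f"{chrom}\t{pos}\t{mid}\tA\tT\t.\t.\t.\tGT\t{calls}\n")
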