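"""Genetic maps, meiosis simulation and doubled-haploid derivation.

Positions are genetic-map coordinates in centimorgan (cM); loci are points on
continuous chromosomes. Recombination follows the Haldane (no-interference)
model: crossover counts per chromosome are Poisson with mean ``length_cM/100``
and crossover positions are uniform. Because the crossover process is Poisson,
the strand inherited along a chromosome is equivalently a Markov chain whose
switch probability between two loci ``d`` cM apart is the Haldane map function
``r(d) = (1 - exp(-2d/100)) / 2``; the vectorised batch sampler uses that
representation, the single-gamete sampler simulates the crossover events
explicitly. Both produce the same distribution of gametes at the loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("embvsel")

__all__ = [
    "GeneticMap",
    "PhasedGenotype",
    "recombination_fraction",
    "simulate_crossovers",
    "sample_gamete",
    "sample_gametes",
    "gamete_batch",
    "make_dh",
]


class DataError(ValueError):
    """Inconsistent or malformed genotype/map data."""


class ConfigError(ValueError):
    """Invalid configuration value."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class GeneticMap:
    """Per-chromosome locus positions on a genetic (cM) map.

    Parameters
    ----------
    lengths_cM
        Length of each chromosome in centimorgan, shape ``(n_chrom,)``.
    positions_cM
        Concatenated locus positions, shape ``(L,)``; strictly increasing
        within each chromosome and contained in ``[0, length]``.
    chrom_index
        Chromosome index of each locus, shape ``(L,)``, non-decreasing.
    locus_ids
        Unique locus identifiers, shape ``(L,)``.
    """

    lengths_cM: np.ndarray
    positions_cM: np.ndarray
    chrom_index: np.ndarray
    locus_ids: np.ndarray
    _switch_probs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.lengths_cM = np.asarray(self.lengths_cM, dtype=float)
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        self.chrom_index = np.asarray(self.chrom_index, dtype=np.int64)
        self.locus_ids = np.asarray(self.locus_ids)
        if self.lengths_cM.ndim != 1 or np.any(self.lengths_cM < 0):
            raise DataError("chromosome lengths must be a 1-d non-negative array")
        L = self.positions_cM.shape[0]
        if self.chrom_index.shape != (L,) or self.locus_ids.shape != (L,):
            raise DataError("positions, chrom_index and locus_ids must have equal length")
        if L and (self.chrom_index.min() < 0 or self.chrom_index.max() >= self.n_chrom):
            raise DataError("chrom_index out of range")
        if np.any(np.diff(self.chrom_index) < 0):
            raise DataError("loci must be ordered by chromosome")
        for c in range(self.n_chrom):
            pos = self.positions_cM[self.chrom_index == c]
            if pos.size == 0:
                continue
            if np.any(np.diff(pos) <= 0):
                raise DataError(f"positions on chromosome {c} must be strictly increasing")
            if pos[0] < 0 or pos[-1] > self.lengths_cM[c]:
                raise DataError(f"positions on chromosome {c} outside [0, length]")
        if len(set(map(str, self.locus_ids))) != L:
            raise DataError("duplicate locus ids")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_chrom(self) -> int:
        return int(self.lengths_cM.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.positions_cM.shape[0])

    def chrom_slices(self) -> list[slice]:
        """Half-open index ranges of each chromosome's loci, genome order."""
        bounds = np.searchsorted(self.chrom_index, np.arange(self.n_chrom + 1))
        return [slice(int(bounds[c]), int(bounds[c + 1])) for c in range(self.n_chrom)]

    @property
    def switch_probs(self) -> np.ndarray:
        """Per-locus strand-switch probability for the Markov meiosis sampler.

        Entry ``l`` is the Haldane recombination fraction between locus
        ``l-1`` and ``l``; at the first locus of every chromosome it is 0.5
        (fair choice of starting strand, chromosomes assort independently).
        """
        if self._switch_probs is None:
            d = np.diff(self.positions_cM, prepend=0.0)
            first = np.r_[True, np.diff(self.chrom_index) != 0] if self.n_loci else np.zeros(0, bool)
            q = recombination_fraction(np.where(first, 0.0, d))
            q[first] = 0.5
            self._switch_probs = q
        return self._switch_probs

    def pairwise_recombination(self) -> np.ndarray:
        """(L, L) recombination fractions; 0.5 between chromosomes."""
        d = np.abs(self.positions_cM[:, None] - self.positions_cM[None, :])
        r = recombination_fraction(d)
        r[self.chrom_index[:, None] != self.chrom_index[None, :]] = 0.5
        return r

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """New map restricted to a boolean/index mask of loci (order kept)."""
        keep = np.asarray(keep)
        return GeneticMap(
            self.lengths_cM.copy(),
            self.positions_cM[keep],
            self.chrom_index[keep],
            self.locus_ids[keep],
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def equidistant(cls, n_chrom: int = 20, genome_cM: float = 2000.0,
                    n_loci: int = 1000) -> "GeneticMap":
        """Equal-length chromosomes with loci spread evenly along the genome.

        The default emulates a 2,000 cM genome carrying 1,000 evenly spaced
        bi-allelic QTL on ``n_chrom`` chromosomes of equal length.
        """
        if n_chrom < 1 or n_loci < 1 or genome_cM <= 0:
            raise ConfigError("n_chrom, n_loci and genome_cM must be positive")
        if n_loci % n_chrom:
            raise ConfigError("n_loci must be divisible by n_chrom for an equidistant map")
        per = n_loci // n_chrom
        clen = genome_cM / n_chrom
        pos = (np.arange(per) + 0.5) * (clen / per)
        return cls(
            np.full(n_chrom, clen),
            np.tile(pos, n_chrom),
            np.repeat(np.arange(n_chrom), per),
            np.array([f"q{c + 1}_{j + 1}" for c in range(n_chrom) for j in range(per)]),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneticMap":
        """Build from a table with columns ``chrom``, ``pos_cM``, ``id``.

        Chromosome order of first appearance defines genome order; chromosome
        length is taken as the last locus position (loci are points, the map
        carries no physical end beyond them).
        """
        required = {"chrom", "pos_cM", "id"}
        if not required.issubset(df.columns):
            raise DataError(f"map table must have columns {sorted(required)}")
        chroms = list(dict.fromkeys(df["chrom"]))
        lengths, pos, cidx, ids = [], [], [], []
        for c, name in enumerate(chroms):
            sub = df[df["chrom"] == name]
            p = sub["pos_cM"].to_numpy(float)
            lengths.append(p.max() if p.size else 0.0)
            pos.append(p)
            cidx.append(np.full(p.size, c))
            ids.append(sub["id"].to_numpy())
        return cls(np.array(lengths), np.concatenate(pos),
                   np.concatenate(cidx), np.concatenate(ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [f"chr{c + 1}" for c in self.chrom_index],
            "pos_cM": self.positions_cM,
            "id": self.locus_ids,
        })


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class PhasedGenotype:
    """One diploid individual as two phased haploid genomes.

    ``hap1``/``hap2`` are 0/1 vectors over the map's loci; 1 marks the
    favorable allele B. Dosage is ``hap1 + hap2``.
    """

    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        self.hap1 = np.ascontiguousarray(self.hap1, dtype=np.uint8)
        self.hap2 = np.ascontiguousarray(self.hap2, dtype=np.uint8)
        if self.hap1.shape != self.hap2.shape or self.hap1.ndim != 1:
            raise DataError("haplotypes must be 1-d arrays of equal length")
        if self.hap1.max(initial=0) > 1 or self.hap2.max(initial=0) > 1:
            raise DataError("haplotype alleles must be 0 or 1")

    @property
    def n_loci(self) -> int:
        return int(self.hap1.shape[0])

    @property
    def dosage(self) -> np.ndarray:
        return self.hap1.astype(np.int64) + self.hap2

    @property
    def haps(self) -> np.ndarray:
        """Stacked ``(2, L)`` view of the two haplotypes."""
        return np.stack([self.hap1, self.hap2])

    def is_homozygous(self) -> bool:
        return bool(np.array_equal(self.hap1, self.hap2))


# ---------------------------------------------------------------------------
# Map function and meiosis
# ---------------------------------------------------------------------------

def recombination_fraction(d_cM):
    """Haldane map function ``r = (1 - exp(-2 d / 100)) / 2``.

    Converts a genetic distance in cM into a recombination fraction in
    ``[0, 0.5)`` assuming no crossover interference.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def simulate_crossovers(gmap: GeneticMap, rng: np.random.Generator):
    """Draw one meiosis: per chromosome, a starting strand and crossovers.

    Returns a list of ``(start_strand, crossover_positions)`` tuples, one per
    chromosome: crossover count ~ Poisson(length/100), positions i.i.d.
    uniform on the chromosome (sorted), start strand fair. Zero-crossover
    meioses are allowed (no obligate chiasma).
    """
    out = []
    for c in range(gmap.n_chrom):
        n_x = rng.poisson(gmap.lengths_cM[c] / 100.0)
        xpos = np.sort(rng.uniform(0.0, gmap.lengths_cM[c], size=n_x)) if n_x else np.empty(0)
        out.append((int(rng.integers(2)), xpos))
    return out


def sample_gamete(parent: PhasedGenotype, gmap: GeneticMap,
                  rng: np.random.Generator) -> np.ndarray:
    """Simulate one recombinant gamete from a phased parent.

    The strand at each locus is the starting strand flipped once per
    crossover to its left; chromosomes segregate independently.
    """
    if parent.n_loci != gmap.n_loci:
        raise DataError("genotype length does not match the map")
    gamete = np.empty(gmap.n_loci, dtype=np.uint8)
    haps = parent.haps
    for sl, (start, xpos) in zip(gmap.chrom_slices(), simulate_crossovers(gmap, rng)):
        n_left = np.searchsorted(xpos, gmap.positions_cM[sl], side="right")
        strand = (start + n_left) % 2
        loci = np.arange(sl.start, sl.stop)
        gamete[sl] = haps[strand, loci]
    return gamete


def gamete_batch(haps: np.ndarray, gmap: GeneticMap,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete from each of ``n`` parents, vectorised.

    ``haps`` has shape ``(n, 2, L)``. Uses the Markov strand-switch
    representation of Haldane meiosis: the inherited strand flips between
    consecutive loci with probability equal to their recombination fraction,
    and restarts with a fair coin at each chromosome. Identical in
    distribution to :func:`sample_gamete`.
    """
    haps = np.asarray(haps)
    n, two, L = haps.shape
    if two != 2 or L != gmap.n_loci:
        raise DataError("haps must have shape (n, 2, L) matching the map")
    switches = rng.random((n, L)) < gmap.switch_probs
    strand = np.cumsum(switches, axis=1, dtype=np.int64) & 1
    h1 = haps[:, 0, :]
    h2 = haps[:, 1, :]
    return np.where(strand == 1, h2, h1).astype(np.uint8)


def sample_gametes(parent: PhasedGenotype, gmap: GeneticMap, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. gametes of one parent as an ``(n, L)`` matrix."""
    haps = np.broadcast_to(parent.haps, (n, 2, gmap.n_loci))
    return gamete_batch(haps, gmap, rng)


def make_dh(gamete: np.ndarray) -> PhasedGenotype:
    """Doubled haploid: a fully homozygous diploid carrying the gamete twice."""
    g = np.asarray(gamete, dtype=np.uint8)
    return PhasedGenotype(g, g.copy())
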