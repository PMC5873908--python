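"""Base-population construction and synthetic test fixtures.

The base population is built forward in time by random mating: a large
historical population drifts for many generations, a severe bottleneck builds
up linkage disequilibrium resembling elite plant-breeding germplasm, and a
final expansion removes close family relationships. Generation 0 starts from
i.i.d. Bernoulli(0.5) allele copies and there is no mutation, so polymorphism
only decays; monomorphic loci are removed at the end. Mating draws, for each
offspring, two parents uniformly with replacement (selfing allowed) and one
gamete from each — at a single locus this is exactly a Wright-Fisher model on
2N gene copies.

``make_fixture_population`` provides linkage-equilibrium populations with
prescribed allele frequencies for fast unit tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ConfigError, DataError, GeneticMap, PhasedGenotype, gamete_batch

logger = logging.getLogger("embvsel")

__all__ = [
    "PhasedPopulation",
    "simulate_base_population",
    "reduced_base_population",
    "ld_summary",
    "sample_founders",
    "make_fixture_population",
]

# historical / bottleneck / expansion defaults of the full-scale simulation
FULL_SCALE = dict(n_hist=1500, gens_hist=3000, n_bottleneck=40,
                  gens_bottleneck=15, n_final=5000, gens_final=3)
# desk-scale preset: same demography shape at reduced size
REDUCED_SCALE = dict(n_hist=150, gens_hist=300, n_bottleneck=40,
                     gens_bottleneck=15, n_final=150, gens_final=3)


class DegeneratePopulationError(RuntimeError):
    """Population carries no usable polymorphism."""


@dataclass
class PhasedPopulation:
    """A set of phased diploid individuals sharing one genetic map.

    ``haps`` has shape ``(n, 2, L)`` over {0, 1}; 1 is the favorable allele.
    """

    haps: np.ndarray
    gmap: GeneticMap
    generation_label: str = ""

    def __post_init__(self) -> None:
        self.haps = np.ascontiguousarray(self.haps, dtype=np.uint8)
        if self.haps.ndim != 3 or self.haps.shape[1] != 2:
            raise DataError("haps must have shape (n, 2, L)")
        if self.haps.shape[2] != self.gmap.n_loci:
            raise DataError("population and map disagree on the number of loci")
        if self.haps.size and self.haps.max() > 1:
            raise DataError("alleles must be 0 or 1")

    @property
    def n_individuals(self) -> int:
        return int(self.haps.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.haps.shape[2])

    def __getitem__(self, i: int) -> PhasedGenotype:
        return PhasedGenotype(self.haps[i, 0], self.haps[i, 1])

    @property
    def dosages(self) -> np.ndarray:
        return self.haps.sum(axis=1, dtype=np.int64)

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of the favorable allele at every locus."""
        return self.haps.mean(axis=(0, 1), dtype=float)

    def heterozygosity(self) -> np.ndarray:
        """Observed per-locus heterozygote fraction."""
        return (self.haps[:, 0, :] != self.haps[:, 1, :]).mean(axis=0)

    def subset_loci(self, keep: np.ndarray) -> "PhasedPopulation":
        return PhasedPopulation(self.haps[:, :, np.asarray(keep)],
                                self.gmap.subset(keep), self.generation_label)


def _random_mating_generation(haps: np.ndarray, n_offspring: int,
                              gmap: GeneticMap,
                              rng: np.random.Generator) -> np.ndarray:
    n = haps.shape[0]
    mothers = rng.integers(0, n, size=n_offspring)
    fathers = rng.integers(0, n, size=n_offspring)
    gam_m = gamete_batch(haps[mothers], gmap, rng)
    gam_f = gamete_batch(haps[fathers], gmap, rng)
    return np.stack([gam_m, gam_f], axis=1)


def simulate_base_population(gmap: GeneticMap, n_hist: int = 1500,
                             gens_hist: int = 3000, n_bottleneck: int = 40,
                             gens_bottleneck: int = 15, n_final: int = 5000,
                             gens_final: int = 3,
                             rng: np.random.Generator | None = None,
                             ) -> PhasedPopulation:
    """Forward simulation: drift, bottleneck, expansion; drop fixed loci.

    Defaults reproduce the full-scale demography (1,500 individuals for
    3,000 generations, a 40-individual bottleneck for 15 generations, then
    expansion to 5,000 for 3 generations). The returned population and its
    map contain only loci still polymorphic at the end.
    """
    for name, v in [("n_hist", n_hist), ("gens_hist", gens_hist),
                    ("n_bottleneck", n_bottleneck), ("gens_bottleneck", gens_bottleneck),
                    ("n_final", n_final), ("gens_final", gens_final)]:
        if v < (1 if name.startswith("n_") else 0):
            raise ConfigError(f"{name} must be at least {'1' if name.startswith('n_') else '0'}")
    if rng is None:
        rng = np.random.default_rng()
    haps = (rng.random((n_hist, 2, gmap.n_loci)) < 0.5).astype(np.uint8)
    phases = [(n_hist, gens_hist), (n_bottleneck, gens_bottleneck),
              (n_final, gens_final)]
    for size, gens in phases:
        if haps.shape[0] != size:  # resize via one round of random mating
            haps = _random_mating_generation(haps, size, gmap, rng)
        for _ in range(gens):
            haps = _random_mating_generation(haps, size, gmap, rng)
    p = haps.mean(axis=(0, 1), dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DegeneratePopulationError("all loci monomorphic after the base simulation")
    logger.info("base population: %d of %d loci polymorphic", poly.sum(), gmap.n_loci)
    pop = PhasedPopulation(haps, gmap, generation_label="base")
    return pop.subset_loci(poly)


def reduced_base_population(gmap: GeneticMap,
                            rng: np.random.Generator) -> PhasedPopulation:
    """Desk-scale base population (150 individuals, 300+15+3 generations)."""
    return simulate_base_population(gmap, rng=rng, **REDUCED_SCALE)


def ld_summary(pop: PhasedPopulation, max_dist_cM: float = 50.0,
               bins: int = 10) -> pd.DataFrame:
    """Mean r^2 between intra-chromosomal locus pairs, binned by cM distance.

    r^2 is the squared correlation of the 0/1 allele indicators across the
    2n observed haplotypes (phased data, counted directly). Monomorphic loci
    are ignored.
    """
    gmap = pop.gmap
    H = pop.haps.reshape(2 * pop.n_individuals, pop.n_loci).astype(float)
    p = H.mean(axis=0)
    edges = np.linspace(0.0, max_dist_cM, bins + 1)
    sums = np.zeros(bins)
    counts = np.zeros(bins, dtype=np.int64)
    for sl in gmap.chrom_slices():
        idx = np.arange(sl.start, sl.stop)
        idx = idx[(p[idx] > 0) & (p[idx] < 1)]
        if idx.size < 2:
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(H[:, idx], rowvar=False)
        pos = gmap.positions_cM[idx]
        d = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(idx.size, k=1)
        dist = d[iu]
        r2 = corr[iu] ** 2
        ok = dist <= max_dist_cM
        which = np.clip(np.digitize(dist[ok], edges) - 1, 0, bins - 1)
        np.add.at(sums, which, r2[ok])
        np.add.at(counts, which, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "dist_low_cM": edges[:-1], "dist_high_cM": edges[1:],
        "n_pairs": counts, "mean_r2": mean_r2,
    })


def sample_founders(pop: PhasedPopulation, n: int,
                    rng: np.random.Generator) -> PhasedPopulation:
    """Uniform sample of ``n`` individuals without replacement."""
    if not 1 <= n <= pop.n_individuals:
        raise ConfigError("founder count must be between 1 and the population size")
    idx = rng.choice(pop.n_individuals, size=n, replace=False)
    return PhasedPopulation(pop.haps[idx], pop.gmap, generation_label="C0")


def make_fixture_population(gmap: GeneticMap, n: int, freq_spec="uniform",
                            rng: np.random.Generator | None = None,
                            ) -> PhasedPopulation:
    """Linkage-equilibrium population with prescribed allele frequencies.

    ``freq_spec`` is ``"uniform"`` (p ~ U(0, 1) per locus), a tuple
    ``("beta", a, b)`` for Beta-distributed frequencies (u-shaped for
    a, b < 1), or an explicit length-L frequency vector. Haplotypes are drawn
    i.i.d. Bernoulli(p): no linkage disequilibrium, Hardy-Weinberg genotype
    proportions in expectation.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(freq_spec, str):
        if freq_spec != "uniform":
            raise ConfigError(f"unknown frequency spec {freq_spec!r}")
        p = rng.uniform(0.0, 1.0, size=gmap.n_loci)
    elif isinstance(freq_spec, tuple) and freq_spec and freq_spec[0] == "beta":
        _, a, b = freq_spec
        p = rng.beta(a, b, size=gmap.n_loci)
    else:
        p = np.asarray(freq_spec, dtype=float)
        if p.shape != (gmap.n_loci,) or np.any((p < 0) | (p > 1)):
            raise ConfigError("explicit frequencies must be a length-L vector in [0, 1]")
    haps = (rng.random((n, 2, gmap.n_loci)) < p).astype(np.uint8)
    return PhasedPopulation(haps, gmap, generation_label="fixture")
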