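"""Quantitative-genetic trait model.

A bi-allelic additive/dominance model at every locus. With alleles A and B
(B favorable by construction), the genotypic value contributed by a locus
with B-dosage x is 0, (1+k)a or 2a for x = 0, 1, 2, where a > 0 is the
homozygous effect (half the difference between the two homozygotes) and
k in {-1, 0, +1} the dominance coefficient. Allele substitution effects
alpha = a (1 + k (1 - 2 p)) and breeding values g_i = sum_l (x_il - 2 p_l)
alpha_l follow the classical decomposition, with allele frequencies p taken
from the current candidate set.

Homozygous effects are drawn i.i.d. from Gamma(shape 1.66, scale 0.4) and
rescaled once so the base population has unit additive genetic variance, so
the trait unit is sigma_a0 of the base population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import ConfigError, DataError, GeneticMap, PhasedGenotype

__all__ = [
    "TraitArchitecture",
    "sample_architecture",
    "genotypic_value",
    "genotypic_values",
    "substitution_effects",
    "breeding_values",
    "additive_variance",
    "scale_to_unit_variance",
]

GAMMA_SHAPE = 1.66
GAMMA_SCALE = 0.4


@dataclass(frozen=True)
class TraitArchitecture:
    """Per-locus homozygous effects ``a`` and dominance coefficients ``k``.

    ``scale_factor`` records the multiplier applied to the raw effects when
    normalising to unit additive variance in a reference population.
    """

    a: np.ndarray
    k: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        if self.a.shape != self.k.shape or self.a.ndim != 1:
            raise DataError("a and k must be 1-d arrays of equal length")
        if np.any(self.a <= 0):
            raise DataError("homozygous effects must be positive (B is favorable)")
        if not np.all(np.isin(self.k, (-1.0, 0.0, 1.0))):
            raise DataError("dominance coefficients must be in {-1, 0, +1}")

    @property
    def n_loci(self) -> int:
        return int(self.a.shape[0])

    def subset(self, keep: np.ndarray) -> "TraitArchitecture":
        return replace(self, a=self.a[np.asarray(keep)], k=self.k[np.asarray(keep)])


def sample_architecture(gmap: GeneticMap, mode: str,
                        rng: np.random.Generator) -> TraitArchitecture:
    """Draw a trait architecture for the map's loci.

    ``mode='additive'`` sets every k to 0; ``mode='dominant'`` draws k = +1 or
    -1 with equal probability, independently of the effect sizes.
    """
    a = rng.gamma(GAMMA_SHAPE, GAMMA_SCALE, size=gmap.n_loci)
    # gamma(0) cannot occur for continuous draws, but guard degenerate zeros
    a = np.maximum(a, np.finfo(float).tiny)
    if mode == "additive":
        k = np.zeros(gmap.n_loci)
    elif mode == "dominant":
        k = rng.choice([-1.0, 1.0], size=gmap.n_loci)
    else:
        raise ConfigError(f"unknown gene-action mode {mode!r}; use 'additive' or 'dominant'")
    return TraitArchitecture(a, k)


def _locus_values(dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    x = np.asarray(dosage)
    if x.shape[-1] != arch.n_loci:
        raise DataError("dosage length does not match the architecture")
    if not np.all(np.isin(x, (0, 1, 2))):
        raise DataError("dosages must be 0, 1 or 2")
    return np.where(x == 1, (1.0 + arch.k) * arch.a, x * arch.a)


def genotypic_values(dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Genome-wide genotypic value G_i for each row of a dosage matrix."""
    return _locus_values(dosages, arch).sum(axis=-1)


def genotypic_value(genotype: PhasedGenotype, arch: TraitArchitecture) -> float:
    """Genotypic value of a single phased individual."""
    return float(genotypic_values(genotype.dosage[None, :], arch)[0])


def substitution_effects(arch: TraitArchitecture, p: np.ndarray) -> np.ndarray:
    """Allele substitution effects ``alpha = a (1 + k (1 - 2p))``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("allele frequencies must lie in [0, 1]")
    return arch.a * (1.0 + arch.k * (1.0 - 2.0 * p))


def breeding_values(dosages: np.ndarray, arch: TraitArchitecture,
                    p: np.ndarray) -> np.ndarray:
    """Breeding values ``g_i = sum_l (x_il - 2 p_l) alpha_l``.

    When ``p`` is computed from the same individuals the mean of ``g`` is 0.
    """
    alpha = substitution_effects(arch, p)
    return (np.asarray(dosages) - 2.0 * np.asarray(p, dtype=float)) @ alpha


def additive_variance(dosages: np.ndarray, arch: TraitArchitecture,
                      p: np.ndarray) -> float:
    """Population variance (denominator n) of the candidates' breeding values."""
    g = breeding_values(dosages, arch, p)
    return float(np.var(g))


def scale_to_unit_variance(arch: TraitArchitecture,
                           ref_dosages: np.ndarray,
                           ref_p: np.ndarray) -> TraitArchitecture:
    """Rescale effects so the reference population has unit additive variance.

    Breeding values are linear in ``a`` (alpha scales with a), so the factor
    is ``c = 1 / sigma_before``; it is recorded in ``scale_factor``.
    """
    var = additive_variance(ref_dosages, arch, ref_p)
    if var <= 0:
        raise DataError("reference population has zero additive variance; cannot scale")
    c = 1.0 / np.sqrt(var)
    return TraitArchitecture(arch.a * c, arch.k.copy(),
                             scale_factor=arch.scale_factor * c)
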