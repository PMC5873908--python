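"""Selection criteria for phased candidates: GEBV, wGEBV, OHV and EMBV.

GEBV is the genome-wide sum of dosages times substitution effects. wGEBV
up-weights substitution effects at loci where the favorable allele is rare.
OHV partitions the genome into haplotype segments and doubles the sum of the
better of the two segment values, i.e. the GEBV of the best doubled haploid
(DH) constructible under free recombination between segments and complete
linkage within them. EMBV is the expected GEBV of the best of N_G DH lines a
candidate would contribute if selected: the mean of the largest order
statistic of N_G gamete breeding values (doubled), estimated either by Monte
Carlo over simulated meioses or through a normal approximation
``EMBV = GEBV + E(X_(N_G)) * sigma_i``, where sigma_i is the standard
deviation of the candidate's DH GEBVs and ``E(X_(n))`` the expected maximum
of n standard normal draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import integrate, stats

from .genome import (
    ConfigError,
    DataError,
    GeneticMap,
    PhasedGenotype,
    recombination_fraction,
)

logger = logging.getLogger("embvsel")

__all__ = [
    "CriterionScores",
    "HaplotypePartition",
    "gebv",
    "wgebv_weights",
    "wgebv",
    "partition_haplotypes",
    "ohv",
    "embv_mc",
    "expected_max_std_normal",
    "dh_sd_analytic",
    "embv_normal",
]

MIN_SEGMENT_CM = 6.25  # shortest haplotype length considered for OHV sweeps


@dataclass
class CriterionScores:
    """Per-candidate scores of one criterion plus estimation metadata."""

    criterion: str
    scores: np.ndarray
    ng: int | None = None
    mc_replicates: np.ndarray | None = None
    mc_se: np.ndarray | None = None
    ns_per_chrom: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        needs_ng = self.criterion in ("EMBV", "EMBV_normal")
        if needs_ng != (self.ng is not None):
            raise DataError("ng must be present exactly for EMBV criteria")
        if (self.criterion == "OHV") != (self.ns_per_chrom is not None):
            raise DataError("ns_per_chrom must be present exactly for OHV")


# ---------------------------------------------------------------------------
# GEBV and wGEBV
# ---------------------------------------------------------------------------

def gebv(dosages: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """GEBV_i = sum_l x_il * alpha_l for each row of the dosage matrix."""
    return np.asarray(dosages, dtype=float) @ np.asarray(alpha, dtype=float)


def wgebv_weights(p: np.ndarray) -> np.ndarray:
    """Frequency-dependent locus weights for weighted genomic selection.

    ``w = (pi/2 - arcsin(sqrt(p))) / sqrt(p (1 - p))`` for interior p, which
    grows without bound as the favorable allele becomes rare. Fixed loci
    (p in {0, 1}) get weight 0: a monomorphic locus cannot respond to
    selection.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("allele frequencies must lie in [0, 1]")
    interior = (p > 0) & (p < 1)
    w = np.zeros_like(p)
    pi_ = p[interior]
    w[interior] = (np.pi / 2 - np.arcsin(np.sqrt(pi_))) / np.sqrt(pi_ * (1 - pi_))
    return w


def wgebv(dosages: np.ndarray, alpha: np.ndarray, p: np.ndarray) -> np.ndarray:
    """wGEBV_i = sum_l x_il * w_l * alpha_l with weights from ``wgebv_weights``."""
    return gebv(dosages, wgebv_weights(p) * np.asarray(alpha, dtype=float))


# ---------------------------------------------------------------------------
# OHV
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePartition:
    """Ordered, disjoint, contiguous locus-index segments covering the genome."""

    segments: list[tuple[int, int]]  # half-open [start, stop) into genome order
    n_loci: int
    ns_per_chrom: int | None = None

    def __post_init__(self) -> None:
        prev = 0
        for start, stop in self.segments:
            if stop <= start:
                raise DataError("segments must be non-empty")
            if start != prev:
                raise DataError("segments must be contiguous and ordered")
            prev = stop
        if prev != self.n_loci:
            raise DataError("segments must cover all loci")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.segments], dtype=np.int64)


def partition_haplotypes(gmap: GeneticMap, ns_per_chrom: int) -> HaplotypePartition:
    """Split every chromosome into ``ns_per_chrom`` equal-length segments.

    Breakpoints sit at ``j * length / NS``; loci are assigned to half-open
    intervals ``[left, right)`` (a locus exactly on a breakpoint goes right,
    the last interval is closed at the chromosome end). Segments that contain
    no locus are dropped with a warning, as is a segment length below
    6.25 cM.
    """
    if ns_per_chrom < 1:
        raise ConfigError("ns_per_chrom must be a positive integer")
    segments: list[tuple[int, int]] = []
    for c, sl in enumerate(gmap.chrom_slices()):
        clen = gmap.lengths_cM[c]
        if clen / ns_per_chrom < MIN_SEGMENT_CM:
            warnings.warn(
                f"segment length {clen / ns_per_chrom:.3g} cM on chromosome {c} "
                f"is below {MIN_SEGMENT_CM} cM", stacklevel=2)
        pos = gmap.positions_cM[sl]
        cuts = clen * np.arange(1, ns_per_chrom) / ns_per_chrom
        bounds = np.r_[0, np.searchsorted(pos, cuts, side="left"), pos.size]
        for j in range(ns_per_chrom):
            start, stop = int(bounds[j]), int(bounds[j + 1])
            if stop > start:
                segments.append((sl.start + start, sl.start + stop))
            else:
                logger.warning("dropping empty OHV segment %d on chromosome %d", j, c)
    return HaplotypePartition(segments, gmap.n_loci, ns_per_chrom=ns_per_chrom)


def ohv(haps: np.ndarray, alpha: np.ndarray,
        partition: HaplotypePartition) -> np.ndarray:
    """OHV_i = 2 * sum over segments of the better haplotype segment value.

    ``haps`` has shape ``(n, 2, L)``.
    """
    haps = np.asarray(haps)
    if haps.shape[-1] != partition.n_loci:
        raise DataError("haplotype matrix does not match the partition")
    vals = haps * np.asarray(alpha, dtype=float)
    seg = np.add.reduceat(vals, partition.starts, axis=-1)  # (n, 2, S)
    return 2.0 * seg.max(axis=1).sum(axis=-1)


# ---------------------------------------------------------------------------
# EMBV
# ---------------------------------------------------------------------------

@njit(cache=True)
def _embv_mc_kernel(base, beta, hpos, bounds, ng, se_tol, min_reps,
                    max_reps, seed):  # pragma: no cover - exercised via embv_mc
    # DH GEBV of one meiosis = base + sum of beta over het loci inheriting
    # hap1. Per chromosome only the span between its first and last
    # heterozygous locus matters: the starting strand there is a fair coin
    # (crossovers left of the span only reshuffle a fair coin) and crossover
    # events inside the span are Poisson with uniform positions (Haldane).
    np.random.seed(seed)
    H = beta.shape[0]
    cumb = np.empty(H + 1)
    cumb[0] = 0.0
    for i in range(H):
        cumb[i + 1] = cumb[i] + beta[i]
    n_chrom = bounds.shape[0] - 1
    # per-chromosome Poisson CDF of the crossover count inside the het span
    kmax = 64
    pois_cdf = np.empty((n_chrom, kmax))
    spans = np.empty(n_chrom)
    for c in range(n_chrom):
        span = hpos[bounds[c + 1] - 1] - hpos[bounds[c]]
        spans[c] = span
        lam = span / 100.0
        term = np.exp(-lam)
        acc = term
        pois_cdf[c, 0] = acc
        for k in range(1, kmax):
            term *= lam / k
            acc += term
            pois_cdf[c, k] = acc
    xbuf = np.empty(kmax)
    s = 0.0
    s2 = 0.0
    n = 0
    while True:
        m = -1.0e300
        for _ in range(ng):
            val = base
            for c in range(n_chrom):
                a = bounds[c]
                b = bounds[c + 1]
                # one uniform supplies the start-strand coin (its first bit)
                # and, rescaled, the inverse-CDF crossover count
                u = np.random.random()
                if u < 0.5:
                    state = 1
                    u = 2.0 * u
                else:
                    state = 0
                    u = 2.0 * u - 1.0
                k = 0
                while k < kmax - 1 and u > pois_cdf[c, k]:
                    k += 1
                if k == 0:
                    if state == 1:
                        val += cumb[b] - cumb[a]
                    continue
                span = spans[c]
                for t in range(k):  # insertion sort of crossover positions
                    x = hpos[a] + span * np.random.random()
                    j = t
                    while j > 0 and xbuf[j - 1] > x:
                        xbuf[j] = xbuf[j - 1]
                        j -= 1
                    xbuf[j] = x
                cur = a
                for t in range(k):
                    lo = cur
                    hi = b
                    x = xbuf[t]
                    while lo < hi:  # first locus with pos >= crossover
                        mid = (lo + hi) // 2
                        if hpos[mid] >= x:
                            hi = mid
                        else:
                            lo = mid + 1
                    if state == 1:
                        val += cumb[lo] - cumb[cur]
                    state = 1 - state
                    cur = lo
                if state == 1:
                    val += cumb[b] - cumb[cur]
            if val > m:
                m = val
        s += m
        s2 += m * m
        n += 1
        if n >= min_reps:
            var = (s2 - s * s / n) / (n - 1)
            if var < 0.0:
                var = 0.0
            se = np.sqrt(var / n)
            if se < se_tol or n >= max_reps:
                return s / n, n, se


def _het_layout(candidate: PhasedGenotype, alpha: np.ndarray, gmap: GeneticMap):
    """Constant part and heterozygous-locus layout of a candidate's DH GEBVs.

    DH GEBV = base + sum over heterozygous loci of I_l * beta_l, where I_l
    indicates inheritance of hap1 and beta_l = 2 alpha_l (hap1_l - hap2_l).
    Homozygous loci contribute to ``base`` only. Returns the het-locus
    positions and the index bounds grouping them by chromosome.
    """
    alpha = np.asarray(alpha, dtype=float)
    if candidate.n_loci != gmap.n_loci or alpha.shape[0] != gmap.n_loci:
        raise DataError("candidate/alpha length does not match the map")
    h1 = candidate.hap1.astype(np.int64)
    h2 = candidate.hap2.astype(np.int64)
    het = h1 != h2
    base = 2.0 * float(alpha @ h2)
    beta = 2.0 * alpha[het] * (h1[het] - h2[het])
    pos = gmap.positions_cM[het]
    chrom = gmap.chrom_index[het]
    if pos.size:
        first = np.r_[True, np.diff(chrom) != 0]
        bounds = np.r_[np.flatnonzero(first), pos.size].astype(np.int64)
    else:
        bounds = np.zeros(1, dtype=np.int64)
    return base, beta, pos, bounds, het


def embv_mc(candidate: PhasedGenotype, alpha: np.ndarray, gmap: GeneticMap,
            ng: int, se_tol: float = 0.01, min_reps: int = 10,
            max_reps: int = 10_000, rng: np.random.Generator | None = None,
            ) -> tuple[float, int, float]:
    """Monte-Carlo EMBV of one candidate.

    Each replicate simulates ``ng`` meioses, doubles the gametes and records
    the maximum DH GEBV; replicates accumulate until the empirical standard
    error of the mean drops below ``se_tol`` (at least ``min_reps``, at most
    ``max_reps`` replicates — hitting the cap is logged, the estimate is
    still returned). Returns ``(score, replicates_used, se)``.
    """
    if ng < 1:
        raise ConfigError("ng must be a positive integer")
    if se_tol <= 0 or min_reps < 2 or max_reps < min_reps:
        raise ConfigError("require se_tol > 0 and 2 <= min_reps <= max_reps")
    if rng is None:
        rng = np.random.default_rng()
    base, beta, hpos, bounds, _ = _het_layout(candidate, alpha, gmap)
    if beta.size == 0:  # homozygote: every DH equals the candidate's GEBV
        return base, min_reps, 0.0
    seed = int(rng.integers(1 << 31))
    score, reps, se = _embv_mc_kernel(base, beta, hpos, bounds,
                                      int(ng), float(se_tol), int(min_reps),
                                      int(max_reps), seed)
    if reps >= max_reps and se >= se_tol:
        logger.warning("embv_mc replicate cap %d reached (se=%.4g >= tol %.4g)",
                       max_reps, se, se_tol)
    return float(score), int(reps), float(se)


def expected_max_std_normal(ng: int) -> float:
    """Expected largest order statistic of ``ng`` standard normal draws.

    Numerical integration of ``ng * x * phi(x) * Phi(x)**(ng-1)`` to absolute
    accuracy better than 1e-6.
    """
    if ng < 1:
        raise ConfigError("ng must be a positive integer")
    if ng == 1:
        return 0.0

    def integrand(x):
        return ng * x * stats.norm.pdf(x) * stats.norm.cdf(x) ** (ng - 1)

    val, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-10, limit=200)
    return float(val)


def dh_sd_analytic(candidate: PhasedGenotype, alpha: np.ndarray,
                   gmap: GeneticMap) -> float:
    """Standard deviation sigma_i of the GEBVs of a candidate's DH lines.

    Only heterozygous loci segregate. With s_l = +1 when the favorable allele
    sits on hap1 (else -1), ``sigma_i^2 = sum_l alpha_l^2 + sum_{l != m}
    alpha_l alpha_m s_l s_m (1 - 2 r_lm)`` over heterozygous loci, with
    Haldane recombination fractions r (0.5 across chromosomes).
    """
    alpha = np.asarray(alpha, dtype=float)
    if candidate.n_loci != gmap.n_loci or alpha.shape[0] != gmap.n_loci:
        raise DataError("candidate/alpha length does not match the map")
    h1 = candidate.hap1.astype(np.int64)
    h2 = candidate.hap2.astype(np.int64)
    het = h1 != h2
    if not het.any():
        return 0.0
    s = (h1[het] - h2[het]).astype(float)  # +1 if B on hap1, -1 otherwise
    v = alpha[het] * s
    pos = gmap.positions_cM[het]
    chrom = gmap.chrom_index[het]
    r = recombination_fraction(np.abs(pos[:, None] - pos[None, :]))
    r[chrom[:, None] != chrom[None, :]] = 0.5
    var = float(v @ (1.0 - 2.0 * r) @ v)
    return float(np.sqrt(max(var, 0.0)))


def embv_normal(candidate: PhasedGenotype, alpha: np.ndarray,
                gmap: GeneticMap, ng: int) -> float:
    """Normal-approximation EMBV: ``GEBV + E(X_(ng)) * sigma_i``.

    Treats the candidate's DH GEBV distribution as normal with mean GEBV and
    standard deviation sigma_i; exact for homozygotes and for ng = 1.
    """
    score = float(gebv(candidate.dosage[None, :], alpha)[0])
    if ng == 1:
        return score
    return score + expected_max_std_normal(ng) * dh_sd_analytic(candidate, alpha, gmap)
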