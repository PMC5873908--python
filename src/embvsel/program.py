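"""Recurrent genomic selection engine.

Each cycle: recompute allele frequencies and substitution effects from the
current candidates, score every candidate with the configured criterion,
truncation-select the best N_sel, and random-mate them (parents drawn with
replacement, selfing allowed, one gamete per parent) into N_cand offspring.
Genetic gain R is the progress of the population mean genotypic value in
units of sigma_a0, the standard deviation of founder breeding values;
diversity is tracked as sigma_at^2 / sigma_a0^2 plus polymorphic-locus
counts. Experiments run the four criteria as paired programs from identical
founders and trait architectures so criteria differ only through selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import ConfigError, gamete_batch
from .population import DegeneratePopulationError, PhasedPopulation, sample_founders
from . import criteria as crit
from .trait import (
    TraitArchitecture,
    additive_variance,
    genotypic_values,
    sample_architecture,
    scale_to_unit_variance,
    substitution_effects,
)

logger = logging.getLogger("embvsel")

__all__ = [
    "ProgramConfig",
    "CRITERIA",
    "compute_ng",
    "select",
    "random_mate",
    "score_candidates",
    "allelic_diversity",
    "run_program",
    "run_experiment",
    "crossing_cycle",
]

CRITERIA = ("gebv", "wgebv", "ohv", "embv", "embv_normal")


@dataclass
class ProgramConfig:
    """Parameters of one breeding program.

    Defaults are the standard scenario: 50 candidates, 3 selected parents,
    additive gene action, 50 cycles (the map carries N_chr).
    """

    n_cand: int = 50
    n_sel: int = 3
    criterion: str = "gebv"
    cycles: int = 50
    ns_per_chrom: int = 2          # OHV only
    gene_action: str = "additive"
    seed: int = 0
    embv_se_tol: float = 0.01
    embv_min_reps: int = 10
    embv_max_reps: int = 10_000
    founder_resample_attempts: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.n_sel <= self.n_cand:
            raise ConfigError("require 1 <= n_sel <= n_cand")
        if self.cycles < 1:
            raise ConfigError("cycles must be >= 1")
        if self.criterion not in CRITERIA:
            raise ConfigError(f"criterion must be one of {CRITERIA}")
        if self.gene_action not in ("additive", "dominant"):
            raise ConfigError("gene_action must be 'additive' or 'dominant'")
        if self.ns_per_chrom < 1:
            raise ConfigError("ns_per_chrom must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_ng(n_cand: int, n_sel: int) -> int:
    """Expected gametes per selected parent: round(2 N_cand / N_sel), >= 1.

    Rounding is half-away-from-zero (so 33.5 -> 34).
    """
    if n_cand < 1 or n_sel < 1:
        raise ConfigError("n_cand and n_sel must be positive")
    return max(1, int(np.floor(2.0 * n_cand / n_sel + 0.5)))


def select(scores: np.ndarray | crit.CriterionScores, n_sel: int) -> np.ndarray:
    """Indices of the ``n_sel`` largest scores, ranked; ties -> lower index."""
    s = scores.scores if isinstance(scores, crit.CriterionScores) else np.asarray(scores)
    if not 1 <= n_sel <= s.shape[0]:
        raise ConfigError("n_sel must be between 1 and the number of candidates")
    order = np.argsort(-s, kind="stable")  # stable: equal scores keep index order
    return order[:n_sel]


def random_mate(selected: PhasedPopulation, n_offspring: int,
                rng: np.random.Generator) -> PhasedPopulation:
    """Random mating with replacement and selfing; one gamete per parent."""
    n = selected.n_individuals
    mothers = rng.integers(0, n, size=n_offspring)
    fathers = rng.integers(0, n, size=n_offspring)
    gam_m = gamete_batch(selected.haps[mothers], selected.gmap, rng)
    gam_f = gamete_batch(selected.haps[fathers], selected.gmap, rng)
    return PhasedPopulation(np.stack([gam_m, gam_f], axis=1), selected.gmap)


def allelic_diversity(pop: PhasedPopulation) -> float:
    """Average number of distinct alleles per locus (between 1 and 2)."""
    p = pop.allele_frequencies()
    return float(np.mean(np.where((p > 0) & (p < 1), 2.0, 1.0)))


def score_candidates(pop: PhasedPopulation, arch: TraitArchitecture,
                     config: ProgramConfig,
                     rng: np.random.Generator) -> crit.CriterionScores:
    """Score all candidates under the configured criterion.

    Frequencies, substitution effects (and wGEBV weights) are freshly
    computed from the candidate set itself.
    """
    p = pop.allele_frequencies()
    alpha = substitution_effects(arch, p)
    X = pop.dosages
    name = config.criterion
    if name == "gebv":
        return crit.CriterionScores("GEBV", crit.gebv(X, alpha))
    if name == "wgebv":
        return crit.CriterionScores("wGEBV", crit.wgebv(X, alpha, p))
    if name == "ohv":
        part = crit.partition_haplotypes(pop.gmap, config.ns_per_chrom)
        return crit.CriterionScores("OHV", crit.ohv(pop.haps, alpha, part),
                                    ns_per_chrom=config.ns_per_chrom)
    ng = compute_ng(config.n_cand, config.n_sel)
    if name == "embv_normal":
        scores = np.array([crit.embv_normal(pop[i], alpha, pop.gmap, ng)
                           for i in range(pop.n_individuals)])
        return crit.CriterionScores("EMBV_normal", scores, ng=ng)
    scores = np.empty(pop.n_individuals)
    reps = np.empty(pop.n_individuals, dtype=np.int64)
    ses = np.empty(pop.n_individuals)
    for i in range(pop.n_individuals):
        scores[i], reps[i], ses[i] = crit.embv_mc(
            pop[i], alpha, pop.gmap, ng, se_tol=config.embv_se_tol,
            min_reps=config.embv_min_reps, max_reps=config.embv_max_reps,
            rng=rng)
    return crit.CriterionScores("EMBV", scores, ng=ng, mc_replicates=reps,
                                mc_se=ses)


def _cycle_record(pop: PhasedPopulation, arch: TraitArchitecture,
                  cycle: int, mean_g0: float, sigma_a0: float) -> dict:
    p = pop.allele_frequencies()
    mean_g = float(genotypic_values(pop.dosages, arch).mean())
    var_a = additive_variance(pop.dosages, arch, p)
    poly = (p > 0) & (p < 1)
    return {
        "cycle": cycle,
        "mean_G": mean_g,
        "R": (mean_g - mean_g0) / sigma_a0,
        "var_rel": var_a / sigma_a0 ** 2,
        "n_poly": int(poly.sum()),
        "mean_alleles": float(np.mean(np.where(poly, 2.0, 1.0))),
    }


def _run_cycles(founders: PhasedPopulation, arch: TraitArchitecture,
                config: ProgramConfig, rng: np.random.Generator,
                sigma_a0: float) -> pd.DataFrame:
    pop = founders
    mean_g0 = float(genotypic_values(pop.dosages, arch).mean())
    records = [_cycle_record(pop, arch, 0, mean_g0, sigma_a0)]
    for t in range(1, config.cycles + 1):
        scores = score_candidates(pop, arch, config, rng)
        winners = select(scores, config.n_sel)
        parents = PhasedPopulation(pop.haps[winners], pop.gmap)
        pop = random_mate(parents, config.n_cand, rng)
        records.append(_cycle_record(pop, arch, t, mean_g0, sigma_a0))
    df = pd.DataFrame.from_records(records)
    df.insert(0, "criterion", config.criterion)
    return df


def _founder_sigma(founders: PhasedPopulation, arch: TraitArchitecture) -> float:
    p = founders.allele_frequencies()
    return float(np.sqrt(additive_variance(founders.dosages, arch, p)))


def run_program(config: ProgramConfig, base_pop: PhasedPopulation,
                arch: TraitArchitecture,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Run one breeding program; founders are sampled from the base population.

    ``arch`` must already be scaled to unit additive variance in the base
    population. Founder sets with zero additive variance are resampled a few
    times before raising.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(config.founder_resample_attempts):
        founders = sample_founders(base_pop, config.n_cand, rng)
        sigma_a0 = _founder_sigma(founders, arch)
        if sigma_a0 > 0:
            return _run_cycles(founders, arch, config, rng, sigma_a0)
    raise DegeneratePopulationError("founder sample has zero additive variance")


def _config_key(config: ProgramConfig) -> int:
    import hashlib
    import json

    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:6], "big")


def run_experiment(configs: list[ProgramConfig], base_pop: PhasedPopulation,
                   n_replicates: int, seed: int = 0,
                   progress: bool = False) -> pd.DataFrame:
    """Paired comparison of criteria sharing founders and architecture.

    Per replicate, one trait architecture is drawn and scaled against the
    base population and one founder set is sampled; every config then runs
    from bit-identical C0 with its own deterministic mating stream. Returns
    the per-replicate, per-cycle trajectory table.
    """
    if not configs:
        raise ConfigError("need at least one program configuration")
    gene_action = configs[0].gene_action
    n_cand = configs[0].n_cand
    if any(c.gene_action != gene_action or c.n_cand != n_cand for c in configs):
        raise ConfigError("paired configs must share gene_action and n_cand")
    rows = []
    root = np.random.SeedSequence(seed)
    for rep in range(n_replicates):
        rep_ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(rep,))
        rng_setup = np.random.default_rng(rep_ss.spawn(1)[0])
        arch = sample_architecture(base_pop.gmap, gene_action, rng_setup)
        arch = scale_to_unit_variance(arch, base_pop.dosages,
                                      base_pop.allele_frequencies())
        founders = None
        for _ in range(configs[0].founder_resample_attempts):
            cand = sample_founders(base_pop, n_cand, rng_setup)
            sigma_a0 = _founder_sigma(cand, arch)
            if sigma_a0 > 0:
                founders = cand
                break
        if founders is None:
            raise DegeneratePopulationError("founder sample has zero additive variance")
        for config in configs:
            # stream keyed by config content: identical programs replay the
            # same randomness, different criteria diverge only via selection
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy,
                                       spawn_key=(rep, _config_key(config))))
            df = _run_cycles(founders, arch, config, rng, sigma_a0)
            df.insert(0, "replicate", rep)
            rows.append(df)
        if progress:
            logger.info("replicate %d/%d done", rep + 1, n_replicates)
    return pd.concat(rows, ignore_index=True)


def aggregate_trajectories(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-criterion, per-cycle means and standard errors across replicates."""
    g = traj.groupby(["criterion", "cycle"])
    out = g.agg(
        mean_R=("R", "mean"),
        se_R=("R", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0),
        mean_var_rel=("var_rel", "mean"),
        mean_n_poly=("n_poly", "mean"),
        mean_alleles=("mean_alleles", "mean"),
        n_replicates=("R", "size"),
    ).reset_index()
    return out


def relative_gain(agg: pd.DataFrame, baseline: str = "gebv") -> pd.DataFrame:
    """Percent gain of each criterion's mean R relative to the baseline's."""
    base = agg[agg["criterion"] == baseline].set_index("cycle")["mean_R"]
    rows = []
    for name, sub in agg.groupby("criterion"):
        if name == baseline:
            continue
        sub = sub.set_index("cycle")
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = 100.0 * (sub["mean_R"] - base) / base
        rows.append(pd.DataFrame({"criterion": name, "cycle": rel.index,
                                  "rel_gain_pct": rel.values}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["criterion", "cycle", "rel_gain_pct"])


def crossing_cycle(agg: pd.DataFrame, criterion: str,
                   baseline: str = "gebv", persist: int = 2) -> int | None:
    """First cycle where a criterion's mean R exceeds the baseline's and stays
    above it for ``persist`` consecutive cycles; None if it never does."""
    base = agg[agg["criterion"] == baseline].set_index("cycle")["mean_R"]
    other = agg[agg["criterion"] == criterion].set_index("cycle")["mean_R"]
    cycles = sorted(set(base.index) & set(other.index))
    above = {t: bool(other[t] > base[t]) for t in cycles}
    for i, t in enumerate(cycles):
        window = cycles[i:i + persist]
        if len(window) == persist and all(above[u] for u in window):
            return t
    return None


__all__ += ["aggregate_trajectories", "relative_gain"]
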