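"""Configuration, file formats, run manifests and the OHV segment sweep.

Formats
-------
- genetic map: TSV with header ``chrom  pos_cM  id``; chromosome order of
  first appearance defines genome order.
- effect table: TSV with header ``id  a  k`` (model parameters) or
  ``id  alpha`` (pre-computed substitution effects for scoring).
- phased genotypes: VCF with phased GT (``|`` separator); ALT is taken as
  the favorable allele B. Unphased records are rejected.
- trajectories: CSV with fixed column order and 12 significant digits,
  accompanied by a JSON run manifest (config snapshot, package version,
  master seed, base-population checksum, timestamp).
- populations: NumPy ``.npz`` archive embedding map, haplotypes, seed and a
  SHA-256 checksum of the haplotype bytes.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import ConfigError, DataError, GeneticMap
from .population import PhasedPopulation
from .program import ProgramConfig, aggregate_trajectories, run_experiment
from .criteria import MIN_SEGMENT_CM

logger = logging.getLogger("embvsel")

__version__ = "0.1.0"

__all__ = [
    "RunManifest",
    "load_config",
    "read_map_tsv",
    "write_map_tsv",
    "read_effects_tsv",
    "write_effects_tsv",
    "write_trajectories",
    "read_trajectories",
    "save_population",
    "load_population",
    "write_vcf",
    "read_phased_vcf",
    "admissible_ns",
    "sweep_ohv_ns",
]

TRAJECTORY_COLUMNS = ["replicate", "criterion", "cycle", "mean_G", "R",
                      "var_rel", "n_poly", "mean_alleles"]

# experiment-level keys allowed in a config file beyond ProgramConfig fields
_EXPERIMENT_KEYS = {"criteria", "n_chr", "n_loci", "genome_cM", "replicates"}
_LIST_OK = {"n_cand", "n_sel", "criterion", "criteria", "n_chr"}


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility sidecar written next to every output table."""

    config: dict
    seed: int
    base_population_checksum: str | None = None
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def population_checksum(pop: PhasedPopulation) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(pop.haps).tobytes())
    h.update(np.ascontiguousarray(pop.gmap.positions_cM).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _validate_keys(raw: dict) -> None:
    allowed = set(ProgramConfig().to_dict()) | _EXPERIMENT_KEYS
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; allowed: {sorted(allowed)}")


def load_config(path) -> list[ProgramConfig]:
    """Load a YAML config into one or more validated program configurations.

    An empty file yields the standard scenario defaults. List values for
    ``n_cand``, ``n_sel`` and ``criterion``/``criteria`` expand into the
    factorial of configurations. Unknown keys are rejected with a message
    naming the key.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return configs_from_dict(raw)


def configs_from_dict(raw: dict) -> list[ProgramConfig]:
    raw = dict(raw)
    _validate_keys(raw)
    if "criteria" in raw:
        raw["criterion"] = raw.pop("criteria")
    raw.pop("n_chr", None)
    raw.pop("n_loci", None)
    raw.pop("genome_cM", None)
    raw.pop("replicates", None)
    lists = {k: v for k, v in raw.items()
             if isinstance(v, (list, tuple)) and k in _LIST_OK}
    bad_lists = [k for k, v in raw.items()
                 if isinstance(v, (list, tuple)) and k not in _LIST_OK]
    if bad_lists:
        raise ConfigError(f"list values not allowed for keys {sorted(bad_lists)}")
    scalars = {k: v for k, v in raw.items() if k not in lists}
    if not lists:
        return [ProgramConfig(**scalars)]
    keys = sorted(lists)
    out = []
    for combo in itertools.product(*(lists[k] for k in keys)):
        d = dict(scalars)
        d.update(dict(zip(keys, combo)))
        out.append(ProgramConfig(**d))
    return out


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------

def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap.from_dataframe(df)


def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.to_dataframe().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_effects_tsv(path, gmap: GeneticMap) -> pd.DataFrame:
    """Effect table aligned to the map's loci (by ``id``).

    Returns a DataFrame with either columns ``a``/``k`` or ``alpha``.
    """
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise DataError("effect table needs an 'id' column")
    has_model = {"a", "k"}.issubset(df.columns)
    if not has_model and "alpha" not in df.columns:
        raise DataError("effect table needs columns 'a' and 'k', or 'alpha'")
    df = df.set_index("id")
    ids = pd.Index(gmap.locus_ids)
    missing = ids.difference(df.index)
    if len(missing):
        raise DataError(f"effect table missing loci: {list(missing[:5])} ...")
    return df.loc[ids].reset_index(names="id")


def write_effects_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectories(traj: pd.DataFrame, path,
                       manifest: RunManifest | None = None) -> None:
    """Write a trajectory table as CSV (12 significant digits, LF endings)."""
    if traj is None or len(traj) == 0:
        df = pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    else:
        df = traj.copy()
        if "replicate" not in df.columns:
            df.insert(0, "replicate", 0)
        df = df[TRAJECTORY_COLUMNS]
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
    if manifest is not None:
        manifest.write(str(path) + ".manifest.json")


def read_trajectories(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Population serialization
# ---------------------------------------------------------------------------

def save_population(pop: PhasedPopulation, path, seed: int | None = None) -> None:
    """Binary ``.npz`` archive with embedded seed and checksum."""
    np.savez_compressed(
        path,
        haps=pop.haps,
        lengths_cM=pop.gmap.lengths_cM,
        positions_cM=pop.gmap.positions_cM,
        chrom_index=pop.gmap.chrom_index,
        locus_ids=np.asarray(pop.gmap.locus_ids, dtype=str),
        generation_label=np.array(pop.generation_label),
        seed=np.array(-1 if seed is None else seed),
        checksum=np.array(population_checksum(pop)),
    )


def load_population(path) -> tuple[PhasedPopulation, int]:
    with np.load(path, allow_pickle=False) as z:
        gmap = GeneticMap(z["lengths_cM"], z["positions_cM"],
                          z["chrom_index"], z["locus_ids"])
        pop = PhasedPopulation(z["haps"], gmap,
                               generation_label=str(z["generation_label"]))
        if str(z["checksum"]) != population_checksum(pop):
            raise DataError("population checksum mismatch; file corrupted")
        return pop, int(z["seed"])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(pop: PhasedPopulation, path, sample_prefix: str = "cand") -> None:
    """Minimal phased VCF (ALT = favorable allele B, positions in 0.01 cM units)."""
    gmap = pop.gmap
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for c in range(gmap.n_chrom):
        lines.append(f"##contig=<ID=chr{c + 1}>")
    samples = [f"{sample_prefix}{i + 1}" for i in range(pop.n_individuals)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for l in range(gmap.n_loci):
        chrom = f"chr{gmap.chrom_index[l] + 1}"
        pos = int(round(gmap.positions_cM[l] * 100)) + 1  # unique integer bp proxy
        gts = "\t".join(f"{pop.haps[i, 0, l]}|{pop.haps[i, 1, l]}"
                        for i in range(pop.n_individuals))
        lines.append(f"{chrom}\t{pos}\t{gmap.locus_ids[l]}\tA\tB\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phased_vcf(path, gmap: GeneticMap) -> tuple[PhasedPopulation, list[str]]:
    """Read phased genotypes aligned to the map's loci by VCF ID.

    Any unphased genotype raises a clear error. Returns the population and
    the sample names.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_id: dict[str, np.ndarray] = {}
    for var in vcf:
        g = np.array(var.genotypes)  # (n, 3): allele0, allele1, phased flag
        if g.shape[1] < 3 or not np.all(g[:, 2] == 1):
            raise DataError(f"unphased genotype at record {var.ID or var.POS}; "
                            "phased GT ('|') is required")
        if np.any(g[:, :2] < 0) or np.any(g[:, :2] > 1):
            raise DataError(f"missing or multi-allelic genotype at {var.ID or var.POS}")
        by_id[str(var.ID)] = g[:, :2].astype(np.uint8)
    vcf.close()
    haps = np.empty((len(samples), 2, gmap.n_loci), dtype=np.uint8)
    for l, locus in enumerate(gmap.locus_ids):
        key = str(locus)
        if key not in by_id:
            raise DataError(f"locus {key} from the map is missing in the VCF")
        haps[:, :, l] = by_id[key]
    return PhasedPopulation(haps, gmap, generation_label="scored"), samples


# ---------------------------------------------------------------------------
# OHV segment-count sweep
# ---------------------------------------------------------------------------

def admissible_ns(gmap: GeneticMap, min_len_cM: float = MIN_SEGMENT_CM) -> list[int]:
    """Geometric grid NS = 1, 2, 4, ... while segments stay >= 6.25 cM."""
    clen = float(np.min(gmap.lengths_cM))
    out = []
    ns = 1
    while clen / ns >= min_len_cM:
        out.append(ns)
        ns *= 2
    return out or [1]


def sweep_ohv_ns(config: ProgramConfig, base_pop: PhasedPopulation,
                 ns_values: list[int] | None = None, n_replicates: int = 10,
                 seed: int = 0, horizon: int | None = None,
                 ) -> tuple[pd.DataFrame, int]:
    """Mean R trajectories of OHV programs over a grid of segment counts.

    Returns the (ns, cycle, mean_R) table and the NS maximizing mean R at the
    chosen horizon (default: the final cycle).
    """
    if ns_values is None:
        ns_values = admissible_ns(base_pop.gmap)
    horizon = config.cycles if horizon is None else horizon
    frames = []
    for ns in ns_values:
        cfg = ProgramConfig(**{**config.to_dict(), "criterion": "ohv",
                               "ns_per_chrom": int(ns)})
        traj = run_experiment([cfg], base_pop, n_replicates, seed=seed)
        agg = aggregate_trajectories(traj)
        agg.insert(0, "ns", int(ns))
        frames.append(agg[["ns", "cycle", "mean_R", "se_R"]])
    table = pd.concat(frames, ignore_index=True)
    at_h = table[table["cycle"] == horizon].reset_index(drop=True)
    best = int(at_h.loc[at_h["mean_R"].idxmax(), "ns"])
    return table, best
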