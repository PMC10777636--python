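"""Synthetic soil-community generator with planted ground truth.

Emulates the sampling design the pipeline targets — three zones
(abandoned land AL, root zone RZ, transition zone TZ) with four
replicates each — using a log-normal latent-factor compositional model
with multinomial read sampling:

* each of K ecological modules has a latent factor ``f_m(s) ~ N(0, 1)``
  per sample; in the treatment zone (RZ) the driver module's factor is
  shifted by ``+effect_size_zone`` and the antagonist module's by
  ``-effect_size_zone`` (in SD units);
* a module member's per-sample log-abundance deviation is
  ``sqrt(rho) * f_m + sqrt(1 - rho) * noise`` so that member pairs share
  correlation ``rho`` on the log scale; non-module taxa are independent;
* planted core taxa (drawn from the driver and antagonist modules, so
  that the factors driving soil functions are core-taxa factors) get an
  elevated baseline log-abundance, placing them in the top abundance
  decile and in every sample;
* reads are drawn per sample as a multinomial over softmax-transformed
  log-abundances at a configurable depth;
* each soil-function variable is linear in the latent factors,
  ``effect_size_function * (f_driver - f_antagonist)`` plus Gaussian
  noise, affinely mapped to a plausible positive range;
* phyla are assigned so driver-module taxa are majority copiotrophic and
  antagonist-module taxa majority oligotrophic; taxa outside modules are
  fungi, giving the taxonomy both kingdoms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (FunctionTable, OtuTable, SampleMetadata, TaxonomyTable,
                     write_function_table, write_otu_table,
                     write_sample_metadata, write_taxonomy_table)

logger = logging.getLogger(__name__)

FUNCTION_NAMES = ("SOC", "TN", "AN", "AP", "UE", "CAT", "ACP", "PPO", "POD",
                  "INV")
# plausible central values (SOC/TN in g/kg, AN/AP in mg/kg, enzymes in
# activity units); only the shape of the distribution matters downstream
FUNCTION_CENTERS = (18.0, 1.6, 120.0, 8.5, 260.0, 14.0, 550.0, 3.2, 2.1, 21.0)

COPIOTROPH_PHYLA = ("Proteobacteria", "Actinobacteria", "Bacteroidetes",
                    "Firmicutes")
OLIGOTROPH_PHYLA = ("Acidobacteria", "Chloroflexi", "Planctomycetes",
                    "Verrucomicrobia")
FUNGAL_PHYLA = ("Ascomycota", "Basidiomycota", "Zygomycota")


@dataclass
class SyntheticConfig:
    reps_per_zone: int = 4
    zones: tuple[str, ...] = ("AL", "RZ", "TZ")
    treatment_zone: str = "RZ"
    n_taxa: int = 400
    n_core: int = 40
    n_modules: int = 5
    module_sizes: tuple[int, ...] | None = None   # default: 60 each
    within_module_cor: float = 0.8
    driver_module_index: int = 1
    antagonist_module_index: int = 4
    effect_size_zone: float = 1.5        # SD shift of driver factor in RZ
    effect_size_function: float = 1.0    # factor loading of functions
    noise_sd: float = 0.5                # residual SD of functions
    n_functions: int = 10
    depth: int = 50_000                  # reads per sample
    core_log_boost: float = 4.3          # baseline log-abundance lift of core
    core_baseline_sd: float = 0.25
    baseline_sd: float = 0.8
    taxon_noise_sd: float = 1.0          # per-sample biological variation
    trophic_bias: float = 0.8            # majority fraction in driver/antagonist
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = (60,) * self.n_modules
        self.module_sizes = tuple(self.module_sizes)
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError("module sizes exceed n_taxa")
        if self.n_core > self.n_taxa:
            raise ValueError("n_core exceeds n_taxa")
        if not (0 < self.within_module_cor < 1):
            raise ValueError("within_module_cor must be in (0, 1)")
        for name in ("effect_size_zone", "effect_size_function", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.driver_module_index <= self.n_modules):
            raise ValueError("driver_module_index out of range")
        if not (1 <= self.antagonist_module_index <= self.n_modules):
            raise ValueError("antagonist_module_index out of range")
        if self.treatment_zone not in self.zones:
            raise ValueError("treatment_zone must be one of the zones")

    @property
    def n_samples(self) -> int:
        return len(self.zones) * self.reps_per_zone


@dataclass
class SyntheticTruth:
    core_set: set[str]
    module_label: dict[str, int]          # otu_id -> 1..K, 0 = unassigned
    driver_sign: dict[int, int]           # module -> {+1, -1, 0}
    latent_factors: pd.DataFrame          # modules x samples

    def to_json(self) -> str:
        return json.dumps({
            "core_set": sorted(self.core_set),
            "module_label": self.module_label,
            "driver_sign": {str(k): v for k, v in self.driver_sign.items()},
            "latent_factors": {
                str(m): self.latent_factors.loc[m].tolist()
                for m in self.latent_factors.index},
            "sample_ids": list(self.latent_factors.columns),
        }, indent=1)


def _sample_ids(config: SyntheticConfig) -> tuple[list[str], list[str], list[int]]:
    ids, zones, reps = [], [], []
    for z in config.zones:
        for r in range(1, config.reps_per_zone + 1):
            ids.append(f"{z}{r:02d}")
            zones.append(z)
            reps.append(r)
    return ids, zones, reps


def _assign_modules(config: SyntheticConfig) -> np.ndarray:
    labels = np.zeros(config.n_taxa, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start:start + size] = m
        start += size
    return labels


def _pick_core(config: SyntheticConfig, module_label: np.ndarray) -> np.ndarray:
    """Core indices drawn alternately from the driver and antagonist modules
    (so the factors that drive the functions belong to core taxa), spilling
    to the remaining modules and then unassigned taxa if needed."""
    from itertools import chain, zip_longest

    drv = list(np.nonzero(module_label == config.driver_module_index)[0])
    ant = (list(np.nonzero(module_label == config.antagonist_module_index)[0])
           if config.antagonist_module_index != config.driver_module_index
           else [])
    rest: list[int] = []
    for m in range(1, config.n_modules + 1):
        if m not in (config.driver_module_index, config.antagonist_module_index):
            rest.extend(np.nonzero(module_label == m)[0])
    rest.extend(np.nonzero(module_label == 0)[0])
    interleaved = (x for pair in zip_longest(drv, ant) for x in pair
                   if x is not None)
    chosen = [int(i) for _, i in zip(range(config.n_core),
                                     chain(interleaved, rest))]
    return np.array(sorted(chosen), dtype=int)


def _assign_phyla(config: SyntheticConfig, module_label: np.ndarray,
                  rng: np.random.Generator) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    all_bact = COPIOTROPH_PHYLA + OLIGOTROPH_PHYLA
    for i in range(config.n_taxa):
        m = module_label[i]
        if m == 0:
            out.append(("Fungi", FUNGAL_PHYLA[i % len(FUNGAL_PHYLA)]))
        elif m == config.driver_module_index:
            pool = (COPIOTROPH_PHYLA if rng.random() < config.trophic_bias
                    else OLIGOTROPH_PHYLA)
            out.append(("Bacteria", pool[i % len(pool)]))
        elif m == config.antagonist_module_index:
            pool = (OLIGOTROPH_PHYLA if rng.random() < config.trophic_bias
                    else COPIOTROPH_PHYLA)
            out.append(("Bacteria", pool[i % len(pool)]))
        else:
            out.append(("Bacteria", all_bact[i % len(all_bact)]))
    return out


def generate(config: SyntheticConfig
             ) -> tuple[OtuTable, TaxonomyTable, SampleMetadata, FunctionTable,
                        SyntheticTruth]:
    """Generate all four tables plus the planted truth, deterministically."""
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_counts, rng_fx, rng_tax = (
        np.random.default_rng(s) for s in ss.spawn(4))

    sample_ids, zone_of, reps = _sample_ids(config)
    n_s = config.n_samples
    n_t = config.n_taxa
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n_t)]
    module_label = _assign_modules(config)
    core_idx = _pick_core(config, module_label)

    # latent factors, shifted in the treatment zone
    factors = rng_latent.standard_normal((config.n_modules, n_s))
    in_rz = np.array([z == config.treatment_zone for z in zone_of])
    factors[config.driver_module_index - 1, in_rz] += config.effect_size_zone
    factors[config.antagonist_module_index - 1, in_rz] -= config.effect_size_zone

    # baseline log-abundance: elevated for core taxa
    baseline = rng_latent.normal(0.0, config.baseline_sd, n_t)
    baseline[core_idx] = rng_latent.normal(config.core_log_boost,
                                           config.core_baseline_sd,
                                           core_idx.size)

    rho = config.within_module_cor
    eps = rng_latent.standard_normal((n_t, n_s))
    log_ab = np.empty((n_t, n_s))
    for i in range(n_t):
        m = module_label[i]
        if m > 0:
            dev = np.sqrt(rho) * factors[m - 1] + np.sqrt(1 - rho) * eps[i]
        else:
            dev = eps[i]
        log_ab[i] = baseline[i] + config.taxon_noise_sd * dev

    # multinomial read sampling of softmax-transformed log-abundances
    counts = np.empty((n_t, n_s))
    for s in range(n_s):
        w = np.exp(log_ab[:, s] - log_ab[:, s].max())
        counts[:, s] = rng_counts.multinomial(config.depth, w / w.sum())

    otu = OtuTable(otu_ids, sample_ids, counts, "counts")

    # occupancy guarantee check for the planted core
    occ = (counts[core_idx] > 0).mean(axis=1)
    if occ.min() < 0.95:
        logger.warning(
            "sequencing depth %d too low for the core occupancy guarantee: "
            "minimum achieved occupancy %.3f", config.depth, occ.min())

    meta = SampleMetadata(dict(zip(sample_ids, zone_of)),
                          dict(zip(sample_ids, reps)), tuple(config.zones))

    # soil functions: linear in the driver/antagonist factors
    f_drv = factors[config.driver_module_index - 1]
    f_ant = factors[config.antagonist_module_index - 1]
    fx_names = list(FUNCTION_NAMES[:config.n_functions])
    fx_names += [f"F{k + 1}" for k in range(len(fx_names), config.n_functions)]
    centers = list(FUNCTION_CENTERS[:config.n_functions])
    centers += [10.0] * (config.n_functions - len(centers))
    fx_vals = np.empty((n_s, config.n_functions))
    for k in range(config.n_functions):
        raw = (config.effect_size_function * (f_drv - f_ant)
               + config.noise_sd * rng_fx.standard_normal(n_s))
        fx_vals[:, k] = centers[k] * (1.0 + 0.1 * raw)
    fx = FunctionTable(sample_ids, fx_names, fx_vals)

    tax = TaxonomyTable(dict(zip(otu_ids,
                                 _assign_phyla(config, module_label, rng_tax))))

    driver_sign = {m: 0 for m in range(1, config.n_modules + 1)}
    driver_sign[config.driver_module_index] = 1
    driver_sign[config.antagonist_module_index] = -1
    truth = SyntheticTruth(
        core_set={otu_ids[i] for i in core_idx},
        module_label={otu_ids[i]: int(module_label[i]) for i in range(n_t)},
        driver_sign=driver_sign,
        latent_factors=pd.DataFrame(factors, columns=sample_ids,
                                    index=range(1, config.n_modules + 1)),
    )
    return otu, tax, meta, fx, truth


def write_dataset(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Generate and write the four TSVs plus truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    otu, tax, meta, fx, truth = generate(config)
    paths = {
        "otu": str(outdir / "otu_table.tsv"),
        "taxonomy": str(outdir / "taxonomy.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "functions": str(outdir / "functions.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_otu_table(otu, paths["otu"])
    write_taxonomy_table(tax, paths["taxonomy"])
    write_sample_metadata(meta, paths["metadata"])
    write_function_table(fx, paths["functions"])
    Path(paths["truth"]).write_text(truth.to_json())
    return paths
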