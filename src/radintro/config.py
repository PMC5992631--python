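"""Flat run configuration: seeds, thresholds and paths for a whole run.

A config file is a flat YAML mapping (``key: value`` lines).  Unknown keys
are rejected so that typos fail loudly, every run can log its fully
resolved configuration, and two runs with the same config and seed are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import yaml

from .filtering import FilterConfig

__all__ = ["RunConfig", "run_config"]

log = logging.getLogger("radintro")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration with the package's canonical defaults."""

    seed: int = 0
    alpha: float = 0.01
    n_boot: int = 1000
    theta: float = 0.01
    locus_length: int = 87
    k_grid: tuple[int, ...] = (1, 2, 3, 5, 10, 20, 50, 100)
    binning_boot: int = 128
    # filter thresholds (see FilterConfig)
    max_het_sites_per_consensus: int = 10
    max_haplotypes_per_individual: int = 2
    max_site_heterozygosity: float = 0.75
    min_individual_fraction_per_locus: float = 0.50
    max_missing_per_individual: float = 0.80
    min_polymorphic_sites: int = 0
    drop_indel_loci: bool = False

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            max_het_sites_per_consensus=self.max_het_sites_per_consensus,
            max_haplotypes_per_individual=self.max_haplotypes_per_individual,
            max_site_heterozygosity=self.max_site_heterozygosity,
            min_individual_fraction_per_locus=self.min_individual_fraction_per_locus,
            max_missing_per_individual=self.max_missing_per_individual,
            min_polymorphic_sites=self.min_polymorphic_sites,
            drop_indel_loci=self.drop_indel_loci,
        )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def run_config(path) -> RunConfig:
    """Load and validate a flat key-value config file.

    Missing keys take package defaults; unknown keys raise; the resolved
    configuration (and its seed) is logged so any run can be replayed.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "k_grid" in raw:
        raw["k_grid"] = tuple(int(k) for k in raw["k_grid"])
    cfg = RunConfig(**raw)
    log.info("resolved config: %s", cfg.as_dict())
    return cfg
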