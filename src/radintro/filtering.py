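"""Locus- and individual-level quality filters for RAD data.

The rules mirror the standard assembled-loci cleanup for ddRAD panels:
per-individual excess heterozygosity (a paralog signature), excess
haplotypes per individual, excess per-site heterozygosity across
individuals (another paralog signature), minimum polymorphism / indel
screens, a minimum share of individuals per locus, and finally removal of
individuals with too much missing data.  Rules are applied sequentially in
that declared order, each rule seeing the previous rule's survivors, so
per-rule removal counts are additive and the whole pass is deterministic.
Read-depth filtering is out of scope: this stage starts from assembled
loci, not reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .alphabet import GAP, N, BASES, _PAIR_TO_IUPAC
from .loci import Locus, LocusSet

__all__ = ["FilterConfig", "FilterReport", "filter_loci", "extract_unlinked_snps"]

RULE_ORDER = (
    "het_sites_per_individual",
    "excess_haplotypes",
    "site_heterozygosity",
    "min_polymorphic_sites",
    "indels",
    "min_individuals",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the sequential locus/individual filters.

    Defaults are the conventional assembled-ddRAD settings: a locus is
    discarded when any individual consensus has more than 10 heterozygous
    sites, when any individual would contribute more than two haplotypes,
    when any site is heterozygous in more than 75% of the individuals with
    data there, or when fewer than 50% of individuals carry the locus;
    individuals missing more than 80% of surviving loci are dropped.
    ``min_polymorphic_sites=2`` together with ``drop_indel_loci`` gives the
    stricter screen used for filtered binning runs.
    """

    max_het_sites_per_consensus: int = 10
    max_haplotypes_per_individual: int = 2
    max_site_heterozygosity: float = 0.75
    min_individual_fraction_per_locus: float = 0.50
    max_missing_per_individual: float = 0.80
    min_polymorphic_sites: int = 0
    drop_indel_loci: bool = False

    def __post_init__(self) -> None:
        for name in (
            "max_site_heterozygosity",
            "min_individual_fraction_per_locus",
            "max_missing_per_individual",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "max_het_sites_per_consensus",
            "max_haplotypes_per_individual",
            "min_polymorphic_sites",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterReport:
    loci_in: int = 0
    loci_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    individuals_removed: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("loci_in", self.loci_in)]
        rows += [(f"removed_{rule}", self.removed.get(rule, 0)) for rule in RULE_ORDER]
        rows += [
            ("loci_out", self.loci_out),
            ("individuals_removed", ",".join(self.individuals_removed) or "none"),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _het_sites_per_individual(locus: Locus) -> dict[str, int]:
    out = {}
    for ind, mat in locus.seqs.items():
        callable_ = (mat < 4).all(axis=0)  # both haplotypes A/C/G/T
        out[ind] = int(((mat[0] != mat[1]) & callable_).sum())
    return out


def _max_site_heterozygosity(locus: Locus) -> float:
    """Max over sites of: heterozygous individuals / individuals with data."""
    if not locus.seqs:
        return 0.0
    mats = list(locus.seqs.values())
    het = np.zeros(locus.length, dtype=np.int64)
    with_data = np.zeros(locus.length, dtype=np.int64)
    for mat in mats:
        ok = (mat < 4).all(axis=0)
        with_data += ok
        het += ok & (mat[0] != mat[1])
    frac = np.divide(het, with_data, out=np.zeros(locus.length), where=with_data > 0)
    return float(frac.max()) if locus.length else 0.0


def _polymorphic_site_count(locus: Locus) -> int:
    """Sites with >= 2 distinct called bases across all haplotypes."""
    if not locus.seqs:
        return 0
    stacked = locus.stacked()
    counts = np.zeros((4, locus.length), dtype=np.int64)
    for b in range(4):
        counts[b] = (stacked == b).sum(axis=0)
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def _has_indel(locus: Locus) -> bool:
    return any((mat == GAP).any() for mat in locus.seqs.values())


def filter_loci(locus_set: LocusSet, cfg: FilterConfig) -> tuple[LocusSet, FilterReport]:
    """Apply the sequential quality filters; return survivors and a report."""
    report = FilterReport(loci_in=locus_set.n_loci)
    n_panel = len(locus_set.individuals)
    survivors = list(range(locus_set.n_loci))

    def apply_rule(name: str, discard) -> None:
        nonlocal survivors
        kept = [j for j in survivors if not discard(locus_set.loci[j])]
        report.removed[name] = len(survivors) - len(kept)
        survivors = kept

    apply_rule(
        "het_sites_per_individual",
        lambda loc: any(
            v > cfg.max_het_sites_per_consensus
            for v in _het_sites_per_individual(loc).values()
        ),
    )
    # With a diploid (2, L) representation each individual contributes at
    # most two haplotypes; the rule is kept as a validation hook for
    # malformed external input and never fires on internal data.
    apply_rule("excess_haplotypes", lambda loc: 2 > cfg.max_haplotypes_per_individual)
    apply_rule(
        "site_heterozygosity",
        lambda loc: _max_site_heterozygosity(loc) > cfg.max_site_heterozygosity,
    )
    apply_rule(
        "min_polymorphic_sites",
        lambda loc: _polymorphic_site_count(loc) < cfg.min_polymorphic_sites,
    )
    if cfg.drop_indel_loci:
        apply_rule("indels", _has_indel)
    else:
        report.removed["indels"] = 0
    apply_rule(
        "min_individuals",
        lambda loc: len(loc.seqs) / n_panel < cfg.min_individual_fraction_per_locus,
    )

    filtered = locus_set.subset_loci(survivors)
    # individual-level missingness over the surviving loci
    if filtered.n_loci > 0:
        presence = filtered.presence_matrix()
        missing_frac = 1.0 - presence.mean(axis=1)
        bad = [
            ind
            for ind in filtered.individuals
            if missing_frac[ind] > cfg.max_missing_per_individual
        ]
    else:
        bad = []
        warnings.warn("all loci removed by filtering", stacklevel=2)
    if bad:
        filtered = filtered.drop_individuals(bad)
        report.individuals_removed = bad
    report.loci_out = filtered.n_loci
    return filtered, report


# -- unlinked SNP extraction ---------------------------------------------

_IUPAC_OF_PAIR = {k: v for k, v in _PAIR_TO_IUPAC.items()}


def _biallelic_sites(locus: Locus) -> np.ndarray:
    """Indices of sites with exactly two called alleles across haplotypes."""
    if not locus.seqs:
        return np.empty(0, dtype=int)
    stacked = locus.stacked()
    counts = np.zeros((4, locus.length), dtype=np.int64)
    for b in range(4):
        counts[b] = (stacked == b).sum(axis=0)
    return np.flatnonzero((counts > 0).sum(axis=0) == 2)


def extract_unlinked_snps(
    locus_set: LocusSet, picker: str = "first", seed: int = 0
) -> tuple[pd.DataFrame, int]:
    """One biallelic SNP per locus, heterozygotes as IUPAC codes.

    Returns an individual x locus matrix of single characters ('N' where
    the individual lacks the locus) plus the count of loci skipped for
    having no biallelic variable site.  ``picker`` chooses the first
    qualifying site or a seeded-random one; sites with more than two
    alleles are never eligible.
    """
    if picker not in ("first", "random"):
        raise ValueError("picker must be 'first' or 'random'")
    rng = np.random.default_rng(seed)
    inds = locus_set.individuals
    columns: dict[str, list[str]] = {}
    skipped = 0
    for j, locus in enumerate(locus_set.loci):
        sites = _biallelic_sites(locus)
        if sites.size == 0:
            skipped += 1
            continue
        site = int(sites[0]) if picker == "first" else int(rng.choice(sites))
        col = []
        for ind in inds:
            mat = locus.seqs.get(ind)
            if mat is None or (mat[:, site] >= 4).any():
                col.append("N")
                continue
            x, y = int(mat[0, site]), int(mat[1, site])
            if x == y:
                col.append(BASES[x])
            else:
                col.append(_IUPAC_OF_PAIR[frozenset((BASES[x], BASES[y]))])
        columns[f"locus{j}"] = col
    matrix = pd.DataFrame(columns, index=inds)
    return matrix, skipped
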