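"""Patterson's D-statistic batteries on RAD loci.

A four-taxon test (P1, P2, P3, O) asks whether the two site patterns that
are discordant with the assumed ((P1,P2),P3),O relationships — ABBA
(P2 and P3 share the derived allele) and BABA (P1 and P3 share it) — occur
equally often, as expected under incomplete lineage sorting alone.  The
statistic

    D = (ABBA - BABA) / (ABBA + BABA)

has expectation 0 without gene flow; a significant excess of ABBA points
to introgression between P3 and P2 (BABA: P3 and P1).  Significance is
assessed with a locus-resampling bootstrap Z-score, and batteries of tests
(all combinations of one individual per taxon) are corrected with the
Holm-Bonferroni procedure.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .loci import LocusSet

__all__ = [
    "QuartetTest",
    "DResult",
    "BatterySummary",
    "count_patterns",
    "bootstrap_d_distribution",
    "compute_D",
    "bootstrap_Z",
    "permute_individuals",
    "holm_bonferroni",
    "run_battery",
    "split_by_geography",
]


@dataclass(frozen=True)
class QuartetTest:
    """A (P1, P2, P3, O) hypothesis with the individuals backing each taxon."""

    p1: tuple[str, tuple[str, ...]]
    p2: tuple[str, tuple[str, ...]]
    p3: tuple[str, tuple[str, ...]]
    o: tuple[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        sets = [set(t[1]) for t in self.taxa]
        if any(not s for s in sets):
            raise ValueError("every taxon needs at least one individual")
        for (na, a), (nb, b) in itertools.combinations(zip(self.names, sets), 2):
            if a & b:
                raise ValueError(f"taxa {na} and {nb} share individuals {sorted(a & b)}")

    @property
    def taxa(self):
        return (self.p1, self.p2, self.p3, self.o)

    @property
    def names(self):
        return tuple(t[0] for t in self.taxa)

    def swapped(self) -> "QuartetTest":
        """P1 and P2 exchanged (D should negate)."""
        return QuartetTest(self.p2, self.p1, self.p3, self.o)


@dataclass
class DResult:
    test: QuartetTest
    abba: float
    baba: float
    nloci: int
    d: float | None
    z: float | None = None
    p: float | None = None
    significant: bool | None = None

    @property
    def informative(self) -> bool:
        return self.nloci >= 2


@dataclass
class BatterySummary:
    """Battery roll-up in the style of a D-statistic results table row."""

    mean_d: float
    mean_abba: float
    mean_baba: float
    mean_nloci: float
    z_min: float
    z_max: float
    n_sig: int
    n_test: int
    n_uninformative: int = 0

    def to_row(self) -> dict:
        return {
            "D": self.mean_d,
            "BABA": self.mean_baba,
            "ABBA": self.mean_abba,
            "nloci": self.mean_nloci,
            "RangeZ": f"{self.z_min:.2f}, {self.z_max:.2f}",
            "nSig/ntest": f"{self.n_sig}/{self.n_test}",
        }


def compute_D(abba: float, baba: float) -> float | None:
    """(ABBA - BABA) / (ABBA + BABA); None when there is no signal at all."""
    if abba < 0 or baba < 0:
        raise ValueError("pattern weights must be >= 0")
    total = abba + baba
    if total == 0:
        return None
    return (abba - baba) / total


def _per_locus_counts(
    locus_set: LocusSet, test: QuartetTest, mode: str = "sampled", seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus ABBA/BABA weights.

    sampled: one allele per taxon per site, drawn uniformly from the
    haplotypes of the taxon's individuals present at the locus (seeded);
    sites where the drawn allele is uncalled are skipped.

    frequency: the allele-frequency estimator; per site the ABBA weight is
    (1-p1) p2 p3 (1-pO) and the BABA weight p1 (1-p2) p3 (1-pO), with p the
    derived-allele frequency in each taxon and the ancestral state set by
    the outgroup's major allele.  Sites with more than two alleles across
    the four taxa, or with no data in some taxon, are skipped.
    """
    if mode not in ("sampled", "frequency"):
        raise ValueError("mode must be 'sampled' or 'frequency'")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    n = locus_set.n_loci
    abba = np.zeros(n)
    baba = np.zeros(n)
    taxa_inds = [list(t[1]) for t in test.taxa]
    for j, locus in enumerate(locus_set.loci):
        stacks = [locus.stacked(inds) for inds in taxa_inds]
        if any(s.shape[0] == 0 for s in stacks):
            continue
        L = locus.length
        if mode == "sampled":
            alleles = []
            for s in stacks:
                idx = rng.integers(0, s.shape[0], size=L)
                alleles.append(s[idx, np.arange(L)])
            a1, a2, a3, ao = alleles
            called = (a1 < 4) & (a2 < 4) & (a3 < 4) & (ao < 4)
            abba_m = called & (a1 == ao) & (a2 == a3) & (a2 != ao)
            baba_m = called & (a2 == ao) & (a1 == a3) & (a1 != ao)
            abba[j] = abba_m.sum()
            baba[j] = baba_m.sum()
        else:
            counts = np.zeros((4, 4, L), dtype=np.int64)  # taxon x base x site
            for t, s in enumerate(stacks):
                for b in range(4):
                    counts[t, b] = (s == b).sum(axis=0)
            totals = counts.sum(axis=1)  # taxon x site
            pooled = counts.sum(axis=0)  # base x site
            n_alleles = (pooled > 0).sum(axis=0)
            ok = (totals > 0).all(axis=0) & (n_alleles == 2)
            if not ok.any():
                continue
            anc = np.argmax(counts[3], axis=0)  # outgroup major allele
            present = pooled > 0
            present[anc, np.arange(L)] = False
            der = np.argmax(present, axis=0)
            cols = np.arange(L)
            p = np.stack(
                [counts[t, der, cols] / np.maximum(totals[t], 1) for t in range(4)]
            )
            w_abba = (1 - p[0]) * p[1] * p[2] * (1 - p[3])
            w_baba = p[0] * (1 - p[1]) * p[2] * (1 - p[3])
            abba[j] = (w_abba * ok).sum()
            baba[j] = (w_baba * ok).sum()
    return abba, baba


def count_patterns(
    locus_set: LocusSet, test: QuartetTest, mode: str = "sampled", seed: int = 0
) -> tuple[float, float, int]:
    """Total ABBA and BABA weights plus the number of contributing loci."""
    abba, baba = _per_locus_counts(locus_set, test, mode=mode, seed=seed)
    informative = (abba + baba) > 0
    return float(abba.sum()), float(baba.sum()), int(informative.sum())


def bootstrap_d_distribution(
    abba: np.ndarray, baba: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> np.ndarray:
    """Bootstrap distribution of D from per-locus pattern weights.

    Loci are resampled with replacement; replicates whose resampled totals
    are all zero (D undefined) are dropped.
    """
    abba = np.asarray(abba, dtype=float)
    baba = np.asarray(baba, dtype=float)
    n = abba.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    idx = rng.integers(0, n, size=(n_boot, n))
    tot_a = abba[idx].sum(axis=1)
    tot_b = baba[idx].sum(axis=1)
    with np.errstate(invalid="ignore"):
        d_boot = (tot_a - tot_b) / (tot_a + tot_b)
    return d_boot[np.isfinite(d_boot)]


def bootstrap_Z(
    locus_set: LocusSet,
    test: QuartetTest,
    n_boot: int = 1000,
    seed: int = 0,
    mode: str = "sampled",
    counts: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float | None, float | None]:
    """Locus-resampling bootstrap Z-score and two-sided normal p-value.

    Informative loci (those contributing at least one counted site) are
    resampled with replacement ``n_boot`` times and D recomputed from the
    resampled totals; Z = |D_obs| / SD(bootstrap D).  A degenerate
    bootstrap (SD = 0) yields Z = 0 when D_obs = 0 and Z = inf (p = 0)
    otherwise.  Fewer than two informative loci is reported uninformative
    (None, None).
    """
    if counts is None:
        counts = _per_locus_counts(locus_set, test, mode=mode, seed=seed)
    abba, baba = counts
    keep = (abba + baba) > 0
    abba, baba = abba[keep], baba[keep]
    n = abba.size
    if n < 2:
        return None, None
    d_obs = compute_D(float(abba.sum()), float(baba.sum()))
    d_boot = bootstrap_d_distribution(abba, baba, n_boot=n_boot, seed=seed)
    if d_boot.size < 2:
        return None, None
    sd = float(np.std(d_boot, ddof=1))
    if sd == 0.0:
        if d_obs == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    z = abs(d_obs) / sd
    return z, float(2.0 * norm.sf(z))


def permute_individuals(
    p1: tuple[str, list[str]],
    p2: tuple[str, list[str]],
    p3: tuple[str, list[str]],
    o: tuple[str, list[str]],
    cap: int | None = None,
    seed: int = 0,
) -> list[QuartetTest]:
    """All combinations of one individual per taxon (optionally subsampled).

    The full battery is the Cartesian product of single-individual choices
    across the four taxa; with ``cap`` set, a seeded uniform subsample of
    that product is returned (without replacement), preserving order.
    """
    combos = list(
        itertools.product(p1[1], p2[1], p3[1], o[1])
    )
    if cap is not None and cap < len(combos):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
        pick = np.sort(rng.choice(len(combos), size=cap, replace=False))
        combos = [combos[i] for i in pick]
    return [
        QuartetTest(
            (p1[0], (a,)), (p2[0], (b,)), (p3[0], (c,)), (o[0], (d,))
        )
        for a, b, c, d in combos
    ]


def holm_bonferroni(pvalues, alpha: float = 0.01) -> np.ndarray:
    """Holm's sequentially rejective correction; flags in input order.

    Sort ascending and reject p_(i) while p_(i) <= alpha / (m - i + 1),
    stopping at the first failure.  NaN p-values are excluded from m and
    flagged not significant (with a warning).
    """
    p = np.asarray(list(pvalues), dtype=float)
    flags = np.zeros(p.size, dtype=bool)
    valid = ~np.isnan(p)
    if valid.sum() < p.size:
        warnings.warn("NaN p-values excluded from Holm correction", stacklevel=2)
    if p[valid].size and ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(valid.sum())
    if m == 0:
        return flags
    order = np.argsort(p[valid], kind="stable")
    idx_valid = np.flatnonzero(valid)[order]
    for rank, i in enumerate(idx_valid):
        if p[i] <= alpha / (m - rank):
            flags[i] = True
        else:
            break
    return flags


def run_battery(
    locus_set: LocusSet,
    p1: tuple[str, list[str]],
    p2: tuple[str, list[str]],
    p3: tuple[str, list[str]],
    o: tuple[str, list[str]],
    mode: str = "sampled",
    n_boot: int = 1000,
    alpha: float = 0.01,
    cap: int | None = None,
    seed: int = 0,
) -> tuple[BatterySummary, pd.DataFrame]:
    """Permute individuals, run count -> D -> Z per test, correct with Holm.

    The correction family is the battery itself (all permutations of one
    hypothesized event).  Tests with fewer than two informative loci are
    excluded from the summary and from nSig/ntest, and counted separately.
    """
    tests = permute_individuals(p1, p2, p3, o, cap=cap, seed=seed)
    seeds = np.random.SeedSequence([int(seed), 6]).generate_state(len(tests)) % (2**31)
    rows = []
    results: list[DResult] = []
    for test, tseed in zip(tests, seeds):
        abba_v, baba_v = _per_locus_counts(locus_set, test, mode=mode, seed=int(tseed))
        informative = (abba_v + baba_v) > 0
        abba, baba = float(abba_v.sum()), float(baba_v.sum())
        nloci = int(informative.sum())
        d = compute_D(abba, baba)
        z, pval = bootstrap_Z(
            locus_set, test, n_boot=n_boot, seed=int(tseed), mode=mode,
            counts=(abba_v, baba_v),
        )
        results.append(DResult(test, abba, baba, nloci, d, z, pval))
    pvals = [r.p if r.p is not None else np.nan for r in results]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        flags = holm_bonferroni(pvals, alpha=alpha)
    for r, f in zip(results, flags):
        r.significant = bool(f) if r.p is not None else None
    informative_results = [r for r in results if r.informative and r.d is not None]
    n_uninf = len(results) - len(informative_results)
    if informative_results:
        summary = BatterySummary(
            mean_d=float(np.mean([r.d for r in informative_results])),
            mean_abba=float(np.mean([r.abba for r in informative_results])),
            mean_baba=float(np.mean([r.baba for r in informative_results])),
            mean_nloci=float(np.mean([r.nloci for r in informative_results])),
            z_min=float(min(r.z for r in informative_results)),
            z_max=float(max(r.z for r in informative_results)),
            n_sig=int(sum(bool(r.significant) for r in informative_results)),
            n_test=len(informative_results),
            n_uninformative=n_uninf,
        )
    else:
        summary = BatterySummary(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0, n_uninf
        )
    for r in results:
        rows.append(
            {
                "P1": r.test.p1[1][0],
                "P2": r.test.p2[1][0],
                "P3": r.test.p3[1][0],
                "O": r.test.o[1][0],
                "ABBA": r.abba,
                "BABA": r.baba,
                "nloci": r.nloci,
                "D": r.d,
                "Z": r.z,
                "p": r.p,
                "significant": r.significant,
            }
        )
    return summary, pd.DataFrame(rows)


def split_by_geography(
    per_individual_d: pd.DataFrame,
    grouping: dict[str, str],
    individual_column: str = "P2",
    ratio: float = 2.0,
) -> tuple[pd.DataFrame, bool, dict[str, list[str]]]:
    """Per-region D summaries and region-level taxon maps.

    ``per_individual_d`` is a battery result table; each row's D is
    attributed to the individual in ``individual_column``.  Returns the
    per-region mean/variance table, a flag recommending a split (raised
    when the variance of region means exceeds ``ratio`` times the mean
    within-region variance), and region -> individuals maps for re-forming
    taxa.  The decision to split remains the caller's.
    """
    d = per_individual_d.dropna(subset=["D"])
    regions = d[individual_column].map(grouping)
    if regions.isna().any():
        missing = sorted(set(d.loc[regions.isna(), individual_column]))
        raise ValueError(f"individuals without a region: {missing}")
    grouped = d.groupby(regions)["D"]
    stats = grouped.agg(["mean", "var", "count"])
    if (stats["count"] == 0).any():
        raise ValueError("region with no individuals")
    between = float(stats["mean"].var(ddof=0)) if len(stats) > 1 else 0.0
    within = float(stats["var"].fillna(0.0).mean())
    flag = between > ratio * within if within > 0 else (between > 0 and len(stats) > 1)
    maps: dict[str, list[str]] = {}
    for ind, region in grouping.items():
        maps.setdefault(region, []).append(ind)
    return stats, bool(flag), maps
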