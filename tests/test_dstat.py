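"""Patterson's D: pattern definitions, bootstrap enumeration, permutation
batteries, Holm correction and geography splitting."""

import numpy as np
import pandas as pd
import pytest

import radintro as ri
from conftest import locus_set_from_consensus
from oracles import brute_force_holm, brute_force_patterns


def one_ind_test():
    return ri.QuartetTest(
        ("P1", ("P1_1",)), ("P2", ("P2_1",)), ("P3", ("P3_1",)), ("O", ("O_1",))
    )


def site_fixture(a1, a2, a3, ao):
    """Single-locus, single-site LocusSet with homozygous genotypes."""
    return locus_set_from_consensus(
        [{"P1_1": a1, "P2_1": a2, "P3_1": a3, "O_1": ao}]
    )


@pytest.mark.parametrize("mode", ["sampled", "frequency"])
def test_single_site_pattern_definitions(mode):
    abba, baba, nloci = ri.count_patterns(
        site_fixture("G", "T", "T", "G"), one_ind_test(), mode=mode
    )
    assert (abba, baba, nloci) == (1.0, 0.0, 1)
    abba, baba, nloci = ri.count_patterns(
        site_fixture("T", "G", "T", "G"), one_ind_test(), mode=mode
    )
    assert (abba, baba, nloci) == (0.0, 1.0, 1)


@pytest.mark.parametrize("mode", ["sampled", "frequency"])
def test_three_state_site_contributes_nothing(mode):
    abba, baba, nloci = ri.count_patterns(
        site_fixture("A", "C", "G", "G"), one_ind_test(), mode=mode
    )
    assert (abba, baba, nloci) == (0.0, 0.0, 0)


def test_concordant_and_invariant_sites_contribute_nothing():
    for pattern in ("AAAA", "CCAA", "CAAA", "ACAA"):  # BBAA, BAAA, ABAA
        abba, baba, _ = ri.count_patterns(
            site_fixture(*pattern), one_ind_test()
        )
        assert (abba, baba) == (0.0, 0.0)


def test_compute_d_symmetries_and_sentinel():
    assert ri.compute_D(5, 5) == 0.0
    assert ri.compute_D(7, 0) == 1.0
    assert ri.compute_D(0, 7) == -1.0
    assert ri.compute_D(0, 0) is None
    with pytest.raises(ValueError):
        ri.compute_D(-1, 2)


def test_missing_individual_skips_locus():
    ls = locus_set_from_consensus(
        [
            {"P1_1": "G", "P2_1": "T", "P3_1": "T", "O_1": "G"},
            {"P1_1": "G", "P2_1": "T", "P3_1": "T"},  # outgroup absent
        ]
    )
    abba, baba, nloci = ri.count_patterns(ls, one_ind_test())
    assert (abba, baba, nloci) == (1.0, 0.0, 1)


@pytest.mark.parametrize("seed", range(5))
def test_sampled_counts_match_brute_force_on_homozygous_fixtures(seed):
    # one individual per taxon, all genotypes homozygous: the sampled draw
    # is value-deterministic, so exhaustive per-site enumeration must agree
    rng = np.random.default_rng(100 + seed)
    rows, truth = [], []
    for _ in range(12):
        length = int(rng.integers(3, 9))
        row = {}
        sites = []
        for ind in ("P1_1", "P2_1", "P3_1", "O_1"):
            if rng.random() < 0.15:
                continue
            row[ind] = "".join(rng.choice(list("ACGT"), size=length))
        for i in range(length):
            if len(row) < 4:
                sites.append(None)
            else:
                sites.append(tuple(row[ind][i] for ind in ("P1_1", "P2_1", "P3_1", "O_1")))
        rows.append(row)
        truth.append(sites)
    # ragged loci are fine for counting; build per-locus LocusSets and sum
    abba = baba = nloci = 0
    for row in rows:
        ls = locus_set_from_consensus([row], species={
            "P1_1": "P1", "P2_1": "P2", "P3_1": "P3", "O_1": "O"})
        a, b, n = ri.count_patterns(ls, one_ind_test(), seed=seed)
        abba, baba, nloci = abba + a, baba + b, nloci + n
    exp_abba, exp_baba, exp_nloci = brute_force_patterns(truth)
    assert (abba, baba, nloci) == (exp_abba, exp_baba, exp_nloci)


def test_bootstrap_z_from_exact_two_locus_enumeration():
    # loci with (ABBA, BABA) = (2,0) and (0,1): the 4 equiprobable
    # resamples give D in {1, 1/3, -1} with probs {1/4, 1/2, 1/4}
    ls = locus_set_from_consensus(
        [
            {"P1_1": "GG", "P2_1": "TT", "P3_1": "TT", "O_1": "GG"},  # 2 ABBA
            {"P1_1": "TA", "P2_1": "GA", "P3_1": "TA", "O_1": "GA"},  # 1 BABA
        ]
    )
    d_obs = 1 / 3
    resamples = [(4, 0), (2, 1), (2, 1), (0, 2)]
    ds = [(a - b) / (a + b) for a, b in resamples]
    sd_exact = np.std(ds, ddof=0)
    z_exact = d_obs / sd_exact
    z, p = ri.bootstrap_Z(ls, one_ind_test(), n_boot=60_000, seed=1)
    # bootstrap SD estimate converges to the enumeration value
    assert abs(z - z_exact) < 0.02
    assert 0 < p < 1


def test_bootstrap_degenerate_cases():
    # identical (ABBA, BABA) per locus with D_obs = 0 -> Z = 0
    ls = locus_set_from_consensus(
        [
            {"P1_1": "GT", "P2_1": "TG", "P3_1": "TT", "O_1": "GG"},
            {"P1_1": "GT", "P2_1": "TG", "P3_1": "TT", "O_1": "GG"},
        ]
    )
    z, p = ri.bootstrap_Z(ls, one_ind_test(), n_boot=200, seed=0)
    assert z == 0.0 and p == 1.0
    # fewer than two informative loci -> uninformative
    ls1 = site_fixture("G", "T", "T", "G")
    assert ri.bootstrap_Z(ls1, one_ind_test(), n_boot=50, seed=0) == (None, None)


def test_duplicating_every_locus_preserves_d():
    ls = locus_set_from_consensus(
        [
            {"P1_1": "GG", "P2_1": "TT", "P3_1": "TT", "O_1": "GG"},
            {"P1_1": "TA", "P2_1": "GA", "P3_1": "TA", "O_1": "GA"},
        ]
    )
    doubled = ri.LocusSet(
        [l.copy() for l in ls.loci] + [l.copy() for l in ls.loci],
        ls.popmap, ls.locus_length,
    )
    a1, b1, _ = ri.count_patterns(ls, one_ind_test())
    a2, b2, _ = ri.count_patterns(doubled, one_ind_test())
    assert ri.compute_D(a1, b1) == ri.compute_D(a2, b2)


def test_permutation_counts():
    taxa = [
        ("P1", [f"a{i}" for i in range(2)]),
        ("P2", [f"b{i}" for i in range(5)]),
        ("P3", [f"c{i}" for i in range(4)]),
        ("O", [f"d{i}" for i in range(9)]),
    ]
    tests = ri.permute_individuals(*taxa)
    assert len(tests) == 2 * 5 * 4 * 9 == 360
    single = ri.permute_individuals(
        ("P1", ["a"]), ("P2", ["b"]), ("P3", ["c"]), ("O", ["d"])
    )
    assert len(single) == 1
    capped1 = ri.permute_individuals(*taxa, cap=10, seed=3)
    capped2 = ri.permute_individuals(*taxa, cap=10, seed=3)
    assert capped1 == capped2 and len(capped1) == 10


def test_quartet_test_validation():
    with pytest.raises(ValueError, match="share"):
        ri.QuartetTest(("P1", ("x",)), ("P2", ("x",)), ("P3", ("y",)), ("O", ("z",)))
    with pytest.raises(ValueError, match="at least one"):
        ri.QuartetTest(("P1", ()), ("P2", ("x",)), ("P3", ("y",)), ("O", ("z",)))


def test_holm_worked_example_and_edges():
    flags = ri.holm_bonferroni([0.001, 0.02, 0.03], alpha=0.01)
    assert flags.tolist() == [True, False, False]
    assert ri.holm_bonferroni([], alpha=0.01).size == 0
    with pytest.warns(UserWarning, match="NaN"):
        flags = ri.holm_bonferroni([0.001, np.nan], alpha=0.01)
    assert flags.tolist() == [True, False]


@pytest.mark.parametrize("seed", range(8))
def test_holm_matches_independent_references(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 25))
    p = np.round(rng.random(m) ** 2, 4)
    alpha = float(rng.choice([0.01, 0.05, 0.1]))
    got = ri.holm_bonferroni(p, alpha=alpha)
    assert got.tolist() == brute_force_holm(p.tolist(), alpha)
    from statsmodels.stats.multitest import multipletests
    sm = multipletests(p, alpha=alpha, method="holm")[0]
    assert got.tolist() == sm.tolist()


def _het_fixture(rng, n_loci=12):
    """Random loci over 2 individuals per taxon with heterozygotes."""
    rows = []
    for _ in range(n_loci):
        row = {}
        for sp in ("P1", "P2", "P3", "O"):
            for k in (1, 2):
                chars = rng.choice(list("ACGTRYSWKM"), size=6,
                                   p=[0.2] * 4 + [1 / 30] * 6)
                row[f"{sp}_{k}"] = "".join(chars)
        rows.append(row)
    return locus_set_from_consensus(rows)


def test_frequency_mode_antisymmetry_is_exact(rng):
    ls = _het_fixture(rng)
    test = ri.QuartetTest(
        ("P1", ("P1_1", "P1_2")), ("P2", ("P2_1", "P2_2")),
        ("P3", ("P3_1", "P3_2")), ("O", ("O_1", "O_2")),
    )
    a, b, n = ri.count_patterns(ls, test, mode="frequency")
    a2, b2, n2 = ri.count_patterns(ls, test.swapped(), mode="frequency")
    assert a == pytest.approx(b2) and b == pytest.approx(a2) and n == n2
    d = ri.compute_D(a, b)
    d_sw = ri.compute_D(a2, b2)
    assert d == pytest.approx(-d_sw)


def test_battery_swapping_p1_p2_negates_mean_d(rng):
    ls = _het_fixture(rng, n_loci=20)
    taxa = dict(
        p1=("P1", ["P1_1", "P1_2"]), p2=("P2", ["P2_1", "P2_2"]),
        p3=("P3", ["P3_1", "P3_2"]), o=("O", ["O_1", "O_2"]),
    )
    s1, _ = ri.run_battery(ls, mode="frequency", n_boot=50, seed=4, **taxa)
    taxa_sw = dict(taxa, p1=taxa["p2"], p2=taxa["p1"])
    s2, _ = ri.run_battery(ls, mode="frequency", n_boot=50, seed=4, **taxa_sw)
    assert s1.mean_d == pytest.approx(-s2.mean_d)
    assert s1.mean_abba == pytest.approx(s2.mean_baba)


def test_battery_summary_shape_and_correction_family(rng):
    ls = _het_fixture(rng, n_loci=15)
    summary, table = ri.run_battery(
        ls,
        ("P1", ["P1_1", "P1_2"]), ("P2", ["P2_1", "P2_2"]),
        ("P3", ["P3_1", "P3_2"]), ("O", ["O_1", "O_2"]),
        n_boot=50, seed=0,
    )
    assert len(table) == 16
    assert summary.n_test + summary.n_uninformative == 16
    assert summary.n_sig <= summary.n_test
    row = summary.to_row()
    assert set(row) == {"D", "BABA", "ABBA", "nloci", "RangeZ", "nSig/ntest"}


def test_split_by_geography_flags_constructed_contrast():
    d = pd.DataFrame(
        {
            "P2": ["i1", "i2", "i3", "i4"],
            "D": [0.6, 0.62, 0.01, -0.02],
        }
    )
    grouping = {"i1": "north", "i2": "north", "i3": "south", "i4": "south"}
    stats, flag, maps = ri.split_by_geography(d, grouping)
    assert flag
    assert maps == {"north": ["i1", "i2"], "south": ["i3", "i4"]}
    assert stats.loc["north", "mean"] > 0.5 > stats.loc["south", "mean"]


def test_split_by_geography_uniform_d_not_flagged():
    d = pd.DataFrame({"P2": ["i1", "i2", "i3", "i4"],
                      "D": [0.30, 0.31, 0.30, 0.29]})
    grouping = {"i1": "n", "i2": "n", "i3": "s", "i4": "s"}
    _, flag, _ = ri.split_by_geography(d, grouping)
    assert not flag


def test_split_by_geography_identity_grouping_preserves_individuals():
    d = pd.DataFrame({"P2": ["i1", "i2"], "D": [0.1, 0.2]})
    grouping = {"i1": "i1", "i2": "i2"}
    _, _, maps = ri.split_by_geography(d, grouping)
    assert maps == {"i1": ["i1"], "i2": ["i2"]}
    with pytest.raises(ValueError, match="region"):
        ri.split_by_geography(d, {"i1": "r"})
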