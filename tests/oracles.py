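"""Independent brute-force reference implementations used only by tests.

Everything here is written against the plain-string/loop view of the data,
deliberately sharing no code with the package internals it checks.
"""

from __future__ import annotations


IUPAC = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
}


def genotype(cons: str, i: int) -> str | None:
    ch = cons[i].upper()
    return IUPAC.get(ch)


def brute_force_filter(loci_rows, n_panel, cfg) -> list[int]:
    """Indices of surviving loci; loci_rows = [{ind: consensus}, ...]."""
    survivors = list(range(len(loci_rows)))

    def het_count(cons):
        return sum(1 for i in range(len(cons))
                   if genotype(cons, i) and genotype(cons, i)[0] != genotype(cons, i)[1])

    def max_site_het(row):
        length = len(next(iter(row.values())))
        worst = 0.0
        for i in range(length):
            het = tot = 0
            for cons in row.values():
                g = genotype(cons, i)
                if g is None:
                    continue
                tot += 1
                het += g[0] != g[1]
            if tot:
                worst = max(worst, het / tot)
        return worst

    def n_poly(row):
        length = len(next(iter(row.values())))
        count = 0
        for i in range(length):
            alleles = set()
            for cons in row.values():
                g = genotype(cons, i)
                if g:
                    alleles.update(g)
            if len(alleles) >= 2:
                count += 1
        return count

    def has_indel(row):
        return any("-" in cons for cons in row.values())

    survivors = [j for j in survivors
                 if all(het_count(c) <= cfg.max_het_sites_per_consensus
                        for c in loci_rows[j].values())]
    survivors = [j for j in survivors
                 if max_site_het(loci_rows[j]) <= cfg.max_site_heterozygosity]
    survivors = [j for j in survivors
                 if n_poly(loci_rows[j]) >= cfg.min_polymorphic_sites]
    if cfg.drop_indel_loci:
        survivors = [j for j in survivors if not has_indel(loci_rows[j])]
    survivors = [j for j in survivors
                 if len(loci_rows[j]) / n_panel
                 >= cfg.min_individual_fraction_per_locus]
    return survivors


def brute_force_patterns(loci_alleles) -> tuple[int, int, int]:
    """ABBA/BABA/nloci from per-locus lists of (a1, a2, a3, ao) site tuples
    of single called bases (uppercase ACGT) or None for missing."""
    abba = baba = nloci = 0
    for sites in loci_alleles:
        la = lb = 0
        for site in sites:
            if site is None or any(x is None for x in site):
                continue
            a1, a2, a3, ao = site
            if a1 == ao and a2 == a3 and a2 != ao:
                la += 1
            elif a2 == ao and a1 == a3 and a1 != ao:
                lb += 1
        abba += la
        baba += lb
        nloci += (la + lb) > 0
    return abba, baba, nloci


def brute_force_holm(pvalues, alpha):
    """Reject set of Holm's procedure via explicit re-testing."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    flags = [False] * m
    for rank, i in enumerate(order):
        if pvalues[i] <= alpha / (m - rank):
            flags[i] = True
        else:
            break
    return flags


def brute_force_p_distance(s1: str, s2: str) -> float:
    diff = comp = 0.0
    for c1, c2 in zip(s1.upper(), s2.upper()):
        if c1 in "N-" or c2 in "N-":
            continue
        set1, set2 = set(IUPAC[c1]), set(IUPAC[c2])
        comp += 1
        if set1 == set2:
            pass
        elif set1 & set2:
            diff += 0.5
        else:
            diff += 1.0
    if comp == 0:
        raise ValueError("no comparable sites")
    return diff / comp


def newick_bipartitions(newick: str) -> set[frozenset]:
    """All non-trivial splits of an unrooted newick (brute parse)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(taxa) - 1:
            out.add(min(side, taxa - side, key=lambda s: (len(s), sorted(s))))
    return out


def brute_force_rf(nwk_a: str, nwk_b: str) -> int:
    return len(newick_bipartitions(nwk_a) ^ newick_bipartitions(nwk_b))


def all_quartet_topologies(a, b, c, d):
    return [
        frozenset((frozenset((a, b)), frozenset((c, d)))),
        frozenset((frozenset((a, c)), frozenset((b, d)))),
        frozenset((frozenset((a, d)), frozenset((b, c)))),
    ]
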