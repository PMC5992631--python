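"""Distance / quartet species-tree inference and tree comparison.

Concatenation-based inference here is neighbor joining on uncorrected
(p-) distances, and coalescent-aware inference is dominant-quartet
assembly over per-locus (or per-bin) gene trees.  Both are deliberately
simple, fully deterministic engines: the scientific contrast of interest
is between the two inference *families* — concatenation, which pools all
sites into one signal, versus quartet-based multispecies-coalescent
assembly, which lets each locus vote — not between likelihood engines.

Trees cross the public API as :class:`dendropy.Tree`; internally a light
(label | tuple) nested representation keeps per-bin inference fast.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np

from .alphabet import masks_from_string
from .loci import LocusSet

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "neighbor_joining",
    "nj_newick",
    "bootstrap_support",
    "quartet_species_tree",
    "rf_distance",
    "concat_alignment",
    "concat_tree",
    "tree_bipartitions",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    n_sites: np.ndarray  # comparable sites per pair

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix must have a zero diagonal")


# -- p-distance ----------------------------------------------------------

# pair score on IUPAC bitmasks: identical sets 0, disjoint 1, overlapping 0.5
_SCORE = np.zeros((16, 16))
_COMPARABLE = np.zeros((16, 16), dtype=bool)
for _a in range(1, 16):
    for _b in range(1, 16):
        _COMPARABLE[_a, _b] = True
        if _a == _b:
            _SCORE[_a, _b] = 0.0
        elif _a & _b:
            _SCORE[_a, _b] = 0.5
        else:
            _SCORE[_a, _b] = 1.0


def p_distance(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise proportion of differing comparable sites.

    Sequences may carry two-base IUPAC ambiguity codes (diploid consensus
    rows); a heterozygote against a matching homozygote counts as half a
    difference.  'N' and gaps are excluded pairwise; a pair with no
    comparable site at all is an error.
    """
    labels = list(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    masks = [masks_from_string(alignment[lab]) for lab in labels]
    L = {m.size for m in masks}
    if len(L) != 1:
        raise ValueError("sequences differ in length")
    n = len(labels)
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            comp = _COMPARABLE[masks[i], masks[j]]
            nc = int(comp.sum())
            if nc == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            diff = _SCORE[masks[i], masks[j]][comp].sum()
            d[i, j] = d[j, i] = diff / nc
            counts[i, j] = counts[j, i] = nc
    return DistanceMatrix(labels, d, counts)


# -- neighbor joining ----------------------------------------------------


def _nj_nested(labels: list[str], dist: np.ndarray):
    """Classical NJ; returns a nested (child, branch-length) structure.

    Ties on the Q-criterion break toward the lexicographically smallest
    (cluster-representative) label pair; negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [(lab,) for lab in labels]  # (payload,) leaf or (children-list,)
    reps = list(labels)  # smallest leaf label per cluster, for tie-breaks
    d = dist.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i, j] - sums[i] - sums[j]
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or q < best[0] - 1e-12 or (
                abs(q - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new = ([(nodes[i], li), (nodes[j], lj)],)
        d_new = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            d_new[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : d_new.size] = d_new
        d[: d_new.size, -1] = d_new
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    if len(active) == 2:
        i, j = active
        li = lj = 0.5 * d[i, j]
        return ([(nodes[i], li), (nodes[j], lj)],)
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return (
        [
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ],
    )


def _nested_newick(node, length: float | None = None) -> str:
    payload = node[0]
    if isinstance(payload, str):
        body = payload
    else:
        body = "(" + ",".join(_nested_newick(c, l) for c, l in payload) + ")"
    return body if length is None else f"{body}:{length:.8g}"


def _nested_bipartitions(node, all_taxa: frozenset) -> set[frozenset]:
    """Non-trivial splits, each canonicalized as its smaller/sorted side."""
    out: set[frozenset] = set()

    def tips(nd) -> frozenset:
        payload = nd[0]
        if isinstance(payload, str):
            return frozenset((payload,))
        below = frozenset()
        for c, _ in payload:
            t = tips(c)
            if 1 < len(t) < len(all_taxa) - 1:
                out.add(_canon_split(t, all_taxa))
            below |= t
        return below

    tips(node)
    return out


def _canon_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    other = all_taxa - side
    a, b = sorted((side, other), key=lambda s: (len(s), sorted(s)))
    return a


def nj_newick(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as an (unrooted) Newick string."""
    return _nested_newick(_nj_nested(dm.labels, dm.d)) + ";"


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree as a dendropy Tree (unrooted)."""
    tree = dendropy.Tree.get(data=nj_newick(dm), schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


# -- tree utilities ------------------------------------------------------


def tree_bipartitions(tree) -> set[frozenset]:
    """Non-trivial unrooted splits of a tree (dendropy or nested tuple),
    each encoded as its canonical (smaller, sorted-tiebreak) taxon side."""
    if isinstance(tree, tuple):
        all_taxa = frozenset(_nested_tips(tree))
        return _nested_bipartitions(tree, all_taxa)
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            out.add(_canon_split(side, labels))
    return out


def _nested_tips(node) -> list[str]:
    payload = node[0]
    if isinstance(payload, str):
        return [payload]
    return [t for c, _ in payload for t in _nested_tips(c)]


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Robinson-Foulds (symmetric bipartition difference) count."""
    la = {lf.taxon.label for lf in a.leaf_node_iter()}
    lb = {lf.taxon.label for lf in b.leaf_node_iter()}
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    sa, sb = tree_bipartitions(a), tree_bipartitions(b)
    return len(sa ^ sb)


# -- quartet species tree ------------------------------------------------


def _quartet_resolution_from_splits(
    splits: set[frozenset], all_taxa: frozenset, quartet: tuple[str, ...]
) -> frozenset | None:
    qs = frozenset(quartet)
    for split in splits:
        side = split & qs
        if len(side) == 2:  # 2-2 separation; unique in any one tree
            return frozenset((side, qs - side))
    return None


@lru_cache(maxsize=8)
def _enumerate_topologies(taxa: tuple[str, ...]):
    """All unrooted binary topologies on the given taxa, as split-sets."""
    if len(taxa) < 4:
        return [((tuple(taxa)), frozenset())]

    def insert(node, leaf):
        """All subtrees from grafting `leaf` onto an edge in `node`,
        including the edge directly above `node`."""
        results = [(node, leaf)]
        if not isinstance(node, str):
            for idx, child in enumerate(node):
                for newchild in insert(child, leaf):
                    results.append(
                        tuple(newchild if k == idx else c for k, c in enumerate(node))
                    )
        return results

    trees = [(taxa[0], taxa[1], taxa[2])]  # unrooted star; root is trifurcating
    for leaf in taxa[3:]:
        nxt = []
        for tr in trees:
            for idx, child in enumerate(tr):
                for newchild in insert(child, leaf):
                    nxt.append(
                        tuple(newchild if k == idx else c for k, c in enumerate(tr))
                    )
        trees = nxt
    all_taxa = frozenset(taxa)
    return [(tr, _splits_of_unrooted(tr, all_taxa)) for tr in trees]


def _splits_of_unrooted(tree, all_taxa: frozenset) -> set[frozenset]:
    out: set[frozenset] = set()

    def tips(node) -> frozenset:
        if isinstance(node, str):
            return frozenset((node,))
        below = frozenset()
        for child in node:
            t = tips(child)
            if 1 < len(t) < len(all_taxa) - 1:
                out.add(_canon_split(t, all_taxa))
            below |= t
        return below

    tips(tree)
    return out


def _unrooted_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(_unrooted_newick(c) for c in tree) + ")"


def quartet_species_tree(
    gene_trees,
    taxa_map: dict[str, str] | None = None,
    outgroup: str | None = None,
    return_details: bool = False,
):
    """Assemble a species tree from dominant quartet resolutions.

    For every quartet of species, the induced resolution is tallied across
    gene trees (tips are mapped to species through ``taxa_map``; each tree
    must carry at most one tip per species).  The species tree is the
    topology satisfying the largest number of dominant quartets, found
    exhaustively for up to 8 species and by greedy pair-joining beyond.
    Edge support is the mean frequency (percent) of the tree's own induced
    resolution over the quartets spanning that edge.

    Gene trees may be dendropy Trees, Newick strings, or internal nested
    structures.  Quartets with zero informative gene trees are excluded
    (with a warning).  Returns a dendropy Tree with integer support labels
    on internal nodes; with ``return_details`` also the per-quartet tally.
    """
    split_sets = []
    for gt in gene_trees:
        if isinstance(gt, str):
            gt = dendropy.Tree.get(data=gt, schema="newick", preserve_underscores=True)
        if isinstance(gt, dendropy.Tree):
            labels = [lf.taxon.label for lf in gt.leaf_node_iter()]
            mapped = {
                lab: (taxa_map.get(lab, lab) if taxa_map else lab) for lab in labels
            }
            if len(set(mapped.values())) != len(mapped):
                raise ValueError("gene tree has multiple tips for one species")
            splits = {
                frozenset(mapped[t] for t in side)
                for side in tree_bipartitions(gt)
            }
            all_sp = frozenset(mapped.values())
        else:  # nested tuple with (payload,) convention from NJ
            tips = _nested_tips(gt)
            mapped = {
                lab: (taxa_map.get(lab, lab) if taxa_map else lab) for lab in tips
            }
            splits = {
                frozenset(mapped[t] for t in side)
                for side in tree_bipartitions(gt)
            }
            all_sp = frozenset(mapped.values())
        split_sets.append((splits, all_sp))

    species = sorted({s for _, sp in split_sets for s in sp})
    if len(species) < 4:
        raise ValueError("need at least four species")
    tallies: dict[tuple[str, ...], dict[frozenset, int]] = {}
    for quartet in itertools.combinations(species, 4):
        tally: dict[frozenset, int] = {}
        for splits, all_sp in split_sets:
            if not frozenset(quartet) <= all_sp:
                continue
            res = _quartet_resolution_from_splits(splits, all_sp, quartet)
            if res is not None:
                tally[res] = tally.get(res, 0) + 1
        if tally:
            tallies[quartet] = tally
        else:
            warnings.warn(
                f"quartet {quartet} has no informative gene tree", stacklevel=2
            )

    dominant = {
        q: max(t.items(), key=lambda kv: (kv[1], sorted(sorted(p) for p in kv[0])))[0]
        for q, t in tallies.items()
    }

    if len(species) <= 8:
        best = None
        for tr, splits in _enumerate_topologies(tuple(species)):
            score = 0
            for q, dom in dominant.items():
                res = _quartet_resolution_from_splits(splits, frozenset(species), q)
                if res == dom:
                    score += 1
            if best is None or score > best[0]:
                best = (score, tr, splits)
        _, topo, topo_splits = best
    else:
        topo, topo_splits = _greedy_join(species, dominant)

    # per-edge support: mean induced-resolution frequency over spanning quartets
    support: dict[frozenset, float] = {}
    all_sp = frozenset(species)
    for split in topo_splits:
        vals = []
        for q, tally in tallies.items():
            res = _quartet_resolution_from_splits({split}, all_sp, q)
            if res is None:
                continue
            total = sum(tally.values())
            vals.append(100.0 * tally.get(res, 0) / total)
        support[split] = float(np.mean(vals)) if vals else 0.0

    newick = _unrooted_newick(topo) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _canon_split(side, all_sp)
        if key in support:
            node.label = str(int(round(support[key])))
    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        tree.to_outgroup_position(og, update_bipartitions=False)
    if return_details:
        return tree, {"tallies": tallies, "dominant": dominant, "support": support}
    return tree


def _greedy_join(species: list[str], dominant: dict) -> tuple:
    """Greedy pair-joining fallback for more than eight species: repeatedly
    merge the cluster pair most often placed together by dominant quartets."""
    clusters: dict[str, tuple] = {s: s for s in species}

    def votes(a: str, b: str) -> int:
        v = 0
        for q, dom in dominant.items():
            qa = [x for x in q if _member(clusters, a, x)]
            qb = [x for x in q if _member(clusters, b, x)]
            if len(qa) == 1 and len(qb) == 1:
                pair = frozenset((qa[0], qb[0]))
                if pair in dom:
                    v += 1
        return v

    keys = sorted(clusters)
    while len(keys) > 3:
        best = None
        for a, b in itertools.combinations(keys, 2):
            v = votes(a, b)
            if best is None or v > best[0]:
                best = (v, a, b)
        _, a, b = best
        clusters[a] = (clusters[a], clusters[b])
        del clusters[b]
        keys = sorted(clusters)
    topo = tuple(clusters[k] for k in keys)
    return topo, _splits_of_unrooted(topo, frozenset(species))


def _member(clusters: dict, key: str, taxon: str) -> bool:
    def walk(node) -> bool:
        if isinstance(node, str):
            return node == taxon
        return any(walk(c) for c in node)

    return walk(clusters[key])


# -- concatenation pipeline ----------------------------------------------


def concat_alignment(locus_set: LocusSet) -> tuple[dict[str, str], list[int]]:
    """Concatenated diploid-consensus alignment and locus boundary offsets.

    Rows are individuals; an individual missing a locus is N-filled there.
    Boundaries list the start of each locus (plus the total length).
    """
    inds = locus_set.individuals
    parts: dict[str, list[str]] = {ind: [] for ind in inds}
    boundaries = [0]
    for locus in locus_set.loci:
        L = locus.length
        for ind in inds:
            if ind in locus.seqs:
                parts[ind].append(locus.consensus(ind))
            else:
                parts[ind].append("N" * L)
        boundaries.append(boundaries[-1] + L)
    return {ind: "".join(parts[ind]) for ind in inds}, boundaries


def concat_tree(locus_set: LocusSet) -> dendropy.Tree:
    """Concatenation pipeline: NJ on p-distances of the pooled alignment."""
    aln, _ = concat_alignment(locus_set)
    return neighbor_joining(p_distance(aln))


def bootstrap_support(
    locus_set: LocusSet,
    n_reps: int = 100,
    unit: str = "site",
    seed: int = 0,
) -> dendropy.Tree:
    """Concatenation tree with bootstrap support percentages.

    Resamples alignment columns (``unit='site'``) or whole loci
    (``unit='locus'``, gene resampling) with replacement, re-infers the NJ
    tree, and labels each internal node of the full-data tree with the
    percentage of replicates containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if unit not in ("site", "locus"):
        raise ValueError("unit must be 'site' or 'locus'")
    aln, boundaries = concat_alignment(locus_set)
    labels = list(aln)
    mat = np.stack([masks_from_string(aln[lab]) for lab in labels])
    all_taxa = frozenset(labels)
    base_nested = _nj_nested(*_dm_from_masks(labels, mat))
    base_splits = _nested_bipartitions(base_nested, all_taxa)
    counts = {s: 0 for s in base_splits}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    L = mat.shape[1]
    n_loci = len(boundaries) - 1
    for _ in range(n_reps):
        if unit == "site":
            cols = rng.integers(0, L, size=L)
        else:
            picks = rng.integers(0, n_loci, size=n_loci)
            cols = np.concatenate(
                [np.arange(boundaries[k], boundaries[k + 1]) for k in picks]
            )
        sub = mat[:, cols]
        try:
            nested = _nj_nested(*_dm_from_masks(labels, sub))
        except ValueError:
            continue
        splits = _nested_bipartitions(nested, all_taxa)
        for s in base_splits:
            if s in splits:
                counts[s] += 1
    tree = dendropy.Tree.get(data=_nested_newick(base_nested) + ";", schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = _canon_split(side, all_taxa)
        if key in counts:
            node.label = str(int(round(100.0 * counts[key] / n_reps)))
    return tree


def _dm_from_masks(labels: list[str], mat: np.ndarray) -> tuple[list[str], np.ndarray]:
    """(labels, distance matrix) from stacked IUPAC bitmask rows."""
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = _COMPARABLE[mat[i], mat[j]]
            nc = int(comp.sum())
            if nc == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = _SCORE[mat[i], mat[j]][comp].sum() / nc
    return labels, d
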