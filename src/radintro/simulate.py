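"""Multispecies-coalescent simulation of ddRAD-style loci.

The generator produces, per locus, an independent gene tree under the
multispecies coalescent on a user-declared species tree, optionally
perturbed by instantaneous admixture pulses; evolves short (87 bp by
default) sequences along each gene tree under Jukes-Cantor; and overlays
restriction-site-style missingness (uniform per-individual dropout plus a
divergence-correlated component).

Time is measured in coalescent units (2N generations) throughout, with any
per-branch population-size variation absorbed into branch durations.
Within a species branch, every pair of lineages coalesces at rate 1.  At an
admixture pulse from a donor branch into a recipient branch at time ``t``
(before present), each lineage present in the recipient at ``t``
independently reassigns to the donor with probability ``gamma`` — the
backward-in-time view of a discrete introgression event.  A gene tree is
flagged introgressed when at least one of its lineages took the donor path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alphabet import GAP
from .loci import Locus, LocusSet, PopulationMap, Truth

__all__ = [
    "AdmixturePulse",
    "SpeciesTreeModel",
    "GeneTree",
    "simulate_gene_trees",
    "simulate_sequences",
    "apply_missingness",
    "simulate_dataset",
]


@dataclass(frozen=True)
class AdmixturePulse:
    """Instantaneous gene flow: recipient lineages trace through the donor.

    ``time`` is in coalescent units before present; ``gamma`` is the
    probability that a lineage sampled from the recipient branch at the
    pulse time has its ancestry in the donor branch.
    """

    donor: str
    recipient: str
    time: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"pulse {self.donor}->{self.recipient}: gamma must be in [0, 1]")
        if self.donor == self.recipient:
            raise ValueError(f"pulse at t={self.time}: donor and recipient are both {self.donor}")


class _SNode:
    """Species-tree node; its branch spans [height, parent_height)."""

    __slots__ = ("name", "children", "parent", "height", "parent_height")

    def __init__(self, name):
        self.name = name
        self.children: list[_SNode] = []
        self.parent: _SNode | None = None
        self.height = 0.0
        self.parent_height = np.inf


class SpeciesTreeModel:
    """Rooted species tree with branch durations, pulses and sample sizes.

    Built from a Newick string whose branch lengths are durations in
    coalescent units; leaves must be contemporaneous (the tree must be
    ultrametric).  Internal branches are addressable by the '+'-joined
    sorted labels of their descendant species (e.g. ``"A+B"``).
    """

    def __init__(
        self,
        newick: str,
        samples_per_species: int | dict[str, int] = 1,
        pulses: list[AdmixturePulse] | None = None,
    ):
        self.newick_source = newick
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        self.nodes: dict[str, _SNode] = {}
        self.root = self._build(tree.seed_node)
        self._finalize_heights()
        self.species = sorted(n.name for n in self.nodes.values() if not n.children)
        if isinstance(samples_per_species, int):
            samples_per_species = {s: samples_per_species for s in self.species}
        missing = set(self.species) - set(samples_per_species)
        if missing:
            raise ValueError(f"no sample count for species {sorted(missing)}")
        self.samples_per_species = dict(samples_per_species)
        self.pulses = list(pulses or [])
        for p in self.pulses:
            self._validate_pulse(p)

    def _build(self, dnode) -> _SNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            if not name:
                raise ValueError("unlabeled leaf in species tree")
            node = _SNode(name)
        else:
            children = [self._build(c) for c in dnode.child_nodes()]
            tips = sorted(t for c in children for t in _tips_below(c))
            node = _SNode("+".join(tips))
            node.children = children
            for c in children:
                c.parent = node
        # stash the edge duration on parent_height temporarily
        node.parent_height = dnode.edge.length if dnode.edge.length is not None else None
        if node.name in self.nodes:
            raise ValueError(f"duplicate branch name {node.name!r}")
        self.nodes[node.name] = node
        return node

    def _finalize_heights(self) -> None:
        # heights bottom-up from edge durations; leaves at 0
        def set_height(node: _SNode) -> float:
            if not node.children:
                node.height = 0.0
                return 0.0
            tops = []
            for c in children_sorted(node):
                h = set_height(c)
                dur = c.parent_height  # stashed duration
                if dur is None or dur <= 0:
                    raise ValueError(f"branch {c.name!r}: duration must be > 0")
                tops.append(h + dur)
            if max(tops) - min(tops) > 1e-9 * max(1.0, max(tops)):
                raise ValueError(
                    f"species tree is not ultrametric at node {node.name!r}: "
                    f"child branch tops {tops}"
                )
            node.height = tops[0]
            return node.height

        def children_sorted(node: _SNode) -> list[_SNode]:
            return sorted(node.children, key=lambda c: c.name)

        set_height(self.root)
        for node in self.nodes.values():
            node.parent_height = node.parent.height if node.parent else np.inf

    def _validate_pulse(self, p: AdmixturePulse) -> None:
        for role, name in (("donor", p.donor), ("recipient", p.recipient)):
            if name not in self.nodes:
                raise ValueError(f"pulse {p.donor}->{p.recipient} at t={p.time}: unknown {role} branch {name!r}")
            node = self.nodes[name]
            if not node.height < p.time < node.parent_height:
                raise ValueError(
                    f"pulse {p.donor}->{p.recipient} at t={p.time}: time outside "
                    f"{role} branch interval [{node.height}, {node.parent_height})"
                )

    # -- queries ---------------------------------------------------------

    def individuals(self) -> list[str]:
        out = []
        for s in self.species:
            out.extend(f"{s}_{i}" for i in range(1, self.samples_per_species[s] + 1))
        return out

    def popmap(self) -> PopulationMap:
        return PopulationMap.from_pairs(
            {ind: ind.rsplit("_", 1)[0] for ind in self.individuals()}
        )

    def mrca_height(self, species_a: str, species_b: str) -> float:
        if species_a == species_b:
            return 0.0
        node = self.nodes[species_a]
        ancestors = set()
        while node is not None:
            ancestors.add(node.name)
            node = node.parent
        node = self.nodes[species_b]
        while node.name not in ancestors:
            node = node.parent
        return node.height

    def distance(self, species_a: str, species_b: str) -> float:
        """Path length (in coalescent time units) between two species."""
        return 2.0 * self.mrca_height(species_a, species_b)

    def newick(self) -> str:
        def rec(node: _SNode) -> str:
            if not node.children:
                label = node.name
            else:
                label = "(" + ",".join(rec(c) for c in sorted(node.children, key=lambda c: c.name)) + ")"
            if node.parent is not None:
                label += f":{node.parent_height - node.height:g}"
            return label

        return rec(self.root) + ";"


def _tips_below(node: _SNode) -> list[str]:
    if not node.children:
        return [node.name]
    return [t for c in node.children for t in _tips_below(c)]


# -- gene trees ----------------------------------------------------------


class GNode:
    __slots__ = ("time", "children", "parent", "label")

    def __init__(self, time: float, label: str | None = None, children=None):
        self.time = time
        self.label = label
        self.children = children or []
        self.parent: GNode | None = None
        for c in self.children:
            c.parent = self


@dataclass
class GeneTree:
    """Per-locus genealogy over haploid lineage labels ('<ind>.a'/'<ind>.b')."""

    root: GNode
    introgressed: bool = False

    def tips(self) -> list[GNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            if n.children:
                stack.extend(n.children)
            else:
                out.append(n)
        return out

    def tip_labels(self) -> list[str]:
        return sorted(t.label for t in self.tips())

    def newick(self) -> str:
        def rec(n: GNode) -> str:
            if not n.children:
                body = n.label
            else:
                body = "(" + ",".join(rec(c) for c in n.children) + ")"
            bl = (n.parent.time - n.time) if n.parent else None
            return body if bl is None else f"{body}:{bl:.6g}"

        return rec(self.root) + ";"

    def tmrca(self, label_a: str, label_b: str) -> float:
        nodes = {t.label: t for t in self.tips()}
        chain = {}
        n = nodes[label_a]
        while n is not None:
            chain[id(n)] = n.time
            n = n.parent
        n = nodes[label_b]
        while id(n) not in chain:
            n = n.parent
        return n.time

    def quartet_resolution(self, a: str, b: str, c: str, d: str) -> frozenset:
        """Induced unrooted resolution of four tips, as a pair of pairs.

        The pair with the smallest TMRCA among the four lineages forms a
        cherry of the induced quartet, which fixes the resolution.
        """
        tips = (a, b, c, d)
        best = None
        for x, y in itertools.combinations(tips, 2):
            t = self.tmrca(x, y)
            if best is None or t < best[0]:
                best = (t, x, y)
        _, x, y = best
        other = frozenset(t for t in tips if t not in (x, y))
        return frozenset((frozenset((x, y)), other))


def _coalesce(pop: list[GNode], t0: float, t1: float, rng) -> float:
    """Pairwise-rate-1 coalescent within one population from t0 to t1."""
    t = t0
    while len(pop) >= 2:
        k = len(pop)
        dt = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t + dt >= t1:
            return t1
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = GNode(t, children=[pop[i], pop[j]])
        pop[i] = parent
        del pop[j]
    return t1


def simulate_gene_trees(
    model: SpeciesTreeModel, n_loci: int, seed: int
) -> list[GeneTree]:
    """One independent MSC gene tree per locus (with pulse admixture).

    Seeding: per-locus RNG streams are spawned deterministically from the
    master seed, so outputs are reproducible and independent across loci.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    streams = np.random.SeedSequence([int(seed), 0]).spawn(n_loci)
    merge_events = sorted(
        ((n.height, n.name) for n in model.nodes.values() if n.children),
        key=lambda x: (x[0], x[1]),
    )
    pulse_events = sorted(
        ((p.time, p) for p in model.pulses), key=lambda x: (x[0], x[1].recipient)
    )
    events: list[tuple[float, int, object]] = [
        (t, 1, name) for t, name in merge_events
    ] + [(t, 0, p) for t, p in pulse_events]
    events.sort(key=lambda e: (e[0], e[1]))

    out = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        pops: dict[str, list[GNode]] = {}
        for s in model.species:
            tips = []
            for i in range(1, model.samples_per_species[s] + 1):
                tips.append(GNode(0.0, label=f"{s}_{i}.a"))
                tips.append(GNode(0.0, label=f"{s}_{i}.b"))
            pops[s] = tips
        t_now = 0.0
        introgressed = False
        for t_ev, kind, payload in events:
            for name in sorted(pops):
                _coalesce(pops[name], t_now, t_ev, rng)
            t_now = t_ev
            if kind == 1:  # species-tree merge into branch `payload`
                node = model.nodes[payload]
                merged: list[GNode] = []
                for c in sorted(node.children, key=lambda c: c.name):
                    merged.extend(pops.pop(c.name, []))
                pops[payload] = merged
            else:  # admixture pulse
                p: AdmixturePulse = payload
                recipient = pops.get(p.recipient, [])
                moved = []
                for lin in list(recipient):
                    if rng.random() < p.gamma:
                        moved.append(lin)
                        recipient.remove(lin)
                if moved:
                    introgressed = True
                    pops.setdefault(p.donor, []).extend(moved)
        (root_pop,) = pops.values()
        t = t_now
        while len(root_pop) > 1:
            k = len(root_pop)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i, j = rng.choice(k, size=2, replace=False)
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            parent = GNode(t, children=[root_pop[i], root_pop[j]])
            root_pop[i] = parent
            del root_pop[j]
        out.append(GeneTree(root_pop[0], introgressed))
    return out


# -- sequences -----------------------------------------------------------


def _evolve_tree(tree: GeneTree, length: int, theta: float, rng) -> dict[str, np.ndarray]:
    """Jukes-Cantor evolution along one gene tree; returns tip sequences.

    ``theta`` is the expected number of substitutions per site per
    coalescent time unit, so a branch of duration t changes each site with
    probability (3/4)(1 - exp(-4*theta*t/3)).
    """
    root_seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    tips: dict[str, np.ndarray] = {}
    stack: list[tuple[GNode, np.ndarray]] = [(tree.root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if not node.children:
            tips[node.label] = seq
            continue
        for child in node.children:
            dt = node.time - child.time
            p_change = 0.75 * (1.0 - np.exp(-4.0 * theta * dt / 3.0))
            change = rng.random(length) < p_change
            child_seq = seq.copy()
            n_ch = int(change.sum())
            if n_ch:
                child_seq[change] = (
                    child_seq[change] + rng.integers(1, 4, size=n_ch, dtype=np.uint8)
                ) % 4
            stack.append((child, child_seq))
    return tips


def _apply_indels(tree: GeneTree, seqs: dict[str, np.ndarray], rate: float, rng) -> None:
    """Single-column gap events: each event gaps one random column in the
    clade below one random internal edge (exercises the indel filter)."""
    n_events = rng.poisson(rate)
    if n_events == 0:
        return
    nodes = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        if n is not tree.root:
            nodes.append(n)
        stack.extend(n.children)
    nodes.sort(key=lambda n: (n.time, n.label or ""))
    length = len(next(iter(seqs.values())))
    for _ in range(n_events):
        col = int(rng.integers(length))
        node = nodes[int(rng.integers(len(nodes)))]
        sub = [node]
        while sub:
            n = sub.pop()
            if n.children:
                sub.extend(n.children)
            else:
                seqs[n.label][col] = GAP


def simulate_sequences(
    trees: list[GeneTree],
    locus_length: int = 87,
    theta: float = 0.01,
    seed: int = 0,
    indel_rate: float = 0.0,
    model: SpeciesTreeModel | None = None,
) -> LocusSet:
    """Evolve one alignment per gene tree; assemble diploid individuals.

    Tip labels '<species>_<i>.a'/'.b' pair into diploid individuals, and
    heterozygous sites arise wherever an individual's two haplotypes
    differ.  Base composition at the root is uniform (JC stationarity).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    streams = np.random.SeedSequence([int(seed), 1]).spawn(len(trees))
    loci = []
    all_inds: dict[str, None] = {}
    for tree, stream in zip(trees, streams):
        rng = np.random.default_rng(stream)
        tip_seqs = _evolve_tree(tree, locus_length, theta, rng)
        if indel_rate > 0:
            _apply_indels(tree, tip_seqs, indel_rate, rng)
        by_ind: dict[str, np.ndarray] = {}
        for label in sorted(tip_seqs):
            ind, hap = label.rsplit(".", 1)
            all_inds.setdefault(ind, None)
            if ind not in by_ind:
                by_ind[ind] = np.empty((2, locus_length), dtype=np.uint8)
            by_ind[ind][0 if hap == "a" else 1] = tip_seqs[label]
        loci.append(Locus(by_ind))
    if model is not None:
        popmap = model.popmap()
    else:
        popmap = PopulationMap.from_pairs(
            {ind: ind.rsplit("_", 1)[0] for ind in sorted(all_inds)}
        )
    truth = Truth(model=model, gene_trees=list(trees))
    return LocusSet(loci, popmap, locus_length, truth)


def apply_missingness(
    locus_set: LocusSet,
    dropout_per_individual: float = 0.0,
    divergence_dropout_rate: float = 0.0,
    reference_individual: str | None = None,
    seed: int = 0,
) -> LocusSet:
    """Drop (individual, locus) cells to emulate restriction-site loss.

    Each cell survives with probability
    ``(1 - dropout_per_individual) * exp(-divergence_dropout_rate * d)``
    where ``d`` is the true-tree path distance between the individual and
    the reference individual at that locus (gene-tree distance when the
    ground truth carries gene trees, species-tree distance otherwise).
    The realized dropout mask is recorded in the output's truth block.
    """
    if not 0.0 <= dropout_per_individual <= 1.0:
        raise ValueError("dropout_per_individual must be in [0, 1]")
    if divergence_dropout_rate < 0:
        raise ValueError("divergence_dropout_rate must be >= 0")
    inds = locus_set.individuals
    if reference_individual is None:
        reference_individual = inds[0]
    if reference_individual not in inds:
        raise ValueError(f"unknown reference individual {reference_individual!r}")

    truth = locus_set.truth
    use_gene_trees = (
        divergence_dropout_rate > 0
        and truth is not None
        and truth.gene_trees is not None
    )
    if divergence_dropout_rate > 0 and not use_gene_trees and (
        truth is None or truth.model is None
    ):
        raise ValueError(
            "divergence-correlated dropout needs ground truth (gene trees or model)"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    dropped = np.zeros((len(inds), locus_set.n_loci), dtype=bool)
    new_loci = []
    ref = reference_individual
    for j, locus in enumerate(locus_set.loci):
        if use_gene_trees:
            gt = truth.gene_trees[j]
            dist = {
                ind: 2.0 * gt.tmrca(f"{ind}.a", f"{ref}.a") if ind != ref else 0.0
                for ind in inds
            }
        elif divergence_dropout_rate > 0:
            dist = {
                ind: truth.model.distance(
                    locus_set.popmap.species_of(ind), locus_set.popmap.species_of(ref)
                )
                for ind in inds
            }
        else:
            dist = {ind: 0.0 for ind in inds}
        keep = {}
        for i, ind in enumerate(inds):
            p_keep = (1.0 - dropout_per_individual) * np.exp(
                -divergence_dropout_rate * dist[ind]
            )
            if rng.random() < p_keep:
                keep[ind] = True
            else:
                dropped[i, j] = True
        new_loci.append(
            Locus({k: v.copy() for k, v in locus.seqs.items() if keep.get(k)})
        )
    new_truth = Truth(
        model=truth.model if truth else None,
        gene_trees=truth.gene_trees if truth else None,
        dropout=pd.DataFrame(dropped, index=inds, columns=range(locus_set.n_loci)),
    )
    return LocusSet(new_loci, locus_set.popmap, locus_set.locus_length, new_truth)


def simulate_dataset(
    model: SpeciesTreeModel,
    n_loci: int,
    theta: float = 0.01,
    seed: int = 0,
    locus_length: int = 87,
    indel_rate: float = 0.0,
    dropout_per_individual: float = 0.0,
    divergence_dropout_rate: float = 0.0,
    reference_individual: str | None = None,
) -> LocusSet:
    """Gene trees -> sequences -> missingness in one deterministic call."""
    trees = simulate_gene_trees(model, n_loci, seed)
    ls = simulate_sequences(
        trees, locus_length=locus_length, theta=theta, seed=seed,
        indel_rate=indel_rate, model=model,
    )
    if dropout_per_individual > 0 or divergence_dropout_rate > 0:
        ls = apply_missingness(
            ls,
            dropout_per_individual=dropout_per_individual,
            divergence_dropout_rate=divergence_dropout_rate,
            reference_individual=reference_individual,
            seed=seed,
        )
    return ls
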