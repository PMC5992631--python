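import numpy as np
import pytest

from radintro import LocusSet, Locus, PopulationMap
from radintro.alphabet import split_consensus


def locus_set_from_consensus(rows_per_locus, popmap=None, species=None):
    """Build a LocusSet from per-locus {individual: IUPAC consensus} dicts.

    Heterozygous sites split into arbitrary phase; absent individuals are
    simply missing at that locus.  ``species`` maps individual -> species
    (defaults to everything-before-the-last-underscore, else identity).
    """
    individuals = {}
    for row in rows_per_locus:
        for ind in row:
            individuals.setdefault(ind, None)
    if popmap is None:
        if species is None:
            species = {
                ind: ind.rsplit("_", 1)[0] if "_" in ind else ind
                for ind in individuals
            }
        popmap = PopulationMap.from_pairs(species)
    loci = []
    for row in rows_per_locus:
        seqs = {}
        for ind, cons in row.items():
            a, b = split_consensus(cons)
            seqs[ind] = np.stack([a, b])
        loci.append(Locus(seqs))
    lengths = {l.length for l in loci if l.seqs}
    return LocusSet(loci, popmap, lengths.pop() if len(lengths) == 1 else 0)


def random_locus_set(rng, n_loci=8, n_species=4, inds_per_species=2,
                     length=12, missing=0.2, het=0.15):
    """Small random LocusSet (uniform bases, random heterozygotes and
    per-cell missingness) for oracle-equivalence fixtures."""
    species = [f"S{i}" for i in range(n_species)]
    inds = [f"{s}_{k}" for s in species for k in range(1, inds_per_species + 1)]
    pm = PopulationMap.from_pairs({i: i.rsplit("_", 1)[0] for i in inds})
    loci = []
    for _ in range(n_loci):
        seqs = {}
        for ind in inds:
            if rng.random() < missing:
                continue
            mat = rng.integers(0, 4, size=(2, length)).astype(np.uint8)
            # make most sites homozygous
            hom = rng.random(length) > het
            mat[1, hom] = mat[0, hom]
            seqs[ind] = mat
        loci.append(Locus(seqs))
    return LocusSet(loci, pm, length)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
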