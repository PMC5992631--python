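"""Central data containers: RAD loci, individuals, and population maps.

A :class:`LocusSet` holds a collection of equal-role RAD loci.  Each locus
is an alignment of diploid individuals, every present individual
contributing two haplotypes of identical length.  Missingness lives at the
(individual, locus) level: an individual either has both haplotypes at a
locus or is absent from it entirely.  Site-level absence is encoded in the
sequence itself with 'N'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import alphabet


@dataclass
class Locus:
    """One RAD locus: individual id -> (2, L) uint8 haplotype matrix."""

    seqs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {v.shape for v in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged locus: haplotype shapes {lengths}")
        for ind, mat in self.seqs.items():
            if mat.ndim != 2 or mat.shape[0] != 2:
                raise ValueError(f"individual {ind}: expected (2, L) matrix")

    @property
    def length(self) -> int:
        for mat in self.seqs.values():
            return int(mat.shape[1])
        return 0

    @property
    def individuals(self) -> list[str]:
        return list(self.seqs)

    def consensus(self, individual: str) -> str:
        mat = self.seqs[individual]
        return alphabet.consensus(mat[0], mat[1])

    def stacked(self, individuals: Iterable[str] | None = None) -> np.ndarray:
        """All haplotypes of the given (present) individuals as (2m, L)."""
        inds = self.individuals if individuals is None else [
            i for i in individuals if i in self.seqs
        ]
        if not inds:
            return np.empty((0, self.length), dtype=np.uint8)
        return np.concatenate([self.seqs[i] for i in inds], axis=0)

    def copy(self) -> "Locus":
        return Locus({k: v.copy() for k, v in self.seqs.items()})


class PopulationMap:
    """Individual -> species (and optional population/region) assignment."""

    def __init__(self, table: pd.DataFrame):
        required = {"individual", "species"}
        if not required.issubset(table.columns):
            raise ValueError(f"population map needs columns {sorted(required)}")
        if table["individual"].duplicated().any():
            dups = table.loc[table["individual"].duplicated(), "individual"]
            raise ValueError(f"duplicate individual ids: {sorted(set(dups))}")
        if "population" not in table.columns:
            table = table.assign(population=pd.NA)
        self.table = table[["individual", "species", "population"]].reset_index(
            drop=True
        )
        self._species = dict(zip(self.table["individual"], self.table["species"]))
        self._population = dict(
            zip(self.table["individual"], self.table["population"])
        )

    @classmethod
    def from_pairs(cls, pairs: dict[str, str]) -> "PopulationMap":
        return cls(
            pd.DataFrame(
                {"individual": list(pairs), "species": list(pairs.values())}
            )
        )

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def individuals(self) -> list[str]:
        return list(self.table["individual"])

    def species_of(self, individual: str) -> str:
        return self._species[individual]

    def population_of(self, individual: str):
        return self._population.get(individual)

    def individuals_of(self, species: str) -> list[str]:
        return [i for i in self.individuals if self._species[i] == species]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.table["species"]:
            seen.setdefault(s, None)
        return list(seen)

    def __contains__(self, individual: str) -> bool:
        return individual in self._species

    def subset(self, individuals: Iterable[str]) -> "PopulationMap":
        keep = set(individuals)
        return PopulationMap(
            self.table[self.table["individual"].isin(keep)].copy()
        )


@dataclass
class Truth:
    """Simulation ground truth carried alongside a synthetic LocusSet."""

    model: Any = None  # SpeciesTreeModel
    gene_trees: list | None = None  # list[GeneTree], aligned with loci
    dropout: pd.DataFrame | None = None  # bool individuals x loci, True = dropped


@dataclass
class LocusSet:
    """A collection of RAD loci over a fixed panel of diploid individuals."""

    loci: list[Locus]
    popmap: PopulationMap
    locus_length: int = 87
    truth: Truth | None = None

    def __post_init__(self) -> None:
        known = set(self.popmap.individuals)
        for idx, locus in enumerate(self.loci):
            unknown = set(locus.seqs) - known
            if unknown:
                raise ValueError(
                    f"locus {idx}: unmapped individuals {sorted(unknown)}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def individuals(self) -> list[str]:
        return self.popmap.individuals

    def presence_matrix(self) -> pd.DataFrame:
        """Boolean individual x locus presence (True = data present)."""
        inds = self.individuals
        mat = np.zeros((len(inds), self.n_loci), dtype=bool)
        pos = {ind: k for k, ind in enumerate(inds)}
        for j, locus in enumerate(self.loci):
            for ind in locus.seqs:
                mat[pos[ind], j] = True
        return pd.DataFrame(mat, index=inds, columns=range(self.n_loci))

    def subset_loci(self, indices: Iterable[int]) -> "LocusSet":
        idx = list(indices)
        truth = self.truth
        if truth is not None:
            truth = Truth(
                model=truth.model,
                gene_trees=None
                if truth.gene_trees is None
                else [truth.gene_trees[i] for i in idx],
                dropout=None if truth.dropout is None else truth.dropout.iloc[:, idx],
            )
        return LocusSet(
            [self.loci[i] for i in idx], self.popmap, self.locus_length, truth
        )

    def drop_individuals(self, individuals: Iterable[str]) -> "LocusSet":
        gone = set(individuals)
        loci = [
            Locus({k: v for k, v in loc.seqs.items() if k not in gone})
            for loc in self.loci
        ]
        keep = [i for i in self.popmap.individuals if i not in gone]
        return LocusSet(loci, self.popmap.subset(keep), self.locus_length, self.truth)

    def equal_sequences(self, other: "LocusSet") -> bool:
        """Haplotype-level equality (individuals, presence and sequences)."""
        if self.n_loci != other.n_loci or self.individuals != other.individuals:
            return False
        for a, b in zip(self.loci, other.loci):
            if set(a.seqs) != set(b.seqs):
                return False
            for ind in a.seqs:
                if not np.array_equal(a.seqs[ind], b.seqs[ind]):
                    return False
        return True

    def equal_consensus(self, other: "LocusSet") -> bool:
        """Genotype-level equality, ignoring haplotype phase."""
        if self.n_loci != other.n_loci or self.individuals != other.individuals:
            return False
        for a, b in zip(self.loci, other.loci):
            if set(a.seqs) != set(b.seqs):
                return False
            for ind in a.seqs:
                if a.consensus(ind) != b.consensus(ind):
                    return False
        return True
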