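"""Readers, writers and reports for RAD-locus data.

Three dialects are supported, all plain text:

* ``loci`` — assembled-locus blocks: per locus, one ``name<ws>sequence``
  line per individual (diploid consensus, IUPAC heterozygotes), terminated
  by a ``//`` separator line (trailing match markers after ``//`` are
  tolerated and ignored).
* ``phylip`` — relaxed Phylip of the concatenated consensus alignment,
  N-filling missing loci; a ``.partitions`` sidecar (locus<TAB>start<TAB>end,
  1-based inclusive) preserves locus boundaries so the round trip is
  lossless.
* ``fasta`` — one FASTA file per locus in a directory, two records per
  individual (``>ind/a``, ``>ind/b``), the only dialect that preserves
  haplotype phase.

Site indices are 0-based half-open internally and 1-based in reports.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet
from .loci import Locus, LocusSet, PopulationMap

__all__ = [
    "write_loci",
    "read_loci",
    "missingness_report",
    "write_truth",
]


def write_loci(locus_set: LocusSet, path, dialect: str = "loci") -> None:
    """Write a LocusSet in the requested dialect (see module docstring)."""
    if dialect == "loci":
        _write_loci_dialect(locus_set, path)
    elif dialect == "phylip":
        _write_phylip(locus_set, path)
    elif dialect == "fasta":
        _write_fasta_dir(locus_set, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_loci(
    path, dialect: str = "loci", popmap: PopulationMap | None = None
) -> LocusSet:
    """Read a LocusSet; a popmap is synthesized (one species per
    individual) when none is given and no sidecar map is found."""
    if dialect == "loci":
        return _read_loci_dialect(path, popmap)
    if dialect == "phylip":
        return _read_phylip(path, popmap)
    if dialect == "fasta":
        return _read_fasta_dir(path, popmap)
    raise ValueError(f"unknown dialect {dialect!r}")


def _default_popmap(individuals) -> PopulationMap:
    return PopulationMap.from_pairs(
        {ind: ind.rsplit("_", 1)[0] if "_" in ind else ind for ind in individuals}
    )


# -- .loci dialect -------------------------------------------------------


def _write_loci_dialect(locus_set: LocusSet, path) -> None:
    with open(path, "w") as fh:
        for j, locus in enumerate(locus_set.loci):
            for ind in locus_set.individuals:
                if ind in locus.seqs:
                    fh.write(f"{ind}\t{locus.consensus(ind)}\n")
            fh.write(f"//\t|{j}|\n")


def _read_loci_dialect(path, popmap: PopulationMap | None) -> LocusSet:
    loci: list[Locus] = []
    current: dict[str, np.ndarray] = {}
    individuals: dict[str, None] = {}
    length = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("//"):
                loci.append(Locus({k: v for k, v in current.items()}))
                current = {}
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name sequence'")
            name, seq = parts
            try:
                a, b = alphabet.split_consensus(seq)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if current and len(seq) != next(iter(current.values())).shape[1]:
                raise ValueError(f"{path}:{lineno}: ragged locus {len(loci)}")
            current[name] = np.stack([a, b])
            individuals.setdefault(name, None)
    if current:
        loci.append(Locus(current))
    if popmap is None:
        popmap = _default_popmap(individuals)
    lengths = {l.length for l in loci if l.seqs}
    locus_length = lengths.pop() if len(lengths) == 1 else 0
    return LocusSet(loci, popmap, locus_length or 0)


# -- relaxed Phylip ------------------------------------------------------


def _write_phylip(locus_set: LocusSet, path) -> None:
    from .trees import concat_alignment

    aln, boundaries = concat_alignment(locus_set)
    total = boundaries[-1]
    with open(path, "w") as fh:
        fh.write(f"{len(aln)} {total}\n")
        for ind, seq in aln.items():
            fh.write(f"{ind}  {seq}\n")
    with open(str(path) + ".partitions", "w") as fh:
        for j in range(len(boundaries) - 1):
            fh.write(f"locus{j}\t{boundaries[j] + 1}\t{boundaries[j + 1]}\n")


def _read_phylip(path, popmap: PopulationMap | None) -> LocusSet:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed Phylip header")
        n_ind, total = int(header[0]), int(header[1])
        rows: dict[str, str] = {}
        for raw in fh:
            if not raw.strip():
                continue
            name, seq = raw.split(maxsplit=1)
            rows[name] = seq.strip()
    if len(rows) != n_ind:
        raise ValueError(f"{path}: header says {n_ind} rows, found {len(rows)}")
    for name, seq in rows.items():
        if len(seq) != total:
            raise ValueError(f"{path}: row {name} length {len(seq)} != {total}")
    part_path = str(path) + ".partitions"
    if os.path.exists(part_path):
        bounds = []
        with open(part_path) as fh:
            for line in fh:
                _, start, end = line.split("\t")
                bounds.append((int(start) - 1, int(end)))
    else:
        bounds = [(0, total)]
    loci = []
    for start, end in bounds:
        seqs = {}
        for name, seq in rows.items():
            chunk = seq[start:end]
            if set(chunk) == {"N"}:  # missing cell, not data
                continue
            a, b = alphabet.split_consensus(chunk)
            seqs[name] = np.stack([a, b])
        loci.append(Locus(seqs))
    if popmap is None:
        popmap = _default_popmap(rows)
    lengths = {l.length for l in loci if l.seqs}
    return LocusSet(loci, popmap, lengths.pop() if len(lengths) == 1 else 0)


# -- per-locus FASTA -----------------------------------------------------


def _write_fasta_dir(locus_set: LocusSet, path) -> None:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(locus_set.n_loci)))
    for j, locus in enumerate(locus_set.loci):
        records = []
        for ind in locus_set.individuals:
            if ind not in locus.seqs:
                continue
            for h, hap in zip("ab", locus.seqs[ind]):
                records.append(
                    SeqRecord(
                        Seq(alphabet.decode(hap)), id=f"{ind}/{h}", description=""
                    )
                )
        SeqIO.write(records, d / f"locus_{j:0{width}d}.fa", "fasta")


def _read_fasta_dir(path, popmap: PopulationMap | None) -> LocusSet:
    d = Path(path)
    files = sorted(d.glob("locus_*.fa"))
    loci = []
    individuals: dict[str, None] = {}
    for f in files:
        haps: dict[str, dict[str, np.ndarray]] = {}
        for rec in SeqIO.parse(str(f), "fasta"):
            ind, hap = rec.id.rsplit("/", 1)
            haps.setdefault(ind, {})[hap] = alphabet.encode(str(rec.seq))
            individuals.setdefault(ind, None)
        seqs = {}
        for ind, pair in haps.items():
            if set(pair) != {"a", "b"}:
                raise ValueError(f"{f}: individual {ind} lacks two haplotypes")
            seqs[ind] = np.stack([pair["a"], pair["b"]])
        loci.append(Locus(seqs))
    if popmap is None:
        popmap = _default_popmap(individuals)
    lengths = {l.length for l in loci if l.seqs}
    return LocusSet(loci, popmap, lengths.pop() if len(lengths) == 1 else 0)


# -- reports -------------------------------------------------------------


def missingness_report(
    locus_set: LocusSet, order=None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Presence/absence matrix plus per-individual missing fractions.

    ``order`` may be a tree (dendropy) whose tip order arranges the rows —
    the conventional display puts individuals in phylogeny order so that
    missingness structure correlated with placement is visible.  Returns
    (matrix, per-individual missing fraction, quantiles of that fraction).
    """
    matrix = locus_set.presence_matrix()
    if order is not None:
        tips = [lf.taxon.label for lf in order.leaf_node_iter()]
        unknown = set(tips) ^ set(matrix.index)
        if unknown:
            raise ValueError(f"tree tips do not match individuals: {sorted(unknown)}")
        matrix = matrix.loc[tips]
    missing = 1.0 - matrix.mean(axis=1)
    quantiles = missing.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    return matrix, missing, quantiles


def write_truth(locus_set: LocusSet, directory) -> None:
    """Persist simulation ground truth: species tree (Newick), per-locus
    gene trees (Newick, one per line, with an introgression flag), and a
    flat key-value sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    truth = locus_set.truth
    if truth is None:
        raise ValueError("locus set carries no ground truth")
    if truth.model is not None:
        (d / "species_tree.nwk").write_text(truth.model.newick() + "\n")
        with open(d / "model.txt", "w") as fh:
            for s in truth.model.species:
                fh.write(f"samples_{s} = {truth.model.samples_per_species[s]}\n")
            for p in truth.model.pulses:
                fh.write(
                    f"pulse = {p.donor} -> {p.recipient} "
                    f"t={p.time:g} gamma={p.gamma:g}\n"
                )
    if truth.gene_trees is not None:
        with open(d / "gene_trees.nwk", "w") as fh:
            for gt in truth.gene_trees:
                flag = "introgressed" if gt.introgressed else "non-introgressed"
                fh.write(f"[&{flag}] {gt.newick()}\n")
    if truth.dropout is not None:
        truth.dropout.to_csv(d / "dropout_mask.tsv", sep="\t")
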