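"""Aligned-sequence, tree, and tabular input/output.

The central container is :class:`CodonAlignment`, an ordered label → sequence
map over the alphabet ``A/C/G/T/N/-`` in which every record has the same
length.  Coordinates are 0-based and half-open throughout the library;
1-based positions appear only in human-readable reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN-")
MISSING = frozenset("N-")


class AlignmentError(ValueError):
    """Records violate the equal-length alignment invariant."""


class FormatError(ValueError):
    """Input file is empty, malformed, or contains illegal characters."""


class ConfigurationError(ValueError):
    """Labels or topology do not match the analysis configuration."""


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences keyed by taxon or allele label.

    Parameters
    ----------
    records
        Ordered mapping of unique labels to equal-length nucleotide strings.
    frame_offset
        Number of leading nucleotides before the first complete codon.
    """

    records: dict[str, str]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.frame_offset < 0:
            raise ValueError("frame_offset must be >= 0")
        for label, seq in self.records.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise FormatError(f"illegal characters {sorted(bad)} in record {label!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return list(self.records)

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def __getitem__(self, label: str) -> str:
        return self.records[label]

    def subset(self, labels: list[str]) -> "CodonAlignment":
        missing = [l for l in labels if l not in self.records]
        if missing:
            raise ConfigurationError(f"labels not in alignment: {missing}")
        return CodonAlignment({l: self.records[l] for l in labels}, self.frame_offset)


@dataclass
class SpeciesTopology:
    """Rooted species tree with a designated focal duplicate pair and outgroups.

    ``focal`` is ``(new_gene_label, parental_gene_label)``; ``outgroups`` are
    the ortholog labels used for parsimony polarization, in increasing
    phylogenetic distance.
    """

    tree: dendropy.Tree
    focal: tuple[str, str]
    outgroups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        leaves = {t.label for t in self.tree.taxon_namespace}
        for label in (*self.focal, *self.outgroups):
            if label not in leaves:
                raise ConfigurationError(f"label {label!r} not a leaf of the topology")
        if not self.outgroups:
            raise ConfigurationError("at least one outgroup is required")

    @property
    def new_label(self) -> str:
        return self.focal[0]

    @property
    def parental_label(self) -> str:
        return self.focal[1]


def read_alignment(path: str | Path, frame_offset: int = 0) -> CodonAlignment:
    """Read an aligned FASTA file into a :class:`CodonAlignment`.

    Lowercase bases are normalised to uppercase.  The FASTA description after
    the first whitespace is ignored for keying; duplicate IDs are an error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return CodonAlignment(records, frame_offset)


def write_alignment(aln: CodonAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=l, description="") for l, s in aln.records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_topology(
    path: str | Path, focal: tuple[str, str], outgroups: list[str]
) -> SpeciesTopology:
    """Read a newick tree and annotate the focal pair and outgroup labels."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse newick file {path}: {exc}") from exc
    return SpeciesTopology(tree, tuple(focal), list(outgroups))


def codon_iter(aln: CodonAlignment) -> Iterator[tuple[int, dict[str, str]]]:
    """Yield ``(codon_index, {label: codon})`` columns in 5'→3' order.

    Yields ``⌊(length − frame_offset)/3⌋`` columns; a trailing partial codon
    is dropped.  Codon index 0 covers nucleotides
    ``[frame_offset, frame_offset + 3)``.
    """
    off = aln.frame_offset
    for i in range(aln.n_codons):
        start = off + 3 * i
        yield i, {l: s[start : start + 3] for l, s in aln.records.items()}


def read_trait_table(path: str | Path, genotype_col: str = "genotype"):
    """Read a phenotype TSV (one row per individual, genotype + trait columns)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if genotype_col not in df.columns:
        raise FormatError(f"trait table lacks a {genotype_col!r} column")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
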