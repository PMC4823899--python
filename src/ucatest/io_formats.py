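"""Reading and writing FASTA sequence sets and Newick trees.

One canonical dialect is supported on purpose: upper-case residues over the
20 amino-acid letters plus ``-`` as the only gap character, 60-column FASTA
wrapping, Newick with real-valued branch lengths.  Everything round-trips
bit-identically.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import dendropy
import numpy as np
from Bio import SeqIO

from .models import AMINO_ACIDS, GAP
from .phylo.tree import Node, Tree

_VALID = set(AMINO_ACIDS) | {GAP}
_STATE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_ENCODE_LUT = np.full(256, -2, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _ENCODE_LUT[ord(_aa)] = _i
_ENCODE_LUT[ord(GAP)] = -1


class FastaParseError(ValueError):
    pass


@dataclass
class SequenceSet:
    """An ordered set of (identifier, residues) records.

    Residues are upper-case amino-acid letters plus ``-``.  A set is
    *aligned* when all residue strings have equal length.
    """

    records: List[Tuple[str, str]]

    def __post_init__(self):
        seen = set()
        for ident, seq in self.records:
            if not ident:
                raise ValueError("empty sequence identifier")
            if ident in seen:
                raise ValueError(f"duplicate sequence identifier: {ident!r}")
            seen.add(ident)
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"invalid residue letter(s) {sorted(bad)} in sequence {ident!r}"
                )

    # -- basic container behaviour ------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, ident: str) -> str:
        for i, s in self.records:
            if i == ident:
                return s
        raise KeyError(ident)

    @property
    def ids(self) -> List[str]:
        return [i for i, _ in self.records]

    @property
    def sequences(self) -> List[str]:
        return [s for _, s in self.records]

    @property
    def is_aligned(self) -> bool:
        lengths = {len(s) for _, s in self.records}
        return len(lengths) <= 1

    @property
    def n_columns(self) -> int:
        if not self.records:
            return 0
        if not self.is_aligned:
            raise ValueError("sequence set is not aligned")
        return len(self.records[0][1])

    def subset(self, idents: Iterable[str]) -> "SequenceSet":
        """Rows for the given identifiers, preserving this set's order."""
        want = set(idents)
        missing = want - set(self.ids)
        if missing:
            raise KeyError(f"unknown identifiers: {sorted(missing)}")
        return SequenceSet([(i, s) for i, s in self.records if i in want])

    # -- numeric views ------------------------------------------------

    def to_matrix(self) -> np.ndarray:
        """(n_sequences, n_columns) int8 matrix; gap encoded as -1."""
        if not self.is_aligned:
            raise ValueError("sequence set is not aligned")
        mat = np.empty((len(self.records), self.n_columns), dtype=np.int8)
        for r, (_, seq) in enumerate(self.records):
            mat[r] = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        return mat

    @classmethod
    def from_matrix(cls, idents: Sequence[str], mat: np.ndarray) -> "SequenceSet":
        rows = []
        for ident, row in zip(idents, mat):
            rows.append(
                (ident, "".join(GAP if v < 0 else AMINO_ACIDS[v] for v in row))
            )
        return cls(rows)


def read_fasta(path) -> SequenceSet:
    """Read a FASTA file into a SequenceSet.

    Whitespace inside sequence lines is stripped and residues are
    upper-cased; letters outside the 20-residue alphabet plus ``-`` (``X``,
    ``.`` and other ambiguity codes included) are rejected.
    """
    with open(path) as fh:
        text = fh.read()
    return parse_fasta(text)


def parse_fasta(text: str) -> SequenceSet:
    # pre-scan for structural problems so errors can name the line
    header_lines = [
        (n, line) for n, line in enumerate(text.splitlines(), 1) if line.startswith(">")
    ]
    if text.strip() and not header_lines:
        raise FastaParseError("line 1: expected a '>' FASTA header")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        records.append((rec.id, seq))
    for (n, line), (ident, seq) in zip(header_lines, records):
        if not seq:
            raise FastaParseError(f"line {n}: empty sequence for record {ident!r}")
        if not ident:
            raise FastaParseError(f"line {n}: empty FASTA header")
    if len(records) != len(header_lines):
        n = header_lines[len(records)][0] if len(records) < len(header_lines) else "?"
        raise FastaParseError(f"line {n}: malformed FASTA record")
    try:
        return SequenceSet(records)
    except ValueError as exc:
        raise FastaParseError(str(exc)) from exc


def write_fasta(seqs: SequenceSet, path, width: int = 60) -> None:
    """Write a SequenceSet as FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        fh.write(format_fasta(seqs, width))


def format_fasta(seqs: SequenceSet, width: int = 60) -> str:
    parts = []
    for ident, seq in seqs:
        parts.append(f">{ident}\n")
        for i in range(0, len(seq), width):
            parts.append(seq[i : i + width] + "\n")
    return "".join(parts)


def read_newick(text: str) -> Tree:
    """Parse a Newick string; absent branch lengths default to zero."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"could not parse Newick input: {exc}") from exc

    def rec(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = Node(label, length)
        for child in dnode.child_nodes():
            node.add(rec(child))
        return node

    root = rec(dtree.seed_node)
    root.length = 0.0
    tree = Tree(root)
    labels = [lab for lab in tree.leaf_labels()]
    if any(lab is None for lab in labels):
        raise ValueError("Newick input has unlabelled leaves")
    if len(set(labels)) != len(labels):
        raise ValueError("Newick input has duplicate leaf labels")
    return tree


def write_newick(tree: Tree) -> str:
    return tree.newick()
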