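"""Sequence, tree and matrix I/O.

Containers and readers/writers for the formats the toolkit touches:
FASTA (nucleotide and protein), Newick trees, and symmetric pairwise-matrix
TSV files.  Parsing of FASTA and Newick is delegated to Biopython and
DendroPy; this module adds the strict validation the downstream analyses
rely on (unique record ids, restricted alphabets, matrix symmetry).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger("rhizotax")

# --------------------------------------------------------------------------
# Alphabets
# --------------------------------------------------------------------------

#: DNA: the four bases plus IUPAC ambiguity codes.  'U' is deliberately
#: excluded: assemblies are DNA.
NUCLEOTIDE_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: Protein: the 20 standard residues, 'X' (unknown), '*' (stop) and '-' (gap).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*-")

_ALPHABETS = {
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "protein": PROTEIN_ALPHABET,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """Malformed input file (empty FASTA, asymmetric matrix, bad Newick)."""


class AlphabetError(ValueError):
    """Sequence contains a character outside the declared alphabet."""


# --------------------------------------------------------------------------
# Core containers
# --------------------------------------------------------------------------

@dataclass
class SeqRecord:
    """A single named sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header and
    ``description`` the remainder.  Sequences are stored uppercase.
    """

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """Named set of nucleotide contigs for one strain."""

    genome_id: str
    contigs: list[SeqRecord]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise FormatError(
                f"assembly {self.genome_id!r}: duplicate contig ids"
            )

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str | None = None
                   ) -> "GenomeAssembly":
        path = Path(path)
        if genome_id is None:
            genome_id = path.name
            for suffix in (".gz", ".fasta", ".fa", ".fna"):
                if genome_id.endswith(suffix):
                    genome_id = genome_id[: -len(suffix)]
        return cls(genome_id, read_fasta(path, "nucleotide"))


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, alphabet: str) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file with alphabet validation.

    Parameters
    ----------
    path:
        FASTA file; line wrapping is irrelevant.
    alphabet:
        ``"nucleotide"`` or ``"protein"``.  Lowercase letters are silently
        uppercased; any character outside the alphabet raises
        :class:`AlphabetError` naming the record and position.
    """
    try:
        allowed = _ALPHABETS[alphabet]
    except KeyError:
        raise ValueError(f"unknown alphabet {alphabet!r}") from None

    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FormatError(f"{path}: record with empty id")
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
            bad = set(seq) - allowed
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise AlphabetError(
                    f"{path}: record {rec.id!r} has illegal {alphabet} "
                    f"character {seq[pos]!r} at position {pos}"
                )
            # Biopython's rec.description includes the id token itself.
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SeqRecord(rec.id, seq, desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                width: int = 80) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    with open(path, "wt") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i:i + width] + "\n")


# --------------------------------------------------------------------------
# Newick trees
# --------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, enforcing unique leaf labels.

    Accepts either a path to a file or a Newick string (detected by the
    presence of parentheses/semicolon).  Internal node labels are kept as
    support strings; branch lengths are preserved when present.
    """
    s = str(path_or_string)
    if "(" in s or ";" in s:
        kw = {"data": s}
    else:
        kw = {"path": s}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **kw,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"invalid Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels in tree: {dupes}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# --------------------------------------------------------------------------
# Symmetric pairwise matrices
# --------------------------------------------------------------------------

#: Metrics for which self-comparison is 100 % by construction.
_AAI_METRICS = {"cpAAI", "wpAAI"}

#: Written / compared precision of matrix TSV files (decimal places).
MATRIX_PRECISION = 4


@dataclass
class PairwiseMatrix:
    """Symmetric taxa x taxa matrix of percentages in [0, 100].

    ``support`` optionally carries per-pair counts (e.g. compared alignment
    sites); ``unreliable`` flags pairs whose support fell below a minimum.
    """

    metric: str
    taxa: list[str]
    values: np.ndarray
    support: np.ndarray | None = None
    unreliable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} taxa"
            )
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxa labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("matrix values outside [0, 100]")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if self.metric in _AAI_METRICS:
            diag = np.diag(self.values)
            if not np.allclose(diag[np.isfinite(diag)], 100.0):
                raise ValueError(f"{self.metric} diagonal must be 100")

    def value(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def submatrix(self, taxa: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        sub = self.values[np.ix_(idx, idx)]
        sup = self.support[np.ix_(idx, idx)] if self.support is not None else None
        return PairwiseMatrix(self.metric, list(taxa), sub, sup)

    @property
    def condensed(self) -> np.ndarray:
        """Off-diagonal upper-triangle values (each pair once)."""
        iu = np.triu_indices(len(self.taxa), k=1)
        return self.values[iu]


def write_matrix(matrix: PairwiseMatrix, path: str | Path) -> None:
    """Serialize a :class:`PairwiseMatrix` as TSV.

    Header row of taxa with an empty first cell; one row per taxon; values
    rounded to 4 decimals ('.' decimal separator).
    """
    with open(path, "wt") as handle:
        handle.write("\t" + "\t".join(matrix.taxa) + "\n")
        for label, row in zip(matrix.taxa, matrix.values):
            cells = "\t".join(
                "nan" if not np.isfinite(v) else f"{v:.{MATRIX_PRECISION}f}"
                for v in row
            )
            handle.write(f"{label}\t{cells}\n")


def read_matrix(path: str | Path, metric: str = "other") -> PairwiseMatrix:
    """Read a symmetric matrix TSV written by :func:`write_matrix`.

    Raises :class:`FormatError` when the row/column taxa disagree or the
    matrix is asymmetric beyond the written precision.
    """
    with _open_text(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: matrix file needs a header and rows")
    header = lines[0].split("\t")[1:]
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        row_labels.append(cells[0])
        rows.append([float(c) for c in cells[1:]])
    if row_labels != header:
        raise FormatError(f"{path}: row labels do not match header taxa")
    values = np.array(rows, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: matrix is not square")
    tol = 10.0 ** (-MATRIX_PRECISION) / 2 + 1e-6
    asym = np.nanmax(np.abs(values - values.T)) if values.size else 0.0
    if asym > tol:
        raise FormatError(
            f"{path}: matrix asymmetric (max |a-b| = {asym:.6g})"
        )
    values = (values + values.T) / 2.0
    return PairwiseMatrix(metric, header, values)
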