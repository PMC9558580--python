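"""Marker extraction and supermatrix construction.

Locates orthologs of a reference set of single-copy core marker proteins in
a nucleotide assembly by Smith-Waterman search of each marker's consensus
against all six reading frames of every contig, places extracted proteins
back into the fixed-column reference alignments, and concatenates the
per-marker rows into the taxa x columns protein supermatrix from which
core-proteome AAI is computed.

The search is self-contained (no external BLAST binaries): local and global
alignments run on Biotite's C kernels with BLOSUM62 and affine gap costs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import biotite.sequence as bseq
import biotite.sequence.align as balign
import numpy as np
from Bio.Data import CodonTable

from .seqio import (
    AMINO_ACIDS,
    GenomeAssembly,
    SeqRecord,
    read_fasta,
)

logger = logging.getLogger("rhizotax")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# Translation
# --------------------------------------------------------------------------

def _codon_map(table: int) -> dict[str, str]:
    t = CodonTable.unambiguous_dna_by_id[table]
    mapping = dict(t.forward_table)
    for codon in t.stop_codons:
        mapping[codon] = "*"
    return mapping


def translate(nt: str, table: int = 11) -> str:
    """Translate a nucleotide string codon by codon.

    Stop codons become ``'*'``; any codon containing a non-ACGT base becomes
    ``'X'``; a trailing partial codon is dropped.
    """
    mapping = _codon_map(table)
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        out.append(mapping.get(nt[i:i + 3], "X"))
    return "".join(out)


@dataclass(frozen=True)
class Frame:
    """One of the six reading frames of a contig."""

    contig_id: str
    strand: str          # '+' or '-'
    offset: int          # 0-2, frame start within the strand
    protein: str
    contig_length: int

    def nt_interval(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval of protein slice [p_start, p_end)."""
        s = self.offset + 3 * p_start
        e = self.offset + 3 * p_end
        if self.strand == "+":
            return s, e
        return self.contig_length - e, self.contig_length - s


def six_frame_translate(contig: SeqRecord, table: int = 11) -> list[Frame]:
    """All six translation frames of a contig (3 forward, 3 reverse)."""
    seq = contig.sequence
    if len(seq) < 3:
        warnings.warn(
            f"contig {contig.id!r} shorter than one codon; no frames",
            stacklevel=2,
        )
        return []
    frames = []
    rc = reverse_complement(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for offset in range(3):
            prot = translate(s[offset:], table)
            if prot:
                frames.append(Frame(contig.id, strand, offset, prot, len(seq)))
    return frames


# --------------------------------------------------------------------------
# Marker sets
# --------------------------------------------------------------------------

@dataclass
class Marker:
    """One reference marker: an aligned protein family plus its consensus.

    ``consensus`` is the majority residue of each alignment column, with
    gap-majority columns dropped; ``consensus_columns[k]`` is the reference
    alignment column that consensus position ``k`` came from, which is what
    lets an extracted ortholog be written back into the original columns.
    """

    marker_id: str
    alignment: list[SeqRecord]
    consensus: str = field(init=False)
    consensus_columns: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.alignment:
            raise ValueError(f"marker {self.marker_id!r}: empty alignment")
        lengths = {len(r.sequence) for r in self.alignment}
        if len(lengths) != 1:
            raise ValueError(
                f"marker {self.marker_id!r}: rows of unequal length {lengths}"
            )
        self.consensus, self.consensus_columns = _consensus(self.alignment)
        if not self.consensus:
            raise ValueError(f"marker {self.marker_id!r}: all-gap alignment")

    @property
    def n_columns(self) -> int:
        return len(self.alignment[0].sequence)


def _consensus(alignment: list[SeqRecord]) -> tuple[str, list[int]]:
    rows = np.array([list(r.sequence) for r in alignment])
    residues: list[str] = []
    columns: list[int] = []
    for col in range(rows.shape[1]):
        chars, counts = np.unique(rows[:, col], return_counts=True)
        order = np.lexsort((chars, -counts))  # most frequent, ties lexicographic
        best = chars[order[0]]
        if best in "-X*":
            # gap/ambiguity-majority column: contribute nothing to the query
            if best == "-" and counts[order[0]] * 2 >= rows.shape[0]:
                continue
            # fall back to the most frequent real residue if one exists
            real = [c for c in chars[order] if c in AMINO_ACIDS]
            if not real:
                continue
            best = real[0]
        residues.append(best)
        columns.append(col)
    return "".join(residues), columns


@dataclass
class MarkerSet:
    """Ordered collection of reference markers (canonically 170)."""

    markers: list[Marker]

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def total_columns(self) -> int:
        return sum(m.n_columns for m in self.markers)

    @classmethod
    def from_directory(cls, directory: str | Path,
                       suffixes: tuple[str, ...] = (".fasta", ".fa", ".faa", ".aln")
                       ) -> "MarkerSet":
        """Load a marker set from a directory of aligned protein FASTA files.

        One file per marker; the filename stem is the marker id; files are
        taken in sorted order so the concatenation layout is deterministic.
        """
        directory = Path(directory)
        paths = sorted(
            p for p in directory.iterdir()
            if p.suffix in suffixes or (p.suffix == ".gz" and Path(p.stem).suffix in suffixes)
        )
        if not paths:
            raise ValueError(f"no marker alignment files in {directory}")
        markers = []
        for p in paths:
            stem = Path(p.stem).stem if p.suffix == ".gz" else p.stem
            markers.append(Marker(stem, read_fasta(p, "protein")))
        return cls(markers)


# --------------------------------------------------------------------------
# Translated search
# --------------------------------------------------------------------------

@dataclass
class SearchParams:
    """Scoring scheme and acceptance thresholds for the translated search.

    ``min_identity`` (percent) and ``min_coverage`` (fraction of the marker
    consensus aligned) follow the same spirit as the reciprocal-best-hit
    ortholog criteria used for whole-proteome AAI; both are configurable.

    ``query_mode`` selects the search query: ``"consensus"`` (default, one
    alignment per frame) or ``"all_rows"`` (every ungapped reference row is
    tried and the best-scoring hit kept — slower, but more sensitive when
    the family is deeply split).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_identity: float = 30.0
    min_coverage: float = 0.70
    translation_table: int = 11
    query_mode: str = "consensus"

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if not (0 <= self.min_identity <= 100):
            raise ValueError("min_identity must be in [0, 100]")
        if self.query_mode not in ("consensus", "all_rows"):
            raise ValueError(f"unknown query_mode {self.query_mode!r}")


_MATRIX_CACHE: dict[str, balign.SubstitutionMatrix] = {}


def _substitution_matrix(name: str) -> balign.SubstitutionMatrix:
    if name not in _MATRIX_CACHE:
        if name == "BLOSUM62":
            m = balign.SubstitutionMatrix.std_protein_matrix()
        else:
            alph = bseq.ProteinSequence.alphabet
            m = balign.SubstitutionMatrix(alph, alph, name)
        _MATRIX_CACHE[name] = m
    return _MATRIX_CACHE[name]


def _as_protein(seq: str) -> bseq.ProteinSequence:
    # Biotite's protein alphabet covers the 20 residues plus B/Z/X/*; map
    # anything else ('-', rare codes) to X before aligning.
    cleaned = "".join(
        c if c in "ACDEFGHIKLMNPQRSTVWYBZX*" else "X" for c in seq
    )
    return bseq.ProteinSequence(cleaned)


def _align_stats(aln: balign.Alignment) -> tuple[int, int]:
    """(matches, alignment_columns) of a biotite alignment."""
    codes = balign.get_codes(aln)
    valid = (codes[0] != -1) & (codes[1] != -1)
    matches = int(np.count_nonzero(valid & (codes[0] == codes[1])))
    return matches, codes.shape[1]


@dataclass
class MarkerHit:
    """Best placement of one marker in one genome.

    Coordinates are 0-based half-open on the forward strand of ``contig_id``;
    ``protein`` is the translation of that interval (reverse-complemented
    first when ``strand`` is '-').
    """

    marker_id: str
    genome_id: str
    contig_id: str
    strand: str
    nt_start: int
    nt_end: int
    frame: int
    score: float
    identity: float
    coverage: float
    protein: str

    @property
    def has_internal_stop(self) -> bool:
        return "*" in self.protein


def find_marker(genome: GenomeAssembly, marker: Marker,
                params: SearchParams | None = None) -> MarkerHit | None:
    """Locate the best ortholog of ``marker`` in ``genome``, if any.

    Aligns the marker consensus locally against all six reading frames of
    every contig and returns the single highest-scoring hit passing the
    identity and coverage thresholds, or ``None``.  Equal scores are broken
    by contig id, then forward-strand nucleotide start, then '+' strand, so
    the result is deterministic.
    """
    params = params or SearchParams()
    sub = _substitution_matrix(params.matrix)
    if params.query_mode == "all_rows":
        queries = [(r.sequence.replace("-", ""), len(r.sequence.replace("-", "")))
                   for r in marker.alignment]
        queries = [(q, n) for q, n in queries if n > 0]
    else:
        queries = [(marker.consensus, len(marker.consensus))]
    gap = (-params.gap_open, -params.gap_extend)

    best: MarkerHit | None = None
    best_key: tuple | None = None
    for contig in genome.contigs:
        for fr in six_frame_translate(contig, params.translation_table):
            target = _as_protein(fr.protein)
            for query_seq, query_len in queries:
                alns = balign.align_optimal(
                    _as_protein(query_seq), target, sub, gap_penalty=gap,
                    local=True, max_number=1
                )
                if not alns:
                    continue
                aln = alns[0]
                if aln.trace.shape[0] == 0:
                    continue
                matches, columns = _align_stats(aln)
                identity = 100.0 * matches / columns if columns else 0.0
                q_lo, q_hi = aln.trace[0, 0], aln.trace[-1, 0] + 1
                t_lo, t_hi = aln.trace[0, 1], aln.trace[-1, 1] + 1
                coverage = (q_hi - q_lo) / query_len
                if identity < params.min_identity or coverage < params.min_coverage:
                    continue
                nt_start, nt_end = fr.nt_interval(t_lo, t_hi)
                key = (-aln.score, contig.id, nt_start,
                       0 if fr.strand == "+" else 1)
                if best_key is None or key < best_key:
                    best_key = key
                    best = MarkerHit(
                        marker_id=marker.marker_id,
                        genome_id=genome.genome_id,
                        contig_id=contig.id,
                        strand=fr.strand,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        frame=fr.offset,
                        score=float(aln.score),
                        identity=identity,
                        coverage=coverage,
                        protein=fr.protein[t_lo:t_hi],
                    )
    if best is not None and best.has_internal_stop:
        warnings.warn(
            f"marker {marker.marker_id!r} hit in {genome.genome_id!r} spans "
            "an internal stop codon (possible frameshift or pseudogene)",
            stacklevel=2,
        )
    return best


@dataclass
class ExtractionReport:
    """Summary of one genome's marker extraction."""

    genome_id: str
    n_markers: int
    found: list[str]
    missing: list[str]

    @property
    def found_fraction(self) -> float:
        return len(self.found) / self.n_markers


def extract_markers(genome: GenomeAssembly, marker_set: MarkerSet,
                    params: SearchParams | None = None,
                    warn_fraction: float = 0.5
                    ) -> tuple[list[MarkerHit], ExtractionReport]:
    """Search a genome for every marker in the set.

    Returns at most one hit per marker plus a report of what was and was not
    found.  A warning is emitted when fewer than ``warn_fraction`` of the
    markers are located, since a core-proteome AAI computed on a sparse row
    is unlikely to be comparable across genome pairs.
    """
    if len(marker_set) == 0:
        raise ValueError("empty marker set")
    if not genome.contigs:
        raise ValueError(f"genome {genome.genome_id!r} has no contigs")
    params = params or SearchParams()
    hits: list[MarkerHit] = []
    missing: list[str] = []
    for marker in marker_set:
        hit = find_marker(genome, marker, params)
        if hit is None:
            missing.append(marker.marker_id)
        else:
            hits.append(hit)
    report = ExtractionReport(
        genome_id=genome.genome_id,
        n_markers=len(marker_set),
        found=[h.marker_id for h in hits],
        missing=missing,
    )
    if report.found_fraction < warn_fraction:
        warnings.warn(
            f"genome {genome.genome_id!r}: only "
            f"{len(hits)}/{len(marker_set)} markers found",
            stacklevel=2,
        )
    return hits, report


# --------------------------------------------------------------------------
# Placement into the reference alignment
# --------------------------------------------------------------------------

def add_to_reference(protein: str, marker: Marker,
                     params: SearchParams | None = None) -> str:
    """Align an extracted protein into the marker's reference columns.

    The protein is globally aligned to the marker consensus (terminal gaps
    free, so partial proteins align where they belong); residues matched to
    consensus position *k* are written into the reference column that hosts
    that position.  Insertions relative to the consensus are discarded and
    unmatched reference columns stay ``'-'`` — the reference column count is
    preserved, which keeps supermatrix coordinates stable across genomes.
    """
    if not protein:
        raise ValueError("empty protein")
    params = params or SearchParams()
    sub = _substitution_matrix(params.matrix)
    aln = balign.align_optimal(
        _as_protein(protein), _as_protein(marker.consensus), sub,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=False, terminal_penalty=False, max_number=1,
    )[0]
    row = ["-"] * marker.n_columns
    for q_pos, c_pos in aln.trace:
        if q_pos != -1 and c_pos != -1:
            row[marker.consensus_columns[c_pos]] = protein[q_pos]
    return "".join(row)


# --------------------------------------------------------------------------
# Concatenation
# --------------------------------------------------------------------------

@dataclass
class ConcatenatedAlignment:
    """Taxa x columns protein supermatrix with per-marker column spans."""

    taxa: list[str]
    rows: list[str]
    spans: dict[str, tuple[int, int]]
    found_fraction: dict[str, float]

    def __post_init__(self) -> None:
        n_cols = self.n_columns
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != n_cols:
                raise ValueError(
                    f"row for {taxon!r} has {len(row)} columns, expected {n_cols}"
                )

    @property
    def n_columns(self) -> int:
        return max(end for _, end in self.spans.values()) if self.spans else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def to_records(self) -> list[SeqRecord]:
        return [SeqRecord(t, r) for t, r in zip(self.taxa, self.rows)]


def concatenate(rows: Mapping[str, Mapping[str, str]],
                marker_set: MarkerSet) -> ConcatenatedAlignment:
    """Concatenate per-genome aligned marker rows into a supermatrix.

    ``rows`` maps genome id -> (marker id -> aligned row of that marker's
    column count).  Markers are laid out in marker-set order; a genome
    missing a marker gets a gap run of that marker's width, so the total
    column count never depends on which genomes lack which markers.
    """
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for marker in marker_set:
        spans[marker.marker_id] = (offset, offset + marker.n_columns)
        offset += marker.n_columns

    taxa = list(rows)
    out_rows: list[str] = []
    found_fraction: dict[str, float] = {}
    for genome_id in taxa:
        per_marker = rows[genome_id]
        parts: list[str] = []
        n_found = 0
        for marker in marker_set:
            row = per_marker.get(marker.marker_id)
            if row is None:
                parts.append("-" * marker.n_columns)
            else:
                if len(row) != marker.n_columns:
                    raise ValueError(
                        f"genome {genome_id!r}, marker {marker.marker_id!r}: "
                        f"row length {len(row)} != {marker.n_columns} columns"
                    )
                parts.append(row)
                n_found += 1
        out_rows.append("".join(parts))
        found_fraction[genome_id] = n_found / len(marker_set)
    return ConcatenatedAlignment(taxa, out_rows, spans, found_fraction)


def build_supermatrix(genomes: Iterable[GenomeAssembly],
                      marker_set: MarkerSet,
                      params: SearchParams | None = None
                      ) -> tuple[ConcatenatedAlignment, list[ExtractionReport]]:
    """Extract, place and concatenate markers for a collection of genomes."""
    params = params or SearchParams()
    rows: dict[str, dict[str, str]] = {}
    reports = []
    for genome in genomes:
        hits, report = extract_markers(genome, marker_set, params)
        by_id = {m.marker_id: m for m in marker_set}
        rows[genome.genome_id] = {
            h.marker_id: add_to_reference(h.protein, by_id[h.marker_id], params)
            for h in hits
        }
        reports.append(report)
    return concatenate(rows, marker_set), reports
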