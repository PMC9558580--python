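"""Overall genome relatedness indices (OGRIs).

The four pairwise measures the genus-demarcation framework rests on:

* **cpAAI** — core-proteome average amino-acid identity, computed from the
  concatenated alignment of the core marker proteins as the fraction of
  identical residues over sites where both taxa have an unambiguous residue
  (pairwise deletion of gap/ambiguous columns).
* **wpAAI** — whole-proteome AAI, the unweighted mean percent identity of
  reciprocal-best-hit ortholog pairs between two proteomes.
* **POCP** — percentage of conserved proteins, 100 x (C1 + C2) / (T1 + T2)
  where C counts proteins of one genome with a qualifying hit in the other
  and T the proteome sizes.
* **GANTC density** — genomic frequency of the self-complementary CcrM
  methylation motif GANTC, in sites per kilobase.

wpAAI and POCP consume all-vs-all protein hit tables in the standard
12-column tabular search format; tables can come from an external search
tool or from the built-in Smith-Waterman generator (small inputs only).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import biotite.sequence.align as balign
import numpy as np
import pandas as pd

from .markers import ConcatenatedAlignment, SearchParams, _align_stats, _as_protein, _substitution_matrix
from .seqio import FormatError, GenomeAssembly, PairwiseMatrix, SeqRecord

logger = logging.getLogger("rhizotax")

# --------------------------------------------------------------------------
# cpAAI
# --------------------------------------------------------------------------

#: Characters excluded from cpAAI site comparisons (missing or ambiguous).
_EXCLUDED = b"-X*"


@dataclass
class CpaaiThresholds:
    """Reliability threshold for cpAAI pairs."""

    min_compared_sites: int = 100


def cpaai(alignment: ConcatenatedAlignment,
          thresholds: CpaaiThresholds | None = None) -> PairwiseMatrix:
    """Core-proteome AAI matrix from a concatenated marker alignment.

    For each taxon pair, sites where either row holds ``'-'``, ``'X'`` or
    ``'*'`` are dropped (pairwise deletion); the value is
    ``100 * (1 - differences / compared_sites)``.  ``support`` carries the
    per-pair compared-site counts; pairs with fewer than
    ``min_compared_sites`` sites are retained but flagged unreliable, and a
    pair with no comparable site at all is reported as NaN.
    """
    thresholds = thresholds or CpaaiThresholds()
    n = len(alignment.taxa)
    if n < 2:
        raise ValueError("cpAAI needs at least two taxa")
    mat = np.frombuffer(
        "".join(alignment.rows).encode("ascii"), dtype=np.uint8
    ).reshape(n, -1)
    usable = np.ones(mat.shape, dtype=bool)
    for c in _EXCLUDED:
        usable &= mat != c

    values = np.full((n, n), 100.0)
    support = np.zeros((n, n), dtype=np.int64)
    unreliable = np.zeros((n, n), dtype=bool)
    support[np.diag_indices(n)] = np.count_nonzero(usable, axis=1)
    for i in range(n):
        both = usable[i] & usable[i + 1:]
        same = (mat[i] == mat[i + 1:]) & both
        L = np.count_nonzero(both, axis=1)
        D = L - np.count_nonzero(same, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = 100.0 * (1.0 - D / L)
        val = np.where(L > 0, val, np.nan)
        for k, j in enumerate(range(i + 1, n)):
            values[i, j] = values[j, i] = val[k]
            support[i, j] = support[j, i] = L[k]
            if L[k] < thresholds.min_compared_sites:
                unreliable[i, j] = unreliable[j, i] = True
    return PairwiseMatrix("cpAAI", list(alignment.taxa), values,
                          support=support, unreliable=unreliable)


# --------------------------------------------------------------------------
# Hit tables (12-column tabular search output)
# --------------------------------------------------------------------------

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class HitTable:
    """All-vs-all protein search hits between one ordered genome pair."""

    query_genome: str
    subject_genome: str
    hits: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.hits.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        if len(self.hits):
            pid = self.hits["pident"]
            if pid.min() < 0 or pid.max() > 100:
                raise ValueError("pident outside [0, 100]")
            if (self.hits["length"] < 1).any():
                raise ValueError("alignment length < 1")
            ev = self.hits["evalue"]
            if (ev.dropna() < 0).any():
                raise ValueError("negative e-value")

    def __len__(self) -> int:
        return len(self.hits)


def read_hit_table(path: str | Path, query_genome: str,
                   subject_genome: str) -> HitTable:
    """Read 12-column tab-separated search output (BLAST/DIAMOND outfmt 6)."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None,
                     comment="#")
    return HitTable(query_genome, subject_genome, df)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    table.hits.to_csv(path, sep="\t", header=False, index=False,
                      columns=HIT_COLUMNS)


@dataclass
class Proteome:
    """All predicted proteins of one genome."""

    genome_id: str
    proteins: list[SeqRecord]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError(f"proteome {self.genome_id!r}: duplicate protein ids")

    @property
    def T(self) -> int:
        return len(self.proteins)

    def lengths(self) -> dict[str, int]:
        return {p.id: len(p.sequence) for p in self.proteins}


# --------------------------------------------------------------------------
# wpAAI
# --------------------------------------------------------------------------

@dataclass
class WpaaiThresholds:
    """Ortholog acceptance criteria for whole-proteome AAI.

    A hit qualifies when e-value < ``max_evalue``, identity > ``min_identity``
    percent and alignment length > ``min_coverage`` of the query protein.
    ``ignore_evalue`` admits tables without meaningful e-values (e.g. from
    the built-in aligner, which emits no e-value statistics).
    """

    max_evalue: float = 1e-3
    min_identity: float = 30.0
    min_coverage: float = 0.70
    ignore_evalue: bool = False


@dataclass
class PocpThresholds:
    """Conserved-protein criteria for POCP (identity > 40 %, coverage > 50 %)."""

    max_evalue: float = 1e-5
    min_identity: float = 40.0
    min_coverage: float = 0.50
    ignore_evalue: bool = False


def _qualifying(table: HitTable, lengths: dict[str, int], max_evalue: float,
                min_identity: float, min_coverage: float,
                ignore_evalue: bool) -> pd.DataFrame:
    df = table.hits
    qlen = df["qseqid"].map(lengths)
    if qlen.isna().any():
        unknown = sorted(df.loc[qlen.isna(), "qseqid"].unique())[:3]
        raise ValueError(f"hits reference unknown query proteins, e.g. {unknown}")
    mask = (df["pident"] > min_identity) & (df["length"] > min_coverage * qlen)
    if not ignore_evalue:
        mask &= df["evalue"] < max_evalue
    return df[mask]


def _best_hits(df: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: highest bitscore, ties by e-value then id."""
    if not len(df):
        return {}
    ranked = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
    )
    firsts = ranked.drop_duplicates("qseqid", keep="first")
    return dict(zip(firsts["qseqid"], firsts["sseqid"]))


@dataclass(frozen=True)
class OrthologPair:
    protein_a: str
    protein_b: str
    identity: float  # mean of the two directional identities


def reciprocal_best_hits(ab: HitTable, ba: HitTable,
                         proteome_a: Proteome, proteome_b: Proteome,
                         thresholds: WpaaiThresholds | None = None
                         ) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    ``(p, q)`` is an ortholog pair iff ``q`` is ``p``'s best qualifying hit
    in the A->B table and ``p`` is ``q``'s best qualifying hit in B->A, where
    qualifying means e-value, identity and query-coverage thresholds are all
    met in that direction.
    """
    thresholds = thresholds or WpaaiThresholds()
    if (ab.query_genome, ab.subject_genome) != (ba.subject_genome, ba.query_genome):
        raise ValueError(
            f"hit tables are not opposite directions of one pair: "
            f"{ab.query_genome}->{ab.subject_genome} vs "
            f"{ba.query_genome}->{ba.subject_genome}"
        )
    if {ab.query_genome, ab.subject_genome} != {proteome_a.genome_id, proteome_b.genome_id}:
        raise ValueError("proteome labels do not match hit-table genomes")
    if proteome_a.genome_id != ab.query_genome:
        proteome_a, proteome_b = proteome_b, proteome_a

    t = thresholds
    fwd = _qualifying(ab, proteome_a.lengths(), t.max_evalue, t.min_identity,
                      t.min_coverage, t.ignore_evalue)
    rev = _qualifying(ba, proteome_b.lengths(), t.max_evalue, t.min_identity,
                      t.min_coverage, t.ignore_evalue)
    best_fwd = _best_hits(fwd)
    best_rev = _best_hits(rev)

    fwd_ident = {(q, s): i for q, s, i in
                 zip(fwd["qseqid"], fwd["sseqid"], fwd["pident"])}
    rev_ident = {(q, s): i for q, s, i in
                 zip(rev["qseqid"], rev["sseqid"], rev["pident"])}

    pairs = []
    for p, q in sorted(best_fwd.items()):
        if best_rev.get(q) == p:
            ident = (fwd_ident[(p, q)] + rev_ident[(q, p)]) / 2.0
            pairs.append(OrthologPair(p, q, float(ident)))
    return pairs


def wpaai(pairs: Sequence[OrthologPair]) -> float:
    """Whole-proteome AAI: unweighted mean RBH identity (NaN when no pairs)."""
    if not pairs:
        logger.warning("wpAAI undefined: no ortholog pairs")
        return float("nan")
    return float(np.mean([p.identity for p in pairs]))


# --------------------------------------------------------------------------
# POCP
# --------------------------------------------------------------------------

def pocp(ab: HitTable, ba: HitTable,
         proteome_a: Proteome, proteome_b: Proteome,
         thresholds: PocpThresholds | None = None) -> float:
    """Percentage of conserved proteins between two genomes.

    ``C1`` counts proteins of A with at least one qualifying hit in B
    (e-value < 1e-5, identity > 40 %, alignment length > 50 % of the query
    protein length); ``C2`` symmetrically; the result is
    ``100 * (C1 + C2) / (T1 + T2)``.
    """
    thresholds = thresholds or PocpThresholds()
    if proteome_a.T < 1 or proteome_b.T < 1:
        raise ValueError("empty proteome")
    if (ab.query_genome, ab.subject_genome) != (ba.subject_genome, ba.query_genome):
        raise ValueError("hit tables are not opposite directions of one pair")
    if proteome_a.genome_id != ab.query_genome:
        proteome_a, proteome_b = proteome_b, proteome_a

    t = thresholds
    c1 = _qualifying(ab, proteome_a.lengths(), t.max_evalue, t.min_identity,
                     t.min_coverage, t.ignore_evalue)["qseqid"].nunique()
    c2 = _qualifying(ba, proteome_b.lengths(), t.max_evalue, t.min_identity,
                     t.min_coverage, t.ignore_evalue)["qseqid"].nunique()
    return 100.0 * (c1 + c2) / (proteome_a.T + proteome_b.T)


# --------------------------------------------------------------------------
# GANTC density
# --------------------------------------------------------------------------

@dataclass
class GantcReport:
    """Genomic frequency of the CcrM methylation motif GANTC."""

    genome_id: str
    site_count: int
    total_length: int

    @property
    def sites_per_kb(self) -> float:
        return 1000.0 * self.site_count / self.total_length


# Overlapping occurrences counted via lookahead; the middle position admits
# 'N' (an unknown base is still potentially a site), the outer four do not.
_GANTC = re.compile(r"(?=GA[ACGTN]TC)")


def gantc_frequency(genome: GenomeAssembly) -> GantcReport:
    """Count GANTC motifs per kb, forward strand only.

    GANTC is self-complementary, so a one-strand scan covers both strands.
    """
    if not genome.contigs or genome.total_length < 5:
        raise ValueError(f"genome {genome.genome_id!r}: too short to scan")
    count = sum(len(_GANTC.findall(c.sequence)) for c in genome.contigs)
    return GantcReport(genome.genome_id, count, genome.total_length)


# --------------------------------------------------------------------------
# Built-in protein aligner / hit-table generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalAlignment:
    """One optimal Smith-Waterman local alignment."""

    score: float
    identity: float          # matches / alignment columns x 100
    length: int              # alignment columns
    q_start: int             # 0-based half-open, query
    q_end: int
    s_start: int             # 0-based half-open, subject
    s_end: int
    mismatches: int
    gap_opens: int


def local_align(a: str, b: str,
                params: SearchParams | None = None) -> LocalAlignment | None:
    """Optimal local alignment of two proteins (BLOSUM62, affine gaps).

    Returns ``None`` when no alignment scores above zero.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    params = params or SearchParams()
    sub = _substitution_matrix(params.matrix)
    alns = balign.align_optimal(
        _as_protein(a), _as_protein(b), sub,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=True, max_number=1,
    )
    if not alns or alns[0].trace.shape[0] == 0:
        return None
    aln = alns[0]
    matches, columns = _align_stats(aln)
    codes = balign.get_codes(aln)
    in_both = (codes[0] != -1) & (codes[1] != -1)
    mismatches = int(np.count_nonzero(in_both)) - matches
    gaps = ~in_both
    gap_opens = int(np.count_nonzero(gaps & ~np.concatenate(([False], gaps[:-1]))))
    return LocalAlignment(
        score=float(aln.score),
        identity=100.0 * matches / columns,
        length=columns,
        q_start=int(aln.trace[0, 0]),
        q_end=int(aln.trace[-1, 0]) + 1,
        s_start=int(aln.trace[0, 1]),
        s_end=int(aln.trace[-1, 1]) + 1,
        mismatches=mismatches,
        gap_opens=gap_opens,
    )


def all_vs_all_hits(proteome_a: Proteome, proteome_b: Proteome,
                    params: SearchParams | None = None) -> HitTable:
    """Generate a hit table by exhaustive pairwise local alignment.

    Intended for small or synthetic proteomes; emits no e-value (NaN), so
    downstream thresholds must run with ``ignore_evalue=True``.
    """
    params = params or SearchParams()
    rows = []
    for p in proteome_a.proteins:
        for q in proteome_b.proteins:
            aln = local_align(p.sequence, q.sequence, params)
            if aln is None:
                continue
            rows.append({
                "qseqid": p.id, "sseqid": q.id,
                "pident": round(aln.identity, 3), "length": aln.length,
                "mismatch": aln.mismatches, "gapopen": aln.gap_opens,
                "qstart": aln.q_start + 1, "qend": aln.q_end,
                "sstart": aln.s_start + 1, "send": aln.s_end,
                "evalue": float("nan"), "bitscore": aln.score,
            })
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HitTable(proteome_a.genome_id, proteome_b.genome_id, df)
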