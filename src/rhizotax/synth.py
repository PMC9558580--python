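"""Synthetic data: trees, evolved marker proteins, assemblies with planted genes.

Desk-scale stand-in for a real multi-genome dataset.  Taxa are related by a
Yule tree; marker proteins evolve along it under a 20-state equal-rates
(Poisson) substitution model, chosen over an empirical matrix because it has
a closed-form expected pairwise identity,

    P_identity(d) = 1/20 + (19/20) * exp(-(20/19) * d),

for taxa separated by path distance ``d`` substitutions/site — which is what
lets parameter-recovery tests compare a measured cpAAI against truth.
Proteins are back-translated with uniformly drawn synonymous codons and
embedded, on either strand, in i.i.d. random background contigs of a
configured GC content; exact coordinates are recorded as ground truth.

No indels by default, so reference placement is exactly invertible; realism
is secondary to testability here.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .markers import Marker, MarkerSet, reverse_complement
from .seqio import AMINO_ACIDS, GenomeAssembly, SeqRecord

logger = logging.getLogger("rhizotax")

_N_STATES = 20
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    ``tree_depth`` is the mean root-to-tip path length in expected
    substitutions/site after rescaling the Yule tree; pairwise distances are
    then of order ``2 * tree_depth`` for taxa on opposite sides of the root.
    """

    n_taxa: int = 8
    n_markers: int = 170
    marker_length_range: tuple[int, int] = (100, 500)
    tree_depth: float = 0.1
    gc: float = 0.6                     # rhizobial genomes are GC-rich
    n_contigs: int = 2
    contig_length_range: tuple[int, int] = (20_000, 30_000)
    translation_table: int = 11
    forward_only: bool = False
    #: per-leaf probability that a marker receives one indel (robustness
    #: testing only; breaks exact closed-form identity bookkeeping)
    indel_rate: float = 0.0
    #: geometric mean length of an indel, residues
    indel_mean_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_markers < 1 or self.n_contigs < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if self.tree_depth < 0:
            raise ValueError("tree_depth must be non-negative")
        if not (0 <= self.indel_rate <= 1):
            raise ValueError("indel_rate must be in [0, 1]")


# --------------------------------------------------------------------------
# Trees
# --------------------------------------------------------------------------

def sample_tree(n_taxa: int, seed: int, depth: float = 0.1) -> dendropy.Tree:
    """Sample a Yule (pure-birth, rate 1) tree and rescale its depth.

    Branch lengths are multiplied by one constant so the mean root-to-tip
    path length equals ``depth`` (expected substitutions/site).  Leaves are
    labelled ``T01..Tnn``.  Fully reproducible for a fixed seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = _random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"T{i + 1:02d}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=rng,
    )
    tree.is_rooted = True
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    mean_depth = float(np.mean(depths))
    scale = depth / mean_depth if mean_depth > 0 else 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def path_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf labels and the matrix of pairwise path lengths (subst/site)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return labels, d


# --------------------------------------------------------------------------
# Substitution model
# --------------------------------------------------------------------------

def expected_identity(d: float | np.ndarray) -> float | np.ndarray:
    """Expected fraction of identical sites at path distance ``d``.

    Closed form for the 20-state equal-rates model:
    ``1/20 + (19/20) * exp(-(20/19) * d)``; 1 at d=0, 1/20 as d -> inf.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    p = 1.0 / _N_STATES + (1.0 - 1.0 / _N_STATES) * np.exp(
        -(_N_STATES / (_N_STATES - 1.0)) * d
    )
    return float(p) if p.ndim == 0 else p


def _evolve_branch(parent: np.ndarray, t: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One branch of the equal-rates (Poisson) process, vectorized over sites.

    With event probability 1 - exp(-(20/19) t) a site is redrawn uniformly
    over all 20 residues (a redraw may restore the parent residue).  This is
    the exact marginal of the equal-rates Markov chain, so branch effects
    compose along root-to-tip paths and pairwise identity follows
    :func:`expected_identity` of the path distance.
    """
    p_hit = 1.0 - np.exp(-(_N_STATES / (_N_STATES - 1.0)) * t)
    child = parent.copy()
    hit = np.nonzero(rng.random(parent.size) < p_hit)[0]
    if hit.size:
        child[hit] = _AA[rng.integers(0, _N_STATES, size=hit.size)]
    return child


def _maybe_indel(protein: str, config: SimulationConfig,
                 rng: np.random.Generator) -> str:
    """Optionally apply one geometric-length insertion or deletion.

    Robustness-testing aid: with probability ``indel_rate`` the protein gets
    one internal indel of geometric length (mean ``indel_mean_length``).
    The no-indel default keeps reference placement exactly invertible.
    """
    if rng.random() >= config.indel_rate or len(protein) < 10:
        return protein
    k = 1 + int(rng.geometric(1.0 / max(config.indel_mean_length, 1.0)) - 1)
    k = min(k, len(protein) // 4)
    pos = int(rng.integers(1, len(protein) - k))
    if rng.random() < 0.5:
        return protein[:pos] + protein[pos + k:]            # deletion
    ins = _AA[rng.integers(0, _N_STATES, size=k)].tobytes().decode()
    return protein[:pos] + ins + protein[pos:]              # insertion


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    tree: dendropy.Tree
    taxa: list[str]
    distances: np.ndarray            # substitutions/site, path sums
    marker_lengths: list[int]
    partition: list[list[str]] | None = None
    coordinates: dict[str, list["PlantedMarker"]] = field(default_factory=dict)

    @property
    def expected_identity_matrix(self) -> np.ndarray:
        """100 x P_identity(d) with a diagonal of 100."""
        e = 100.0 * expected_identity(self.distances)
        np.fill_diagonal(e, 100.0)
        return e


def evolve_markers(tree: dendropy.Tree, config: SimulationConfig
                   ) -> tuple[dict[str, list[str]], GroundTruth]:
    """Evolve ``n_markers`` protein families down the tree.

    Root sequences are uniform over the 20 residues; marker lengths are
    drawn once (shared by all taxa — single-copy orthologs, no indels).
    Returns per-taxon protein lists in marker order plus the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.marker_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_markers).tolist()
    total = int(sum(lengths))

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = _AA[rng.integers(0, _N_STATES, size=total)]
    per_taxon: dict[str, list[str]] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length or 0.0
            seqs[id(node)] = _evolve_branch(seqs[id(node.parent_node)], t, rng)
        if node.is_leaf():
            concat = seqs[id(node)].tobytes().decode()
            parts, off = [], 0
            for L in lengths:
                parts.append(concat[off:off + L])
                off += L
            if config.indel_rate > 0:
                parts = [_maybe_indel(p, config, rng) for p in parts]
            per_taxon[node.taxon.label] = parts

    labels, dmat = path_distances(tree)
    truth = GroundTruth(tree=tree, taxa=labels, distances=dmat,
                        marker_lengths=lengths)
    return per_taxon, truth


# --------------------------------------------------------------------------
# Assemblies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMarker:
    """Where one marker's CDS ended up in a simulated assembly."""

    marker_id: str
    contig_id: str
    strand: str
    nt_start: int   # 0-based half-open, forward strand, protein codons only
    nt_end: int


def _back_translate(protein: str, rng: np.random.Generator,
                    table: int = 11) -> str:
    t = CodonTable.unambiguous_dna_by_id[table]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in t.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for codons in by_aa.values():
        codons.sort()
    out = []
    for aa in protein:
        codons = by_aa[aa]
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def _random_background(length: int, gc: float,
                       rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def build_assemblies(proteins: dict[str, list[str]],
                     config: SimulationConfig,
                     marker_ids: Sequence[str] | None = None
                     ) -> tuple[dict[str, GenomeAssembly],
                                dict[str, list[PlantedMarker]]]:
    """Embed back-translated marker CDSs in random-background contigs.

    Each protein is back-translated with uniformly chosen synonymous codons
    (standard bacterial/archaeal code by default), given an ATG start codon
    and a stop codon, and planted at a uniformly chosen non-overlapping
    offset on a uniformly chosen strand.  Recorded coordinates cover the
    protein codons only, so translating ``contig[nt_start:nt_end]``
    (reverse-complemented for '-' plants) reproduces the protein exactly.
    """
    rng = np.random.default_rng((config.seed + 1) * 7919)
    if marker_ids is None:
        n = len(next(iter(proteins.values())))
        marker_ids = [f"M{i + 1:03d}" for i in range(n)]
    stop_codons = CodonTable.unambiguous_dna_by_id[
        config.translation_table].stop_codons

    assemblies: dict[str, GenomeAssembly] = {}
    planted: dict[str, list[PlantedMarker]] = {}
    for taxon in sorted(proteins):
        lo, hi = config.contig_length_range
        contig_lengths = rng.integers(lo, hi + 1, size=config.n_contigs)
        contigs = [
            list(_random_background(int(L), config.gc, rng))
            for L in contig_lengths
        ]
        # non-overlapping placement by rejection sampling
        occupied: list[list[tuple[int, int]]] = [[] for _ in contigs]
        records: list[PlantedMarker] = []
        for marker_id, protein in zip(marker_ids, proteins[taxon]):
            cds = _back_translate(protein, rng, config.translation_table)
            stop = stop_codons[rng.integers(0, len(stop_codons))]
            cassette = "ATG" + cds + stop
            placed = False
            for _ in range(200):
                ci = int(rng.integers(0, len(contigs)))
                L = len(contigs[ci])
                if L < len(cassette):
                    continue
                start = int(rng.integers(0, L - len(cassette) + 1))
                end = start + len(cassette)
                if any(s < end and start < e for s, e in occupied[ci]):
                    continue
                strand = "+" if config.forward_only else ("+", "-")[
                    int(rng.integers(0, 2))]
                insert = cassette if strand == "+" else reverse_complement(cassette)
                contigs[ci][start:end] = list(insert)
                occupied[ci].append((start, end))
                if strand == "+":
                    cds_start, cds_end = start + 3, end - 3
                else:
                    cds_start, cds_end = start + 3, end - 3
                records.append(PlantedMarker(
                    marker_id=marker_id,
                    contig_id=f"{taxon}_c{ci + 1}",
                    strand=strand,
                    nt_start=cds_start,
                    nt_end=cds_end,
                ))
                placed = True
                break
            if not placed:
                raise ValueError(
                    "contigs too short to host all markers; increase "
                    "contig_length_range or n_contigs"
                )
        assemblies[taxon] = GenomeAssembly(
            taxon,
            [SeqRecord(f"{taxon}_c{i + 1}", "".join(c))
             for i, c in enumerate(contigs)],
        )
        planted[taxon] = records
    return assemblies, planted


# --------------------------------------------------------------------------
# Reference marker sets and whole datasets
# --------------------------------------------------------------------------

def reference_marker_set(proteins: dict[str, list[str]],
                         reference_taxa: Sequence[str],
                         marker_ids: Sequence[str] | None = None) -> MarkerSet:
    """Build a marker set from the proteins of designated reference taxa.

    With no indels every ortholog of a marker has the same length, so the
    reference "alignment" is simply the stacked reference rows.
    """
    if not reference_taxa:
        raise ValueError("need at least one reference taxon")
    n = len(proteins[reference_taxa[0]])
    if marker_ids is None:
        marker_ids = [f"M{i + 1:03d}" for i in range(n)]
    markers = []
    for k, marker_id in enumerate(marker_ids):
        rows = [SeqRecord(taxon, proteins[taxon][k]) for taxon in reference_taxa]
        markers.append(Marker(marker_id, rows))
    return MarkerSet(markers)


@dataclass
class SyntheticDataset:
    """A complete simulated study: assemblies, markers, tree, truth."""

    config: SimulationConfig
    assemblies: dict[str, GenomeAssembly]
    marker_set: MarkerSet
    proteins: dict[str, list[str]]
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig,
                     n_reference_taxa: int = 2,
                     partition: list[list[str]] | None = None
                     ) -> SyntheticDataset:
    """Run the whole generator: tree -> proteins -> assemblies -> references."""
    tree = sample_tree(config.n_taxa, config.seed, config.tree_depth)
    proteins, truth = evolve_markers(tree, config)
    assemblies, planted = build_assemblies(proteins, config)
    truth.coordinates = planted
    truth.partition = partition
    reference_taxa = truth.taxa[:n_reference_taxa]
    marker_set = reference_marker_set(proteins, reference_taxa)
    return SyntheticDataset(config, assemblies, marker_set, proteins, truth)


# --------------------------------------------------------------------------
# Planted-partition scenarios used by recovery tests
# --------------------------------------------------------------------------

def genus_forest_tree(group_sizes: Sequence[int], within_depth: float,
                      between_extra: float, seed: int) -> dendropy.Tree:
    """A tree of several clades with controlled within/between divergence.

    Each clade (genus) is a rescaled Yule tree of depth ``within_depth``;
    clades hang off the root on stem branches of length ``between_extra/2``
    each, so between-clade path distances exceed within-clade ones by about
    ``between_extra``.  Leaves of group *k* are labelled with the letter
    prefix A, B, C, ...
    """
    if len(group_sizes) < 2:
        raise ValueError("need at least two groups")
    prefixes = [chr(ord("A") + k) for k in range(len(group_sizes))]
    labels = [f"{p}{i + 1:02d}" for p, n in zip(prefixes, group_sizes)
              for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    rng = _random.Random(seed)

    def clade(sub_labels: list[str]) -> dendropy.Node:
        if len(sub_labels) == 1:
            node = dendropy.Node(edge_length=within_depth)
            node.taxon = taxa.get_taxon(sub_labels[0])
            return node
        sub = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0,
            num_extant_tips=len(sub_labels),
            taxon_namespace=dendropy.TaxonNamespace(sub_labels), rng=rng,
        )
        depths = [l.distance_from_root() for l in sub.leaf_node_iter()]
        scale = within_depth / float(np.mean(depths))
        for edge in sub.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
        for leaf in sub.leaf_node_iter():
            leaf.taxon = taxa.get_taxon(leaf.taxon.label)
        root = sub.seed_node
        root.edge.length = 0.0
        return root

    root = dendropy.Node()
    off = 0
    for n in group_sizes:
        child = clade(labels[off:off + n])
        child.edge.length = (child.edge.length or 0.0) + between_extra / 2.0
        root.add_child(child)
        off += n
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


def two_genus_tree(n_a: int, n_b: int, within_depth: float,
                   between_extra: float, seed: int) -> dendropy.Tree:
    """Two-clade special case of :func:`genus_forest_tree`."""
    return genus_forest_tree([n_a, n_b], within_depth, between_extra, seed)


def simulate_partitioned_dataset(group_sizes: Sequence[int],
                                 within_depth: float,
                                 between_extra: float,
                                 config: SimulationConfig,
                                 n_reference_taxa: int = 2
                                 ) -> SyntheticDataset:
    """Simulate a study with a planted genus partition.

    ``within_depth`` and ``between_extra`` (substitutions/site) control the
    within- and between-genus divergence; identities follow
    :func:`expected_identity` of the resulting path distances.  The planted
    partition is recorded in the ground truth.
    """
    if sum(group_sizes) != config.n_taxa:
        raise ValueError("group sizes must sum to n_taxa")
    tree = genus_forest_tree(group_sizes, within_depth, between_extra,
                             config.seed)
    proteins, truth = evolve_markers(tree, config)
    assemblies, planted = build_assemblies(proteins, config)
    truth.coordinates = planted
    prefixes = sorted({t[0] for t in truth.taxa})
    truth.partition = [[t for t in truth.taxa if t.startswith(p)]
                       for p in prefixes]
    reference_taxa = truth.taxa[:n_reference_taxa]
    marker_set = reference_marker_set(proteins, reference_taxa)
    return SyntheticDataset(config, assemblies, marker_set, proteins, truth)
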