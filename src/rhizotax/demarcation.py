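"""Genus demarcation from OGRI distributions and a core-genome phylogeny.

The framework: genera are monophyletic groups in a rooted core-genome tree
whose members share pairwise cpAAI at or above a threshold (default 86 %)
while all comparisons against outside taxa fall below it.  Because nearly
every biological rule has exceptions, clades that stay above the threshold
are never split automatically — a split must be requested as an explicit
override carrying its justification, which is propagated into the reports.

``gap_scan`` locates candidate thresholds as empty (or near-empty) runs of
bins in the histogram of all pairwise values, the same evidence used to pick
the 86 % default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .seqio import PairwiseMatrix

logger = logging.getLogger("rhizotax")

# --------------------------------------------------------------------------
# Histogram gap scan
# --------------------------------------------------------------------------

@dataclass
class GapScanConfig:
    """Binning rules for the OGRI histogram scan.

    Bin edges sit at multiples of ``bin_width`` (percent); a "gap" is a
    maximal run of interior bins whose count is at most ``max_count``.
    """

    bin_width: float = 0.5
    max_count: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.max_count < 0:
            raise ValueError("max_count must be non-negative")


@dataclass(frozen=True)
class GapInterval:
    """A low-density interval of the pairwise-value distribution."""

    low: float
    high: float
    n_inside: int
    left_count: int   # count of the occupied bin flanking below
    right_count: int  # count of the occupied bin flanking above

    @property
    def midpoint(self) -> float:
        return (self.low + self.high) / 2.0


def gap_scan(values: Sequence[float],
             config: GapScanConfig | None = None) -> list[GapInterval]:
    """Find low-density runs in a histogram of pairwise OGRI values.

    Bins of width ``bin_width`` anchored at 0 cover the observed range;
    every maximal run of bins with count <= ``max_count`` lying strictly
    between occupied bins is returned, ordered by lower bound.  Values that
    all fall in one bin produce no gaps.
    """
    config = config or GapScanConfig()
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size < 2:
        raise ValueError("gap scan needs at least two values")
    w = config.bin_width
    lo_bin = int(np.floor(vals.min() / w))
    hi_bin = int(np.floor(vals.max() / w))
    edges = np.arange(lo_bin, hi_bin + 2) * w
    counts, _ = np.histogram(vals, bins=edges)

    occupied = np.nonzero(counts > config.max_count)[0]
    if occupied.size == 0:
        return []
    gaps: list[GapInterval] = []
    first, last = occupied[0], occupied[-1]
    i = first + 1
    while i <= last:
        if counts[i] <= config.max_count:
            j = i
            while counts[j + 1] <= config.max_count:
                j += 1
            gaps.append(GapInterval(
                low=float(edges[i]),
                high=float(edges[j + 1]),
                n_inside=int(counts[i:j + 1].sum()),
                left_count=int(counts[i - 1]),
                right_count=int(counts[j + 1]),
            ))
            i = j + 2
        else:
            i += 1
    return gaps


# --------------------------------------------------------------------------
# Monophyly
# --------------------------------------------------------------------------

def _tree_leafsets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label set of every node's clade, leaves included."""
    sets: dict[int, frozenset[str]] = {}
    out = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.child_nodes()))
        sets[id(node)] = s
        out.append(s)
    return out


def is_monophyletic(tree: dendropy.Tree, leaves: Iterable[str]) -> bool:
    """True iff ``leaves`` is exactly the clade of some node of the rooted tree."""
    target = frozenset(leaves)
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = target - all_leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if not target:
        raise ValueError("empty leaf set")
    return target in set(_tree_leafsets(tree))


# --------------------------------------------------------------------------
# Clade reports
# --------------------------------------------------------------------------

@dataclass
class Override:
    """An explicit, justified exception to the threshold rule."""

    action: str             # 'force_split' or 'force_merge'
    leaves: frozenset[str]  # clade the override applies to
    justification: str

    def __post_init__(self) -> None:
        if self.action not in ("force_split", "force_merge"):
            raise ValueError(f"unknown override action {self.action!r}")
        if not self.justification.strip():
            raise ValueError("an override requires a justification")


@dataclass
class DemarcationConfig:
    """Threshold and override policy for genus proposals.

    ``threshold`` is inclusive: a pairwise value exactly at the threshold
    counts as within-genus.  Reports whose decisive value falls within
    ``warn_band`` of the threshold are flagged borderline, reflecting that
    the threshold is approximate and per-genus flexibility is expected.
    """

    threshold: float = 86.0
    warn_band: float = 1.0
    overrides: list[Override] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 100):
            raise ValueError("threshold must be in (0, 100)")


@dataclass
class CladeReport:
    """Within/between cpAAI summary for one clade of the tree."""

    node_id: int
    members: list[str]
    min_within: float      # NaN for singletons
    max_between: float     # NaN when the clade is the whole tree
    status: str            # consistent_genus | supra_threshold | sub_threshold_within | singleton
    borderline: bool = False
    override: Override | None = None


def _classify(min_within: float, max_between: float, n_members: int,
              config: DemarcationConfig) -> tuple[str, bool]:
    t = config.threshold
    if n_members == 1:
        status = "singleton"
        if np.isfinite(max_between) and max_between >= t:
            status = "supra_threshold"
        decisive = max_between
    elif np.isfinite(max_between) and max_between >= t:
        status = "supra_threshold"
        decisive = max_between
    elif np.isfinite(min_within) and min_within < t:
        status = "sub_threshold_within"
        decisive = min_within
    else:
        status = "consistent_genus"
        decisive = min_within
    borderline = bool(np.isfinite(decisive) and abs(decisive - t) <= config.warn_band)
    return status, borderline


def clade_reports(tree: dendropy.Tree, matrix: PairwiseMatrix,
                  config: DemarcationConfig | None = None) -> list[CladeReport]:
    """Summarize every clade of the tree against the cpAAI threshold.

    For each node (leaves included, as singletons): ``min_within`` is the
    minimum pairwise value among members, ``max_between`` the maximum value
    between a member and any non-member of the whole taxon set (stricter
    than sister-clade-only).  Status is ``consistent_genus`` iff all within
    values reach the threshold and all between values stay below it.
    """
    config = config or DemarcationConfig()
    tree_leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(tree_leaves) - set(matrix.taxa)
    if missing:
        raise ValueError(f"tree leaves missing from matrix: {sorted(missing)}")
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    n_all = len(tree_leaves)

    reports = []
    for node_id, node in enumerate(tree.preorder_node_iter()):
        members = sorted(l.taxon.label for l in node.leaf_iter())
        mi = np.array([idx[m] for m in members])
        others = np.array([idx[t] for t in tree_leaves if t not in set(members)])
        if len(members) > 1:
            sub = matrix.values[np.ix_(mi, mi)]
            iu = np.triu_indices(len(members), k=1)
            within = sub[iu]
            min_within = float(np.nanmin(within)) if within.size else float("nan")
        else:
            min_within = float("nan")
        if others.size:
            between = matrix.values[np.ix_(mi, others)]
            max_between = float(np.nanmax(between)) if between.size else float("nan")
        else:
            max_between = float("nan")
        status, borderline = _classify(min_within, max_between, len(members), config)
        reports.append(CladeReport(node_id, members, min_within, max_between,
                                   status, borderline))
    return reports


# --------------------------------------------------------------------------
# Genus proposals
# --------------------------------------------------------------------------

@dataclass
class GenusProposal:
    """A partition of the taxa into candidate genera."""

    partition: list[list[str]]
    reports: list[CladeReport]
    applied_overrides: list[Override]
    flagged_singletons: list[str]

    @property
    def n_genera(self) -> int:
        return len(self.partition)


def _report_for(node: dendropy.Node, matrix: PairwiseMatrix,
                tree_leaves: list[str], config: DemarcationConfig) -> CladeReport:
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    members = sorted(l.taxon.label for l in node.leaf_iter())
    mi = np.array([idx[m] for m in members])
    others = np.array([idx[t] for t in tree_leaves if t not in set(members)])
    if len(members) > 1:
        sub = matrix.values[np.ix_(mi, mi)]
        within = sub[np.triu_indices(len(members), k=1)]
        min_within = float(np.nanmin(within)) if within.size else float("nan")
    else:
        min_within = float("nan")
    max_between = (float(np.nanmax(matrix.values[np.ix_(mi, others)]))
                   if others.size else float("nan"))
    status, borderline = _classify(min_within, max_between, len(members), config)
    return CladeReport(-1, members, min_within, max_between, status, borderline)


def propose_genera(tree: dendropy.Tree, matrix: PairwiseMatrix,
                   config: DemarcationConfig | None = None) -> GenusProposal:
    """Propose a tree-consistent genus partition under the cpAAI threshold.

    Recursing from the root, the shallowest clade whose report is
    ``consistent_genus`` becomes a genus; inconsistent clades recurse into
    their children.  Leaves reached without ever joining a consistent clade
    become singleton genera flagged for expert review.  ``force_split``
    overrides replace a supra-threshold clade by its child clades;
    ``force_merge`` accepts a clade as one genus despite sub-threshold
    within values.  Overrides must name monophyletic leaf sets.
    """
    config = config or DemarcationConfig()
    tree_leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(tree_leaves) - set(matrix.taxa)
    if missing:
        raise ValueError(f"tree leaves missing from matrix: {sorted(missing)}")

    clade_sets = set(_tree_leafsets(tree))
    by_leafset: dict[frozenset[str], Override] = {}
    for ov in config.overrides:
        if ov.leaves not in clade_sets:
            raise ValueError(
                f"override names a non-monophyletic leaf set: {sorted(ov.leaves)}"
            )
        by_leafset[ov.leaves] = ov

    partition: list[list[str]] = []
    reports: list[CladeReport] = []
    applied: list[Override] = []
    flagged: list[str] = []

    def accept(node: dendropy.Node, report: CladeReport,
               override: Override | None = None) -> None:
        report.override = override
        partition.append(report.members)
        reports.append(report)
        if override is not None:
            applied.append(override)

    def descend(node: dendropy.Node) -> None:
        report = _report_for(node, matrix, tree_leaves, config)
        leafset = frozenset(report.members)
        override = by_leafset.get(leafset)
        if override is not None and override.action == "force_merge":
            accept(node, report, override)
            return
        if override is not None and override.action == "force_split":
            applied.append(override)
            report.override = override
            reports.append(report)
            for child in node.child_nodes():
                child_set = frozenset(l.taxon.label for l in child.leaf_iter())
                child_ov = by_leafset.get(child_set)
                if child_ov is not None and child_ov.action == "force_split":
                    descend(child)  # nested split
                else:
                    child_report = _report_for(child, matrix, tree_leaves, config)
                    child_report.override = override
                    partition.append(child_report.members)
                    reports.append(child_report)
            return
        if node.is_leaf():
            if report.status == "supra_threshold":
                # isolated lineage: above threshold with outside taxa, yet no
                # consistent clade ever contained it — needs expert review
                flagged.append(report.members[0])
            accept(node, report)
            return
        if report.status == "consistent_genus":
            accept(node, report)
            return
        reports.append(report)
        for child in node.child_nodes():
            descend(child)

    descend(tree.seed_node)

    covered = sorted(t for block in partition for t in block)
    assert covered == sorted(tree_leaves), "partition is not a cover"
    if flagged:
        logger.warning(
            "taxa not in any threshold-consistent clade, proposed as "
            "singletons for review: %s", flagged
        )
    return GenusProposal(partition, reports, applied, flagged)
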