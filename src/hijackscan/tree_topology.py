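"""Viral-cluster detection and depth statistics on family trees.

A *viral cluster* (VC) is a maximal sub-tree whose descendant leaves are
all viral proteins; each VC is taken as evidence of a single acquisition
episode from the host. A family in which the few viral members collapse
into one or two such clusters — or into at most ten clusters with a high
*condensation factor* (#viral / #VC) — is a candidate for a host-to-virus
transfer.

Depth is topological: the number of edges from the root (the root itself
has depth 0); branch lengths are ignored. The *normalized depth* of a leaf
or of a VC root is its depth divided by the maximum leaf depth of the same
tree, so a value near 1 marks a recent, terminal placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .io_model import ConsistencyError, ProteinRecord, RootedTree, TaxonClass, TreeNode

__all__ = [
    "ViralCluster",
    "SelectionThresholds",
    "TopologyReport",
    "DegenerateTreeError",
    "leaf_depths",
    "find_viral_clusters",
    "normalized_depth",
    "vc_depth",
    "classify_family",
]


class DegenerateTreeError(ValueError):
    """Raised when a depth statistic is undefined (single-leaf tree)."""


@dataclass(frozen=True)
class ViralCluster:
    """A maximal all-viral sub-tree: its root's node id, leaves and depth."""

    root_node: str
    leaf_ids: frozenset[str]
    depth: int


@dataclass
class SelectionThresholds:
    """Candidate-selection rule constants.

    A family is selected when it passes BOTH clauses:
      rarity   — viral fraction <= ``max_viral_fraction`` OR at most
                 ``max_viral_count_override`` viral leaves;
      clustering — at most ``max_vc_simple`` VCs OR at most
                 ``max_vc_condensed`` VCs with condensation factor
                 >= ``min_condensation``.
    """

    max_viral_fraction: float = 0.05
    max_viral_count_override: int = 2
    max_vc_simple: int = 2
    max_vc_condensed: int = 10
    min_condensation: float = 3.0

    def __post_init__(self):
        for name in (
            "max_viral_fraction",
            "max_viral_count_override",
            "max_vc_simple",
            "max_vc_condensed",
            "min_condensation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TopologyReport:
    family_id: str
    n_viral: int
    n_metazoan: int
    n_leaves: int
    viral_fraction: float
    n_vc: int
    condensation: float
    max_leaf_depth: int
    deepest_viral_depth: int
    deepest_viral_leaves: list[str]
    normalized_viral_depths: list[float]
    vc_normalized_depths: list[float]
    selected: bool
    selection_reason: str


def leaf_depths(tree: RootedTree) -> dict[str, int]:
    """Edge-count depth of every leaf; the root has depth 0."""
    return tree.leaf_depths()


def _taxon_of(leaf_label: str, records: dict[str, ProteinRecord]) -> TaxonClass:
    rec = records.get(leaf_label)
    if rec is None:
        raise ConsistencyError(f"tree leaf {leaf_label!r} has no protein record")
    return rec.taxon_class


def find_viral_clusters(
    tree: RootedTree, records: dict[str, ProteinRecord]
) -> list[ViralCluster]:
    """All maximal all-viral sub-trees, in preorder of their roots.

    The returned leaf sets are pairwise disjoint and their union is exactly
    the set of viral leaves; a lone viral leaf with a non-viral sibling is a
    cluster of size 1. If every leaf is viral the whole tree is one cluster.
    """
    pure: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            pure[id(node)] = _taxon_of(node.leaf_label, records) is TaxonClass.VIRUS
        else:
            pure[id(node)] = all(pure[id(c)] for c in node.children)

    depths = tree.node_depths()
    clusters = []
    for node in tree.preorder():
        if pure[id(node)] and (node.parent is None or not pure[id(node.parent)]):
            clusters.append(
                ViralCluster(node.node_id, tree.leaf_set(node), depths[node.node_id])
            )
    return clusters


def normalized_depth(tree: RootedTree, leaf: str) -> Fraction:
    """depth(leaf) / max leaf depth, as an exact fraction in (0, 1]."""
    depths = tree.leaf_depths()
    if leaf not in depths:
        raise KeyError(f"no leaf labeled {leaf!r}")
    max_depth = max(depths.values())
    if max_depth == 0:
        raise DegenerateTreeError("normalized depth undefined: maximum leaf depth is 0")
    return Fraction(depths[leaf], max_depth)


def vc_depth(tree: RootedTree, vc: ViralCluster) -> Fraction:
    """depth(VC root) / max leaf depth, as an exact fraction."""
    max_depth = tree.max_leaf_depth()
    if max_depth == 0:
        raise DegenerateTreeError("VC depth undefined: maximum leaf depth is 0")
    return Fraction(vc.depth, max_depth)


def classify_family(
    family_id: str,
    tree: RootedTree,
    records: dict[str, ProteinRecord],
    thresholds: Optional[SelectionThresholds] = None,
) -> TopologyReport:
    """Full topology report and candidate-selection verdict for one family."""
    thresholds = thresholds or SelectionThresholds()

    labels = tree.leaf_labels()
    taxa = {label: _taxon_of(label, records) for label in labels}
    viral = [l for l in labels if taxa[l] is TaxonClass.VIRUS]
    metazoan = [l for l in labels if taxa[l] is TaxonClass.METAZOA]
    if not viral:
        raise ValueError(
            f"family {family_id!r} has no viral leaves; it should have been filtered out"
        )

    n_viral = len(viral)
    n_leaves = len(labels)
    fraction = n_viral / n_leaves

    vcs = find_viral_clusters(tree, records)
    n_vc = len(vcs)
    condensation = n_viral / n_vc

    depths = tree.leaf_depths()
    max_depth = max(depths.values())
    deepest_viral = max(depths[l] for l in viral)
    deepest_leaves = sorted(l for l in viral if depths[l] == deepest_viral)
    if max_depth > 0:
        norm_viral = [depths[l] / max_depth for l in sorted(viral)]
        norm_vcs = [vc.depth / max_depth for vc in vcs]
    else:  # single-leaf tree cannot occur here (needs viral + metazoan)
        norm_viral, norm_vcs = [], []

    rarity = fraction <= thresholds.max_viral_fraction
    rarity_count = n_viral <= thresholds.max_viral_count_override
    clustering_simple = n_vc <= thresholds.max_vc_simple
    clustering_condensed = (
        n_vc <= thresholds.max_vc_condensed and condensation >= thresholds.min_condensation
    )
    selected = (rarity or rarity_count) and (clustering_simple or clustering_condensed)

    reasons = []
    if rarity:
        reasons.append(f"viral_fraction {fraction:.4f} <= {thresholds.max_viral_fraction}")
    if rarity_count:
        reasons.append(f"n_viral {n_viral} <= {thresholds.max_viral_count_override}")
    if not (rarity or rarity_count):
        reasons.append("rarity clause failed")
    if clustering_simple:
        reasons.append(f"n_vc {n_vc} <= {thresholds.max_vc_simple}")
    elif clustering_condensed:
        reasons.append(
            f"n_vc {n_vc} <= {thresholds.max_vc_condensed} "
            f"and condensation {condensation:.2f} >= {thresholds.min_condensation}"
        )
    else:
        reasons.append("clustering clause failed")

    return TopologyReport(
        family_id=family_id,
        n_viral=n_viral,
        n_metazoan=len(metazoan),
        n_leaves=n_leaves,
        viral_fraction=fraction,
        n_vc=n_vc,
        condensation=condensation,
        max_leaf_depth=max_depth,
        deepest_viral_depth=deepest_viral,
        deepest_viral_leaves=deepest_leaves,
        normalized_viral_depths=norm_viral,
        vc_normalized_depths=norm_vcs,
        selected=selected,
        selection_reason="; ".join(reasons),
    )
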