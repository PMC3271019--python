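"""Shared fixtures: small in-memory families and random-tree builders."""

from __future__ import annotations

import numpy as np
import pytest

from hijackscan.io_model import (
    Family,
    FamilyType,
    ProteinRecord,
    RootedTree,
    TaxonClass,
    TreeNode,
)


def make_record(pid, taxon=TaxonClass.METAZOA, length=100, species="Homo sapiens"):
    return ProteinRecord(pid, species, taxon, length)


def records_for(viral_ids, metazoan_ids, length=100):
    recs = {pid: make_record(pid, TaxonClass.VIRUS, length, "Some virus") for pid in viral_ids}
    recs.update({pid: make_record(pid, TaxonClass.METAZOA, length) for pid in metazoan_ids})
    return recs


def random_tree(rng: np.random.Generator, n_leaves: int, viral_prob: float = 0.4):
    """A random rooted binary tree plus records with random viral labels."""
    labels = [f"L{i}" for i in range(n_leaves)]
    if n_leaves == 1:
        root = TreeNode(leaf_label=labels[0])
    else:
        leaves = [TreeNode(leaf_label=labels[0]), TreeNode(leaf_label=labels[1])]
        root = TreeNode(children=list(leaves))
        for label in labels[2:]:
            target = leaves[int(rng.integers(len(leaves)))]
            a = TreeNode(leaf_label=target.leaf_label)
            b = TreeNode(leaf_label=label)
            target.leaf_label = None
            target.children = [a, b]
            leaves.remove(target)
            leaves.extend([a, b])
    tree = RootedTree(root)
    records = {}
    for label in labels:
        taxon = TaxonClass.VIRUS if rng.random() < viral_prob else TaxonClass.METAZOA
        records[label] = make_record(label, taxon)
    return tree, records


def caterpillar_depths(max_depth: int) -> RootedTree:
    """Caterpillar with one leaf at each depth 1..max_depth (two at the bottom).

    Internal chain I0 (root) .. I_{max_depth-1}; node I_k carries a leaf at
    depth k+1; the final internal node carries two leaves at max_depth.
    """
    bottom = TreeNode(
        children=[TreeNode(leaf_label=f"L{max_depth}"), TreeNode(leaf_label=f"L{max_depth}b")]
    )
    node = bottom
    for depth in range(max_depth - 1, 0, -1):
        node = TreeNode(children=[TreeNode(leaf_label=f"L{depth}"), node])
    return RootedTree(node)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_family():
    """Two viral + two metazoan proteins and a tree '((v1,v2),(m1,m2));'."""
    records = records_for(["v1", "v2"], ["m1", "m2"])
    tree = RootedTree.from_newick("((v1,v2),(m1,m2));")
    family = Family("FAM1", FamilyType.DOMAIN_FAMILY, set(records))
    return family, records, tree
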