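"""Synthetic cohorts of cross-taxa protein families with planted effects.

Each family is built from a canonical multi-domain metazoan architecture.
Metazoan members realize that architecture with linkers drawn from the
metazoan linker model; viral members are derived from it the way a
host-to-virus capture followed by trimming would leave them — each internal
domain is dropped independently with ``domain_loss_prob`` and all tails and
inter-domain linkers are redrawn from the (shorter) viral linker model.
The family tree places the viral leaves in exactly ``n_viral_clades``
clades grafted onto a metazoan backbone, so downstream clade detection has
an exact planted truth.

Default linker scales are the study conditions the analysis targets: mean
viral/metazoan TAIL of 14/85 aa and mean IDOL of 30/67 aa; linker lengths
are geometric by default (heavy at short lengths, as empirical linker
histograms are). Ground truth (planted means, clade counts, loss events)
is written to a separate JSON, never into the data files themselves.

Determinism: a fixed ``seed`` makes :func:`generate_cohort` byte-identical
across runs; family ``i`` uses the independent stream ``[seed, i]``.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .io_model import (
    DomainHit,
    Family,
    FamilyType,
    ProteinRecord,
    RootedTree,
    TaxonClass,
    TreeNode,
    write_domain_annotations,
    write_membership_table,
    write_tree,
)

__all__ = [
    "LinkerModel",
    "HostArchitectureModel",
    "TreeModel",
    "CohortParams",
    "FamilyData",
    "generate_family",
    "generate_cohort",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class LinkerModel:
    """Mean linker lengths (aa) per class and the sampling distribution."""

    metazoan_tail_mean: float = 85.0
    viral_tail_mean: float = 14.0
    metazoan_idol_mean: float = 67.0
    viral_idol_mean: float = 30.0
    distribution: str = "geometric"  # or "gamma"

    def __post_init__(self):
        for name in ("metazoan_tail_mean", "viral_tail_mean",
                     "metazoan_idol_mean", "viral_idol_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.distribution not in ("geometric", "gamma"):
            raise ValueError(f"unknown linker distribution {self.distribution!r}")


@dataclass
class HostArchitectureModel:
    """Canonical metazoan architecture: domain count and domain lengths (aa).

    The per-family domain count is Poisson around ``n_domains_mean`` (min 1)
    unless ``n_domains_fixed`` pins it — useful when a planted architecture
    must have internal domains in every family.
    """

    n_domains_mean: float = 3.0
    domain_length_mean: float = 120.0
    domain_length_spread: float = 25.0
    n_domains_fixed: Optional[int] = None

    def __post_init__(self):
        if self.n_domains_mean <= 0 or self.domain_length_mean <= 0:
            raise ValueError("architecture means must be positive")
        if self.n_domains_fixed is not None and self.n_domains_fixed < 1:
            raise ValueError("n_domains_fixed must be >= 1")


@dataclass
class TreeModel:
    n_viral_clades: int = 2
    topology: str = "yule"  # or "caterpillar"

    def __post_init__(self):
        if self.n_viral_clades < 1:
            raise ValueError("n_viral_clades must be >= 1")
        if self.topology not in ("yule", "caterpillar"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class CohortParams:
    """All knobs of a synthetic cohort; every random draw flows from ``seed``."""

    n_families: int = 100
    members_per_family: tuple[float, float] = (60.0, 3.0)  # (metazoan mean, viral mean)
    viral_fraction_target: float = 0.05
    cross_taxa_fraction: float = 1.0
    host_architecture: HostArchitectureModel = field(default_factory=HostArchitectureModel)
    linker_model: LinkerModel = field(default_factory=LinkerModel)
    domain_loss_prob: float = 0.15
    tree_model: TreeModel = field(default_factory=TreeModel)
    seed: int = 0
    with_sequences: bool = False

    def __post_init__(self):
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        meta_mean, viral_mean = self.members_per_family
        if meta_mean <= 0 or viral_mean <= 0:
            raise ValueError("member means must be positive")
        if not (0.0 <= self.domain_loss_prob <= 1.0):
            raise ValueError("domain_loss_prob must be in [0, 1]")
        if not (0.0 <= self.cross_taxa_fraction <= 1.0):
            raise ValueError("cross_taxa_fraction must be in [0, 1]")
        if not (0.0 < self.viral_fraction_target < 1.0):
            raise ValueError("viral_fraction_target must be in (0, 1)")


@dataclass
class FamilyData:
    """One generated family with its planted ground truth."""

    family: Family
    records: dict[str, ProteinRecord]
    hits: list[DomainHit]
    tree: Optional[RootedTree]
    truth: dict


def _draw_linker(rng: np.random.Generator, mean: float, distribution: str) -> int:
    """A non-negative integer linker length with the requested mean."""
    if mean <= 0:
        return 0
    if distribution == "geometric":
        # numpy's geometric has support {1, 2, ...} and mean 1/p;
        # shifting down one gives support {0, 1, ...} with the target mean.
        return int(rng.geometric(1.0 / (mean + 1.0))) - 1
    return int(round(rng.gamma(2.0, mean / 2.0)))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _build_protein(
    pid: str,
    species: str,
    taxon: TaxonClass,
    architecture: list[tuple[str, int]],
    tail_mean: float,
    idol_mean: float,
    distribution: str,
    rng: np.random.Generator,
    with_sequence: bool,
) -> tuple[ProteinRecord, list[DomainHit]]:
    n_tail = _draw_linker(rng, tail_mean, distribution)
    c_tail = _draw_linker(rng, tail_mean, distribution)
    idols = [_draw_linker(rng, idol_mean, distribution) for _ in range(len(architecture) - 1)]

    hits = []
    pos = n_tail + 1
    for i, (domain_id, dom_len) in enumerate(architecture):
        hits.append(DomainHit(pid, domain_id, pos, pos + dom_len - 1))
        pos += dom_len
        if i < len(idols):
            pos += idols[i]
    length = hits[-1].end + c_tail
    sequence = _random_sequence(rng, length) if with_sequence else None
    record = ProteinRecord(pid, species, taxon, length, sequence)
    return record, hits


def _yule_backbone(rng: np.random.Generator, labels: list[str]) -> TreeNode:
    """Random rooted binary tree over ``labels`` by successive leaf splits."""
    if len(labels) == 1:
        return TreeNode(leaf_label=labels[0], branch_length=1.0)
    leaves = [TreeNode(leaf_label=labels[0], branch_length=1.0),
              TreeNode(leaf_label=labels[1], branch_length=1.0)]
    root = TreeNode(children=list(leaves), branch_length=None)
    for label in labels[2:]:
        target = leaves[int(rng.integers(len(leaves)))]
        left = TreeNode(leaf_label=target.leaf_label, branch_length=1.0)
        right = TreeNode(leaf_label=label, branch_length=1.0)
        target.leaf_label = None
        target.children = [left, right]
        leaves.remove(target)
        leaves.extend([left, right])
    return root


def _caterpillar(labels: list[str], branch_length: float = 1.0) -> TreeNode:
    """Caterpillar (fully pectinate) tree: labels attach one per depth."""
    if len(labels) == 1:
        return TreeNode(leaf_label=labels[0], branch_length=branch_length)
    node = TreeNode(
        children=[
            TreeNode(leaf_label=labels[-2], branch_length=branch_length),
            TreeNode(leaf_label=labels[-1], branch_length=branch_length),
        ],
        branch_length=branch_length,
    )
    for label in reversed(labels[:-2]):
        node = TreeNode(
            children=[TreeNode(leaf_label=label, branch_length=branch_length), node],
            branch_length=branch_length,
        )
    node.branch_length = None
    return node


def _leaf_nodes(root: TreeNode) -> list[TreeNode]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(reversed(n.children))
    return out


def _build_family_tree(
    rng: np.random.Generator,
    metazoan_ids: list[str],
    viral_ids: list[str],
    n_clades: int,
    topology: str,
) -> RootedTree:
    """Backbone over metazoan leaves with viral clades grafted onto it.

    Each clade replaces a distinct metazoan leaf M with an internal node
    (M, clade), so the parent of every clade root retains a metazoan
    descendant — the planted clades are exactly the maximal viral
    sub-trees, and their count is exact by construction.
    """
    if n_clades > len(viral_ids):
        raise ValueError(
            f"cannot plant {n_clades} viral clades with only {len(viral_ids)} viral proteins"
        )
    if n_clades > len(metazoan_ids):
        raise ValueError(
            f"cannot plant {n_clades} viral clades with only {len(metazoan_ids)} metazoan leaves"
        )
    meta_order = [metazoan_ids[i] for i in rng.permutation(len(metazoan_ids))]
    if topology == "caterpillar":
        root = _caterpillar(meta_order)
    else:
        root = _yule_backbone(rng, meta_order)

    viral_order = [viral_ids[i] for i in rng.permutation(len(viral_ids))]
    sizes = rng.multinomial(len(viral_ids) - n_clades, [1.0 / n_clades] * n_clades) + 1
    groups, offset = [], 0
    for size in sizes:
        groups.append(viral_order[offset: offset + int(size)])
        offset += int(size)

    leaves = _leaf_nodes(root)
    slots = rng.choice(len(leaves), size=n_clades, replace=False)
    for slot, group in zip(slots, groups):
        target = leaves[int(slot)]
        clade = _caterpillar(group)
        clade.branch_length = 1.0
        host_leaf = TreeNode(leaf_label=target.leaf_label, branch_length=1.0)
        target.leaf_label = None
        target.children = [host_leaf, clade]
    return RootedTree(root)


def generate_family(
    params: CohortParams, family_index: int, cross_taxa: bool = True
) -> FamilyData:
    """Generate one family: records, domain hits, tree and ground truth.

    With ``cross_taxa=False`` the family is metazoan-only (no viral members
    and no tree), emulating the clusters the composition filter removes.
    """
    rng = np.random.default_rng([params.seed, family_index])
    fid = f"FAM{family_index:04d}"
    arch = params.host_architecture
    linkers = params.linker_model
    meta_mean, viral_mean = params.members_per_family
    k = params.tree_model.n_viral_clades

    n_meta = max(2, k, int(rng.poisson(meta_mean)))
    n_viral = max(1, k, int(rng.poisson(viral_mean))) if cross_taxa else 0

    if arch.n_domains_fixed is not None:
        n_dom = arch.n_domains_fixed
    else:
        n_dom = max(1, int(rng.poisson(arch.n_domains_mean)))
    dom_lens = [
        max(20, int(round(rng.normal(arch.domain_length_mean, arch.domain_length_spread))))
        for _ in range(n_dom)
    ]
    canonical = [(f"{fid}_D{j + 1}", dom_lens[j]) for j in range(n_dom)]

    records: dict[str, ProteinRecord] = {}
    hits: list[DomainHit] = []
    for i in range(n_meta):
        pid = f"{fid}_M{i + 1:03d}"
        rec, phits = _build_protein(
            pid, f"Metazoan_sp{int(rng.integers(1, 40)):02d}", TaxonClass.METAZOA,
            canonical, linkers.metazoan_tail_mean, linkers.metazoan_idol_mean,
            linkers.distribution, rng, params.with_sequences,
        )
        records[pid] = rec
        hits.extend(phits)

    losses: dict[str, list[tuple[str, int]]] = {}
    for i in range(n_viral):
        pid = f"{fid}_V{i + 1:03d}"
        keep = [True] * n_dom
        for j in range(1, n_dom - 1):  # flanking domains are always retained
            if rng.random() < params.domain_loss_prob:
                keep[j] = False
        viral_arch = [canonical[j] for j in range(n_dom) if keep[j]]
        losses[pid] = [(canonical[j][0], j + 1) for j in range(n_dom) if not keep[j]]
        rec, phits = _build_protein(
            pid, f"Virus_sp{int(rng.integers(1, 20)):02d}", TaxonClass.VIRUS,
            viral_arch, linkers.viral_tail_mean, linkers.viral_idol_mean,
            linkers.distribution, rng, params.with_sequences,
        )
        records[pid] = rec
        hits.extend(phits)

    viral_ids = sorted(pid for pid in records if records[pid].taxon_class is TaxonClass.VIRUS)
    meta_ids = sorted(pid for pid in records if records[pid].taxon_class is TaxonClass.METAZOA)
    tree = (
        _build_family_tree(rng, meta_ids, viral_ids, k, params.tree_model.topology)
        if cross_taxa
        else None
    )

    family = Family(fid, FamilyType.DOMAIN_FAMILY, set(records), name=f"synthetic family {family_index}")
    truth = {
        "family_id": fid,
        "cross_taxa": cross_taxa,
        "n_metazoan": n_meta,
        "n_viral": n_viral,
        "n_viral_clades": k if cross_taxa else 0,
        "canonical_architecture": [d for d, _ in canonical],
        "domain_lengths": dom_lens,
        "planted_losses": {pid: lost for pid, lost in losses.items() if lost},
        "linker_means": {
            "metazoan_tail": linkers.metazoan_tail_mean,
            "viral_tail": linkers.viral_tail_mean,
            "metazoan_idol": linkers.metazoan_idol_mean,
            "viral_idol": linkers.viral_idol_mean,
        },
    }
    hits.sort(key=lambda h: (h.protein_id, h.start, h.end, h.domain_id))
    return FamilyData(family, records, hits, tree, truth)


def generate_cohort(params: CohortParams, out_dir: Union[str, Path]) -> dict:
    """Write a full cohort (members.tsv, domains.tsv, trees/, truth.json).

    ``round(cross_taxa_fraction * n_families)`` families receive viral
    members; the rest are metazoan-only. Returns the ground-truth dict that
    was written to ``truth.json``. Byte-identical for a fixed seed.
    """
    out = Path(out_dir)
    trees_dir = out / "trees"
    trees_dir.mkdir(parents=True, exist_ok=True)

    selector = np.random.default_rng([params.seed, 2**31 - 1])
    n_cross = int(round(params.cross_taxa_fraction * params.n_families))
    cross_idx = (
        set(int(i) for i in selector.choice(params.n_families, size=n_cross, replace=False))
        if params.n_families
        else set()
    )

    all_records: dict[str, ProteinRecord] = {}
    all_families: dict[str, Family] = {}
    all_hits: list[DomainHit] = []
    truths = {}
    for i in range(params.n_families):
        fd = generate_family(params, i, cross_taxa=i in cross_idx)
        all_records.update(fd.records)
        all_families[fd.family.family_id] = fd.family
        all_hits.extend(fd.hits)
        truths[fd.family.family_id] = fd.truth
        if fd.tree is not None:
            write_tree(fd.tree, trees_dir / f"{fd.family.family_id}.nwk")

    write_membership_table(all_records, all_families, out / "members.tsv")
    write_domain_annotations(all_hits, out / "domains.tsv")

    truth = {
        "params": {
            "n_families": params.n_families,
            "members_per_family": list(params.members_per_family),
            "viral_fraction_target": params.viral_fraction_target,
            "cross_taxa_fraction": params.cross_taxa_fraction,
            "n_cross_taxa": n_cross,
            "host_architecture": dataclasses.asdict(params.host_architecture),
            "linker_model": dataclasses.asdict(params.linker_model),
            "domain_loss_prob": params.domain_loss_prob,
            "tree_model": dataclasses.asdict(params.tree_model),
            "seed": params.seed,
        },
        "families": truths,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth
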