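"""Domain types and file I/O for cross-taxa protein-family screens.

The analysis consumes three plain-text inputs: a family membership table
(TSV), per-protein domain annotations (TSV, 1-based inclusive amino-acid
coordinates in the Pfam/hmmscan convention), and one Newick tree per family
whose leaf names are protein identifiers. FASTA sequences are optional and
only checked for length consistency.

All tables are tab-delimited UTF-8 with a mandatory header row. Taxon
classes are supplied in the table rather than resolved from a taxonomy
service, so the package has no database dependency.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import dendropy
import pandas as pd

__all__ = [
    "TaxonClass",
    "FamilyType",
    "ProteinRecord",
    "DomainHit",
    "Family",
    "TreeNode",
    "RootedTree",
    "RootPolicy",
    "FormatError",
    "RowError",
    "ConsistencyError",
    "TreeError",
    "read_membership_table",
    "write_membership_table",
    "read_domain_annotations",
    "write_domain_annotations",
    "cross_validate_hits",
    "read_tree",
    "write_tree",
    "read_fasta",
    "write_fasta",
    "attach_sequences",
]


class FormatError(ValueError):
    """File-level structural problem, e.g. a missing required column."""


class RowError(ValueError):
    """A problem tied to a specific data row (1-based file line number)."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ConsistencyError(ValueError):
    """Cross-record contradiction, e.g. one protein id with two lengths."""


class TreeError(ValueError):
    """Malformed or unusable tree input."""


class TaxonClass(enum.Enum):
    """Coarse taxonomic partition of a protein.

    Only VIRUS and METAZOA enter the core statistics; the remaining classes
    are carried through so the family filters can see full compositions.
    """

    VIRUS = "virus"
    METAZOA = "metazoa"
    OTHER_EUKARYOTE = "other_eukaryote"
    BACTERIA = "bacteria"
    ARCHAEA = "archaea"

    @classmethod
    def parse(cls, text: str) -> "TaxonClass":
        key = text.strip().lower()
        for member in cls:
            if member.value == key or member.name.lower() == key:
                return member
        raise ValueError(f"unknown taxon class {text!r}")


class FamilyType(enum.Enum):
    CLUSTER = "cluster"            # UniRef-style sequence-identity cluster
    DOMAIN_FAMILY = "domain_family"  # Pfam-style profile family


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, species, taxon class and length in aa."""

    protein_id: str
    species: str
    taxon_class: TaxonClass
    length: int
    sequence: Optional[str] = None
    fragment: bool = False

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.length <= 0:
            raise ValueError(
                f"protein {self.protein_id!r}: length must be positive, got {self.length}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"protein {self.protein_id!r}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True, order=True)
class DomainHit:
    """One domain occurrence; 1-based inclusive coordinates."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(
                f"hit {self.domain_id!r} on {self.protein_id!r}: "
                f"coordinates are 1-based, got start={self.start}"
            )
        if self.end < self.start:
            raise ValueError(
                f"hit {self.domain_id!r} on {self.protein_id!r}: "
                f"end {self.end} < start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Family:
    """A cross-taxa cluster or domain family and its member protein ids."""

    family_id: str
    family_type: FamilyType
    member_ids: set[str] = field(default_factory=set)
    name: Optional[str] = None

    def __post_init__(self):
        if not self.family_id:
            raise ValueError("family_id must be non-empty")


# ---------------------------------------------------------------------------
# Membership tables
# ---------------------------------------------------------------------------

REQUIRED_MEMBER_COLUMNS = ("family_id", "protein_id", "species", "taxon_class", "length")
_TRUE_STRINGS = {"true", "1", "yes"}
_FALSE_STRINGS = {"false", "0", "no", ""}


def _parse_bool(text: str, line: int, column: str) -> bool:
    key = text.strip().lower()
    if key in _TRUE_STRINGS:
        return True
    if key in _FALSE_STRINGS:
        return False
    raise RowError(line, f"column {column!r}: cannot parse boolean {text!r}")


def read_membership_table(
    path: Union[str, Path],
    family_type: FamilyType = FamilyType.CLUSTER,
) -> tuple[dict[str, ProteinRecord], dict[str, Family]]:
    """Read a family membership TSV.

    Required columns: family_id, protein_id, species, taxon_class, length.
    Optional columns: sequence, fragment, family_name. A protein may belong
    to several families; its per-protein fields must agree across rows.

    Returns (protein_id -> ProteinRecord, family_id -> Family).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_MEMBER_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"membership table is missing required column {col!r}")
    has_seq = "sequence" in df.columns
    has_frag = "fragment" in df.columns
    has_name = "family_name" in df.columns

    records: dict[str, ProteinRecord] = {}
    families: dict[str, Family] = {}
    seen_rows: set[tuple[str, str]] = set()

    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        fid = row.family_id.strip()
        pid = row.protein_id.strip()
        if not fid or not pid:
            raise RowError(line, "empty family_id or protein_id")
        if (fid, pid) in seen_rows:
            raise RowError(line, f"duplicate membership row ({fid}, {pid})")
        seen_rows.add((fid, pid))

        try:
            length = int(row.length)
        except ValueError:
            raise RowError(line, f"non-integer length {row.length!r}") from None
        if length <= 0:
            raise RowError(line, f"non-positive length {length}")
        try:
            taxon = TaxonClass.parse(row.taxon_class)
        except ValueError as exc:
            raise RowError(line, str(exc)) from None

        sequence = None
        if has_seq:
            seq = row.sequence.strip()
            sequence = seq or None
        fragment = _parse_bool(row.fragment, line, "fragment") if has_frag else False

        try:
            record = ProteinRecord(pid, row.species.strip(), taxon, length, sequence, fragment)
        except ValueError as exc:
            raise RowError(line, str(exc)) from None

        previous = records.get(pid)
        if previous is None:
            records[pid] = record
        elif previous != record:
            raise ConsistencyError(
                f"protein {pid!r} appears with conflicting fields "
                f"(first seen {previous}, line {line} gives {record})"
            )

        fam = families.get(fid)
        if fam is None:
            fam = Family(fid, family_type, set(), None)
            families[fid] = fam
        fam.member_ids.add(pid)
        if has_name:
            fam_name = row.family_name.strip() or None
            if fam.name is None:
                fam.name = fam_name
            elif fam_name is not None and fam.name != fam_name:
                raise ConsistencyError(
                    f"family {fid!r} given two names: {fam.name!r} and {fam_name!r}"
                )
    return records, families


def write_membership_table(
    records: dict[str, ProteinRecord],
    families: dict[str, Family],
    path: Union[str, Path],
) -> None:
    """Write the membership TSV (inverse of :func:`read_membership_table`)."""
    any_seq = any(r.sequence is not None for r in records.values())
    any_frag = any(r.fragment for r in records.values())
    any_name = any(f.name is not None for f in families.values())
    columns = list(REQUIRED_MEMBER_COLUMNS)
    if any_seq:
        columns.append("sequence")
    if any_frag:
        columns.append("fragment")
    if any_name:
        columns.append("family_name")

    rows = []
    for fid in sorted(families):
        fam = families[fid]
        for pid in sorted(fam.member_ids):
            rec = records[pid]
            row = {
                "family_id": fid,
                "protein_id": pid,
                "species": rec.species,
                "taxon_class": rec.taxon_class.value,
                "length": rec.length,
            }
            if any_seq:
                row["sequence"] = rec.sequence or ""
            if any_frag:
                row["fragment"] = "true" if rec.fragment else "false"
            if any_name:
                row["family_name"] = fam.name or ""
            rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------

REQUIRED_HIT_COLUMNS = ("protein_id", "domain_id", "start", "end")


def read_domain_annotations(path: Union[str, Path]) -> list[DomainHit]:
    """Read a domain-hit TSV; returns hits sorted by (protein_id, start).

    Unknown protein ids are permitted here and validated later against the
    membership records (see :func:`cross_validate_hits`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_HIT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"domain table is missing required column {col!r}")
    has_score = "score" in df.columns

    hits: list[DomainHit] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise RowError(line, f"non-integer coordinates ({row.start!r}, {row.end!r})") from None
        score = None
        if has_score and row.score.strip():
            try:
                score = float(row.score)
            except ValueError:
                raise RowError(line, f"non-numeric score {row.score!r}") from None
        try:
            hit = DomainHit(row.protein_id.strip(), row.domain_id.strip(), start, end, score)
        except ValueError as exc:
            raise RowError(line, str(exc)) from None
        hits.append(hit)
    hits.sort(key=lambda h: (h.protein_id, h.start, h.end, h.domain_id))
    return hits


def write_domain_annotations(hits: Iterable[DomainHit], path: Union[str, Path]) -> None:
    ordered = sorted(hits, key=lambda h: (h.protein_id, h.start, h.end, h.domain_id))
    any_score = any(h.score is not None for h in ordered)
    columns = list(REQUIRED_HIT_COLUMNS) + (["score"] if any_score else [])
    rows = []
    for h in ordered:
        row = {"protein_id": h.protein_id, "domain_id": h.domain_id,
               "start": h.start, "end": h.end}
        if any_score:
            row["score"] = "" if h.score is None else repr(h.score)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def cross_validate_hits(
    hits: Iterable[DomainHit], records: dict[str, ProteinRecord]
) -> list[str]:
    """Check hits against protein records; returns human-readable violations.

    A hit on an unknown protein or a hit extending past its protein's length
    is reported; an empty list means the annotation set is consistent.
    """
    problems = []
    for h in hits:
        rec = records.get(h.protein_id)
        if rec is None:
            problems.append(f"hit {h.domain_id} on unknown protein {h.protein_id!r}")
        elif h.end > rec.length:
            problems.append(
                f"hit {h.domain_id} on {h.protein_id!r} ends at {h.end} "
                f"beyond protein length {rec.length}"
            )
    return problems


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class RootPolicy(enum.Enum):
    REQUIRE_ROOTED = "require_rooted"
    MIDPOINT = "midpoint"


class TreeNode:
    """Node of a rooted leaf-labeled tree; leaf labels are protein ids."""

    __slots__ = ("node_id", "parent", "children", "leaf_label", "branch_length")

    def __init__(
        self,
        children: Optional[list["TreeNode"]] = None,
        leaf_label: Optional[str] = None,
        branch_length: Optional[float] = None,
        node_id: Optional[str] = None,
    ):
        self.node_id = node_id
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = children or []
        self.leaf_label = leaf_label
        self.branch_length = branch_length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        kind = f"leaf {self.leaf_label!r}" if self.is_leaf else f"{len(self.children)} children"
        return f"<TreeNode {self.node_id} ({kind})>"


class RootedTree:
    """A rooted, leaf-labeled tree with stable preorder node ids.

    Depth statistics are purely topological (edge counts); branch lengths
    are preserved for I/O and midpoint rooting but never enter the clade
    statistics.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_ids_and_parents()
        self._nodes = {n.node_id: n for n in self.preorder()}
        self._leaves = {}
        for leaf in (n for n in self.preorder() if n.is_leaf):
            if leaf.leaf_label is None:
                raise TreeError(f"leaf node {leaf.node_id} has no label")
            if leaf.leaf_label in self._leaves:
                raise TreeError(f"duplicate leaf label {leaf.leaf_label!r}")
            self._leaves[leaf.leaf_label] = leaf

    def _assign_ids_and_parents(self) -> None:
        counter = 0
        stack = [(self.root, None)]
        while stack:
            node, parent = stack.pop()
            node.parent = parent
            node.node_id = f"n{counter}"
            counter += 1
            # reversed keeps preorder = left-to-right child order
            for child in reversed(node.children):
                stack.append((child, node))

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def postorder(self) -> Iterator[TreeNode]:
        return reversed(list(self.preorder()))

    def node(self, node_id: str) -> TreeNode:
        return self._nodes[node_id]

    def leaf(self, label: str) -> TreeNode:
        return self._leaves[label]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.leaf_label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self._leaves)

    # -- depth statistics --------------------------------------------------

    def node_depths(self) -> dict[str, int]:
        """Edge-count depth of every node; the root has depth 0."""
        depths = {self.root.node_id: 0}
        for node in self.preorder():
            if node.parent is not None:
                depths[node.node_id] = depths[node.parent.node_id] + 1
        return depths

    def leaf_depths(self) -> dict[str, int]:
        depths = self.node_depths()
        return {n.leaf_label: depths[n.node_id] for n in self.leaves()}

    def max_leaf_depth(self) -> int:
        return max(self.leaf_depths().values())

    def leaf_set(self, node: TreeNode) -> frozenset[str]:
        """Labels of all leaves at or below ``node``."""
        labels = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                labels.append(n.leaf_label)
            else:
                stack.extend(n.children)
        return frozenset(labels)

    # -- Newick I/O --------------------------------------------------------

    @classmethod
    def from_newick(
        cls, newick: str, root_policy: RootPolicy = RootPolicy.REQUIRE_ROOTED
    ) -> "RootedTree":
        """Parse a Newick string; comments stripped, quoted labels honored.

        Under MIDPOINT an unrooted tree is rooted at the midpoint of its
        longest leaf-to-leaf path, which requires branch lengths. Under
        REQUIRE_ROOTED a basal multifurcation is rejected.
        """
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"cannot parse Newick: {exc}") from None

        labels = []
        for leaf in dtree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("tree contains an unlabeled leaf")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")

        if root_policy is RootPolicy.REQUIRE_ROOTED:
            if len(dtree.seed_node.child_nodes()) > 2:
                raise TreeError(
                    "basal multifurcation: tree is unrooted "
                    "(use MIDPOINT rooting or supply a rooted tree)"
                )
        elif root_policy is RootPolicy.MIDPOINT:
            for edge in dtree.preorder_edge_iter():
                if edge.head_node is not dtree.seed_node and edge.length is None:
                    raise TreeError("midpoint rooting requires branch lengths on all edges")
            dtree.reroot_at_midpoint(update_bipartitions=False)
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(f"unknown root policy {root_policy}")

        return cls(_from_dendropy(dtree.seed_node))

    def to_newick(self) -> str:
        rendered: dict[int, str] = {}
        for node in self.postorder():
            if node.is_leaf:
                text = _quote_label(node.leaf_label)
            else:
                text = "(" + ",".join(rendered[id(c)] for c in node.children) + ")"
            if node.branch_length is not None and node.parent is not None:
                text += f":{node.branch_length:.10g}"
            rendered[id(node)] = text
        return rendered[id(self.root)] + ";"


_LABEL_NEEDS_QUOTES = re.compile(r"[\s()\[\]:;,']")


def _quote_label(label: str) -> str:
    if _LABEL_NEEDS_QUOTES.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(seed_node) -> TreeNode:
    """Convert a dendropy subtree into TreeNode structure, iteratively."""
    root = TreeNode(branch_length=None)
    stack = [(seed_node, root)]
    while stack:
        dnode, mine = stack.pop()
        if dnode.is_leaf():
            mine.leaf_label = dnode.taxon.label
        for dchild in dnode.child_nodes():
            child = TreeNode(branch_length=dchild.edge.length)
            mine.children.append(child)
            stack.append((dchild, child))
    return root


def read_tree(
    path: Union[str, Path], root_policy: RootPolicy = RootPolicy.REQUIRE_ROOTED
) -> RootedTree:
    return RootedTree.from_newick(Path(path).read_text(), root_policy)


def write_tree(tree: RootedTree, path: Union[str, Path]) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# FASTA (optional sequences)
# ---------------------------------------------------------------------------


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: Union[str, Path]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sorted(sequences.items())]
    seqio_write(recs, str(path), "fasta")


def attach_sequences(
    records: dict[str, ProteinRecord], sequences: dict[str, str]
) -> dict[str, ProteinRecord]:
    """Return records with sequences attached; lengths must agree."""
    out = {}
    for pid, rec in records.items():
        seq = sequences.get(pid)
        if seq is None:
            out[pid] = rec
            continue
        if len(seq) != rec.length:
            raise ConsistencyError(
                f"protein {pid!r}: FASTA length {len(seq)} != table length {rec.length}"
            )
        out[pid] = ProteinRecord(pid, rec.species, rec.taxon_class, rec.length, seq, rec.fragment)
    return out
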