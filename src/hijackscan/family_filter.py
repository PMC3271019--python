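"""Filtering cascades that reduce raw cross-taxa families to the analysis set.

Two cascades are provided. Sequence clusters (UniRef-style) are kept when
they have a minimal size and contain both a viral and a metazoan member.
Domain families (Pfam-style) additionally drop near-pure viral families
(structural elements such as Env/Coat/Capsid tend to be >95% viral) and a
configurable exclusion list of replication enzymes and known contaminations
(polymerases, exo/endonucleases, helicases, tRNA synthetases, primases, and
the GFP family whose presence in metazoan proteomes reflects cloning
vectors).

Every run returns a :class:`FilterTrace` recording the funnel: families in,
families out and the removed ids at each stage, in the order applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .io_model import ConsistencyError, Family, ProteinRecord, TaxonClass

__all__ = [
    "FilterConfig",
    "FilterStage",
    "FilterTrace",
    "filter_clusters",
    "filter_domain_families",
    "load_default_exclusions",
    "load_exclusions",
    "viral_fraction",
]


def load_exclusions(path: Union[str, Path]) -> tuple[set[str], list[str]]:
    """Read an exclusion TSV with columns kind ∈ {family_id, pattern}, value."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ids: set[str] = set()
    patterns: list[str] = []
    for row in df.itertuples(index=False):
        if row.kind == "family_id":
            ids.add(row.value)
        elif row.kind == "pattern":
            patterns.append(row.value)
        else:
            raise ValueError(f"unknown exclusion kind {row.kind!r}")
    return ids, patterns


def load_default_exclusions() -> tuple[set[str], list[str]]:
    """The shipped exclusion list (replication enzymes, GFP)."""
    ref = resources.files("hijackscan.data").joinpath("default_exclusions.tsv")
    with resources.as_file(ref) as path:
        return load_exclusions(path)


@dataclass
class FilterConfig:
    """Constants of the filtering cascades.

    Defaults follow the screen's published constants: clusters need at
    least 2 members; domain families need at least one viral and two
    metazoan members; families with more than 95% viral members are treated
    as viral structural elements and dropped.
    """

    min_cluster_size: int = 2
    require_viral: bool = True
    require_metazoan: bool = True
    min_metazoan: int = 2
    structural_viral_fraction: float = 0.95
    excluded_family_ids: set[str] = field(default_factory=set)
    excluded_name_patterns: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0 < self.structural_viral_fraction <= 1):
            raise ValueError("structural_viral_fraction must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    @classmethod
    def with_default_exclusions(cls, **kwargs) -> "FilterConfig":
        ids, patterns = load_default_exclusions()
        kwargs.setdefault("excluded_family_ids", ids)
        kwargs.setdefault("excluded_name_patterns", patterns)
        return cls(**kwargs)


@dataclass(frozen=True)
class FilterStage:
    name: str
    n_in: int
    n_out: int
    removed_ids: tuple[str, ...]

    def __post_init__(self):
        if self.n_in - self.n_out != len(self.removed_ids):
            raise ValueError(
                f"stage {self.name!r}: {self.n_in} in - {self.n_out} out "
                f"!= {len(self.removed_ids)} removed"
            )


@dataclass
class FilterTrace:
    """The funnel: one :class:`FilterStage` per applied filter, in order."""

    stages: list[FilterStage] = field(default_factory=list)

    def record(self, name: str, before: dict[str, Family], after: dict[str, Family]) -> None:
        removed = tuple(sorted(set(before) - set(after)))
        self.stages.append(FilterStage(name, len(before), len(after), removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "families_in": s.n_in,
                    "families_out": s.n_out,
                    "n_removed": len(s.removed_ids),
                    "removed_ids": ",".join(s.removed_ids),
                }
                for s in self.stages
            ]
        )


def _class_counts(family: Family, records: dict[str, ProteinRecord]) -> dict[TaxonClass, int]:
    counts = {cls: 0 for cls in TaxonClass}
    for pid in family.member_ids:
        rec = records.get(pid)
        if rec is None:
            raise ConsistencyError(
                f"family {family.family_id!r}: member {pid!r} has no protein record"
            )
        counts[rec.taxon_class] += 1
    return counts


def viral_fraction(family: Family, records: dict[str, ProteinRecord]) -> float:
    """Viral members over all members (member counts, not species counts)."""
    counts = _class_counts(family, records)
    return counts[TaxonClass.VIRUS] / len(family.member_ids)


def _apply_stage(families, keep, name, trace):
    after = {fid: fam for fid, fam in families.items() if keep(fam)}
    trace.record(name, families, after)
    return after


def filter_clusters(
    families: dict[str, Family],
    records: dict[str, ProteinRecord],
    config: Optional[FilterConfig] = None,
) -> tuple[dict[str, Family], FilterTrace]:
    """Cluster cascade: minimal size, then viral member, then metazoan member."""
    config = config or FilterConfig()
    trace = FilterTrace()
    counts = {fid: _class_counts(fam, records) for fid, fam in families.items()}

    out = _apply_stage(
        families,
        lambda f: len(f.member_ids) >= config.min_cluster_size,
        f"size>={config.min_cluster_size}",
        trace,
    )
    if config.require_viral:
        out = _apply_stage(
            out, lambda f: counts[f.family_id][TaxonClass.VIRUS] >= 1, "has_viral", trace
        )
    if config.require_metazoan:
        out = _apply_stage(
            out, lambda f: counts[f.family_id][TaxonClass.METAZOA] >= 1, "has_metazoan", trace
        )
    return out, trace


def _matches_exclusion(family: Family, config: FilterConfig) -> bool:
    if family.family_id in config.excluded_family_ids:
        return True
    targets = [family.family_id] + ([family.name] if family.name else [])
    for pattern in config.excluded_name_patterns:
        rx = re.compile(pattern, re.IGNORECASE)
        if any(rx.search(t) for t in targets):
            return True
    return False


def filter_domain_families(
    families: dict[str, Family],
    records: dict[str, ProteinRecord],
    config: Optional[FilterConfig] = None,
) -> tuple[dict[str, Family], FilterTrace]:
    """Domain-family cascade.

    Stages, in order: (1) composition — at least one viral and at least
    ``min_metazoan`` metazoan members; (2) structural — viral member
    fraction must not exceed ``structural_viral_fraction``; (3) exclusion
    list — family id on the list or id/name matching an excluded pattern.
    """
    config = config or FilterConfig()
    trace = FilterTrace()
    counts = {fid: _class_counts(fam, records) for fid, fam in families.items()}

    out = _apply_stage(
        families,
        lambda f: counts[f.family_id][TaxonClass.VIRUS] >= 1
        and counts[f.family_id][TaxonClass.METAZOA] >= config.min_metazoan,
        f"composition(viral>=1,metazoan>={config.min_metazoan})",
        trace,
    )
    out = _apply_stage(
        out,
        lambda f: counts[f.family_id][TaxonClass.VIRUS] / len(f.member_ids)
        <= config.structural_viral_fraction,
        f"viral_fraction<={config.structural_viral_fraction}",
        trace,
    )
    out = _apply_stage(
        out, lambda f: not _matches_exclusion(f, config), "exclusion_list", trace
    )
    return out, trace
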