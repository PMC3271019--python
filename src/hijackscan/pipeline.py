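"""End-to-end orchestration: filter -> tree scan -> linker stats -> tests.

Mirrors the screen's ordering: the family filter funnel first, then the
tree-topology candidate selection, then the architecture statistics on the
retained families, then the class comparisons (KS on lengths/TAIL/IDOL,
sign enrichment of "viral shorter" families, paired t on per-family domain
occurrences). The run emits TSVs per stage plus one machine-readable JSON
report whose funnel counts reconcile exactly with the filter trace.

Families that survive filtering but have no tree file are not dropped:
they are flagged UNCLASSIFIED for topology and still enter the
architecture statistics, since the two analyses are separable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import architecture as arch
from . import stats as st
from .family_filter import FilterConfig, FilterTrace, filter_clusters, filter_domain_families
from .io_model import (
    DomainHit,
    Family,
    FamilyType,
    ProteinRecord,
    RootPolicy,
    TaxonClass,
    cross_validate_hits,
    read_domain_annotations,
    read_membership_table,
    read_tree,
)
from .tree_topology import SelectionThresholds, TopologyReport, classify_family

__all__ = ["RunConfig", "PipelineError", "run", "validate_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"
logger = logging.getLogger("hijackscan")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and, when known, a family id."""

    def __init__(self, stage: str, message: str, family_id: Optional[str] = None):
        self.stage = stage
        self.family_id = family_id
        where = f"stage {stage!r}" + (f", family {family_id!r}" if family_id else "")
        super().__init__(f"{where}: {message}")


@dataclass
class RunConfig:
    members: Path
    domains: Path
    out_dir: Path
    trees_dir: Optional[Path] = None
    family_type: str = "domain"  # "cluster" or "domain"
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    tests: tuple[str, ...] = ("ks", "sign", "paired_t")
    root_policy: RootPolicy = RootPolicy.REQUIRE_ROOTED
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        self.members = Path(self.members)
        self.domains = Path(self.domains)
        self.out_dir = Path(self.out_dir)
        if self.trees_dir is not None:
            self.trees_dir = Path(self.trees_dir)
        if self.family_type not in ("cluster", "domain"):
            raise ValueError(f"family_type must be 'cluster' or 'domain', got {self.family_type!r}")
        for path in (self.members, self.domains):
            if not path.exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "filter_config" in raw:
            raw["filter_config"] = FilterConfig(**raw["filter_config"])
        if "thresholds" in raw:
            raw["thresholds"] = SelectionThresholds(**raw["thresholds"])
        if "tests" in raw:
            raw["tests"] = tuple(raw["tests"])
        if "root_policy" in raw:
            raw["root_policy"] = RootPolicy(raw["root_policy"])
        return cls(**raw)


def _stage(name):
    logger.info("stage %s", name)
    return time.monotonic()


def _done(name, t0):
    logger.info("stage %s done in %.2fs", name, time.monotonic() - t0)


def per_protein_table(
    families: dict[str, Family],
    records: dict[str, ProteinRecord],
    decompositions: dict[str, arch.ArchitectureDecomposition],
) -> pd.DataFrame:
    """One row per (family, member protein) with architecture statistics."""
    rows = []
    for fid in sorted(families):
        for pid in sorted(families[fid].member_ids):
            rec = records[pid]
            d = decompositions.get(pid)
            row = {
                "family_id": fid,
                "protein_id": pid,
                "taxon_class": rec.taxon_class.value,
                "length": rec.length,
                "n_domains": d.n_domains if d else 0,
                "n_distinct": d.n_distinct_domains if d else 0,
                "n_tail": d.n_tail_len if d else "",
                "c_tail": d.c_tail_len if d else "",
                "tail_mean": arch.tail_length(d) if d else "",
                "idol_mean": "",
            }
            if d is not None:
                idol = arch.idol_length(d)
                row["idol_mean"] = "" if idol is None else idol
            rows.append(row)
    return pd.DataFrame(rows)


def _summary_row(summary: arch.FamilyArchitectureSummary) -> dict:
    row = {"family_id": summary.family_id}
    for cls, prefix in ((TaxonClass.METAZOA, "metazoan"), (TaxonClass.VIRUS, "viral")):
        cs = summary.per_class.get(cls)
        row[f"{prefix}_n"] = cs.n_proteins if cs else 0
        for name in ("mean_length", "median_length", "mean_domain_occurrences",
                     "mean_distinct_domains", "mean_tail", "mean_idol"):
            value = getattr(cs, name) if cs else None
            row[f"{prefix}_{name}"] = "" if value is None else value
    row["ratio_length_m_over_v"] = (
        "" if summary.ratio_length_m_over_v is None else summary.ratio_length_m_over_v
    )
    row["ratio_distinct_domains_m_over_v"] = (
        "" if summary.ratio_distinct_domains_m_over_v is None
        else summary.ratio_distinct_domains_m_over_v
    )
    row["viral_shorter"] = "" if summary.viral_shorter is None else str(summary.viral_shorter).lower()
    row["n_excluded_no_domains"] = summary.n_excluded_no_domains
    return row


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; writes TSVs + report.json, returns the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.out_dir.mkdir(parents=True, exist_ok=True)

    # ---- read & validate -------------------------------------------------
    t0 = _stage("read")
    ftype = FamilyType.CLUSTER if config.family_type == "cluster" else FamilyType.DOMAIN_FAMILY
    records, families = read_membership_table(config.members, ftype)
    hits = read_domain_annotations(config.domains)
    problems = cross_validate_hits(hits, records)
    bounds_problems = [p for p in problems if "beyond protein length" in p]
    if bounds_problems:
        raise PipelineError("read", "; ".join(bounds_problems[:5]))
    known = set(records)
    dropped_unknown = sum(1 for h in hits if h.protein_id not in known)
    if dropped_unknown:
        logger.warning("dropping %d hits on proteins absent from the membership table",
                       dropped_unknown)
        hits = [h for h in hits if h.protein_id in known]
    _done("read", t0)

    # ---- family filter ---------------------------------------------------
    t0 = _stage("filter")
    if config.family_type == "cluster":
        surviving, trace = filter_clusters(families, records, config.filter_config)
    else:
        surviving, trace = filter_domain_families(families, records, config.filter_config)
    trace.to_frame().to_csv(config.out_dir / "trace.tsv", sep="\t", index=False)
    _done("filter", t0)

    # ---- tree topology ---------------------------------------------------
    t0 = _stage("tree_scan")
    topo_rows: list[dict] = []
    topo_reports: dict[str, TopologyReport] = {}
    unclassified: list[str] = []
    for fid in sorted(surviving):
        tree_path = (config.trees_dir / f"{fid}.nwk") if config.trees_dir else None
        if tree_path is None or not tree_path.exists():
            unclassified.append(fid)
            topo_rows.append({"family_id": fid, "status": "UNCLASSIFIED"})
            continue
        try:
            tree = read_tree(tree_path, config.root_policy)
            report = classify_family(fid, tree, records, config.thresholds)
        except Exception as exc:
            raise PipelineError("tree_scan", str(exc), family_id=fid) from exc
        topo_reports[fid] = report
        row = dataclasses.asdict(report)
        row["deepest_viral_leaves"] = ",".join(report.deepest_viral_leaves)
        row["normalized_viral_depths"] = ",".join(f"{v:.6g}" for v in report.normalized_viral_depths)
        row["vc_normalized_depths"] = ",".join(f"{v:.6g}" for v in report.vc_normalized_depths)
        row["status"] = "SELECTED" if report.selected else "REJECTED"
        topo_rows.append(row)
    pd.DataFrame(topo_rows).to_csv(config.out_dir / "topology_report.tsv", sep="\t", index=False)
    selected = [fid for fid, r in topo_reports.items() if r.selected]
    _done("tree_scan", t0)

    # ---- architecture ----------------------------------------------------
    t0 = _stage("architecture")
    arch_family_ids = sorted(set(selected) | set(unclassified))
    arch_families = {fid: surviving[fid] for fid in arch_family_ids}
    member_ids = set().union(*(f.member_ids for f in arch_families.values())) if arch_families else set()
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.protein_id in member_ids:
            by_protein.setdefault(h.protein_id, []).append(h)
    decompositions = {}
    for pid, phits in by_protein.items():
        try:
            decompositions[pid] = arch.decompose(records[pid], arch.resolve_overlaps(phits))
        except ValueError as exc:
            raise PipelineError("architecture", str(exc), family_id=None) from exc
    summaries = {
        fid: arch.summarize_family(arch_families[fid], records, decompositions)
        for fid in arch_family_ids
    }
    per_protein = per_protein_table(arch_families, records, decompositions)
    per_protein.to_csv(config.out_dir / "per_protein.tsv", sep="\t", index=False)
    pd.DataFrame([_summary_row(s) for s in summaries.values()]).to_csv(
        config.out_dir / "per_family.tsv", sep="\t", index=False
    )
    _done("architecture", t0)

    # ---- statistics ------------------------------------------------------
    t0 = _stage("compare")
    test_results: dict[str, st.TestResult] = {}
    pooled = {"viral": {"length": [], "tail": [], "idol": []},
              "metazoan": {"length": [], "tail": [], "idol": []}}
    for fid in arch_family_ids:
        for pid in sorted(arch_families[fid].member_ids):
            rec = records[pid]
            d = decompositions.get(pid)
            if d is None:
                continue
            if rec.taxon_class is TaxonClass.VIRUS:
                side = "viral"
            elif rec.taxon_class is TaxonClass.METAZOA:
                side = "metazoan"
            else:
                continue
            pooled[side]["length"].append(rec.length)
            pooled[side]["tail"].append(arch.tail_length(d))
            idol = arch.idol_length(d)
            if idol is not None:
                pooled[side]["idol"].append(idol)

    both = [s for s in summaries.values() if s.viral_shorter is not None]
    n_shorter = sum(1 for s in both if s.viral_shorter)
    viral_shorter_fraction = n_shorter / len(both) if both else None

    if "ks" in config.tests:
        for quantity in ("length", "tail", "idol"):
            a, b = pooled["viral"][quantity], pooled["metazoan"][quantity]
            if a and b:
                test_results[f"ks_{quantity}"] = st.ks_two_sample(a, b)
    if "sign" in config.tests and both:
        test_results["sign_viral_shorter"] = st.sign_enrichment(len(both), n_shorter)
    if "paired_t" in config.tests:
        pairs = [
            (s.per_class[TaxonClass.METAZOA].mean_domain_occurrences,
             s.per_class[TaxonClass.VIRUS].mean_domain_occurrences)
            for s in both
        ]
        if len(pairs) >= 2:
            try:
                test_results["paired_t_domain_occurrences"] = st.paired_t(
                    [m for m, _ in pairs], [v for _, v in pairs]
                )
            except st.DegenerateInputError as exc:
                logger.warning("paired t skipped: %s", exc)
    pd.DataFrame(
        [
            {"test": name, "statistic": r.statistic, "p_value": r.p_value,
             "n_a": r.n_a, "n_b": r.n_b}
            for name, r in test_results.items()
        ]
    ).to_csv(config.out_dir / "tests.tsv", sep="\t", index=False)
    _done("compare", t0)

    # ---- report ----------------------------------------------------------
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "family_type": config.family_type,
        "funnel": {
            "n_families_in": len(families),
            "stages": [
                {"stage": s.name, "in": s.n_in, "out": s.n_out, "n_removed": len(s.removed_ids)}
                for s in trace.stages
            ],
            "n_surviving": len(surviving),
        },
        "topology": {
            "n_classified": len(topo_reports),
            "n_selected": len(selected),
            "n_unclassified": len(unclassified),
        },
        "architecture": {
            "n_families_summarized": len(summaries),
            "n_proteins_decomposed": len(decompositions),
            "n_excluded_no_domains": sum(s.n_excluded_no_domains for s in summaries.values()),
            "n_families_both_classes": len(both),
            "n_viral_shorter": n_shorter,
            "viral_shorter_fraction": viral_shorter_fraction,
        },
        "tests": {
            name: {"statistic": r.statistic, "p_value": r.p_value, "n_a": r.n_a, "n_b": r.n_b}
            for name, r in test_results.items()
        },
    }
    validate_report(report)
    (config.out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def validate_report(report: dict) -> None:
    """Schema check of the JSON run report; raises ValueError on violation."""
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unexpected schema_version {report.get('schema_version')!r}")
    for key in ("funnel", "topology", "architecture", "tests"):
        if key not in report:
            raise ValueError(f"report is missing section {key!r}")
    funnel = report["funnel"]
    stages = funnel["stages"]
    if stages:
        if stages[0]["in"] != funnel["n_families_in"]:
            raise ValueError("funnel entry count does not match the first stage")
        for prev, cur in zip(stages, stages[1:]):
            if prev["out"] != cur["in"]:
                raise ValueError(f"funnel discontinuity between {prev['stage']} and {cur['stage']}")
        for s in stages:
            if s["in"] - s["out"] != s["n_removed"]:
                raise ValueError(f"stage {s['stage']}: in - out != n_removed")
        if stages[-1]["out"] != funnel["n_surviving"]:
            raise ValueError("funnel exit count does not match n_surviving")
    elif funnel["n_families_in"] != funnel["n_surviving"]:
        raise ValueError("no stages recorded but counts differ")
    topo = report["topology"]
    if topo["n_selected"] > topo["n_classified"]:
        raise ValueError("more selected than classified families")
    archi = report["architecture"]
    if archi["n_viral_shorter"] > archi["n_families_both_classes"]:
        raise ValueError("n_viral_shorter exceeds families with both classes")
    for name, r in report["tests"].items():
        if not (0.0 <= r["p_value"] <= 1.0):
            raise ValueError(f"test {name}: p-value outside [0, 1]")
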