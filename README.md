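# hijackscan

A screen for viral proteins acquired from metazoan hosts ("host-to-virus"
transfer) and for the architectural simplification those captured proteins
undergo. It is aimed at molecular evolution and virology groups who have
cross-taxa protein families — sequence clusters or domain families
containing both viral and cellular members — together with per-family
trees and domain annotations, and who want a reproducible, configurable
implementation of the candidate-selection and linker-statistics pipeline
rather than one-off scripts.

## What it computes

**Family filtering.** Cascades that reduce raw cross-taxa families to an
analysis set: minimal size, required viral and metazoan membership, removal
of >95%-viral (structural) families, and an editable exclusion list of
replication enzymes (polymerases, nucleases, helicases, tRNA synthetases,
primases) and known contaminations (GFP). Every run records a funnel trace.

**Tree topology.** On a rooted family tree with leaves labeled by protein
id, a *viral cluster* (VC) is a maximal sub-tree whose leaves are all
viral. With #Vir viral leaves and #VC clusters, the *condensation factor*
is #Vir/#VC. A family is a transfer candidate iff

```
(viral_fraction ≤ 0.05  OR  #Vir ≤ 2)            # rarity
AND (#VC ≤ 2  OR  (#VC ≤ 10 AND #Vir/#VC ≥ 3))   # clustering
```

Depths are topological: depth(node) = edges from the root, and the
*normalized depth* of a leaf or VC root is depth / max leaf depth — e.g.
a leaf 9 edges deep in a tree of maximum leaf depth 19 has normalized
depth 9/19 ≈ 0.474, and a VC rooted 4 edges deep has 4/19 ≈ 0.211.

**Architecture.** Each protein with domain hits splits into N-tail,
domains, inter-domain linkers (IDOL) and C-tail; per protein, TAIL is the
mean of the two terminal segments and IDOL the mean internal linker
(undefined for single-domain proteins). Family summaries report per-class
means, metazoan/viral ratios, and `detect_internal_loss` finds host
domains eliminated from a viral architecture while the flanking domains
are preserved in order.

**Statistics.** Two-sample Kolmogorov–Smirnov on pooled lengths/TAILs/
IDOLs, a binomial sign test (hypergeometric variant behind a flag) for the
fraction of families where the viral mean is shorter, a paired t test on
per-family domain occurrences, and ECDF tables for cumulative-fraction
plots.

**Synthetic cohorts.** A generator plants all of the above — cross-taxa
composition, viral clades per tree, linker means (defaults: TAIL 14 vs
85 aa, IDOL 30 vs 67 aa for viral vs metazoan), internal-domain losses —
and writes the ground truth to a separate JSON, so the entire pipeline is
testable without any database download. See `docs/methods.md` for the
model and its limits.

## Worked example

Simulate a 30-family cohort under the default study conditions and run the
full pipeline:

```python
from pathlib import Path
from hijackscan import CohortParams, RunConfig, generate_cohort, run

d = Path("demo")
generate_cohort(CohortParams(n_families=30, seed=7), d / "cohort")
report = run(RunConfig(
    members=d / "cohort/members.tsv", domains=d / "cohort/domains.tsv",
    trees_dir=d / "cohort/trees", out_dir=d / "out", family_type="domain",
))
```

The report (also written to `demo/out/report.json`) contains:

```
"topology":     {"n_classified": 30, "n_selected": 15, "n_unclassified": 0}
"architecture": {"n_families_both_classes": 15, "n_viral_shorter": 15,
                 "viral_shorter_fraction": 1.0, ...}
"tests": {
  "ks_tail":            {"statistic": 0.749, "p_value": 3.19e-20, ...},
  "ks_idol":            {"statistic": 0.508, "p_value": 2.90e-06, ...},
  "sign_viral_shorter": {"statistic": 1.0,   "p_value": 3.05e-05, ...},
  ...}
```

Reading it: the default cohort plants families near the 5% viral-fraction
selection boundary, so 15 of 30 pass the candidate rule. In every selected
family the viral mean length is below the metazoan mean
(`viral_shorter_fraction = 1.0`, sign-test p ≈ 3e-5), and the planted
linker trimming surfaces as large KS distances between the viral and
metazoan TAIL and IDOL distributions. The same stages are available from
the shell via `hijack-scan simulate / filter-families / tree-scan /
linker-stats / compare / run`.

The internal-loss detector on the classic two-vs-three-domain kinase
comparison:

```python
>>> from hijackscan import detect_internal_loss
>>> detect_internal_loss(["FYVE", "PI3_PI4_kinase"],
...                      ["FYVE", "PI3Ka", "PI3_PI4_kinase"])
[('PI3Ka', 2)]
```

the viral architecture skips the host's internal `PI3Ka` (host position 2)
while keeping both flanks in order — the signature of internal-domain
elimination.

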