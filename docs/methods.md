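# Methods

## The screen

`hijackscan` implements a desk-scale screen for proteins that viruses
acquired from their metazoan hosts (host-to-virus, H2V, transfer) and for
the architectural "simplification" signature such captured proteins carry.
The screen has three stages, applied in order:

1. **Family filtering.** Cross-taxa families — sequence clusters or domain
   families containing both viral and cellular members — are reduced to an
   analysis set. Clusters must have ≥ 2 members, ≥ 1 viral and ≥ 1 metazoan
   member. Domain families must have ≥ 1 viral and ≥ 2 metazoan members
   (singleton metazoan matches are often contamination), must not be
   > 95% viral (near-pure viral families are viral structural elements —
   Env, Coat, Capsid — not captures), and must not sit on an exclusion
   list of promiscuously exchanged replication enzymes (polymerases,
   exo/endonucleases, helicases, tRNA synthetases, primases) or known
   contaminations (GFP). The exclusion list ships as an editable TSV of
   family ids and case-insensitive regex patterns, because the precise
   database-version family identifiers behind those categories are not
   enumerable here.

2. **Tree topology.** For each family with a leaf-labeled rooted tree, the
   *viral clusters* (VCs) are the maximal sub-trees whose leaves are all
   viral; each VC is parsimoniously read as one acquisition episode. A
   family is a transfer candidate when **(a)** the viral members are rare —
   viral fraction ≤ 5% of leaves, or at most 2 viral proteins — **and**
   **(b)** they are clustered — at most 2 VCs, or at most 10 VCs with a
   condensation factor (#viral / #VC) ≥ 3. Clause (a) excludes ancient,
   broadly distributed families where directionality is unclear; clause
   (b) excludes families whose viral members are scattered across the tree
   (many independent events, or contamination). All five thresholds are
   configurable (`SelectionThresholds`).

   Depth statistics are purely topological: a node's depth is its edge
   count from the root (root = 0), and the *normalized depth* of a leaf or
   VC root is its depth divided by the maximum leaf depth of the same tree.
   This edge-count convention is what makes the canonical worked example
   come out as 9/19 ≈ 0.474 for the deepest viral leaf and 4/19 ≈ 0.211
   for the VC root; counting nodes instead of edges would shift both.
   A VC's depth is the depth of its root node, not of its leaves — the
   only reading under which a cluster can be shallower than its members.
   Branch lengths never enter the statistics; they are used only for
   optional midpoint rooting of unrooted input trees.

3. **Architecture.** Proteins with ≥ 1 domain hit decompose into N-tail,
   domains, inter-domain linkers and C-tail (coordinates 1-based
   inclusive, Pfam convention). Per protein, **TAIL** is the mean of the
   two terminal segment lengths (zeros included) and **IDOL** is the mean
   inter-domain linker length, undefined for single-domain proteins.
   Captured viral proteins are expected to be trimmed relative to their
   metazoan counterparts: shorter overall, fewer domain occurrences and
   distinct domains, shorter TAILs and IDOLs. `detect_internal_loss`
   formalizes the strongest such signal: a viral architecture that is an
   ordered subsequence of the host architecture with the first and last
   domains pinned ("flanking domains maintained in the same order")
   witnesses the elimination of the skipped internal domains. Interior
   matching is leftmost-greedy, which is complete for subsequence testing
   because the final host position is reserved for the pinned last viral
   domain. Architectures with fewer than two viral domains provide no
   flanking evidence and report nothing.

Overlapping or nested domain hits are resolved greedily before
decomposition: descending score, ties broken by longer hit then smaller
start; unscored hits rank last. Pfam-curated hits are already
non-overlapping, so this only matters for raw scanner output.

## Statistical tests

Comparisons between the viral and metazoan sides use the two-sample
Kolmogorov–Smirnov test (D = maximum ECDF distance; asymptotic p-values,
appropriate for the 10³–10⁵ sample sizes this screen targets, with an
exact-formula fallback at degenerate sizes), the classical paired t test
on per-family class means, and one-sided tail probabilities for
enrichment. The "viral mean shorter in a fraction of families" enrichment
is by default a binomial sign test against p₀ = 0.5 — under the null a
family's viral mean is equally likely to fall on either side of the
metazoan mean — with a hypergeometric urn variant available behind a flag
for users who prefer drawing family outcomes from a finite pool; the two
parametrizations are reported explicitly, never silently substituted.
No multiple-testing correction is applied by default; a Benjamini–Hochberg
column is opt-in.

Degenerate inputs are errors, not NaNs: empty samples for KS, zero-variance
nonzero differences for the paired t (identical samples return t = 0,
p = 1), single-leaf trees for normalized depth.

## The synthetic cohort generator

Real inputs at corpus scale (UniRef90-style clusters, Pfam-style families
and their trees) require database snapshots; the generator replaces them
with cohorts whose every relevant property is planted and recorded in a
ground-truth JSON kept separate from the data files.

Per family: a canonical metazoan architecture is drawn (domain count
Poisson around 3, min 1, optionally fixed; domain lengths normal around
120 ± 25 aa, min 20). Metazoan members realize it with linkers from the
metazoan model; viral members are derived captures — each internal domain
dropped independently with probability `domain_loss_prob` (default 0.15;
flanks always retained, which is what makes planted losses recoverable by
the flank-pinned subsequence test), and all linkers redrawn from the viral
model. Linker lengths are geometric by default (discrete, mode at 0,
matching the short-heavy empirical linker histograms); a gamma option
(shape 2) gives a smoother alternative. Default linker means are the
study conditions the screen targets: TAIL 14 (viral) vs 85 (metazoan) aa,
IDOL 30 vs 67 aa. Default member counts (≈60 metazoan, ≈3 viral per
family, Poisson) realize a viral fraction near the 5% selection boundary
so both selection outcomes occur in a default cohort.

Trees: a backbone (Yule-like random splits, or caterpillar) is built over
the metazoan leaves; the viral leaves are partitioned into exactly
`n_viral_clades` groups, and each group's clade replaces a distinct
metazoan leaf M by the node (M, clade). Since every internal node of the
result retains a metazoan descendant, the planted clades are exactly the
maximal viral sub-trees: VC recovery is exact by construction, not
approximately. All branch lengths are 1; the statistics ignore them.

A fixed seed makes cohorts byte-identical; family *i* draws from the
independent stream `[seed, i]`, so families are reproducible individually.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence evolution and alignment/tree-estimation
error (trees are planted, not inferred); UniRef redundancy structure;
fragment annotations; compositional biases of real proteomes; domain
families shared across families. Recovery results on synthetic cohorts
certify the pipeline's operations, not the biological error rates of the
screen on a live database.

## Numerical and design choices

- Normalized depths are computed in exact rational arithmetic
  (`fractions.Fraction`) and converted to float only for reporting.
- The selection rule combines its two clauses with AND and the
  alternatives within each clause with OR. Under the default thresholds a
  family with 10 viral of 146 leaves (6.8%) and 2 VCs is *rejected* — the
  rarity clause fails — even though such families can be biologically
  compelling; the thresholds are configurable precisely because the
  boundary cases are judgment calls.
- Viral fraction uses member counts, not species counts; family summaries
  weight per protein by default with a per-species option (first protein
  per species) behind a flag.
- Proteins with no domain hit are excluded from architecture statistics
  (decomposition is undefined without a domain anchor) and counted.
- Ties for the deepest viral leaf are reported in full.
- Test problem sizes (cohorts of tens of families, hundreds of proteins
  per class, 1,000-tree oracle sweeps) were chosen so the whole suite runs
  in seconds while keeping every Monte-Carlo band at ≥ 3 standard errors;
  the linker-recovery contract averages five replicate 500-protein/class
  cohorts because a single cohort estimates a geometric mean of 14 aa with
  a ~0.46 aa standard error, making a 5% band a ~1.5 SE test.

## Known limitations

- Directionality (host→virus vs virus→host) is asserted by the selection
  heuristic, not proven; deep-branching viral clades, endogenized viral
  elements and database contamination can all mimic or mask the signal.
- The internal-loss detector requires exact domain-id matches and reports
  the leftmost embedding when repeats make the embedding ambiguous.
- Midpoint rooting requires branch lengths on every edge and resolves the
  root deterministically via dendropy; trees rooted elsewhere will yield
  different (still internally consistent) depth statistics.
- The hypergeometric variant of the enrichment test requires the caller to
  specify the urn; no default pool is assumed.
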