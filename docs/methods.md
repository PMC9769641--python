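# Methods

This note records the models, conventions and design choices behind
`simmg-eval`, in the spirit of a statistical-software methods appendix.

## The comparison model

All repertoire comparisons are made in presence/absence. A feature
(KO, EC or MetaCyc pathway) is *present* in a sample iff its reported
abundance is strictly positive; an abundance of 1e-12 counts, because the
upstream tools (HUMAnN2-style profilers, PICRUSt2) already apply their own
evidence thresholds and this package deliberately consumes, rather than
re-litigates, their calls. For pathways in particular, "present" means the
profiler reported a nonzero pathway abundance; pathway completeness is the
profiler's concern.

For three per-sample feature sets MG, MT, simMG, the universe is
partitioned into 7 exclusive regions (three "only", three pairwise-only,
one triple). Region counts are computed per sample and then averaged
across samples; the percent-similarity formula is applied **once to the
averaged counts** (average-then-compute). A compute-then-average variant
(`per_sample_similarity`) exists for sensitivity analysis; the two differ
whenever region counts vary across samples, since the statistic is a
nonlinear ratio.

### Percent similarity

`% = 2I/(2I + R) × 100`. Conventions that the formula alone does not fix:

- **Pairwise X:Y** — *I* is the full two-set intersection, i.e. the
  exclusive-pair region plus the triple region. This makes the pairwise
  statistic identically the Sørensen–Dice coefficient, which is the only
  reading consistent with pairwise values that exceed the three-way value
  when the triple region dominates.
- **Pairwise universe** — *R* is restricted to the pair (features found
  only by the third method are ignored), keeping each pairwise value
  independent of the third method. The stricter alternative that adds
  third-method-only features to *R* is available as
  `pairwise_universe="triple"` but is not the default.
- **Three-way** — *I* is the triple region, *R* the other six regions.
- Δ-similarity values are differences in **percentage points**
  (prokaryote-only minus total), reported to two decimals.
- An all-empty comparison is undefined and returns NaN with a warning
  rather than 0 or 100.

## Prokaryote filtering

Two-step classification of MG/MT features, in order of precedence:

1. **Shared with the simulated metagenome** ⇒ prokaryotic. A 16S-derived
   simulation can only contain bacteria and archaea, so co-occurrence in
   the simMG certifies the domain regardless of lineage text (a feature
   shared with simMG but carrying viral lineage text is retained). A
   stricter alternative would require co-occurrence in MG *and* MT; the
   simMG-shared reading is the implemented rule and the audit table makes
   any feature's evidence inspectable.
2. **Lineage text** — prokaryotic iff the text contains the
   case-sensitive whole token `Bacteria` or `Archaea`. The rule is
   liberal: text containing both prokaryotic and eukaryotic/viral tokens
   is prokaryotic. Recognised non-prokaryotic tokens include `Eukaryota`,
   `Viruses`, `Viridiplantae`, `Metazoa`, `Fungi`. Case sensitivity
   avoids matching incidental words like "bacterial host" but will miss
   lower-cased rank names; this is a recorded limitation, visible in the
   audit rather than silently absorbed.

Features that are neither shared nor resolvable are `unknown` and are
**removed by default** (they cannot be certified prokaryotic); a
`keep_unknown` switch retains them. The simulated profile passes through
the filter unchanged. Filtering is idempotent and can only decrease
per-sample counts.

`extract_lineage` is an offline stand-in for scraping live database
pages: it concatenates the value spans of lines headed by configurable
rank keywords (default `Superclasses`, `Taxonomic Range`, `Organism`,
`Taxonomy`) from saved record text.

## NSTI filter

ASVs whose nearest-sequenced taxon index exceeds the cutoff (default 2)
are discarded; the comparison is **strictly greater than**, so NSTI = 2.0
is retained. The operation reports the computed ASV fraction and the
read-weighted fraction without re-rounding to match any external report
(71/1,129 = 6.29%, for example, is reported as 6.29).

## Gene sets

Curated lists ship as editable TSV fixtures rather than hard-coded
constants, because KEGG/CAZy/MetaCyc are versioned resources.

- **SCFA** — 16 fermentation pathways with product labels. Ten carry
  their real MetaCyc IDs (P161-PWY, P162-PWY, P163-PWY, P124-PWY,
  P461-PWY, PWY-5100, GLUDEG-II-PWY, PWY-5677, PROPFERM-PWY,
  ANAEROFRUCAT-PWY); the remaining six are synthetic stand-ins
  (`SYN-SCFA-PWY-n`, labelled synthetic in code and name) chosen to
  complete the product multiplicities 6 acetate / 7 butyrate / 5 lactate
  / 3 propionate — 21 assignments over 16 pathways, hence 5 multi-product
  pathways. `scfa_geneset(extra=...)` accepts a user-supplied list when
  the full real identities are known.
- **AMR** — 162 unique synthetic KOs (`K99xxx` namespace) over 11
  antibiotic classes with catalogue class sizes
  (aminoglycosides 39, fosfomycin 5, MLS 19, penicillin 66, phenicol 8,
  quinolone 2, rifamycin 4, sulfonamide 3, tetracycline 11,
  trimethoprim 6, vancomycin 18); the 19 assignments beyond 162 are
  distributed as second classes deterministically. A methicillin class
  exists in some catalogues; this fixture follows the 11-class list.
- **CAZy** — a placeholder of 102 synthetic ECs labelled GH5/GH6/GH7.

Reporting percentages (`percent_more`, `coverage_fraction`) round
half-up to two decimals. Note the two are different statistics with
different domains — `percent_more` compares any two repertoires,
`coverage_fraction` requires shared ≤ reference — even though
`coverage = 100 + percent_more` algebraically where both are defined.

## Ordination and tests

- **Jaccard distance** `1 − |A∩B|/|A∪B|` between presence vectors via
  `scipy.spatial.distance`; two all-absent vectors get distance 0 by
  convention, flagged with a warning.
- **PCoA** is classical scaling: eigendecomposition of the
  double-centred −D²/2. Negative eigenvalues (common for Jaccard
  matrices) are reported unaltered — no Cailliez/Lingoes correction —
  and coordinates are built on the positive axes only, with proportions
  relative to the positive eigenvalue sum. When D is
  Euclidean-embeddable the embedding reproduces it to numerical
  precision.
- **PERMANOVA** uses the distance-based one-way formulation computed
  directly from D (no coordinates): SS_total = Σ_{i<j} d²/N,
  SS_within = Σ_groups Σ_{i<j∈g} d²/n_g,
  pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)),
  R² = SS_between/SS_total. The p-value is
  (1 + #{F_perm ≥ F_obs})/(1 + n_permutations) over label permutations
  from a seeded generator; the default 999 permutations give a floor of
  0.001. Because permutations are sampled with replacement from the
  permutation group, the observed partition can recur, so the attained
  minimum can sit slightly above the floor. An exhaustive enumerator
  (`permanova_exact`, two groups) serves as an oracle at small n, and the
  implementation is cross-checked against scikit-bio in the test suite.
- **"Wilcoxon rank-sum"** is implemented as the two-sided Mann–Whitney
  test (not a t test): exact null distribution when both samples have
  ≤ 10 observations and no ties, otherwise the normal approximation with
  tie and continuity corrections. Pairwise method comparisons are
  reported unadjusted by default; `holm_adjust` is available.

## Genus contributions

A genus is *abundant* if its 16S relative abundance **strictly exceeds**
the threshold (default 5%) in at least one sample. Contribution is a
count of **distinct KO identifiers**, not an abundance-weighted share:
per sample, genus fraction = distinct KOs with any stratified abundance
attributed to the genus ÷ distinct KOs detected in the community table.
The combined fraction counts KOs attributed to ≥ 1 selected genus, so
overlapping attributions are not double-counted; KOs stratified only to
unclassified taxa stay in the denominator. An abundance-weighted variant
sits behind a flag. Genus matching strips the `g__` prefix and is
case-sensitive thereafter.

## The synthetic generator

`generate_study` emulates the data *structure* of a paired multi-omics
study, not its biology:

- **Defaults as study conditions** — 9 paired samples; 224 planted
  features with the triple region largest (90), MG∩sim second (45) and
  MT∩sim smallest (4), mirroring the qualitative UpSet structure of
  sequenced-vs-simulated comparisons; 12 viral/eukaryotic contaminants
  planted into MG and MT only; an ASV table of 1,129 variants with
  exactly 71 above the NSTI cutoff; a 9-genus pool with Dirichlet
  (concentration 60) per-sample relative abundances around fixed weights.
- **Noise model** — presence noise drops a planted feature
  independently per feature × sample × method with probability *p*
  (the simplest exchangeable model, sufficient for recovery tests);
  `mt_dropout` removes whole features from the MT table and updates the
  recorded truth so planted-truth recovery remains exact. There are no
  false-positive presences.
- **Namespaces** — feature IDs are syntactically valid but synthetic
  (`K9xxxx`, `9.9.x.x`, `SYN-PWY-n`) so fixtures never collide with or
  imply real catalogue entries.
- **Abundances** are lognormal(5, 1) where present; all downstream
  statistics are presence-based, so the abundance law only matters for
  scaling-invariance tests.

What the generator does **not** emulate: read-level sequencing error,
compositional abundance structure, phylogenetic realism of lineages,
correlated dropout between methods, or database bias. Passing
planted-truth tests therefore certifies the *bookkeeping* of the
pipeline — set arithmetic, filtering, attribution — not the field
accuracy of metagenome simulation on real data, which depends on the
reference databases available for the host's microbiota.

## Numerical and degenerate-input choices

- Duplicate feature rows in input tables are summed, not rejected
  (merged multi-tool exports commonly repeat IDs);
  UNMAPPED/UNGROUPED/UNINTEGRATED rows are excluded from the feature set
  but their summed mass is kept as a diagnostic.
- Samples missing from any method are dropped at merge time (a simulated
  sample without a complementary sequenced sample cannot be compared).
- Noiseless region counts make within-group Jaccard distances zero, so
  the PERMANOVA pseudo-F degenerates to infinity; this is reported with
  a warning rather than masked.
- The pipeline writes its TSV bundle atomically (staged in a temporary
  directory) so failures leave no partial outputs, and a manifest
  records a hash of the analytic configuration (output location
  excluded), the seed and the package version. One seed governs every
  stochastic stage.
- Test and acceptance problem sizes (e.g. 500 null replicates × 999
  permutations for PERMANOVA calibration, 200 replicates for noisy
  recovery, 1,000 random triples for the decomposition oracle) were
  chosen as the smallest sizes at which the checked tolerances are
  statistically meaningful.

## Known limitations

- Case-sensitive token matching can misclassify lower-cased lineage
  text as unknown.
- `percent_similarity` on averaged counts inherits the
  average-then-compute convention; users wanting per-sample uncertainty
  should use the per-sample variant.
- BIOM input, live database retrieval, figure rendering and read-level
  QC are out of scope by design; inputs are the TSV exports of the
  upstream profilers.
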