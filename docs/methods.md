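# Methods

This note documents the models and procedures implemented in `phenomatch`,
the choices made where the design was genuinely open, and what the synthetic
study generator does and does not emulate.

## Merged ontology and information content

The scorer operates on a single rooted directed acyclic graph containing
human-phenotype (HP) and mammalian-phenotype (MP) branches connected through
shared ancestor terms. Only `is_a` edges are honoured: the subsumption
hierarchy of the phenotype ontologies is `is_a`-based, and restricting to it
keeps closure semantics unambiguous (`part_of` and other relationships are
ignored at parse time). Obsolete terms are dropped when parsing; an `is_a`
reference to a dropped or missing term is a hard structural error rather
than a silent remap — no `replaced_by` chasing in this version. Cyclic
`is_a` structure is rejected, naming one cycle member.

Ancestor sets are *reflexive* (every term is an ancestor of itself), so a
term compared with itself attains Jaccard similarity 1 and the
self-comparison baseline below is well defined.

Information content is annotation-frequency based and uses natural
logarithms: `IC(t) = -ln(count(t)/N)`, where `count(t)` is the number of
distinct corpus entities annotated to `t` or any of its descendants and `N`
is the corpus size. Two boundary rules keep the table finite and
well-ordered:

* never-annotated terms receive the maximum `ln(N)` (their frequency is
  treated as 1) instead of infinity — bounded and deterministic, and never
  larger than a genuinely annotated subsumer at equal count;
* roots are fixed at IC 0 by construction. With a single connected root
  this coincides with the counting rule (every entity propagates to the
  root); with multiple roots it enforces the intended semantics that a root
  carries no information even if the corpus happens to annotate only part
  of the graph.

The production corpus behind published cross-species pipelines is not
publicly specified, so the IC corpus here is a deliberate, overridable
default: the union of all annotated diseases and models (internal and
external) supplied to the pipeline, one entity each. Both the corpus and
the log base are config-exposed rather than asserted.

The most-informative common ancestor (MICA) of two terms is the common
ancestor with maximal IC. Ties on IC are broken towards the
lexicographically smallest term id, making the returned term deterministic;
the returned IC value is unique regardless. Disconnected term pairs return
the sentinel `(None, 0.0)`.

## Pairwise term similarity and the percentage score

The default pairwise form is the geometric mean of the Jaccard index of the
reflexive ancestor sets and the MICA's information content:

    s(q, h) = sqrt( J(q, h) * IC(MICA(q, h)) )

This combines topological overlap (J) with specificity (IC) and is the form
used by the cross-species algorithm this package follows; `resnik`
(IC only) and `jaccard` (J only) variants are selectable for sensitivity
analyses, with the geometric form fixed as the default for reproducibility.

A disease (HPO set) is compared against a model (MP set) by matching each
*disease* term to its best model term — disease annotations are the
queries; ties go to the lexicographically smallest hit id. With `raw_max`
and `raw_mean` the max and mean of those per-query best scores, and
`(opt_max, opt_mean)` the same statistics of the per-term self-similarities
`sqrt(IC(t))` of the disease set (the profile a model mimicking every
disease phenotype exactly would achieve):

    percentage = 100 * (raw_max/opt_max + raw_mean/opt_mean) / 2

clamped to [0, 100]; a disease annotated only to zero-IC roots is
degenerate and scores 0 by convention. The max-ratio and mean-ratio
components are weighted equally. The direction is intentional and
asymmetric — more HPO terms make full coverage harder while more MP terms
offer more candidate hits; a symmetric variant that averages both
directions (and normalises against both self-profiles) is available behind
a flag but is not the default, because whether production pipelines average
one or both directions is not publicly specified. Output percentages are
reported to 2 decimals; internal values keep full precision.

Note a structural property of this functional form: for two *distinct*
terms, `J < 1` and `IC(MICA) <= IC(query)`, so a cross-species hit can
never reach the query's self-similarity ceiling exactly. A model therefore
attains percentage 100 only when its term set contains the disease's own
terms — which is why near-maximum scores are the practical ceiling of real
cross-species comparisons, and why the generator's exact-calibration
control (below) uses the identity image.

## Catalogues and the ortholog filter

Models, diseases, orthologs and the external catalogue are TSVs with
semicolon-delimited term lists; readers validate enum labels, term-id shape
(`HP:NNNNNNN`/`MP:NNNNNNN`), and counts, reporting the offending row.
Records with empty term sets are legal but ineligible for scoring. A
`lethal` viability label requires the preweaning-lethality flag; viability
is an input field and is never recomputed from raw viability-screen counts
(those thresholds are out of scope here). Hemizygous models are accepted as
a label and pooled with homozygous in the statistical layer.

The ortholog map keeps pairs supported by at least 5 of 12 prediction
services and then applies a one-to-one constraint in both directions.  The
threshold is applied *before* the bijectivity test, so a low-support
paralog prediction cannot veto a high-support one-to-one pair; the reverse
order is defensible but weaker, and the choice is documented and tested. A
consequence worth knowing: raising the threshold can occasionally *grow*
the map, by removing a low-support pair that was vetoing a high-support
one — the surviving pair set, not the map, is what shrinks monotonically.

## Pipeline semantics

* Eligibility: a pair is scored when the model's mouse gene maps one-to-one
  to the disease's human gene and both term sets are non-empty. All
  eligible models (embryo or adult, homozygous or heterozygous) are scored
  against the same disease HPO set; stage-aligned comparison is future
  work.
* Match calling is strictly `percentage > 0`.
* Gene aggregation takes the best pair per gene; ties break to the smallest
  `(model_id, disease_id)` for determinism (real analyses only need the
  existence and value of the best match, but determinism keeps outputs
  byte-stable).
* Novelty: a matched gene is novel versus the external catalogue when that
  catalogue has no model for the gene or no external model scores above 0
  against the same disorders (external models are scored with the same
  scorer and IC table).
* Lethality rescue applies only to unmatched genes: any preweaning-lethal
  model plus a curated pre-infant death report rescues; childhood reports
  rescue only behind `--include-childhood`. Matched genes are never
  relabelled, so rescues are additive to phenotype matches.

## Statistical layer

* **Enrichment** works per gene; a gene associated with disorders in
  several categories contributes to each category's 2×2 table (category
  labels follow overlapping panel-style disease classes). Each category is
  tested against all others with the two-sided Fisher exact test; the
  sample odds ratio `ad/bc` is reported with a Wald log-scale 95% CI
  (`+inf` when `bc = 0` with `a, d > 0`; undefined cells reported as
  missing), and Benjamini–Hochberg adjustment is applied across the
  category family. The sample OR was chosen over the conditional MLE
  because the reported quantity is a descriptive effect size; the p-value
  is exact either way.
* **Bivariate**: two-sided Wilcoxon rank-sum for annotation counts (exact
  null distribution for small tie-free samples, midranks with the normal
  approximation otherwise), Pearson correlation for score–count relations.
* **Regression**: unpenalised maximum-likelihood logistic regression of
  match status. The unit of analysis is the model–disease *pair* (matches
  are pairs with a positive score), whereas enrichment uses genes; both
  tables are emitted. Continuous covariates are standardised to z-scores so
  coefficients are per-SD effects; categorical features are one-hot against
  a declared reference level. Wald 95% intervals are reported; complete
  separation and non-convergence raise explicit errors instead of returning
  silently divergent estimates. The default feature set is the union of
  features the match analysis names (procedures completed, MP terms, HPO
  terms, zygosity, viability, disease category, early-death indicator,
  mode of inheritance) and is extensible; viability-category match rates
  can be computed at both gene and model level since either unit is
  defensible.

## Synthetic study generator

The generator emulates the *schemas* and the *statistical structure* of a
real KO–disease corpus, not its content:

* **Ontology**: one root, `n_shared_ancestors = 8` phenotype-system nodes,
  and under each a pair of mirrored complete 3-ary subtrees of depth 4
  (27 leaves per namespace per system; 649 terms in total). Every HP leaf
  has an MP counterpart whose only informative shared ancestor is the
  system node — cross-species similarity is achievable and its ceiling
  computable, standing in for the real (undescribed) HP–MP bridging graph.
* **Genes**: 2,400 disease-associated genes (the scale of real
  disease-gene model sets), padded to ~7,700 by non-disease genes
  (`fraction_disease_associated = 0.31`, matching the reported fraction of
  phenotyped genes with a disease ortholog). Each disease gene carries one
  disorder (20% a second, on disjoint phenotype systems); lethal genes get
  a homozygous embryo model plus a heterozygous adult model, others one
  homozygous adult model (2% hemizygous), mirroring how lethal lines are
  phenotyped. Viability mix is 24/8/68% lethal/subviable/viable, the
  reported screen-wide ratio.
* **Planted match structure**: each pair's match propensity follows a
  logistic model on z-scored `n_procedures` (+0.5), `n_mp_terms` (+0.8),
  `n_hpo_terms` (−0.5), `homozygous` (+0.4), `early_death` (+0.6), plus
  log category-odds (endocrine ×3, respiratory ×0.6, others ×1) — the
  qualitative pattern reported for real match determinants. The intercept
  is *calibrated*: a root-finder sets it so the expected gene-level match
  rate equals the configured target (55%, the reported fraction of matched
  disease genes). This calibration is part of the study conditions; the
  realised rate then varies only by binomial noise.
* **Exactness by construction**: a matcher model carries at least one MP
  leaf from the mirror image of its disease's HPO set (guaranteeing a
  positive score); a non-matcher's terms come from systems disjoint from
  every disorder of its gene (guaranteeing zero). Planted labels therefore
  coincide exactly with realised match calls, which the test suite verifies
  by running the scorer over a full study. `mirror_copy` mode instead
  annotates models with the identity image of their disease's term set in
  the merged (species-neutral) graph — the control in which every pair
  scores exactly 100.00.
* **Determinism**: one global seed; each table draws from a derived
  sub-stream, so regeneration is stable and OBO/TSV outputs are
  byte-identical across runs.

What the generator does **not** emulate: real term-set size distributions
beyond order-of-magnitude ranges (config-exposed), tens-of-thousands-term
ontologies, clinical-record text, negative-phenotype annotations, phenotype
frequencies, or genetic-background effects. Its regular tree geometry also
makes matched-pair scores much more homogeneous than real score
distributions — a passing suite shows the algorithms are correct and the
planted structure recoverable, not that real corpora behave this way.

## Numerical and testing choices

* Scores are compared against independent brute-force re-derivations
  (fixpoint closures, explicit entity counting, exhaustive intersection
  scans, scalar re-implementation of the whole percentage formula) to
  1e-9 on hundreds of random toy instances.
* Fisher p-values are checked against full hypergeometric enumeration over
  every 2×2 table with row margins ≤ 20; BH q-values against the step-up
  formula; small-sample Wilcoxon p against exhaustive rank-permutation
  enumeration.
* Coefficient recovery is assessed over 200 full-scale replicates: all
  planted signs must be recovered in ≥95% of replicates, and each planted
  continuous coefficient must lie within 2 standard errors of its estimate
  in ≥90% of replicates (the ±2SE event has ~95% probability per replicate
  by construction, so demanding it of a single fixed replicate would fail
  by chance; the frequency form tests the same property robustly). These
  replicates fit on the generator's planted labels after a full-scoring
  replicate establishes that planted labels and realised calls coincide
  exactly.
* The planted 3× category must reach BH q < 0.05 in ≥90% of 50 full-scale
  seeds. The complementary false-flag check (multiplier-1 categories
  flagged in ≤10% of seeds) is run under an all-multipliers-1
  configuration: when one category is genuinely enriched, the one-vs-rest
  odds ratio of every *other* category shifts away from 1 mechanically, so
  a neutral multiplier does not imply a null hypothesis under the default
  config.
* Problem sizes in the suite: oracle equivalence on 200 instances of ≤60
  terms; ontology invariants on 100 random DAGs of ≤50 terms; recovery at
  the full default scale (2,400 disease genes per replicate). Unit tests
  use smaller studies (80–250 genes) where only logic, not power, is at
  stake.

## Known limitations

* Exact 100% calibration requires the identity image (see the structural
  note above); mirrored cross-species leaf sets score high but below 100 by
  construction of the pairwise form.
* The rescue rule keys on a single curated early-death field; real age-of-
  death records are heterogeneous and harder to compare.
* No `replaced_by`/`consider` resolution for obsolete terms; annotations to
  unknown terms fail loudly by design.
* The regression treats pairs as independent although models of the same
  gene share features; planted-truth recovery is unaffected (the generator
  draws pairs independently), but on real data clustered standard errors
  would be more defensible.
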