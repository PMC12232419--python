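# Methods

This note documents the models, parameters and design choices behind
`herbnet`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, what the
synthetic data do and do not emulate, and where the genuinely open choices
were made.

## Knowledge-base model

Five two-column TSV tables define the analysis universe: prescription→herb
membership, prescription→phenotype indications, herb→compound composition,
compound→target-gene associations and phenotype→gene annotations.
Identifiers are opaque strings — no ontology mapping or cross-database ID
standardization is attempted; a curated knowledge base (or the synthetic
generator) is assumed to have resolved identities upstream. Loading
deduplicates pairs, skips and counts malformed rows, and reports (never
drops) unresolved cross-references: a prescription herb without compound
rows still participates in rule mining, so target sparsity cannot bias
support counts. The loader is agnostic about whether compound–target pairs
are experimentally validated or predicted; that provenance choice belongs
to whoever builds the tables.

## Association rule mining

Transactions are herb itemsets per prescription (herb level) or compound
itemsets per herbal material (compound level, labelled with the union of
phenotypes over prescriptions containing the herb). Rules have the form
`itemset → phenotype`; phenotype labels never enter the item universe, so
no herb→herb rules arise, and multi-phenotype consequents are not mined —
a prescription with k labels contributes to k separate consequent counts.

`min_support` applies to the joint itemset (antecedent ∪ consequent): the
smallest qualifying transaction count is `ceil(min_support · n)`. Defaults
are 0.0005 (herb level) and 0.0008 (compound level); the synthetic-study
analyses in the tests, the examples and `scripts/acceptance.py` use 0.01
and 0.02 respectively, the same thresholds rescaled to a 2000-prescription
/ 120-herb knowledge base so that a qualifying rule still needs on the
order of 20 (resp. 3) supporting transactions.

The miner is an exact level-wise Apriori over transaction-id posting
lists, run per phenotype on the subset of transactions carrying that
label; antecedent counts are taken over all transactions. Antecedent size
is capped at 4 by default (the largest combination the analysis is
expected to surface; configurable). The emitted rule list is sorted by
descending confidence, then descending lift, then lexicographic
antecedent, then consequent — a total order fixed purely for
reproducibility, and the tiebreak used by `per-phenotype-best` selection.
The test suite proves the miner identical to exhaustive subset enumeration
on small instances, including all counts and metrics.

## Interactome distances and the permutation null

The interactome is undirected, simple, and restricted to its largest
connected component. The closest-distance metric

d(P, S) = (1/|S|) Σ_{s∈S} min_{p∈P} d(p, s)

uses unweighted shortest paths; it is deliberately asymmetric (targets are
averaged, module genes are minimised over). Genes absent from the
interactome are dropped from both sets with a logged count; a set left
empty is an error naming the offending side. For graphs up to 5000 nodes a
dense all-pairs BFS matrix (scipy `csgraph`, int16) is cached so the
permutation null is vectorised; larger graphs use per-call multi-source
BFS from P. Both routes are tested against an independent BFS oracle.

The null model replaces **both** P and S with degree-matched random node
sets in each permutation — following the construction of two random groups
— rather than resampling only the target side as some proximity variants
do. Degree matching uses adaptive occupancy bins: nodes are grouped by
exact degree and consecutive degree groups are merged (lowest first) until
every bin holds at least `min_bin_size` nodes (default 10), the tail bin
merging downward. Where a degree is abundant the bin is effectively
exact-degree; in the heavy tail bins span geometrically growing ranges,
which is the conventional logarithmic-style binning for this null — exact
tail matching is infeasible. Within one sample, draws are without
replacement (widening to adjacent bins if a bin is exhausted); across
permutations, draws are independent. With this binning, sampled sets
reproduce template mean degree to within a few percent except for
templates containing the extreme tail, where binning necessarily
underestimates hub degree.

The relative proximity is z = (d_obs − μ_d)/σ_d with μ_d, σ_d the sample
mean and SD (n−1 denominator; configurable via `ddof`) of the
`n_perm` = 1000 null distances (tests and desk-scale runs use 200 with
correspondingly widened tolerances). A zero null SD flags the result
degenerate: z is NaN, never ±∞, and downstream predicates refuse it.
Calibration holds by construction and is verified empirically: for
degree-matched random set pairs the z distribution has mean ≈ 0 and
SD ≈ 1.

## Proximity verdicts

A target set is *proximal* at z ≤ −0.15, the threshold established in
earlier interactome-proximity screens as balancing coverage of known
associations against false positives; the boundary is inclusive. A herbal
combination's verdict requires a strict majority of its resolvable herbs
to pass (`majority_fraction = 0.5`, configurable; herbs with no usable
targets are reported and excluded from the denominator). Note the
operating characteristics of the majority verdict: because z for a random
target set is approximately standard (and the null distance distribution
is right-skewed, putting the empirical per-herb false-positive rate near
0.35 at this threshold), a majority-of-4 verdict falsely calls a random
combination proximal in roughly 10–30% of runs. Screens wanting a stricter
guarantee should set `majority_fraction = 1.0` (all herbs must pass —
which is the pattern actually observed for reported combinations).

Seeds: one master seed per run; each (entity, phenotype) proximity
computation derives a child seed as
`(master · 1000003 + crc32(entity|phenotype)) mod (2³¹−1)`, so individual
results are reproducible and order-independent.

## Group contrast

The Fig.-style summary contrasts the per-herb z values of the top 5% of
rules (by confidence, capped at `max_summary_rules` per phenotype to bound
runtime) against a reference distribution, implemented as the pooled
standardized permutation-null distances gathered while scoring those rules
— mean ≈ 0 by construction, matching the interpretation of the reference
as distances between randomly selected gene groups. The two-sample test is
Student's t when the rule group has ≥ 5 members, otherwise the exact
Mann–Whitney U (two-sided), mirroring the practice of switching to a rank
test when too few rules exist.

## Structural network analysis

Hubs are top-k by degree and bottlenecks top-k by exact normalized
betweenness (endpoints excluded), computed on the subgraph induced on
targets ∪ phenotype genes with node roles annotated. Centralities are
computed on this subnetwork, not the full interactome — on the full graph
every report would be identical regardless of the target set under study;
this is an interpretation choice, documented as such. k defaults to 3.
Ties break lexicographically by gene id.

## Synthetic-data generator

Defaults (the study conditions used throughout the tests and the
acceptance script): 2000 prescriptions, 120 herbs, 300 compounds (5 per
herb, drawn from a shared universe), 1000 genes, 8 phenotypes with
20-gene connected modules grown by BFS, Barabási–Albert interactome with
attachment 3, background co-prescription rate 0.18 per herb (≈ 22 herbs
per background prescription), background label rate 0.003 per phenotype,
planted rules at support 0.15 and confidence 0.8, carrier extra-herb rate
`noise/10`, 3 targets per compound, `proximity_planting` 0.8, and a
6-compound effective pool per planted rule shared across its herbs.

Rationale for the non-obvious choices:

- **Planted support 0.15** gives ≈ 300 carrier prescriptions, enough for
  the empirical confidence of the planted rule to estimate its target to
  within a few hundredths while remaining a small minority of the corpus.
- **Any** prescription containing a planted combination (carrier or
  background) is labelled with its phenotype at the confidence rate, so
  empirical rule confidence converges to the target as n grows regardless
  of background co-occurrence. Labelling is probabilistic per prescription
  (rejection-free), hence unbiased.
- **Background rates** (0.18 co-prescription, 0.003 labels) make proper
  sub-combinations of a planted rule occur, diluted and mostly unlabelled,
  in the background — so the full planted antecedent strictly beats its
  own subsets on confidence — while keeping spurious high-lift pair rules
  effectively impossible at the analysis support thresholds. Targets are
  infeasible when expected background occurrences of a combination exceed
  half its carriers; the generator refuses them.
- **Effective pools** make the planted herbs share most compounds,
  emulating active constituents recurring across a formula's herbs, which
  is what gives compound-level rules their signal.
- The generator does **not** emulate: dosage, plant part or processing
  fields; compound chemistry or pharmacokinetics; phenotype ontology
  structure; shared compounds between unrelated herbs beyond uniform
  reuse; correlated herb popularity. Passing recovery tests therefore
  demonstrate that the pipeline recovers the statistical structure it
  models — not that real curated databases satisfy that structure.

Ground truth (planted rules, effective compounds, module genes, seed) is
written to `ground_truth.json`, never into the KB tables.

## Numerical and degenerate-input conventions

Minimum qualifying counts use `ceil(min_support·n − 1e−9)` to guard float
representation at printed thresholds. Distances are integer shortest
paths averaged, hence multiples of 1/|S|. Deterministic output: all
serialized tables are sorted with fixed float formatting, and repeated
runs under one master seed are byte-identical. Degenerate cases — empty
itemsets, herbs without compounds, phenotypes without genes, empty
induced subnetworks, zero-SD nulls — are skipped-with-count, warned, or
flagged rather than silently propagated.

## Problem sizes

Desk-scale analyses use the synthetic defaults above with 200
permutations per proximity score, 500 draws for null calibration, and
10–20 independently seeded replicates for recovery rates; these sizes
were chosen so the whole suite and the acceptance script each complete in
minutes on a single CPU while leaving Monte-Carlo error well inside the
asserted tolerances. The pipeline defaults (1000 permutations, supports
0.0005/0.0008) remain those appropriate for a full-scale knowledge base
of ~16k prescriptions and a ~27k-node interactome.

## Known limitations

- The proximity threshold −0.15 is inherited, not re-derived; its
  false-positive behaviour under the majority verdict is characterised
  above.
- Log-style degree binning biases tail-hub matching downward; with
  `min_bin_size` well below the node count this only affects templates
  containing the very highest-degree nodes.
- Compound-level transactions inherit phenotype labels from *any*
  labelled prescription containing the herb, which saturates for herbs
  appearing in many prescriptions under dense labelling; discrimination
  at the compound level therefore requires sparse indication labels, as
  in the synthetic defaults.
- Literature evidence is ingested from a user-supplied TSV
  (compound, phenotype, citation) and never inferred.
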