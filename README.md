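# herbnet

Association rule mining plus network pharmacology for traditional-medicine
prescription data: an interpretable, two-level screen for herbal-material
combinations and compounds with potential therapeutic effects on a
phenotype, backed by molecular-level evidence from the human protein
interactome.

It is written for computational pharmacology / systems-biology researchers
who have (or can emulate) a relational knowledge base linking
prescriptions → herbs → compounds → target genes and phenotypes → genes,
plus an undirected protein–protein interactome.

## The method

**Rule mining.** Each prescription is a transaction: its herb itemset,
labelled with its indicated phenotypes. Apriori mining proposes rules
`herb A, herb B, … → phenotype`, evaluated with

- support `= P(antecedent ∧ phenotype)` (joint fraction of transactions),
- confidence `= P(phenotype | antecedent)`,
- lift `= confidence / P(phenotype)`,

keeping rules whose joint support reaches a minimum (default 0.0005 at the
herb level; 0.0008 at the compound level, where each herbal material is a
transaction over its compounds). The best rule per phenotype is the
confidence maximiser with lift as tiebreak.

**Network proximity.** A herb's target set *H* is the union of its
compounds' target genes. Against the phenotype gene module *P*, the closest
distance on the interactome is

    d(P, H) = (1/|H|) Σ_{h∈H} min_{p∈P} d(p, h)

with unweighted shortest paths. Both sets are resampled 1000 times (default)
by degree-matched random node sets, giving a reference distribution with
mean μ_d and SD σ_d, and the relative proximity

    z = (d(P, H) − μ_d) / σ_d.

A herb passes at `z ≤ −0.15`; a combination is called proximal when a
strict majority of its herbs pass. The same machinery scores compounds
(`z_c`), and the candidate compounds for a phenotype are the intersection
of the top compound rules by confidence with the proximal
combination-related compounds. Hub (degree) and bottleneck (betweenness)
centralities on the induced target–phenotype subnetwork indicate which
targets carry the effect.

**Synthetic studies.** `herbnet.synthetic` generates knowledge bases and
preferential-attachment interactomes with planted rules (carrier
prescriptions labelled at a target confidence) and planted proximity
(effective-compound targets placed within distance 1 of the phenotype
module), emitting ground truth separately so every stage has a recovery
test.

## Worked example

```bash
python examples/04_full_pipeline.py
```

runs the whole analysis on the canonical synthetic study (2000
prescriptions, one planted 4-herb rule for phenotype PH00 at confidence
0.8, 1000-gene interactome) and prints:

```
phenotype PH00
  combination: H000 + H001 + H002 + H003
  rule: confidence=0.814 lift=6.43  |  combination proximal: True
  rule mean z = -3.52 vs reference -0.00 (mannwhitney-test p = 5.52e-04)
  ARM route compounds:      101
  proximal combination compounds: ['C0000', 'C0001', 'C0002', 'C0003', 'C0004', 'C0005']
  intersection (candidates):      ['C0000', 'C0001', 'C0002', 'C0003', 'C0004', 'C0005']
  planted effective compounds:    ['C0000', 'C0001', 'C0002', 'C0003', 'C0004', 'C0005']
```

Reading: the planted combination is recovered as the best rule (its
empirical confidence 0.814 matches the 0.8 planting target; lift 6.43 means
the phenotype is 6.4× more frequent under the combination than overall);
all four herbs are strongly proximal (mean z ≈ −3.5 against a reference
standardized to ≈ 0); and the compound-level intersection recovers exactly
the six planted effective compounds. `examples/01–03` walk the stages
individually.

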