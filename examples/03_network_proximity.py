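"""Score a herbal combination's interactome proximity to a phenotype module.

For each herb, the union of its compounds' target genes is compared with
the phenotype gene module via the closest distance d(P, H) — the average
shortest-path length from each target to its nearest module gene — and
standardized against 200 degree-matched permutations into a z-score. A
herb passes at z <= -0.15; the combination verdict needs a strict majority
of passing herbs.
"""

from herbnet import combination_proximity
from herbnet.synthetic import default_study_spec, generate_knowledge_base, herb_id

kb, truth, g = generate_knowledge_base(default_study_spec(seed=1))
planted = truth.planted[0]
ph = planted["phenotype"]

for label, combo in [
    ("planted combination", planted["herbs"]),
    ("random combination", [herb_id(i) for i in (50, 51, 52, 53)]),
]:
    verdict = combination_proximity(g, kb, combo, ph, n_perm=200, master_seed=1)
    print(f"{label} vs {ph}  ->  proximal: {verdict.proximal}")
    for r in verdict.results:
        print(
            f"  {r.entity_id}: d={r.observed_d:.3f}  null {r.null_mean:.3f}"
            f" +/- {r.null_sd:.3f}  z={r.z:+.2f}"
            f"  ({'pass' if r.z <= -0.15 else 'fail'})"
        )
    print()
print(
    "negative z: the herb's targets sit closer to the phenotype module than\n"
    "degree-matched random gene sets; the planted herbs are strongly proximal\n"
    "while the random combination hovers around the null."
)
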