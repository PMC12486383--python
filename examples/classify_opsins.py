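"""Assign opsin subtypes by bootstrapped distance classification.

Queries are placed into the reference alignment column space and voted
into the subtype with the smallest mean corrected distance over 200
column-bootstrap replicates; calls below 95% support are not accepted.
"""

from synopsin import presets
from synopsin.classify import classify_subtype

bundle = presets.paper_scenario(seed=1)
db = bundle.reference_db

species = "sea_lamprey"
truth = bundle.truth_subtypes(species)
genes = {g.gene_id: g for g in bundle.genomes.species[species]}

print(f"{'gene':<12} {'truth':<6} {'call':<10} {'support':>7}  accepted")
for gid, true_sub in sorted(truth.items()):
    res = classify_subtype(genes[gid].protein, db, n_boot=200, seed=42,
                           gene_id=gid)
    print(f"{gid:<12} {true_sub:<6} {res.subtype:<10} {res.support:>7.2f}  "
          f"{res.accepted}")

# a pre-WGD outgroup gene has no post-WGD subtype; it may still attract
# a confident-looking call or be rejected, depending on the realization
amph = {g.gene_id: g for g in bundle.genomes.species["amphioxus"]}
res = classify_subtype(amph["RH"].protein, db, n_boot=200, seed=42,
                       gene_id="RH(pre-WGD)")
print(f"\npre-WGD outgroup RH -> {res.subtype} "
      f"(support {res.support:.2f}, accepted={res.accepted})")
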