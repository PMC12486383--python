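"""Simulate the default vertebrate opsin-paralogon scenario.

Generates annotated genomes for three jawless species (shared WGD then a
genome triplication: hexaploid), three jawed species (two WGD rounds)
and a pre-WGD outgroup, with a known event ledger.
"""

from synopsin import presets

bundle = presets.paper_scenario(seed=1, with_sequences=False)

print("chromosome copies of the opsin-bearing ancestral chromosome 'O':")
for sp in ("sea_lamprey", "spotted_gar", "amphioxus"):
    copies = bundle.truth.chromosome_copies(sp, "O")
    print(f"  {sp:<14} {len(copies)} copies: {', '.join(copies)}")

print("\nevent ledger summary:")
counts = bundle.truth.events_df()["kind"].value_counts()
for kind, n in counts.items():
    print(f"  {kind:<14} {n}")

print("\nsea lamprey visual opsins (truth subtypes):")
labels = bundle.truth_subtypes("sea_lamprey")
for g in bundle.genomes.species["sea_lamprey"]:
    if g.gene_id in labels:
        print(f"  {labels[g.gene_id]:<5} on {g.seq_id:<7} "
              f"[{g.start:>7}-{g.end:>7}] strand {g.strand}")

# A jawless genome carries 6 copies of each ancestral chromosome and a
# jawed genome 4; the five extant opsin subtypes survive on only a few
# of them, with SWS1 moved to a different chromosome in the jawless side.
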