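"""Run a Patterson's D battery and test for introgression.

Simulates gene flow from P3 into P2 (gamma = 0.3), permutes all
single-individual combinations across the four taxa, bootstraps a Z-score
per test, and corrects the battery with Holm-Bonferroni at alpha = 0.01.
"""

import radintro as ri

model = ri.SpeciesTreeModel(
    "(((P1:1,P2:1):1,P3:2):1,O:3);",
    samples_per_species=2,
    pulses=[ri.AdmixturePulse("P3", "P2", 0.25, 0.3)],
)
ls = ri.simulate_dataset(model, 1000, theta=0.01, seed=3)
pm = model.popmap()

summary, table = ri.run_battery(
    ls,
    ("P1", pm.individuals_of("P1")),
    ("P2", pm.individuals_of("P2")),
    ("P3", pm.individuals_of("P3")),
    ("O", pm.individuals_of("O")),
    n_boot=1000, alpha=0.01, seed=3,
)

print(table.round(3).to_string(index=False))
print("\nbattery summary (mean over informative permutations):")
for key, val in summary.to_row().items():
    print(f"  {key:>10}: {val if isinstance(val, str) else round(val, 3)}")
# A positive mean D with most permutations significant indicates an excess
# of ABBA sites: P2 shares more derived alleles with P3 than P1 does,
# exactly the gene flow the pulse injected.  Under gamma = 0 the same
# battery yields D near 0 and no significant tests.
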