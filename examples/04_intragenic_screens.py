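"""Per-locus screens: Tajima's D, the Hudson-Kaplan Rm bound, and Hudson FST.

Tajima's D checks neutrality of a coding fragment; Rm lower-bounds the
number of intragenic recombination events from four-gamete failures; FST
contrasts geographic groups through mean pairwise differences.
"""

from clonescan import (
    fst_all_pairs,
    rm_hudson_kaplan,
    sim_two_species,
    tajimas_d,
)

ds, truth = sim_two_species(seed=5)
clade_a = sorted(t for t, s in truth.species.items() if s == "speciesA")
sub = ds.subset(clade_a)

for loc in sub.loci:
    d = tajimas_d(loc)
    rm = rm_hudson_kaplan(loc)
    dval = "undefined" if d.statistic is None else f"{d.statistic:+.3f}"
    print(f"{loc.locus_name}: Tajima's D = {dval}  "
          f"(S = {d.params.get('S', 0)}),  Rm = {rm.statistic:.0f}")

table = fst_all_pairs(sub.concatenated(), ds.metadata)
print("\nPairwise FST between geographic groups inside the recombining clade:")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"max FST = {table['fst'].max():.4f}")

# D near 0 is consistent with neutrality; Rm > 0 flags intragenic
# recombination.  FST near 0 between regions means geography does not
# structure the clade — strains exchange genes across regions.
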