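"""Phi boundary expansion: where does the recombining population end?

Starting from a seed subsample without a recombination signal (PHI p above
alpha), candidate strain groups are added nearest-first and the PHI test is
re-run after each addition.  The group whose inclusion first drives p below
alpha recombines with the seed; groups that never do are outside the
recombining population's boundary.
"""

from clonescan import find_nonrecombining_seed, phi_boundary_expand, sim_two_species

ds, truth = sim_two_species(seed=31)
concat = ds.concatenated()
clade_a = sorted(t for t, s in truth.species.items() if s == "speciesA")
clade_b = sorted(t for t, s in truth.species.items() if s == "speciesB")

seed_set = find_nonrecombining_seed(concat, clade_a, size=6, seed=3, n_perm=500)
rest_of_a = [t for t in clade_a if t not in seed_set]

trajectory = phi_boundary_expand(
    concat,
    seed_set,
    {"rest_of_recombining_clade": rest_of_a, "clonal_clade": clade_b},
    alpha=0.05,
    n_perm=500,
    seed=9,
)

print(f"seed set ({len(seed_set)} strains): {', '.join(seed_set)}")
for step in trajectory.steps:
    added = f"+ {step.group} ({len(step.added)} strains)" if step.group else "seed only"
    print(f"  {added:<42} PHI = {step.statistic:.4f}  p = {step.p_value:.4f}")
print(f"\nfirst group to trigger recombination signal: {trajectory.flagged_group}")

# Conspecific strains of the recombining clade trip the alarm on inclusion;
# the clonal clade is added later and is never the group that first breaks
# the threshold — it lies outside the recombining population.
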