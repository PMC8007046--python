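"""Grow a small primary tumor with periodic metastatic seeding.

A 20,000-cell primary (death-to-birth ratio 0.72, passenger rate 0.15)
seeds one metastasis every 4,000 cells; the first metastasis is grown to
8,000 cells. Prints the registry totals and the seeding log.
"""

import metdiv as md

cfg = md.SimConfig(rho=0.72, u=0.15, u_b=1e-4, s_mean=0.1,
                   N_s=4_000, N_final=20_000, rng_seed=1)
primary = md.surviving_primary(cfg)

print(f"primary: {primary.n_alive} alive cells, "
      f"{primary.n_births} births, {primary.n_deaths} deaths, "
      f"{primary.n_variants} variants, t = {primary.time:.0f} days")
print("seeding events (cell id, primary size, day):")
for ev in primary.seeding_events():
    print(f"  #{ev.seed_index}: cell {ev.seeding_cell} left at size "
          f"{ev.primary_size_at_seed} (t = {ev.t_seed:.0f})")

ev = primary.seeding_events()[0]
met = md.grow_metastasis(primary, ev, n_final=8_000)
print(f"metastasis #{ev.seed_index}: {met.n_alive} cells, "
      f"{met.clonal_variant_ids.size} clonal variants inherited from the "
      f"seeding cell, {met.n_variants} gained after dissemination "
      f"({met.extinction_retries} extinction retries)")
# The inherited variants are present in every metastatic cell; the
# seeding cell's genotype is the metastasis's clonal background.
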