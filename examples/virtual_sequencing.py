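"""Multi-region virtual sequencing and measured M-P divergence.

Samples ten spherical regions from a paired primary/metastasis, applies
NegBinom(100, 10) depths and Binomial read counts, pools the allele
frequencies, and reports B_m (metastasis-specific variants), B_p
(primary-specific variants) and the mean pairwise Hudson Fst between
primary regions (spatial genetic divergence).
"""

import numpy as np

import metdiv as md

cfg = md.SimConfig(rho=0.72, u=0.15, u_b=1e-4, s_mean=0.1,
                   N_s=5_000, N_final=20_000, rng_seed=2)
primary = md.surviving_primary(cfg)
ev = primary.seeding_events()[1]
met = md.grow_metastasis(primary, ev, n_final=10_000)

rng = np.random.default_rng(7)
rad = md.seq.radius_for_target_cells(primary, 1000)
regions_p = md.sample_regions(primary, n_regions=10, radius=rad, rng=rng)
table_p = md.virtual_sequence(primary, regions_p, m_d=100, sigma_d=10,
                              rng=rng)
regions_m = md.sample_regions(met, n_regions=10,
                              radius=md.seq.radius_for_target_cells(met),
                              rng=rng)
table_m = md.virtual_sequence(met, regions_m, m_d=100, sigma_d=10, rng=rng)

print("primary regions:", [r.n_cells for r in regions_p], "cells")
meas = md.measure_divergence(table_p, table_m, gamma=0.2, alpha=0.01)
print(f"B_m = {meas.B_m} variants substantially present in the met "
      f"(pooled VAF > {meas.gamma}) and absent in the primary (< {meas.alpha})")
print(f"B_p = {meas.B_p} variants the other way around")
print(f"mean pairwise Fst across primary regions: "
      f"{md.fst_mean(table_p):.3f} (between-region divergence)")
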