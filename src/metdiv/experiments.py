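"""Canonical scaled study conditions and replicate batches.

The reference experiments run primaries of 10^5 cells (seeding every
2,500 cells, i.e. 39-40 seeding events each) with metastases grown to
5 * 10^4 cells, ten sampled regions of ~1000 cells per tumor, and
NegBinom(100, 10)/Binomial virtual sequencing — a desk-scale version of
the full-scale setting (10^7-cell tumors, seeding every 25,000 cells).

Growth modes (all at initial death-to-birth ratio 0.72):

* fast growth / progressive diversification — weak selection
  (s = 0.02, driver rate 1e-5);
* branched evolution — strong subclonal selection (s in {0.1, 0.2},
  driver rate 5e-5).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .pipeline import pooled_series, run_paired
from .sim import SimConfig

SCALED_N_FINAL = 100_000
SCALED_N_S = 2_500
SCALED_MET_N_FINAL = 50_000


def fast_growth_config(seed: int, **overrides) -> SimConfig:
    """Fast growth under weak selection (progressive diversification)."""
    kw = dict(lambda0=0.25, rho=0.72, u=0.15, u_b=1e-5, s_mean=0.02,
              N_s=SCALED_N_S, N_final=SCALED_N_FINAL, rng_seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def branched_config(seed: int, s_mean: float = 0.2, **overrides) -> SimConfig:
    """Branched evolution: strong subclonal selection."""
    kw = dict(lambda0=0.25, rho=0.72, u=0.15, u_b=5e-5, s_mean=s_mean,
              N_s=SCALED_N_S, N_final=SCALED_N_FINAL, rng_seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def run_batch(configs, met_n_final: Optional[int] = SCALED_MET_N_FINAL,
              grow_mets: bool = True, n_regions: int = 10,
              alpha: float = 0.01, gamma: float = 0.2) -> pd.DataFrame:
    """Run each configuration through the full pipeline and pool the
    per-seeding-event series (with a ``replicate`` column)."""
    runs = [
        run_paired(cfg, met_n_final=met_n_final, n_regions=n_regions,
                   grow_mets=grow_mets, alpha=alpha, gamma=gamma)
        for cfg in configs
    ]
    return pooled_series(runs)
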