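"""End-to-end paired-tumor runs and the per-seeding-event divergence series.

A full run grows one primary with periodic dissemination, grows a
metastasis from each disseminated cell (survival-conditioned), samples
and virtually sequences every tumor, and assembles one row per seeding
event combining the sequencing-measured divergence (B_m, B_p) with its
tree-based counterparts (bmd_variants, bmd_generations, bp_tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import seq
from .genealogy import GenealogyIndex, divergence_elements, divergence_table
from .sim import (SeedingEvent, SimConfig, TumorExtinctError, TumorState,
                  _met_stream_seed, grow_metastasis, init_tumor)


def surviving_primary(config: SimConfig, max_retries: int = 100) -> TumorState:
    """Grow a primary to ``N_final`` conditioned on non-extinction:
    on extinction, restart with a fresh RNG stream derived from the
    configured seed (attempt 0 uses the seed itself)."""
    last = None
    for attempt in range(max_retries):
        seed = (config.rng_seed if attempt == 0
                else _met_stream_seed(config.rng_seed, 0, attempt))
        tum = TumorState(config, config.N_final, config.rho, seed)
        tum.extinction_retries = attempt
        try:
            return tum.run_to_size(config.N_final)
        except TumorExtinctError as exc:
            last = exc
    raise RuntimeError(f"primary went extinct {max_retries} times") from last


@dataclass
class PairedRun:
    """Results of one paired primary/metastases simulation."""

    config: SimConfig
    primary: TumorState
    events: list
    index: GenealogyIndex
    regions_primary: list
    table_primary: seq.SequencedVariantTable
    series: pd.DataFrame
    sampled_cells: np.ndarray = field(default=None)


def run_paired(config: SimConfig,
               met_n_final: Optional[int] = None,
               n_regions: int = seq.DEFAULT_N_REGIONS,
               radius: Optional[float] = None,
               m_d: float = 100.0, sigma_d: float = 10.0,
               alpha: float = 0.01, gamma: float = 0.2,
               grow_mets: bool = True,
               keep_mets: bool = False) -> PairedRun:
    """Run the full pipeline for one configuration.

    With ``grow_mets`` false, only primary-side quantities (tree elements
    and the detectable fraction of each seeding cell's variants) are
    computed and B_m / B_p are NaN. Metastasis states are dropped after
    sequencing unless ``keep_mets`` (they are large). ``radius=None``
    scales each tumor's region radius to the reference condition of
    ~1000 cells per region (see :func:`metdiv.seq.radius_for_target_cells`)."""
    met_n_final = int(met_n_final if met_n_final is not None
                      else config.N_final)
    primary = surviving_primary(config)
    events = primary.seeding_events()
    index = GenealogyIndex(primary)
    tree = divergence_table(primary, alpha=alpha, gamma=gamma, index=index)

    rng = np.random.default_rng([config.rng_seed, 2025])
    rad_p = radius if radius is not None \
        else seq.radius_for_target_cells(primary)
    regions_p = seq.sample_regions(primary, n_regions, rad_p, rng)
    table_p = seq.virtual_sequence(primary, regions_p, m_d, sigma_d, rng)
    pooled_p = table_p.pooled()
    sampled = (np.concatenate([r.member_cells for r in regions_p])
               if regions_p else np.empty(0, np.int64))

    # tree elements over the sampled population: the apples-to-apples
    # counterpart of the sequencing-measured divergence — same observable
    # universe (the sampled cells) and same region weighting (pooled VAFs
    # average regions equally, irrespective of region size)
    index_sampled = GenealogyIndex(
        primary, weights=seq.region_weights(primary, regions_p))
    samp_rows = []
    for ev in events:
        el = divergence_elements(index_sampled, ev.seeding_cell, alpha, gamma)
        samp_rows.append({
            "seed_index": ev.seed_index,
            "bmd_variants_sampled": el.bmd_variants,
            "bmd_generations_sampled": el.bmd_generations,
            "bp_tree_sampled": el.bp_tree,
        })
    tree = tree.merge(pd.DataFrame(samp_rows), on="seed_index", how="left")

    rows = []
    for ev in events:
        seed_vars = primary.cell_variant_ids(ev.seeding_cell)
        det = float(np.mean(
            pooled_p.reindex(seed_vars, fill_value=0.0).to_numpy() >= alpha
        )) if seed_vars.size else np.nan
        if grow_mets:
            met = grow_metastasis(primary, ev, n_final=met_n_final)
            met_rng = np.random.default_rng(
                [config.rng_seed, ev.seed_index, 2025])
            rad_m = radius if radius is not None \
                else seq.radius_for_target_cells(met)
            regions_m = seq.sample_regions(met, n_regions, rad_m, met_rng)
            table_m = seq.virtual_sequence(met, regions_m, m_d, sigma_d,
                                           met_rng)
            meas = seq.measure_divergence(table_p, table_m, gamma, alpha)
            b_m, b_p = meas.B_m, meas.B_p
            if not keep_mets:
                ev.metastasis = None
        else:
            b_m = b_p = np.nan
        rows.append({"seed_index": ev.seed_index, "B_m": b_m, "B_p": b_p,
                     "detectable_fraction": det})
    meas_df = pd.DataFrame(
        rows, columns=["seed_index", "B_m", "B_p", "detectable_fraction"])
    series = tree.merge(meas_df, on="seed_index", how="left")
    return PairedRun(
        config=config, primary=primary, events=events, index=index,
        regions_primary=regions_p, table_primary=table_p, series=series,
        sampled_cells=sampled,
    )


def pooled_series(runs: list[PairedRun]) -> pd.DataFrame:
    """Concatenate per-run series with a replicate column."""
    parts = []
    for i, r in enumerate(runs):
        s = r.series.copy()
        s.insert(0, "replicate", i)
        parts.append(s)
    return pd.concat(parts, ignore_index=True)
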