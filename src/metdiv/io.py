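"""Readers and writers for the run-directory formats.

All tables are TSV (gzip transparently supported through the ``.gz``
suffix); run metadata is JSON. A simulation run directory contains
``cells.tsv``, ``variants.tsv``, ``seeding_events.tsv`` and
``run_meta.json`` for the primary, plus one ``met_<index>/`` subdirectory
per grown metastasis with the same layout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .seq import Region, SequencedVariantTable
from .sim import SimConfig, TumorState


def write_tumor(outdir, tumor: TumorState, compress: bool = False) -> dict:
    """Write cells.tsv, variants.tsv, seeding_events.tsv and
    run_meta.json; returns the manifest of written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sfx = ".gz" if compress else ""
    paths = {}

    cells = tumor.cells_df()
    paths["cells"] = str(outdir / f"cells.tsv{sfx}")
    cells.to_csv(paths["cells"], sep="\t", index=False)

    variants = tumor.variants_df()
    paths["variants"] = str(outdir / f"variants.tsv{sfx}")
    variants.to_csv(paths["variants"], sep="\t", index=False)

    ev = pd.DataFrame([
        {"seed_index": e.seed_index, "seeding_cell": e.seeding_cell,
         "primary_size_at_seed": e.primary_size_at_seed, "t_seed": e.t_seed}
        for e in tumor.seeding_events()
    ], columns=["seed_index", "seeding_cell", "primary_size_at_seed",
                "t_seed"])
    paths["seeding_events"] = str(outdir / f"seeding_events.tsv{sfx}")
    ev.to_csv(paths["seeding_events"], sep="\t", index=False)

    meta = {
        "config": tumor.config.to_dict(),
        "software_version": __version__,
        "rng_seed": tumor.rng_seed,
        "rho_run": tumor.rho_run,
        "n_cells": tumor.n_cells,
        "n_alive": tumor.n_alive,
        "n_variants": tumor.n_variants,
        "n_births": tumor.n_births,
        "n_deaths": tumor.n_deaths,
        "n_seeding_events": tumor.n_seeding_events,
        "final_time_days": tumor.time,
        "variant_id_start": tumor.variant_id_start,
        "clonal_variant_ids": tumor.clonal_variant_ids.tolist(),
        "extinction_retries": getattr(tumor, "extinction_retries", 0),
    }
    paths["run_meta"] = str(outdir / "run_meta.json")
    with open(paths["run_meta"], "w") as fh:
        json.dump(meta, fh, indent=1)
    return paths


def read_tumor(rundir) -> dict:
    """Read a run directory back as plain tables:
    ``{"cells": DataFrame, "variants": DataFrame, "seeding_events":
    DataFrame, "meta": dict}``."""
    rundir = Path(rundir)

    def find(stem):
        for cand in (rundir / f"{stem}.tsv", rundir / f"{stem}.tsv.gz"):
            if cand.exists():
                return cand
        raise FileNotFoundError(f"{stem}.tsv[.gz] not found in {rundir}")

    cells = pd.read_csv(find("cells"), sep="\t",
                        keep_default_na=False,
                        na_values=[""],
                        dtype={"new_variant_ids": str})
    cells["new_variant_ids"] = cells["new_variant_ids"].fillna("")
    with open(rundir / "run_meta.json") as fh:
        meta = json.load(fh)
    return {
        "cells": cells,
        "variants": pd.read_csv(find("variants"), sep="\t"),
        "seeding_events": pd.read_csv(find("seeding_events"), sep="\t"),
        "meta": meta,
    }


def write_regions(path, regions: list[Region]):
    pd.DataFrame([
        {"region_id": r.region_id, "cx": r.center[0], "cy": r.center[1],
         "cz": r.center[2], "radius": r.radius, "n_cells": r.n_cells}
        for r in regions
    ]).to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vaf_table(path, table: SequencedVariantTable):
    table.table.to_csv(path, sep="\t", index=False)


def read_vaf_table(path) -> SequencedVariantTable:
    t = pd.read_csv(path, sep="\t")
    sizes = t.groupby("region_id").size().to_numpy()
    return SequencedVariantTable(table=t, region_sizes=sizes)


def write_series(path, series: pd.DataFrame):
    series.to_csv(path, sep="\t", index=False)


def write_expansions(path, expansions):
    pd.DataFrame([
        {"cell_id": e.cell_id, "t_birth": e.t_birth,
         "size_fraction_at_birth": e.size_fraction_at_birth,
         "sampled_fraction": e.sampled_fraction}
        for e in expansions
    ], columns=["cell_id", "t_birth", "size_fraction_at_birth",
                "sampled_fraction"]).to_csv(path, sep="\t", index=False)


def read_expansions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(path, report: dict):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)


def write_vcf(path, table: SequencedVariantTable, region_id: int,
              variants: Optional[pd.DataFrame] = None):
    """Minimal single-sample VCF for one region: CHROM is 'virtual', POS
    the variant's genomic coordinate label (or the variant id when no
    variant table is supplied), INFO carries the true cancer-cell
    fraction and read counts."""
    t = table.table
    sub = t[t["region_id"] == region_id].sort_values("variant_id")
    coord = None
    if variants is not None:
        coord = variants.set_index("variant_id")["coordinate"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=metdiv {__version__}\n")
        fh.write('##INFO=<ID=CCF,Number=1,Type=Float,'
                 'Description="True cancer cell fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,'
                 'Description="Alt reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in sub.iterrows():
            vid = int(row["variant_id"])
            pos = int(coord.get(vid, vid)) if coord is not None else vid
            info = (f"CCF={2 * row['true_vaf']:.6g};DP={int(row['depth'])};"
                    f"AD={int(row['alt_reads'])}")
            fh.write(f"virtual\t{pos}\tv{vid}\tN\tA\t.\tPASS\t{info}\n")


def load_config(path) -> SimConfig:
    """SimConfig from a YAML or JSON mapping file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid: {sorted(known)}")
    return SimConfig(**raw)
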