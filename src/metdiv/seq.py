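"""Virtual multi-region sampling and sequencing.

Spherical regions (default radius 6.3 lattice units) are centered on
uniformly chosen occupied sites of the final tumor. For each variant and
region, sequencing depth is drawn from a negative binomial with mean
``m_d`` and dispersion (size) ``sigma_d`` — variance ``m_d +
m_d^2/sigma_d`` — and alt-read counts from Binomial(D, F) where F is the
true variant allele frequency, i.e. carrier fraction / 2 for heterozygous
variants. Pooled frequencies are read-count pools across regions:
``f = sum(M) / sum(D)``.

Between-tumor divergence from sequencing: ``B_m = #{v: f_m > gamma,
f_p < alpha}`` and ``B_p = #{v: f_p > gamma, f_m < alpha}``. Between-
region divergence within a tumor is summarized by the Hudson-style Fst
with numerator and denominator each summed over variants before taking
the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .sim import TumorState

DEFAULT_RADIUS = 6.3
DEFAULT_N_REGIONS = 10


@dataclass
class Region:
    """A spherical sampled region of a tumor."""

    region_id: int
    center: np.ndarray          # lattice coordinates relative to center
    radius: float
    member_cells: np.ndarray    # cell ids, all alive at observation

    @property
    def n_cells(self) -> int:
        return int(self.member_cells.size)


def radius_for_target_cells(tumor: TumorState, target_cells: int = 1000
                            ) -> float:
    """Region radius expected to contain ``target_cells`` cells, from the
    tumor's measured bulk occupancy.

    The reference sampling condition is ~1000 cells per spherical region
    (radius 6.3 at full lattice packing); because the lattice equilibrates
    below full packing, the radius is scaled so regions keep that cell
    count."""
    alive = tumor.alive_list[: tumor.n_alive]
    r = np.linalg.norm(tumor.positions(alive), axis=1)
    # median radius probes the bulk, inside the diffuse growth front
    r50 = float(np.percentile(r, 50))
    occ = 0.5 * tumor.n_alive / (4.0 / 3.0 * np.pi * max(r50, 1.0) ** 3)
    occ = min(occ, 1.0)
    return float((3.0 * target_cells / (4.0 * np.pi * occ)) ** (1.0 / 3.0))


def sample_regions(tumor: TumorState, n_regions: int = DEFAULT_N_REGIONS,
                   radius: float = DEFAULT_RADIUS,
                   rng: Optional[np.random.Generator] = None,
                   disjoint: bool = False) -> list[Region]:
    """Sample spherical regions with centers uniform over occupied sites.

    Overlap between regions is permitted unless ``disjoint`` is set.
    Centers near the tumor surface naturally contain fewer cells; no
    resampling is performed to equalize region sizes."""
    rng = np.random.default_rng(rng)
    alive = tumor.alive_list[: tumor.n_alive]
    if alive.size == 0:
        raise ValueError("tumor has no alive cells to sample")
    xyz = tumor.positions(alive)
    taken = np.zeros(alive.size, dtype=bool)
    regions = []
    for i in range(n_regions):
        pool = np.flatnonzero(~taken) if disjoint else np.arange(alive.size)
        if pool.size == 0:
            raise ValueError("tumor smaller than the requested regions")
        center = xyz[pool[rng.integers(pool.size)]]
        d2 = ((xyz - center) ** 2).sum(axis=1)
        inside = d2 <= radius * radius
        if disjoint:
            inside &= ~taken
            taken |= inside
        regions.append(Region(
            region_id=i, center=center.copy(), radius=radius,
            member_cells=alive[inside].copy(),
        ))
    return regions


def region_weights(tumor: TumorState, regions: Sequence[Region]) -> np.ndarray:
    """Per-cell observation weights mirroring the pooled-VAF estimator.

    Pooled frequencies average regions with equal (depth) weight
    regardless of region size, so a cell contributes
    ``sum over its regions of 1/(n_regions * |region|)``; a variant's
    descendant-weight fraction then equals its expected pooled cancer
    cell fraction."""
    w = np.zeros(tumor.n_cells, dtype=np.float64)
    nonempty = [r for r in regions if r.n_cells > 0]
    for r in nonempty:
        w[r.member_cells] += 1.0 / (len(nonempty) * r.n_cells)
    return w


def carrier_matrix(tumor: TumorState, regions: Sequence[Region]):
    """Carrier counts per (variant, region).

    Returns ``(variant_ids, counts, region_sizes)`` where ``counts`` has
    shape (n_variants, n_regions). Variants clonal by inheritance (the
    founder genotype of a metastasis) are carried by every cell. Variants
    with no carriers in any region are dropped."""
    n = tumor.n_cells
    parent = tumor.parent[:n]
    nreg = len(regions)
    sizes = np.array([r.n_cells for r in regions], dtype=np.int64)
    sub = np.empty((nreg, n), dtype=np.int64)
    for j, r in enumerate(regions):
        w = np.zeros(n, dtype=np.int64)
        w[r.member_cells] = 1
        sub[j] = K.subtree_counts(parent, w)
    nv = tumor.n_variants
    origin = tumor.var_origin[:nv]
    counts = sub[:, origin].T                     # (nv, nreg)
    vids = np.arange(nv, dtype=np.int64) + tumor.variant_id_start
    if tumor.clonal_variant_ids.size:
        cl = tumor.clonal_variant_ids
        counts = np.vstack([np.tile(sizes, (cl.size, 1)), counts])
        vids = np.concatenate([cl, vids])
    keep = counts.sum(axis=1) > 0
    return vids[keep], counts[keep], sizes


def negbinom_depths(shape, m_d: float, sigma_d: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Sequencing depths, NegBinom with mean ``m_d`` and size ``sigma_d``
    (variance ``m_d + m_d**2 / sigma_d``)."""
    p = sigma_d / (sigma_d + m_d)
    return rng.negative_binomial(sigma_d, p, size=shape)


@dataclass
class SequencedVariantTable:
    """Per-(variant, region) virtual sequencing read counts."""

    table: pd.DataFrame   # variant_id, region_id, depth, alt_reads,
                          # true_vaf, obs_vaf
    region_sizes: np.ndarray

    def pooled(self) -> pd.Series:
        """Pooled allele frequency per variant: sum(M) / sum(D) across
        regions (0 where total depth is 0)."""
        g = self.table.groupby("variant_id")[["alt_reads", "depth"]].sum()
        d = g["depth"].to_numpy(dtype=float)
        m = g["alt_reads"].to_numpy(dtype=float)
        f = np.divide(m, d, out=np.zeros_like(m), where=d > 0)
        return pd.Series(f, index=g.index, name="pooled_vaf")

    def region_ids(self) -> np.ndarray:
        return np.sort(self.table["region_id"].unique())


def virtual_sequence(tumor: TumorState, regions: Sequence[Region],
                     m_d: float = 100.0, sigma_d: float = 10.0,
                     rng: Optional[np.random.Generator] = None
                     ) -> SequencedVariantTable:
    """Sequence every variant carried in the sampled regions.

    ``D = 0`` draws yield an undefined observed frequency, recorded as 0
    (the variant is simply not seen)."""
    rng = np.random.default_rng(rng)
    vids, counts, sizes = carrier_matrix(tumor, regions)
    nv, nreg = counts.shape
    F = counts / (2.0 * sizes[None, :])           # heterozygous: CCF / 2
    D = negbinom_depths((nv, nreg), m_d, sigma_d, rng)
    M = rng.binomial(D, F)
    obs = np.divide(M, D, out=np.zeros(M.shape, dtype=float), where=D > 0)
    table = pd.DataFrame({
        "variant_id": np.repeat(vids, nreg),
        "region_id": np.tile(np.arange(nreg), nv),
        "depth": D.ravel(),
        "alt_reads": M.ravel(),
        "true_vaf": F.ravel(),
        "obs_vaf": obs.ravel(),
    })
    return SequencedVariantTable(table=table, region_sizes=sizes)


@dataclass
class DivergenceMeasurement:
    """Sequencing-measured metastasis/primary-specific variant counts."""

    B_m: int
    B_p: int
    gamma: float = 0.2
    alpha: float = 0.01


def measure_divergence(table_primary: SequencedVariantTable,
                       table_met: SequencedVariantTable,
                       gamma: float = 0.2, alpha: float = 0.01
                       ) -> DivergenceMeasurement:
    """B_m and B_p from pooled frequencies of the two tumors.

    Strict inequalities as defined: presence needs ``f > gamma``, absence
    needs ``f < alpha``. A variant absent from one tumor's table has
    pooled frequency 0 there."""
    fp = table_primary.pooled()
    fm = table_met.pooled()
    union = fp.index.union(fm.index)
    fpu = fp.reindex(union, fill_value=0.0).to_numpy()
    fmu = fm.reindex(union, fill_value=0.0).to_numpy()
    b_m = int(np.sum((fmu > gamma) & (fpu < alpha)))
    b_p = int(np.sum((fpu > gamma) & (fmu < alpha)))
    return DivergenceMeasurement(B_m=b_m, B_p=b_p, gamma=gamma, alpha=alpha)


def detectable_fraction(table_primary: SequencedVariantTable,
                        variant_ids: np.ndarray, alpha: float = 0.01) -> float:
    """Fraction of ``variant_ids`` whose pooled primary VAF >= ``alpha``."""
    variant_ids = np.asarray(variant_ids)
    if variant_ids.size == 0:
        return float("nan")
    fp = table_primary.pooled()
    vals = fp.reindex(variant_ids, fill_value=0.0).to_numpy()
    return float(np.mean(vals >= alpha))


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def _region_arrays(table: SequencedVariantTable, r: int, rprime: int):
    t = table.table
    a = t[t["region_id"] == r].set_index("variant_id")
    b = t[t["region_id"] == rprime].set_index("variant_id")
    union = a.index.union(b.index)
    fa = a["obs_vaf"].reindex(union, fill_value=0.0).to_numpy()
    fb = b["obs_vaf"].reindex(union, fill_value=0.0).to_numpy()
    da = a["depth"].reindex(union, fill_value=0).to_numpy(dtype=float)
    db = b["depth"].reindex(union, fill_value=0).to_numpy(dtype=float)
    ma = a["alt_reads"].reindex(union, fill_value=0).to_numpy()
    mb = b["alt_reads"].reindex(union, fill_value=0).to_numpy()
    seen = (ma > 0) | (mb > 0)
    ok = seen & (da > 1) & (db > 1)
    return fa[ok], fb[ok], da[ok], db[ok]


def fst(table: SequencedVariantTable, region_r: int, region_rprime: int
        ) -> float:
    """Hudson-style Fst between two regions.

    Per variant, the numerator is ``(f_r - f_r')^2 - f_r(1-f_r)/(D_r-1)
    - f_r'(1-f_r')/(D_r'-1)`` and the denominator ``f_r(1-f_r') +
    f_r'(1-f_r)``; both are summed over variants observed in either
    region before the ratio. Returns NaN when the denominator is 0."""
    fa, fb, da, db = _region_arrays(table, region_r, region_rprime)
    if fa.size == 0:
        return float("nan")
    num = (fa - fb) ** 2 - fa * (1 - fa) / (da - 1) - fb * (1 - fb) / (db - 1)
    den = fa * (1 - fb) + fb * (1 - fa)
    den_sum = den.sum()
    if den_sum == 0:
        return float("nan")
    return float(num.sum() / den_sum)


def fst_mean(table: SequencedVariantTable) -> float:
    """Average pairwise Fst over all region pairs (NaN pairs skipped)."""
    ids = table.region_ids()
    vals = [
        fst(table, int(r), int(q))
        for i, r in enumerate(ids) for q in ids[i + 1:]
    ]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")
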