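"""Single-cell genealogies and tree-based divergence elements.

The clonal evolutionary tree of a tumor is the directed graph whose
vertices are cells and whose edges are birth events. A progenitor cell is
a *detectable ancestor* at threshold ``a`` (DA) if its descendants make up
a fraction >= ``a`` of the observed final population; with heterozygous
variants and a VAF detectability threshold ``alpha``, the cancer-cell
fraction cutoff is ``2 * alpha``. The most recent detectable ancestor
(MRDA) of a seeding cell is the deepest DA on its root path.

Divergence elements of a seeding cell with ``k`` variants:

* ``bmd_variants`` — ``k`` minus the variants carried by the MRDA at
  ``2 * alpha``: the pre-dissemination part of the metastasis-specific
  branch.
* ``bmd_generations`` — the same path measured in edges (cell
  generations).
* ``bp_tree`` — the total variant-weighted branch length of the genealogy
  of detectable ancestors at ``2 * gamma``, minus the branch between the
  founder and the seeding cell's MRDA at ``2 * gamma``: the tree
  counterpart of the primary-specific branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as K
from .sim import TumorState


class GenealogyIndex:
    """Descendant counts and cumulative variant counts for one tumor.

    Parameters
    ----------
    tumor : TumorState
    observed : array of cell ids or None
        The observation set over which descendant fractions are defined.
        Default: all cells alive at observation time. A cell's descendant
        set includes itself when observed.
    weights : float array over all cells, optional
        Non-uniform observation weights (overrides ``observed``). Used to
        mirror estimators that do not weight sampled cells equally — e.g.
        pooled sequencing weights regions equally regardless of region
        size, so a cell's weight is the sum of 1/(n_regions * |region|)
        over the regions containing it. Descendant "counts" then become
        descendant weights and thresholds apply to the weight fraction.
    """

    def __init__(self, tumor: TumorState, observed: Optional[np.ndarray] = None,
                 weights: Optional[np.ndarray] = None):
        self.tumor = tumor
        n = tumor.n_cells
        if weights is not None:
            weights = np.asarray(weights, dtype=np.float64)
            if weights.shape != (n,) or weights.sum() <= 0:
                raise ValueError("weights must be per-cell with positive sum")
            self.observed = np.flatnonzero(weights > 0)
            self.n_observed = float(weights.sum())
            self.n_desc = K.subtree_weights(tumor.parent[:n], weights)
        else:
            if observed is None:
                observed = tumor.alive_list[: tumor.n_alive]
            observed = np.asarray(observed, dtype=np.int64)
            if observed.size == 0:
                raise ValueError("empty observation set")
            self.observed = observed
            w = np.zeros(n, dtype=np.int64)
            w[observed] = 1
            self.n_observed = int(observed.size)
            self.n_desc = K.subtree_counts(tumor.parent[:n], w)
        self.k_count = K.cumulative_variant_counts(
            tumor.parent[:n], tumor.nvar[:n].astype(np.int64)
        )

    def descendant_fraction(self, cell) -> np.ndarray:
        return self.n_desc[cell] / self.n_observed

    def detectable_ancestors(self, threshold_ccf: float) -> np.ndarray:
        """All cells whose observed-descendant fraction >= ``threshold_ccf``.

        The set is upward-closed: every ancestor of a DA is a DA."""
        if not (0.0 < threshold_ccf <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        cut = threshold_ccf * self.n_observed
        return np.flatnonzero(self.n_desc >= cut).astype(np.int64)

    def mrda(self, seeding_cell: int, threshold_ccf: float) -> int:
        """Deepest detectable ancestor on the path root -> seeding cell.

        Always exists: the founder's descendant fraction is 1."""
        cut = threshold_ccf * self.n_observed
        c = int(seeding_cell)
        while c >= 0:
            if self.n_desc[c] >= cut:
                return c
            c = int(self.tumor.parent[c])
        raise AssertionError("root is always detectable")  # pragma: no cover

    def path_edges(self, descendant: int, ancestor: int) -> int:
        e = 0
        c = int(descendant)
        while c != ancestor:
            c = int(self.tumor.parent[c])
            e += 1
        return e


@dataclass
class DivergenceElements:
    """Tree-based divergence of one seeding event."""

    k: int                 # variants carried by the seeding cell
    bmd_variants: int      # k - variants(MRDA at 2*alpha)
    bmd_generations: int   # edges from seeding cell to MRDA at 2*alpha
    bp_tree: int           # DA-gamma branch total minus founder->MRDA-gamma
    mrda_alpha: int
    mrda_gamma: int


def detectable_ancestors(index: GenealogyIndex, threshold_ccf: float) -> np.ndarray:
    return index.detectable_ancestors(threshold_ccf)


def mrda(index: GenealogyIndex, seeding_cell: int, threshold_ccf: float) -> int:
    return index.mrda(seeding_cell, threshold_ccf)


def divergence_elements(index: GenealogyIndex, seeding_cell: int,
                        alpha: float = 0.01, gamma: float = 0.2) -> DivergenceElements:
    """Tree-based B_md and B_p for one seeding cell, with cancer-cell
    fraction cutoffs ``2 * alpha`` and ``2 * gamma`` (heterozygous
    variants)."""
    if not (0.0 < alpha < gamma < 1.0):
        raise ValueError("need 0 < alpha < gamma < 1")
    tumor = index.tumor
    if seeding_cell >= tumor.n_cells or seeding_cell < 0:
        raise KeyError(f"no such cell: {seeding_cell}")
    k = int(index.k_count[seeding_cell]) + int(tumor.clonal_variant_ids.size)
    ma = index.mrda(seeding_cell, 2.0 * alpha)
    mg = index.mrda(seeding_cell, 2.0 * gamma)
    bmd = int(index.k_count[seeding_cell] - index.k_count[ma])
    gens = index.path_edges(seeding_cell, ma)
    da_g = index.detectable_ancestors(2.0 * gamma)
    # variant-weighted branch total of the DA-gamma genealogy; the founder
    # edge carries no variants by construction (its variants are implicit)
    total = int(tumor.nvar[da_g].astype(np.int64).sum())
    bp = total - int(index.k_count[mg])
    return DivergenceElements(
        k=k, bmd_variants=bmd, bmd_generations=gens, bp_tree=bp,
        mrda_alpha=int(ma), mrda_gamma=int(mg),
    )


def divergence_table(tumor: TumorState, alpha: float = 0.01,
                     gamma: float = 0.2, index: Optional[GenealogyIndex] = None):
    """Tree divergence elements for every seeding event, as a DataFrame
    (columns: seed_index, k, bmd_variants, bmd_generations, bp_tree,
    mrda_alpha, mrda_gamma, size_fraction)."""
    import pandas as pd

    if index is None:
        index = GenealogyIndex(tumor)
    rows = []
    for ev in tumor.seeding_events():
        el = divergence_elements(index, ev.seeding_cell, alpha, gamma)
        rows.append({
            "seed_index": ev.seed_index,
            "seeding_cell": ev.seeding_cell,
            "size_fraction": ev.primary_size_at_seed / tumor.n_alive,
            "k": el.k,
            "bmd_variants": el.bmd_variants,
            "bmd_generations": el.bmd_generations,
            "bp_tree": el.bp_tree,
            "mrda_alpha": el.mrda_alpha,
            "mrda_gamma": el.mrda_gamma,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def export_newick(index: GenealogyIndex, tip_set) -> str:
    """Newick string of the genealogy induced by ``tip_set``.

    Branch lengths are variant counts summed over the collapsed cell
    edges. Internal nodes are unnamed; tips are named ``c<cell_id>``.
    """
    tumor = index.tumor
    tips = np.asarray(list(tip_set), dtype=np.int64)
    if tips.size == 0:
        raise ValueError("tip_set is empty")
    if tips.max() >= tumor.n_cells or tips.min() < 0:
        raise KeyError("tip not in registry")

    # build the induced tree: keep ancestors of tips, collapse unary chains
    keep = np.zeros(tumor.n_cells, dtype=bool)
    for t in tips:
        c = int(t)
        while c >= 0 and not keep[c]:
            keep[c] = True
            c = int(tumor.parent[c])
    kept = np.flatnonzero(keep)
    children: dict[int, list[int]] = {int(c): [] for c in kept}
    root = None
    for c in kept:
        p = int(tumor.parent[c])
        if p >= 0 and keep[p]:
            children[p].append(int(c))
        else:
            root = int(c)
    tipset = set(int(t) for t in tips)
    nvar = tumor.nvar

    def render(node: int, blen: int) -> str:
        # collapse unary internal nodes into the branch
        while node not in tipset and len(children[node]) == 1:
            node2 = children[node][0]
            blen += int(nvar[node2])
            node = node2
        if node in tipset and children[node]:
            # a tip that is also ancestral to other tips: keep as unary label
            inner = ",".join(render(ch, int(nvar[ch])) for ch in children[node])
            return f"({inner})c{node}:{blen}"
        if not children[node]:
            return f"c{node}:{blen}"
        inner = ",".join(render(ch, int(nvar[ch])) for ch in children[node])
        return f"({inner}):{blen}"

    if len(tips) == 1 and root == int(tips[0]):
        return f"(c{root});"
    return render(root, 0) + ";"
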