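"""Non-spatial (well-mixed) birth-death simulation.

A plain supercritical birth-death branching process with per-daughter
Bernoulli(u) passenger mutation, used to cross-check the closed-form
detectability/pmf model on small populations, where the spatial model's
density dependence is absent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels as K


@dataclass
class BranchingRun:
    """Registry of one (survival-conditioned) well-mixed run."""

    parent: np.ndarray     # per cell, -1 for the founder
    nvar: np.ndarray       # new variants at each cell's birth (0/1)
    alive: np.ndarray      # alive cell ids at the end
    n_births: int
    n_deaths: int

    @property
    def n_cells(self) -> int:
        return self.parent.size

    def lineage_variant_frequencies(self, cell: int) -> np.ndarray:
        """Final carrier fractions of the variants along ``cell``'s
        lineage, in order of appearance (non-increasing)."""
        w = np.zeros(self.n_cells, dtype=np.int64)
        w[self.alive] = 1
        counts = K.subtree_counts(self.parent, w)
        freqs = []
        c = int(cell)
        while c >= 0:
            for _ in range(int(self.nvar[c])):
                freqs.append(counts[c] / self.alive.size)
            c = int(self.parent[c])
        return np.array(freqs[::-1])

    def bmd_of_cell(self, cell: int, f: float) -> tuple[int, int]:
        """(k, B_md) for a hypothetical seeding by ``cell``: its variant
        count and how many of its variants stay below frequency ``f`` in
        the final population (a suffix of the lineage, since frequencies
        are non-increasing along it)."""
        freqs = self.lineage_variant_frequencies(cell)
        return freqs.size, int(np.sum(freqs < f))


def simulate_branching(n_final: int, u: float = 0.15, rho: float = 0.72,
                       rng: Optional[np.random.Generator] = None,
                       max_retries: int = 1000) -> BranchingRun:
    """Grow a well-mixed birth-death population to ``n_final`` cells,
    conditioned on survival (extinct attempts are redrawn)."""
    rng = np.random.default_rng(rng)
    p_birth = 1.0 / (1.0 + rho)
    for _ in range(max_retries):
        parent = [-1]
        nvar = [0]
        alive = [0]
        births = deaths = 0
        while 0 < len(alive) < n_final:
            i = rng.integers(len(alive))
            if rng.random() < p_birth:
                c = alive[i]
                parent.append(c)
                nvar.append(1 if rng.random() < u else 0)
                alive.append(len(parent) - 1)
                births += 1
            else:
                alive[i] = alive[-1]
                alive.pop()
                deaths += 1
        if alive:
            return BranchingRun(
                parent=np.array(parent, dtype=np.int64),
                nvar=np.array(nvar, dtype=np.int64),
                alive=np.array(alive, dtype=np.int64),
                n_births=births, n_deaths=deaths,
            )
    raise RuntimeError("population went extinct in every attempt")


def empirical_bmd(n_final: int, f: float, u: float = 0.15, rho: float = 0.72,
                  n_replicates: int = 30,
                  rng: Optional[np.random.Generator] = None):
    """(k, B_md) pairs for one uniformly drawn candidate seeding cell per
    replicate run — the empirical counterpart of the closed-form pmf."""
    rng = np.random.default_rng(rng)
    out = []
    for _ in range(n_replicates):
        run = simulate_branching(n_final, u=u, rho=rho, rng=rng)
        cell = int(run.alive[rng.integers(run.alive.size)])
        out.append(run.bmd_of_cell(cell, f))
    return out
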