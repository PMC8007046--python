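"""Single-cell spatial tumor growth with metastatic seeding.

The model is a stochastic birth-death process on a 3D integer lattice with
the Moore (26-site) neighborhood. A founder cell starts at the lattice
center at time zero. Cell *i* divides at rate ``lambda0 * mult_i * psi_i``,
where ``psi_i`` is the fraction of empty neighboring sites and ``mult_i``
is the product of ``(1 + s)`` over the driver variants the cell inherited;
one daughter stays in place, the other fills a uniformly chosen empty
neighbor. Cells die at rate ``mu`` and vacate their site. Each newborn
daughter gains a passenger variant with probability ``u`` and a driver
with probability ``u_b`` (selection coefficients are Gaussian(s, s/2)
truncated at zero). Density dependence makes growth peripheral: interior
cells are crowded (psi near the birth/death balance) and the tumor expands
at its surface.

Metastatic seeding: every time the primary population first reaches
``I * N_s`` cells (I = 1, 2, ...), the next cell that is born disseminates
instead of joining the lattice. Each disseminated cell can found a
metastasis grown on a fresh lattice with death-to-birth ratio ``rho_met``,
inheriting the rest of the primary's parameters and the founder genotype.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as K


class TumorExtinctError(RuntimeError):
    """The population died out before reaching its target size.

    Carries the partial :class:`TumorState` in ``.tumor``.
    """

    def __init__(self, tumor: "TumorState"):
        super().__init__(
            f"tumor extinct at t={tumor.time:.2f} after "
            f"{tumor.n_births} births"
        )
        self.tumor = tumor


@dataclass
class SimConfig:
    """Growth, mutation and seeding parameters.

    Either ``mu`` or ``rho`` may be given; the other is derived from
    ``lambda0``. Defaults correspond to a fast-growing tumor (initial
    death-to-birth ratio 0.72, cell cycle of four days).
    """

    lambda0: float = 0.25          # birth rate per day
    mu: Optional[float] = None     # death rate per day
    rho: Optional[float] = 0.72    # mu / lambda0
    u: float = 0.15                # passenger variant prob. per daughter birth
    u_b: float = 0.0               # driver variant prob. per daughter birth
    s_mean: float = 0.0            # mean selection coefficient
    s_sd: Optional[float] = None   # default: s_mean / 2
    N_s: int = 25_000              # size increment triggering one seeding
    N_final: int = 10_000_000      # target size of primary and metastases
    m_intra: float = 0.0           # intra-tumoral migration (always 0)
    rho_met: float = 0.72          # death-to-birth ratio for metastases
    genome_len_passenger: int = 50_000_000
    genome_len_driver: int = 200_000
    rng_seed: int = 0
    mutation_model: str = "bernoulli"   # or "poisson"
    lattice_margin: float = 1.5

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.mu is None and self.rho is None:
            raise ValueError("one of mu or rho is required")
        if self.mu is None:
            self.mu = self.rho * self.lambda0
        self.rho = self.mu / self.lambda0
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.u_b <= 1.0):
            raise ValueError("u and u_b must be probabilities")
        if self.s_mean < 0:
            raise ValueError("s_mean must be non-negative")
        if self.s_sd is None:
            self.s_sd = self.s_mean / 2.0
        if self.N_s > self.N_final:
            raise ValueError("N_s must not exceed N_final")
        if self.m_intra != 0.0:
            raise ValueError("intra-tumoral migration is not modeled (m_intra=0)")
        if self.mutation_model not in ("bernoulli", "poisson"):
            raise ValueError("mutation_model must be 'bernoulli' or 'poisson'")
        if self.rho >= 1.0 and self.u_b == 0.0:
            warnings.warn(
                "rho >= 1 without drivers: the tumor is subcritical and will "
                "essentially never reach N_final", stacklevel=2,
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SeedingEvent:
    """A disseminating cell and the primary size at which it left."""

    seed_index: int
    seeding_cell: int
    primary_size_at_seed: int
    t_seed: float
    metastasis: Optional["TumorState"] = None


def _lattice_side(config: SimConfig, n_final: int, rho: float) -> int:
    # bulk occupancy equilibrates near (1 - rho) but the growth front is
    # diffuse; size the box for half that density (it auto-expands anyway)
    occ = max(0.5 * (1.0 - rho), 0.005)
    radius = (3.0 * n_final / (4.0 * np.pi * occ)) ** (1.0 / 3.0)
    side = 2 * int(np.ceil(config.lattice_margin * radius)) + 3
    if side < 9:
        side = 9
    if side > 640:
        raise MemoryError(
            f"lattice side {side} too large; reduce N_final or margin"
        )
    return side


_NBR = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
     for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)


class TumorState:
    """Registry-of-record for one tumor: every cell ever born, every
    variant ever gained, the lattice, and the seeding log.

    Cell ids are 0-based row indices in birth order (the founder is 0).
    """

    def __init__(self, config: SimConfig, n_final: int, rho: float,
                 rng_seed: int, founder_mult: float = 1.0,
                 clonal_variant_ids: Optional[np.ndarray] = None,
                 variant_id_start: int = 0, seeding_on: bool = True):
        self.config = config
        self.n_final = int(n_final)
        self.rho_run = float(rho)
        self.mu_run = float(rho * config.lambda0)
        self.rng_seed = int(rng_seed)
        self.variant_id_start = int(variant_id_start)
        # variants clonal by inheritance (seed-cell genotype of a metastasis)
        self.clonal_variant_ids = (
            np.asarray(clonal_variant_ids, dtype=np.int64)
            if clonal_variant_ids is not None else np.empty(0, np.int64)
        )
        self.founder_mult = float(founder_mult)
        self.seeding_on = bool(seeding_on)
        self.status = K.OK

        side = _lattice_side(config, n_final, rho)
        self.side = side
        self.occ = np.zeros(side ** 3, dtype=np.int32)
        self.nbr_off = (_NBR[:, 0] * side + _NBR[:, 1]) * side + _NBR[:, 2]

        # initial capacities; grown on demand
        cap = int(max(4096, n_final * 1.5))
        self._alloc(cap)
        self.alive_list = np.full(n_final + 2, -1, dtype=np.int64)
        max_seeds = n_final // config.N_s + 2 if seeding_on else 1
        self.seed_cell = np.full(max_seeds, -1, dtype=np.int64)
        self.seed_size = np.zeros(max_seeds, dtype=np.int64)
        self.seed_time = np.zeros(max_seeds, dtype=np.float64)

        self.istate = np.zeros(8, dtype=np.int64)
        self.fstate = np.zeros(2, dtype=np.float64)
        self.rng = K.seed_state(rng_seed)

        # founder at the lattice center
        c = side // 2
        center = (c * side + c) * side + c
        self.parent[0] = -1
        self.pos[0] = center
        self.t_birth[0] = 0.0
        self.t_death[0] = np.nan
        self.mult[0] = founder_mult
        self.first_var[0] = -1
        self.nvar[0] = 0
        self.size_at_birth[0] = 1
        self.diss[0] = 0
        self.occ[center] = 1
        self.alive_list[0] = 0
        self.alive_slot[0] = 0
        self.istate[K.I_NCELLS] = 1
        self.istate[K.I_NALIVE] = 1
        self.istate[K.I_NEXT_SEED_AT] = config.N_s if seeding_on else 2**62
        self.fstate[K.F_MAXMULT] = founder_mult

    # -- storage ------------------------------------------------------------
    def _alloc(self, cap: int):
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.pos = np.zeros(cap, dtype=np.int64)
        self.t_birth = np.zeros(cap, dtype=np.float64)
        self.t_death = np.full(cap, np.nan, dtype=np.float64)
        self.mult = np.ones(cap, dtype=np.float64)
        self.first_var = np.full(cap, -1, dtype=np.int64)
        self.nvar = np.zeros(cap, dtype=np.int16)
        self.size_at_birth = np.zeros(cap, dtype=np.int64)
        self.diss = np.zeros(cap, dtype=np.uint8)
        self.alive_slot = np.full(cap, -1, dtype=np.int64)
        vcap = int(max(1024, cap * (self.config.u + self.config.u_b) * 1.3))
        self.var_origin = np.zeros(vcap, dtype=np.int64)
        self.var_kind = np.zeros(vcap, dtype=np.uint8)
        self.var_coord = np.zeros(vcap, dtype=np.int64)
        self.var_s = np.zeros(vcap, dtype=np.float64)
        self.var_t = np.zeros(vcap, dtype=np.float64)

    def _grow_cells(self):
        old = self.parent.shape[0]
        new = int(old * 1.6)
        for name in ("parent", "pos", "t_birth", "t_death", "mult",
                     "first_var", "nvar", "size_at_birth", "diss",
                     "alive_slot"):
            a = getattr(self, name)
            b = np.empty(new, dtype=a.dtype)
            b[:old] = a
            if name in ("parent", "first_var", "alive_slot"):
                b[old:] = -1
            setattr(self, name, b)

    def _grow_vars(self):
        old = self.var_origin.shape[0]
        new = int(old * 1.6) + 1024
        for name in ("var_origin", "var_kind", "var_coord", "var_s", "var_t"):
            a = getattr(self, name)
            b = np.zeros(new, dtype=a.dtype)
            b[:old] = a
            setattr(self, name, b)

    # -- properties ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return int(self.istate[K.I_NCELLS])

    @property
    def n_alive(self) -> int:
        return int(self.istate[K.I_NALIVE])

    @property
    def n_variants(self) -> int:
        return int(self.istate[K.I_NVARS])

    @property
    def n_births(self) -> int:
        return int(self.istate[K.I_BIRTHS]) + 1  # founder included

    @property
    def n_deaths(self) -> int:
        return int(self.istate[K.I_DEATHS])

    @property
    def n_seeding_events(self) -> int:
        return int(self.istate[K.I_NSEEDS])

    @property
    def time(self) -> float:
        return float(self.fstate[K.F_TIME])

    @property
    def alive_ids(self) -> np.ndarray:
        return np.sort(self.alive_list[: self.n_alive].copy())

    @property
    def alive_mask(self) -> np.ndarray:
        m = np.zeros(self.n_cells, dtype=bool)
        m[self.alive_list[: self.n_alive]] = True
        return m

    def positions(self, cells: np.ndarray) -> np.ndarray:
        """(n, 3) lattice coordinates relative to the lattice center."""
        p = self.pos[cells]
        s = self.side
        xyz = np.stack([p // (s * s), (p // s) % s, p % s], axis=1)
        return xyz - s // 2

    # -- growth -------------------------------------------------------------
    def run_to_size(self, target: int) -> "TumorState":
        """Advance the event loop until the population reaches ``target``.

        Raises :class:`TumorExtinctError` if the population dies out.
        """
        if target < self.n_alive:
            raise ValueError("target below current population")
        cfg = self.config
        while True:
            status = K.grow(
                self.parent, self.pos, self.t_birth, self.t_death, self.mult,
                self.first_var, self.nvar, self.size_at_birth, self.diss,
                self.var_origin, self.var_kind, self.var_coord, self.var_s,
                self.var_t,
                self.occ, self.side, self.nbr_off,
                self.alive_list, self.alive_slot,
                self.seed_cell, self.seed_size, self.seed_time,
                self.istate, self.fstate,
                cfg.lambda0, self.mu_run, cfg.u, cfg.u_b,
                cfg.s_mean, cfg.s_sd,
                cfg.genome_len_passenger, cfg.genome_len_driver,
                1 if cfg.mutation_model == "poisson" else 0,
                target, cfg.N_s, 1 if self.seeding_on else 0,
                self.rng,
            )
            if status == K.NEED_CELL_CAPACITY:
                self._grow_cells()
                continue
            if status == K.NEED_VAR_CAPACITY:
                self._grow_vars()
                continue
            self.status = status
            if status == K.EXTINCT:
                raise TumorExtinctError(self)
            if status == K.HIT_BOUNDARY:
                self._expand_lattice()
                continue
            return self

    def _expand_lattice(self):
        """Rebuild the lattice with a 1.4x larger side, remapping every
        recorded position (the tumor reached the wall)."""
        s0 = self.side
        s1 = 2 * int(np.ceil(0.7 * s0)) + 3
        if s1 > 760:
            raise MemoryError("lattice grew beyond the supported size")
        shift = s1 // 2 - s0 // 2
        n = self.n_cells
        p = self.pos[:n]
        x = p // (s0 * s0) + shift
        y = (p // s0) % s0 + shift
        z = p % s0 + shift
        self.pos[:n] = (x * s1 + y) * s1 + z
        self.side = s1
        self.occ = np.zeros(s1 ** 3, dtype=np.int32)
        alive = self.alive_list[: self.n_alive]
        self.occ[self.pos[alive]] = alive.astype(np.int32) + 1
        self.nbr_off = (_NBR[:, 0] * s1 + _NBR[:, 1]) * s1 + _NBR[:, 2]

    # -- genotype queries ---------------------------------------------------
    def new_variant_ids(self, cell: int) -> np.ndarray:
        """Global ids of the variants gained at this cell's birth."""
        nv = int(self.nvar[cell])
        if nv == 0:
            return np.empty(0, dtype=np.int64)
        f = int(self.first_var[cell])
        return np.arange(f, f + nv, dtype=np.int64) + self.variant_id_start

    def ancestry(self, cell: int) -> np.ndarray:
        """Path of cell ids from the founder down to ``cell`` (inclusive)."""
        path = []
        c = int(cell)
        while c >= 0:
            path.append(c)
            c = int(self.parent[c])
        return np.array(path[::-1], dtype=np.int64)

    def cell_variant_ids(self, cell: int) -> np.ndarray:
        """All (global) variant ids carried by ``cell``, including any
        variants clonal by inheritance (metastasis founder genotype)."""
        own = [self.new_variant_ids(c) for c in self.ancestry(cell)]
        own = [a for a in own if a.size]
        parts = ([self.clonal_variant_ids] if self.clonal_variant_ids.size
                 else []) + own
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)

    def seeding_events(self) -> list[SeedingEvent]:
        n = self.n_seeding_events
        return [
            SeedingEvent(
                seed_index=i + 1,
                seeding_cell=int(self.seed_cell[i]),
                primary_size_at_seed=int(self.seed_size[i]),
                t_seed=float(self.seed_time[i]),
            )
            for i in range(n)
        ]

    # -- dataframe exports --------------------------------------------------
    def cells_df(self):
        import pandas as pd

        n = self.n_cells
        return pd.DataFrame({
            "cell_id": np.arange(n, dtype=np.int64),
            "parent_id": self.parent[:n],
            "x": self.positions(np.arange(n))[:, 0],
            "y": self.positions(np.arange(n))[:, 1],
            "z": self.positions(np.arange(n))[:, 2],
            "t_birth": self.t_birth[:n],
            "t_death": self.t_death[:n],
            "disseminated": self.diss[:n].astype(np.int64),
            "size_at_birth": self.size_at_birth[:n],
            "new_variant_ids": [
                ",".join(map(str, self.new_variant_ids(i))) for i in range(n)
            ],
        })

    def variants_df(self):
        import pandas as pd

        n = self.n_variants
        return pd.DataFrame({
            "variant_id": np.arange(n, dtype=np.int64) + self.variant_id_start,
            "coordinate": self.var_coord[:n],
            "kind": np.where(self.var_kind[:n] == 1, "driver", "passenger"),
            "s_value": self.var_s[:n],
            "origin_cell": self.var_origin[:n],
            "t_origin": self.var_t[:n],
        })


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def init_tumor(config: SimConfig) -> TumorState:
    """A size-1 tumor: one founder at the lattice center at t = 0.

    The founder carries no explicit variants (its clonal variants are
    implicit; time zero is the founder's birth)."""
    return TumorState(config, config.N_final, config.rho, config.rng_seed)


def run_to_size(tumor: TumorState, target: int) -> TumorState:
    return tumor.run_to_size(target)


def run_with_seeding(config: SimConfig):
    """Grow a primary to ``N_final``, seeding one dissemination event each
    time the population first reaches a multiple of ``N_s``.

    Returns ``(primary, events)``; metastases are not grown here (see
    :func:`grow_metastasis`)."""
    tumor = init_tumor(config)
    tumor.run_to_size(config.N_final)
    return tumor, tumor.seeding_events()


def _met_stream_seed(rng_seed: int, seed_index: int, attempt: int) -> int:
    x = (int(rng_seed) ^ (int(seed_index) << 20)) \
        + int(attempt) * 0x9E3779B97F4A7C15
    z, _ = K.splitmix64(np.uint64(x % (1 << 64)))
    return int(z & np.uint64(0x7FFFFFFFFFFFFFFF))

#: variant-id block reserved per metastasis
MET_VARIANT_BLOCK = 2_000_000


def grow_metastasis(primary: TumorState, event: SeedingEvent,
                    n_final: Optional[int] = None,
                    max_retries: int = 100) -> TumorState:
    """Grow the metastasis founded by ``event``'s seeding cell.

    The metastasis starts from a single cell carrying the seeding cell's
    full genotype, on a fresh lattice, with death-to-birth ratio
    ``config.rho_met``; all other parameters are inherited. If the lineage
    goes extinct the growth is refounded from the same genotype with a
    fresh RNG stream (survival conditioning), up to ``max_retries`` times.
    """
    cfg = primary.config
    n_final = int(n_final if n_final is not None else cfg.N_final)
    clonal = primary.cell_variant_ids(event.seeding_cell)
    vstart = (primary.variant_id_start + MET_VARIANT_BLOCK
              + event.seed_index * MET_VARIANT_BLOCK)
    last_exc = None
    for attempt in range(max_retries):
        met = TumorState(
            cfg, n_final, cfg.rho_met,
            rng_seed=_met_stream_seed(cfg.rng_seed, event.seed_index, attempt),
            founder_mult=float(primary.mult[event.seeding_cell]),
            clonal_variant_ids=clonal,
            variant_id_start=vstart,
            seeding_on=False,
        )
        met.extinction_retries = attempt
        try:
            met.run_to_size(n_final)
            event.metastasis = met
            return met
        except TumorExtinctError as exc:
            last_exc = exc
    raise RuntimeError(
        f"metastasis for seeding event {event.seed_index} went extinct "
        f"{max_retries} times"
    ) from last_exc


# -- reference-semantics single-cell operations -----------------------------

@dataclass
class CellRecord:
    """One row of the cell registry (convenience object for single-cell
    operations and tests; the simulator itself stores arrays)."""

    cell_id: int
    parent_id: Optional[int]
    position: tuple = (0, 0, 0)
    t_birth: float = 0.0
    t_death: Optional[float] = None
    new_variant_ids: list = field(default_factory=list)
    birth_rate_multiplier: float = 1.0


def draw_selection(s_mean: float, s_sd: Optional[float],
                   rng: np.random.Generator) -> float:
    """Selection coefficient: Gaussian(s_mean, s_sd) truncated below at 0
    by resampling (s_sd defaults to s_mean / 2)."""
    if s_sd is None:
        s_sd = s_mean / 2.0
    if s_mean == 0.0 and s_sd == 0.0:
        return 0.0
    while True:
        s = rng.normal(s_mean, s_sd)
        if s >= 0.0:
            return float(s)


def apply_birth_mutations(daughter: CellRecord, config: SimConfig,
                          rng: np.random.Generator,
                          next_variant_id: int = 0) -> CellRecord:
    """Assign birth mutations to a newborn daughter (reference semantics
    of the compiled kernel): with probability ``u`` one new passenger,
    with probability ``u_b`` one new driver multiplying the inherited
    birth-rate multiplier by ``1 + s``. Variant ids are always new
    (infinite alleles); genomic coordinates are labels and may collide."""
    vid = next_variant_id
    if config.mutation_model == "poisson":
        n_pass = rng.poisson(config.u)
    else:
        n_pass = int(rng.random() < config.u)
    for _ in range(n_pass):
        daughter.new_variant_ids.append(vid)
        vid += 1
    if rng.random() < config.u_b:
        s = draw_selection(config.s_mean, config.s_sd, rng)
        daughter.birth_rate_multiplier *= 1.0 + s
        daughter.new_variant_ids.append(vid)
        vid += 1
    return daughter
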