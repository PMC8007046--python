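"""Compiled inner loops for the lattice birth-death simulator.

The event loop is an exact stochastic simulation: event times are drawn
from the total-rate bound ``lambda0 * max_mult * n_alive + mu * n_alive``
and proposed births are thinned with acceptance probability
``mult_i * psi_i / max_mult`` (Poisson thinning, statistically exact).
``psi_i`` is the fraction of empty Moore neighbors of cell *i*, so a fully
surrounded cell never divides.

All mutable simulation state lives in preallocated arrays owned by the
Python caller; the kernel returns a status code when it runs out of
capacity and can be resumed after the caller grows the arrays.
"""

import numpy as np
from numba import njit

# status codes returned by grow()
OK = 0
EXTINCT = 1
NEED_CELL_CAPACITY = 2
NEED_VAR_CAPACITY = 3
HIT_BOUNDARY = 4

# ---------------------------------------------------------------------------
# RNG: splitmix64 seeding + xoshiro256++ streams
# ---------------------------------------------------------------------------

_U64 = np.uint64


@njit(cache=True, inline="always")
def _rotl(x, k):
    return _U64((x << _U64(k)) | (x >> _U64(64 - k)))


@njit(cache=True)
def splitmix64(x):
    x = _U64(x + _U64(0x9E3779B97F4A7C15))
    z = x
    z = _U64((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9))
    z = _U64((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB))
    return _U64(z ^ (z >> _U64(31))), x


@njit(cache=True)
def seed_state(seed):
    """Initialize a 4-word xoshiro256++ state from an integer seed."""
    st = np.empty(4, dtype=np.uint64)
    x = _U64(seed)
    for i in range(4):
        z, x = splitmix64(x)
        st[i] = z
    return st


@njit(cache=True, inline="always")
def next_u64(st):
    result = _U64(_rotl(_U64(st[0] + st[3]), 23) + st[0])
    t = _U64(st[1] << _U64(17))
    st[2] ^= st[0]
    st[3] ^= st[1]
    st[1] ^= st[2]
    st[0] ^= st[3]
    st[2] ^= t
    st[3] = _rotl(st[3], 45)
    return result


@njit(cache=True, inline="always")
def runif(st):
    return (next_u64(st) >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def rint(st, n):
    # unbiased enough for n << 2^64
    return np.int64(next_u64(st) % _U64(n))


@njit(cache=True)
def rnorm(st):
    # Box-Muller (cosine branch only)
    u1 = runif(st)
    while u1 <= 1e-300:
        u1 = runif(st)
    u2 = runif(st)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


@njit(cache=True)
def trunc_normal(st, mean, sd):
    """Gaussian(mean, sd) truncated below at 0 by resampling."""
    if mean == 0.0 and sd == 0.0:
        return 0.0
    while True:
        x = mean + sd * rnorm(st)
        if x >= 0.0:
            return x


@njit(cache=True)
def rpoisson(st, lam):
    # Knuth; lam is small (mutation rates)
    limit = np.exp(-lam)
    k = 0
    p = runif(st)
    while p > limit:
        k += 1
        p *= runif(st)
    return k


# ---------------------------------------------------------------------------
# main event loop
# ---------------------------------------------------------------------------

# indices into the istate scalar array
I_NCELLS = 0
I_NALIVE = 1
I_NVARS = 2
I_NSEEDS = 3
I_BIRTHS = 4
I_DEATHS = 5
I_PENDING_SEED = 6
I_NEXT_SEED_AT = 7
# indices into fstate
F_TIME = 0
F_MAXMULT = 1


@njit(cache=True)
def grow(
    # registry arrays (capacity = len(parent))
    parent, pos, t_birth, t_death, mult, first_var, nvar, size_at_birth, diss,
    # variant arrays (capacity = len(var_origin))
    var_origin, var_kind, var_coord, var_s, var_t,
    # lattice
    occ, side, nbr_off,
    # alive bookkeeping
    alive_list, alive_slot,
    # seeding outputs
    seed_cell, seed_size, seed_time,
    # scalar state
    istate, fstate,
    # parameters
    lambda0, mu, u_pass, u_driver, s_mean, s_sd,
    glen_pass, glen_driver, poisson_mode,
    target, n_s, seeding_on,
    rng,
):
    """Advance the tumor until the alive population reaches ``target``.

    Returns a status code; the caller inspects istate/fstate for progress.
    """
    n_cells = istate[I_NCELLS]
    n_alive = istate[I_NALIVE]
    n_vars = istate[I_NVARS]
    t = fstate[F_TIME]
    max_mult = fstate[F_MAXMULT]
    cap = parent.shape[0]
    vcap = var_origin.shape[0]

    while n_alive < target or istate[I_PENDING_SEED] == 1:
        if n_alive == 0:
            istate[I_NCELLS] = n_cells
            istate[I_NALIVE] = n_alive
            istate[I_NVARS] = n_vars
            fstate[F_TIME] = t
            fstate[F_MAXMULT] = max_mult
            return EXTINCT
        if n_cells + 1 > cap:
            istate[I_NCELLS] = n_cells
            istate[I_NALIVE] = n_alive
            istate[I_NVARS] = n_vars
            fstate[F_TIME] = t
            fstate[F_MAXMULT] = max_mult
            return NEED_CELL_CAPACITY
        if n_vars + 16 > vcap:
            istate[I_NCELLS] = n_cells
            istate[I_NALIVE] = n_alive
            istate[I_NVARS] = n_vars
            fstate[F_TIME] = t
            fstate[F_MAXMULT] = max_mult
            return NEED_VAR_CAPACITY

        birth_bound = lambda0 * max_mult * n_alive
        death_rate = mu * n_alive
        total = birth_bound + death_rate
        # exponential waiting time at the bound rate
        uu = runif(rng)
        while uu <= 1e-300:
            uu = runif(rng)
        t += -np.log(uu) / total

        if runif(rng) * total < birth_bound:
            # proposed birth: pick a candidate uniformly among alive cells
            c = alive_list[rint(rng, n_alive)]
            p = pos[c]
            n_empty = 0
            for k in range(26):
                if occ[p + nbr_off[k]] == 0:
                    n_empty += 1
            if n_empty == 0:
                continue  # psi = 0: rejected
            # thinning acceptance: mult_c * (n_empty/26) / max_mult
            if runif(rng) * max_mult * 26.0 >= mult[c] * n_empty:
                continue
            # accept: choose the m-th empty neighbor uniformly
            m = rint(rng, n_empty)
            site = np.int64(-1)
            cnt = 0
            for k in range(26):
                q = p + nbr_off[k]
                if occ[q] == 0:
                    if cnt == m:
                        site = q
                        break
                    cnt += 1
            # boundary guard: site must not touch the lattice wall
            z = site % side
            y = (site // side) % side
            x = site // (side * side)
            if x <= 0 or x >= side - 1 or y <= 0 or y >= side - 1 \
                    or z <= 0 or z >= side - 1:
                istate[I_NCELLS] = n_cells
                istate[I_NALIVE] = n_alive
                istate[I_NVARS] = n_vars
                fstate[F_TIME] = t
                fstate[F_MAXMULT] = max_mult
                return HIT_BOUNDARY

            d = n_cells
            n_cells += 1
            parent[d] = c
            pos[d] = site
            t_birth[d] = t
            t_death[d] = np.nan
            m_d = mult[c]
            first_var[d] = -1
            nv = 0
            # passenger variant(s)
            n_new_pass = 0
            if poisson_mode:
                n_new_pass = rpoisson(rng, u_pass)
            else:
                if runif(rng) < u_pass:
                    n_new_pass = 1
            for _ in range(n_new_pass):
                if first_var[d] < 0:
                    first_var[d] = n_vars
                var_origin[n_vars] = d
                var_kind[n_vars] = 0
                var_coord[n_vars] = 1 + rint(rng, glen_pass)
                var_s[n_vars] = 0.0
                var_t[n_vars] = t
                n_vars += 1
                nv += 1
            # driver variant
            if u_driver > 0.0 and runif(rng) < u_driver:
                s = trunc_normal(rng, s_mean, s_sd)
                m_d = m_d * (1.0 + s)
                if first_var[d] < 0:
                    first_var[d] = n_vars
                var_origin[n_vars] = d
                var_kind[n_vars] = 1
                var_coord[n_vars] = 1 + rint(rng, glen_driver)
                var_s[n_vars] = s
                var_t[n_vars] = t
                n_vars += 1
                nv += 1
            nvar[d] = nv
            mult[d] = m_d
            if m_d > max_mult:
                max_mult = m_d

            if istate[I_PENDING_SEED] == 1:
                # the newborn disseminates: it never occupies the lattice
                diss[d] = 1
                t_death[d] = np.nan
                size_at_birth[d] = n_alive
                ns = istate[I_NSEEDS]
                seed_cell[ns] = d
                seed_size[ns] = n_alive
                seed_time[ns] = t
                istate[I_NSEEDS] = ns + 1
                istate[I_PENDING_SEED] = 0
            else:
                diss[d] = 0
                occ[site] = d + 1
                alive_list[n_alive] = d
                alive_slot[d] = n_alive
                n_alive += 1
                size_at_birth[d] = n_alive
                if seeding_on and n_alive >= istate[I_NEXT_SEED_AT]:
                    istate[I_PENDING_SEED] = 1
                    istate[I_NEXT_SEED_AT] += n_s
            istate[I_BIRTHS] += 1
        else:
            # death: uniform over alive cells
            slot = rint(rng, n_alive)
            c = alive_list[slot]
            occ[pos[c]] = 0
            t_death[c] = t
            last = alive_list[n_alive - 1]
            alive_list[slot] = last
            alive_slot[last] = slot
            alive_slot[c] = -1
            n_alive -= 1
            istate[I_DEATHS] += 1

    istate[I_NCELLS] = n_cells
    istate[I_NALIVE] = n_alive
    istate[I_NVARS] = n_vars
    fstate[F_TIME] = t
    fstate[F_MAXMULT] = max_mult
    return OK


# ---------------------------------------------------------------------------
# genealogy aggregation passes
# ---------------------------------------------------------------------------

@njit(cache=True)
def subtree_counts(parent, weights):
    """Sum ``weights`` over each cell's subtree (cell indices are in birth
    order, so every parent precedes its children)."""
    n = parent.shape[0]
    counts = weights.astype(np.int64).copy()
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p >= 0:
            counts[p] += counts[i]
    return counts


@njit(cache=True)
def subtree_weights(parent, weights):
    """Float variant of subtree_counts (weighted observation sets)."""
    n = parent.shape[0]
    counts = weights.astype(np.float64).copy()
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p >= 0:
            counts[p] += counts[i]
    return counts


@njit(cache=True)
def cumulative_variant_counts(parent, nvar):
    """Total variants carried by each cell (inherited + own)."""
    n = parent.shape[0]
    k = np.zeros(n, dtype=np.int64)
    for i in range(n):
        p = parent[i]
        if p >= 0:
            k[i] = k[p] + nvar[i]
        else:
            k[i] = nvar[i]
    return k
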