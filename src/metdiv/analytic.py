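"""Closed-form branching-process model of expected divergence.

A non-spatial birth-death branching process (birth rate ``lambda0``,
death rate ``mu``, ratio ``rho = mu/lambda0``) accumulates passenger
variants at probability ``u`` per division. The variant count ``k``
carried by the seeding cell acts as the clock for dissemination time.
For the j-th variant on the seeding cell's lineage, the probability that
it ends up detectable in the final primary tumor (frequency above the
threshold ``f``, typically ``2 * alpha`` for heterozygous variants at VAF
cutoff ``alpha``) is

    d_j = (u / (u - log(1 + (rho - 1) f)))**g(j),   d_0 = 1,

where ``g(j)`` maps the j-th lineage variant to its absolute order of
appearance in the whole tumor: successive lineage variants appear at
expected real-time spacing ``1/(u*lambda0)``, the conditioned expected
population size is ``N(t) = e^{(lambda-mu)t}/rho - (1/rho - 1)
e^{-(lambda-mu)t}``, and the expected number of surviving variants in a
population of N cells is ``N*u``, giving

    g(j) = u * (exp(-(1-rho) j / u) + 2 sinh((1-rho) j / u) / rho).

The pre-dissemination metastasis-specific branch B_md for a seeding cell
with ``k`` variants then has the telescoping pmf
``Pr[B_md = k - j] = d_j - d_{j+1}`` (j < k), ``Pr[B_md = 0] = d_k``.

Advantageous types introduced at clock times T_i with final population
fractions f_i mix the neutral expectations: conditioned on the seeding
cell's type, the threshold rescales (``2*alpha/f_i`` within type i,
``2*alpha/(1-f_1)`` for the original type) and the clock restarts at
T_i. The type-origination weights phi_i follow one of three seeding
scenarios: always the most advanced extant type, proportional to type
birth rates, or uniform over living cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SCENARIOS = ("most_advanced", "fitness_proportional", "uniform")


@dataclass
class NeutralParams:
    """Parameters of the neutral detectability model."""

    u: float = 0.15        # variant probability per division
    rho: float = 0.72      # death-to-birth ratio
    f: float = 0.02        # detectability frequency threshold (e.g. 2*alpha)
    lambda0: float = 0.25  # birth rate (cancels in g; used for N(t))

    def __post_init__(self):
        if not (0.0 < self.u <= 1.0):
            raise ValueError("u must be in (0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 < self.f < 1.0):
            raise ValueError("f must be in (0, 1)")


def population_size(t, params: NeutralParams):
    """Expected population size at time ``t`` (days), conditioned on
    long-term survival: ``N(t) = e^{rt}/rho - (1/rho - 1) e^{-rt}`` with
    net growth rate ``r = lambda0 - mu``. ``N(0) = 1``."""
    if params.rho <= 0.0:
        raise ValueError("rho must be positive for the conditioned size")
    r = params.lambda0 * (1.0 - params.rho)
    t = np.asarray(t, dtype=float)
    out = np.exp(r * t) / params.rho - (1.0 / params.rho - 1.0) * np.exp(-r * t)
    return out if out.ndim else float(out)


def order_map(j, params: NeutralParams):
    """g(j): absolute appearance order in the tumor of the j-th variant on
    the seeding cell's lineage. ``g(0) = u``; strictly increasing in j.

    Equals ``u * N(t_j)`` at the expected appearance time
    ``t_j = j / (u * lambda0)``; lambda0 cancels."""
    j = np.asarray(j, dtype=float)
    x = (1.0 - params.rho) * j / params.u
    with np.errstate(over="ignore"):
        out = params.u * (np.exp(-x) + 2.0 * np.sinh(x) / params.rho)
    return out if out.ndim else float(out)


def _log_base(params: NeutralParams) -> float:
    arg = (params.rho - 1.0) * params.f
    if arg <= -1.0:
        raise ValueError(
            f"detectability threshold f={params.f} out of domain for "
            f"rho={params.rho} (requires f < 1/(1-rho))"
        )
    return float(np.log(params.u) - np.log(params.u - np.log1p(arg)))


def detectability(j, params: NeutralParams):
    """d_j: probability the j-th lineage variant is detectable in the
    final primary. ``d_0 = 1`` exactly (the founder variant is clonal);
    the sequence decreases to 0."""
    j_arr = np.atleast_1d(np.asarray(j))
    lb = _log_base(params)  # < 0
    g = np.asarray(order_map(j_arr, params), dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        logd = np.where(np.isinf(g), -np.inf, g * lb)
    d = np.exp(logd)
    d[j_arr == 0] = 1.0
    return d if np.asarray(j).ndim else float(d[0])


@dataclass
class BmdDistribution:
    """Distribution of B_md for a seeding cell with ``k_seed`` variants."""

    k_seed: int
    pmf: np.ndarray      # index i = Pr[B_md = i], support 0..k_seed

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(self.pmf.size), self.pmf))

    @property
    def std(self) -> float:
        i = np.arange(self.pmf.size)
        m = self.mean
        return float(np.sqrt(max(np.dot(i * i, self.pmf) - m * m, 0.0)))


def bmd_pmf_from_detectability(d: np.ndarray) -> BmdDistribution:
    """Telescoping pmf of B_md from lineage detectabilities
    ``d = (d_0, ..., d_k)``: ``Pr[B_md = k - j] = d_j - d_{j+1}`` for
    j < k and ``Pr[B_md = 0] = d_k``; sums to d_0 (= 1)."""
    d = np.asarray(d, dtype=float)
    k_seed = d.size - 1
    if k_seed == 0:
        return BmdDistribution(0, np.ones(1))
    pmf = np.empty(k_seed + 1)
    pmf[0] = d[k_seed]
    pmf[1:] = (d[:-1] - d[1:])[::-1]
    return BmdDistribution(k_seed, pmf)


def bmd_pmf(k_seed: int, params: NeutralParams) -> BmdDistribution:
    """B_md distribution for a seeding cell with ``k_seed`` variants under
    the neutral detectability model."""
    if k_seed < 0:
        raise ValueError("k_seed must be >= 0")
    if k_seed == 0:
        return BmdDistribution(0, np.ones(1))
    return bmd_pmf_from_detectability(
        detectability(np.arange(k_seed + 1), params))


def expected_bmd_neutral(K: int, f: float, rho: float, u: float) -> float:
    """Expected B_md under neutral growth at seeding clock ``K``:
    ``sum_{j=1..K} j (d_{K-j} - d_{K-j+1})`` (direct sum, independent of
    the pmf construction)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if K == 0:
        return 0.0
    params = NeutralParams(u=u, rho=rho, f=f)
    d = detectability(np.arange(K + 1), params)
    j = np.arange(1, K + 1)
    return float(np.sum(j * (d[K - j] - d[K - j + 1])))


# ---------------------------------------------------------------------------
# multi-type mixture
# ---------------------------------------------------------------------------

@dataclass
class TypeStructure:
    """Nested advantageous types (a subtype chain) and a seeding scenario.

    ``rho[0]`` is the original type; each ``rho[i]`` (i >= 1) is a subtype
    of type i-1, introduced at clock time ``T[i]`` and reaching final
    population fraction ``f[i]``. ``T[0] = 0`` and ``f[0]`` is implicit.
    ``birth_rates`` (optional) are the per-type birth rates used by the
    fitness-proportional scenario; default lambda_i proportional to
    1/rho_i (advantage through longer-lived lineages at a common death
    rate)."""

    rho: Sequence[float]
    T: Sequence[float]
    f: Sequence[float]            # final fraction per type, f[0] unused
    scenario: str = "uniform"
    u: float = 0.15
    birth_rates: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.rho = list(map(float, self.rho))
        self.T = list(map(float, self.T))
        self.f = list(map(float, self.f))
        n = len(self.rho)
        if not (len(self.T) == len(self.f) == n):
            raise ValueError("rho, T, f must have equal length")
        if self.T[0] != 0.0:
            raise ValueError("T[0] must be 0 (founder type)")
        for i in range(1, n):
            if self.rho[i] >= self.rho[i - 1]:
                raise ValueError("rho must strictly decrease along the chain")
            if self.T[i] <= self.T[i - 1]:
                raise ValueError("T must strictly increase along the chain")
            if not (0.0 < self.f[i] < 1.0):
                raise ValueError("type fractions must be in (0, 1)")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.birth_rates is None:
            self.birth_rates = [1.0 / r for r in self.rho]

    @property
    def n_types(self) -> int:
        return len(self.rho)


def _expected_type_size(k: float, T_i: float, rho_i: float, u: float) -> float:
    """Expected population founded by one cell at clock T_i, evaluated at
    clock k, with ratio rho_i (clock units: lineage variant count)."""
    x = (1.0 - rho_i) * max(k - T_i, 0.0) / u
    with np.errstate(over="ignore"):
        return float(np.exp(x) / rho_i - (1.0 / rho_i - 1.0) * np.exp(-x))


def seeding_weights(k: float, structure: TypeStructure) -> np.ndarray:
    """Type-origination probabilities phi_i at seeding clock ``k``.

    A type has weight 0 before its introduction time. Scenarios:
    ``most_advanced`` puts all mass on the newest extant type;
    ``fitness_proportional`` weights extant types by birth rate;
    ``uniform`` weights them by expected (exclusive) population size."""
    n = structure.n_types
    extant = [i for i in range(n) if structure.T[i] <= k]
    phi = np.zeros(n)
    if structure.scenario == "most_advanced":
        phi[extant[-1]] = 1.0
        return phi
    if structure.scenario == "fitness_proportional":
        w = np.array([structure.birth_rates[i] for i in extant])
    else:  # uniform over living cells: expected type sizes
        raw = [_expected_type_size(k, structure.T[i], structure.rho[i],
                                   structure.u) for i in extant]
        # exclusive size of a type excludes its (nested) subtype
        w = np.array([
            max(raw[j] - (raw[j + 1] if j + 1 < len(raw) else 0.0), 1e-300)
            for j in range(len(raw))
        ])
    phi[extant] = w / w.sum()
    return phi


def _branch_params(i: int, structure: TypeStructure, f_base: float):
    """(clock offset, threshold, rho) of the type-i branch."""
    if i == 0:
        denom = 1.0 - structure.f[1] if structure.n_types > 1 else 1.0
        return 0.0, f_base / denom, structure.rho[0]
    return structure.T[i], f_base / structure.f[i], structure.rho[i]


def expected_bmd_multitype(k: float, structure: TypeStructure,
                           alpha: float = 0.01):
    """Scenario-weighted expected B_md (and origination-mixture std) at
    seeding clock ``k`` with detectability threshold ``2 * alpha``.

    Each type-i branch is the neutral expectation with clock ``k - T_i``
    and threshold rescaled to the type's sub-population. A rescaled
    threshold >= 1 means the sub-population cannot lift any post-founder
    variant above the overall threshold: that branch degenerates to
    ``B_md = K_i`` exactly (d_j = 0 for j >= 1), with a warning."""
    f_base = 2.0 * alpha
    phi = seeding_weights(k, structure)
    means = np.zeros_like(phi)
    second = np.zeros_like(phi)
    for i in np.flatnonzero(phi > 0):
        T_i, f_i, rho_i = _branch_params(int(i), structure, f_base)
        if f_i <= 0.0:
            raise ValueError(f"rescaled threshold {f_i:.4g} <= 0")
        K_i = int(round(max(k - T_i, 0.0)))
        if f_i >= 1.0:
            warnings.warn(
                f"rescaled threshold {f_i:.3g} >= 1 for type {i}: no "
                "post-founder variant of this type can be detectable; "
                "branch degenerates to B_md = K", stacklevel=2)
            means[i] = float(K_i)
            second[i] = float(K_i) ** 2
            continue
        dist = bmd_pmf(K_i, NeutralParams(u=structure.u, rho=rho_i, f=f_i))
        means[i] = dist.mean
        second[i] = dist.std ** 2 + dist.mean ** 2
    mean = float(np.dot(phi, means))
    var = max(float(np.dot(phi, second)) - mean * mean, 0.0)
    return mean, float(np.sqrt(var))


def origination_variance(k: float, structure: TypeStructure,
                         alpha: float = 0.01) -> float:
    """Variance of the per-type expected B_md under the seeding-weight
    distribution alone (0 under the deterministic most-advanced
    scenario)."""
    f_base = 2.0 * alpha
    phi = seeding_weights(k, structure)
    means = np.zeros_like(phi)
    for i in np.flatnonzero(phi > 0):
        T_i, f_i, rho_i = _branch_params(int(i), structure, f_base)
        K_i = int(round(max(k - T_i, 0.0)))
        means[i] = (float(K_i) if f_i >= 1.0 else
                    expected_bmd_neutral(K_i, f_i, rho_i, structure.u))
    m = float(np.dot(phi, means))
    return max(float(np.dot(phi, means ** 2)) - m * m, 0.0)


def expected_bp(k: float, M_count: float, bmd_at_gamma: float) -> float:
    """Expected primary-specific branch: ``B_p = |M| - k + B_md(gamma)``,
    clamped at 0 (with a warning) where the linear approximation is
    exceeded."""
    val = M_count - k + bmd_at_gamma
    if val < 0:
        warnings.warn("expected B_p clamped at 0 (approximation regime "
                      "exceeded)", stacklevel=2)
        return 0.0
    return float(val)


def size_to_k(n_cells: float, rho: float, u: float) -> float:
    """Clock value (lineage variant count) at which the expected
    population reaches ``n_cells``: inverts N(t) on the k-axis."""
    if n_cells <= 1:
        return 0.0
    # solve e^x / rho - (1/rho - 1) e^{-x} = n for x = (1-rho) k / u
    x = np.log(max(rho * n_cells, 1.0 + 1e-12))
    for _ in range(60):
        ex, emx = np.exp(x), np.exp(-x)
        val = ex / rho - (1.0 / rho - 1.0) * emx - n_cells
        der = ex / rho + (1.0 / rho - 1.0) * emx
        step = val / der
        x -= step
        if abs(step) < 1e-12:
            break
    return float(u * x / (1.0 - rho))


def analytic_curves(k_values, structure: TypeStructure, alpha: float = 0.01,
                    gamma: float = 0.2, M_count: Optional[float] = None):
    """E[B_md], Std[B_md] and E[B_p] over seeding clocks, one row per k.

    ``M_count`` (the number of variants substantially present in the
    primary, from multi-region sampling) is required for the B_p column;
    if omitted, B_p is NaN."""
    import pandas as pd

    rows = []
    for k in k_values:
        e, s = expected_bmd_multitype(k, structure, alpha)
        if M_count is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bmd_g, _ = expected_bmd_multitype(k, structure, gamma)
                bp = expected_bp(k, M_count, bmd_g)
        else:
            bp = np.nan
        rows.append({"k": k, "scenario": structure.scenario,
                     "E_bmd": e, "Std_bmd": s, "E_bp": bp})
    return pd.DataFrame(rows)


def neutral_curve(k_values, params: NeutralParams):
    """E[B_md] under pure neutral growth for each clock value."""
    import pandas as pd

    rows = [{"k": int(k), "scenario": "neutral",
             "E_bmd": expected_bmd_neutral(int(k), params.f, params.rho,
                                           params.u),
             "Std_bmd": bmd_pmf(int(k), params).std,
             "E_bp": np.nan}
            for k in k_values]
    return pd.DataFrame(rows)
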