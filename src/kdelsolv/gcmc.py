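"""Grand canonical Monte Carlo over pocket water occupancy.

The occupancy of the receptor's water sites is sampled at fixed Adams value
B, the dimensionless grand-canonical control parameter (B = βμ′ + ln n̄ for
a region that would hold n̄ waters in equilibrium with bulk). Insertions and
deletions are accepted with the Adams-formulation rules

    P_ins = min(1, e^B / (N+1) · e^(−βΔU)),
    P_del = min(1, N · e^(−B) · e^(−βΔU)),

evaluated in log space. Two system flavours are supported:

* :class:`IdealGasCell` — unbounded particle count, constant insertion
  energy; the stationary law is Poisson with mean e^(B−βU), so ⟨N⟩ = e^B
  for a non-interacting cell. Used as the engine's analytic control.
* :class:`~kdelsolv.toy_models.ToyPocketSystem` — 1–3 discrete sites, each
  holding at most one water. The acceptance rule is applied with the
  site-local count (N_site ∈ {0, 1}), which makes the stationary per-site
  occupancy exactly e^(B−βU_i)/(1+e^(B−βU_i)) and, with coupling, the
  enumerated grand-canonical law.

:func:`titrate` sweeps an Adams grid with independent repeats, producing
the occupancy-vs-B curve that grand-canonical integration turns into a
water transfer free energy (see :mod:`kdelsolv.free_energy`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .toy_models import GCRegion, ToyPocketSystem  # noqa: F401  (re-export)
from .units import beta as _beta

__all__ = [
    "GCRegion",
    "GCParams",
    "GCTrace",
    "TitrationResult",
    "IdealGasCell",
    "run_gcmc",
    "titrate",
    "adams_from_mu",
    "DEFAULT_ADAMS_GRID",
    "write_titration_tsv",
    "read_titration_tsv",
]

#: The Adams sweep used for pocket titrations: −9.0 → −24.0, step 0.5.
DEFAULT_ADAMS_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(-9.0, -24.0 - 0.25, -0.5), 6)
)


def adams_from_mu(
    mu_excess: float, region_volume: float, temperature: float = 298.15,
    bulk_density: float = 0.0334,
) -> float:
    """Adams value equivalent to chemical potential ``mu_excess`` (kcal/mol).

    B = βμ′ + ln(ρ_bulk · V_region): the Adams value at which the region
    exchanges water with a bulk reservoir of number density ``bulk_density``
    (Å⁻³) and excess chemical potential ``mu_excess``.
    """
    if region_volume <= 0:
        raise ValueError("region volume must be positive")
    return _beta(temperature) * mu_excess + math.log(bulk_density * region_volume)


@dataclass(frozen=True)
class IdealGasCell:
    """Unbounded-occupancy cell with constant insertion energy (kcal/mol)."""

    insertion_energy: float = 0.0
    temperature: float = 298.15


@dataclass(frozen=True)
class GCParams:
    """Run-control parameters for one GCMC chain.

    ``move_mix`` gives (insert, delete, translate) proposal probabilities;
    the lattice toys have no translational degrees of freedom, so the
    translate weight must be zero for them. ``n_equil_steps`` defaults to
    10% of production.
    """

    adams_B: float
    n_prod_steps: int
    n_equil_steps: int | None = None
    temperature: float | None = None
    move_mix: tuple[float, float, float] = (0.5, 0.5, 0.0)
    thin: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_prod_steps <= 0:
            raise ValueError("n_prod_steps must be > 0")
        if self.n_equil_steps is not None and self.n_equil_steps < 0:
            raise ValueError("n_equil_steps must be >= 0")
        if abs(sum(self.move_mix) - 1.0) > 1e-9:
            raise ValueError("move_mix probabilities must sum to 1")
        if any(p < 0 for p in self.move_mix):
            raise ValueError("move_mix probabilities must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is required")

    @property
    def equil_steps(self) -> int:
        if self.n_equil_steps is None:
            return self.n_prod_steps // 10
        return self.n_equil_steps


@dataclass(frozen=True)
class GCTrace:
    """Occupancy trace and summary statistics of one GCMC run."""

    samples: np.ndarray  # thinned production-phase N
    mean_N: float
    sd_N: float
    acceptance: dict = field(default_factory=dict)
    adams_B: float = 0.0
    temperature: float = 298.15


def run_gcmc(system, params: GCParams) -> GCTrace:
    """Run one grand-canonical chain and return its occupancy trace.

    ``system`` is a :class:`ToyPocketSystem` (bounded lattice sites) or an
    :class:`IdealGasCell` (unbounded count). Equilibration steps are run
    and discarded before statistics are collected; ``mean_N`` averages
    every production step, ``samples`` holds the thinned trace.
    """
    temperature = params.temperature
    if temperature is None:
        temperature = getattr(system, "temperature", 298.15)
    b = _beta(temperature)
    B = params.adams_B
    rng = np.random.default_rng(params.seed)

    if isinstance(system, IdealGasCell):
        return _run_unbounded(system, params, b, B, rng, temperature)
    if isinstance(system, ToyPocketSystem):
        return _run_sites(system, params, b, B, rng, temperature)
    raise TypeError(f"unsupported system type {type(system).__name__}")


def _run_unbounded(system, params, b, B, rng, temperature) -> GCTrace:
    # log-space acceptance guards e^B overflow for large B
    log_ins_base = B - b * system.insertion_energy
    n_total = params.equil_steps + params.n_prod_steps
    n = 0
    acc = {"insert": [0, 0], "delete": [0, 0]}
    p_ins = params.move_mix[0] / (params.move_mix[0] + params.move_mix[1])
    mean_acc = 0.0
    samples = []
    chunk = 65536
    done = 0
    while done < n_total:
        m = min(chunk, n_total - done)
        u_move = rng.random(m)
        u_acc = rng.random(m)
        for i in range(m):
            step = done + i
            if u_move[i] < p_ins:
                acc["insert"][1] += 1
                # min(1, e^{B-βU}/(N+1))
                if math.log(u_acc[i]) < log_ins_base - math.log(n + 1):
                    n += 1
                    acc["insert"][0] += 1
            else:
                acc["delete"][1] += 1
                if n > 0 and math.log(u_acc[i]) < math.log(n) - log_ins_base:
                    n -= 1
                    acc["delete"][0] += 1
            if step >= params.equil_steps:
                mean_acc += n
                if (step - params.equil_steps) % params.thin == 0:
                    samples.append(n)
        done += m
    samples = np.asarray(samples, dtype=float)
    return GCTrace(
        samples=samples,
        mean_N=mean_acc / params.n_prod_steps,
        sd_N=float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        acceptance={k: tuple(v) for k, v in acc.items()},
        adams_B=B,
        temperature=temperature,
    )


def _run_sites(system: ToyPocketSystem, params, b, B, rng, temperature) -> GCTrace:
    if params.move_mix[2] != 0.0:
        raise ValueError("lattice-site systems support insert/delete moves only")
    sites = system.accessible_sites
    k = len(sites)
    energies = np.array([system.site_energies[s] for s in sites])
    # site-local acceptance exponents without coupling
    log_ins = B - b * energies
    coupling = [
        (sites.index(i), sites.index(j), jij)
        for i, j, jij in system.coupling
        if i in sites and j in sites
    ]
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(k)]
    for i, j, jij in coupling:
        neighbors[i].append((j, jij))
        neighbors[j].append((i, jij))

    occ = np.zeros(k, dtype=np.int64)
    n = 0
    n_total = params.equil_steps + params.n_prod_steps
    acc = {"insert": [0, 0], "delete": [0, 0]}
    p_ins = params.move_mix[0] / (params.move_mix[0] + params.move_mix[1])
    mean_acc = 0.0
    samples = []
    chunk = 65536
    done = 0
    equil = params.equil_steps
    thin = params.thin
    while done < n_total:
        m = min(chunk, n_total - done)
        u_move = rng.random(m)
        u_site = rng.integers(0, k, size=m)
        u_acc = np.log(rng.random(m))
        for i in range(m):
            step = done + i
            s = u_site[i]
            if u_move[i] < p_ins:
                acc["insert"][1] += 1
                if occ[s] == 0:
                    x = log_ins[s]
                    for t, jij in neighbors[s]:
                        if occ[t]:
                            x -= b * jij
                    if u_acc[i] < x:
                        occ[s] = 1
                        n += 1
                        acc["insert"][0] += 1
            else:
                acc["delete"][1] += 1
                if occ[s] == 1:
                    x = -log_ins[s]
                    for t, jij in neighbors[s]:
                        if occ[t]:
                            x += b * jij
                    if u_acc[i] < x:
                        occ[s] = 0
                        n -= 1
                        acc["delete"][0] += 1
            if step >= equil:
                mean_acc += n
                if (step - equil) % thin == 0:
                    samples.append(n)
        done += m
    samples = np.asarray(samples, dtype=float)
    return GCTrace(
        samples=samples,
        mean_N=mean_acc / params.n_prod_steps,
        sd_N=float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        acceptance={k_: tuple(v) for k_, v in acc.items()},
        adams_B=B,
        temperature=temperature,
    )


@dataclass(frozen=True)
class TitrationResult:
    """Mean pocket occupancy vs Adams value, with repeat spread.

    ``repeat_N`` keeps the per-repeat curves (n_repeats × n_B) so that
    downstream free-energy estimates can propagate repeat-level error.
    """

    adams_grid: np.ndarray
    mean_N: np.ndarray
    sd_N: np.ndarray
    n_repeats: int
    repeat_N: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        g = np.asarray(self.adams_grid, dtype=float)
        d = np.diff(g)
        if len(g) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("Adams grid must be strictly monotone")
        if np.any(np.asarray(self.sd_N) < 0):
            raise ValueError("sd_N must be non-negative")


def titrate(
    system,
    adams_grid=DEFAULT_ADAMS_GRID,
    n_repeats: int = 5,
    n_prod_steps: int = 20000,
    n_equil_steps: int | None = None,
    thin: int = 100,
    seed: int | None = None,
    temperature: float | None = None,
) -> TitrationResult:
    """Sweep the Adams grid with independent repeats.

    Per-(repeat, grid-point) seeds are spawned deterministically from the
    base seed, so results are bit-reproducible. Defaults follow the
    pocket-titration protocol: grid −9.0 → −24.0 step 0.5, five repeats.
    """
    grid = np.asarray(adams_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("Adams grid must be non-empty")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    if temperature is None:
        temperature = getattr(system, "temperature", 298.15)
    children = np.random.SeedSequence(seed).spawn(n_repeats * grid.size)
    repeat_N = np.empty((n_repeats, grid.size))
    for r in range(n_repeats):
        for j, B in enumerate(grid):
            child = children[r * grid.size + j]
            params = GCParams(
                adams_B=float(B),
                n_prod_steps=n_prod_steps,
                n_equil_steps=n_equil_steps,
                temperature=temperature,
                thin=thin,
                seed=child,
            )
            repeat_N[r, j] = run_gcmc(system, params).mean_N
    return TitrationResult(
        adams_grid=grid,
        mean_N=repeat_N.mean(axis=0),
        sd_N=repeat_N.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(grid.size),
        n_repeats=n_repeats,
        repeat_N=repeat_N,
        temperature=float(temperature),
    )


def write_titration_tsv(result: TitrationResult, path) -> None:
    df = pd.DataFrame(
        {
            "B": result.adams_grid,
            "mean_N": result.mean_N,
            "sd_N": result.sd_N,
            "n_repeats": result.n_repeats,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_titration_tsv(path, temperature: float = 298.15) -> TitrationResult:
    df = pd.read_csv(path, sep="\t")
    n_rep = int(df["n_repeats"].iloc[0]) if "n_repeats" in df else 1
    mean = df["mean_N"].to_numpy(dtype=float)
    return TitrationResult(
        adams_grid=df["B"].to_numpy(dtype=float),
        mean_N=mean,
        sd_N=df["sd_N"].to_numpy(dtype=float) if "sd_N" in df else np.zeros_like(mean),
        n_repeats=n_rep,
        repeat_N=mean[None, :],
        temperature=temperature,
    )
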