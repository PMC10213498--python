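"""Discrete-time, continuous-space, individual-based forward simulator.

The model: hermaphroditic diploid individuals live on a square habitat
``[0, W]^2``.  Each time step has three stages:

1. *Reproduction with dispersal* — every individual acts as mother exactly
   once, choosing a mate within ``3*sigma_m`` with probability proportional
   to a Gaussian density ``g(d/sigma_m)``.  The brood size is
   ``Poisson(1/L)``; each offspring is displaced from the mother by
   independent ``N(0, sigma_f)`` draws per axis.  Offspring proposed outside
   the habitat (or an optional habitat mask) are not born and are not
   replaced.
2. *Mortality* — individual ``i`` survives with probability
   ``min(0.95, 1 / (1 + n_i / (K (1 + L))))`` times an edge penalty
   ``min(1, sqrt(d_edge / sigma_c))``, where ``n_i`` is the local density
   measured with a Gaussian kernel of width ``sigma_c`` (truncated at
   ``3*sigma_c``).  Both reproduction and survival use start-of-step
   positions and densities; newborns join the population afterwards.
3. Recording — census size, per-step inbreeding effective size, and the
   accumulators for effective dispersal.

Density normalisation: the per-neighbour kernel weight is the standard
normal density of ``d/sigma_c`` (:func:`local_density`), and the survival
stage divides the summed weight by ``sqrt(2*pi)*sigma_c**2`` so that the
regulated density — and hence the equilibrium census near ``K*W**2`` — does
not depend on the interaction scale ``sigma_c``.  This is the area-normalised
2-D kernel; without it the carrying capacity would scale as
``1/sigma_c**2``, which is inconsistent with a census equilibrium set by
``K`` alone.

Individuals are stored in columnar numpy arrays for speed; the
:class:`Individual` view exposes single rows for inspection and for the
scalar operations below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from ._kernels import grid_density_and_mates
from .rng import SIM_STREAMS, spawn_streams

__all__ = [
    "SimParams",
    "init_population",
    "Individual",
    "PopulationState",
    "local_density",
    "survival_probability",
    "choose_mate",
    "reproduce",
    "step",
    "run_spatial_epoch",
    "effective_sigma",
    "inbreeding_Ne",
    "expected_natal_displacement_sq",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def _gauss(x: np.ndarray | float) -> np.ndarray | float:
    """Standard normal density."""
    return np.exp(-0.5 * np.asarray(x, dtype=float) ** 2) / _SQRT_2PI


@dataclass
class SimParams:
    """All knobs of the spatial model.

    Distances are in habitat units; one time step is one generation of the
    reproduction/mortality cycle (generations overlap).

    Parameters
    ----------
    sigma_f
        SD of the per-axis Gaussian natal dispersal kernel.
    sigma_m
        SD of the Gaussian mate-choice kernel (cutoff ``3*sigma_m``).
    sigma_c
        SD of the Gaussian competition kernel (cutoff ``3*sigma_c``).
    K
        Carrying-capacity-per-area parameter.
    L
        Mean-lifetime parameter; brood sizes are Poisson(1/L).
    W
        Habitat width; the habitat is the square ``[0, W]^2``.
    habitat_mask
        Optional vectorised predicate ``mask(x, y) -> bool array`` carving a
        non-rectangular habitat out of the square.
    T_spatial
        Number of spatially explicit time steps to run.
    genome_length, recomb_rate
        Genome model carried along for the ancestry stage.
    seed
        Root seed for the simulator's independent random streams.
    """

    sigma_f: float
    sigma_m: float
    sigma_c: float
    K: float
    W: float
    T_spatial: int
    L: float = 4.0
    habitat_mask: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    genome_length: float = 1e8
    recomb_rate: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_f", "sigma_m", "sigma_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if not self.L >= 1:
            raise ValueError("L must be >= 1")
        if not self.W > 0:
            raise ValueError("W must be > 0")
        if not self.T_spatial >= 0:
            raise ValueError("T_spatial must be >= 0")


@dataclass
class Individual:
    """Read-only row view of one individual."""

    id: int
    location: tuple[float, float]
    age: int
    mother_id: int
    father_id: int
    natal_displacement_sq: float
    offspring_count: int
    alive: bool


class PopulationState:
    """Columnar store of every individual ever alive, plus recorders.

    Attributes
    ----------
    x, y : positions at birth (individuals do not move after dispersal).
    birth_step, death_step : step indices; ``death_step == -1`` while alive.
    mother, father : parent row indices, ``-1`` for founders.
    natal_d2 : mean squared per-axis displacement to the parents (NaN for
        founders), averaged over both parents and both axes.
    f : lifetime offspring count (as mother or father).
    census_trace : census (post-step) per step, length ``time + 1`` counting
        the initial state.
    nei_trace : per-step inbreeding effective size (NaN when undefined).
    """

    def __init__(self, params: SimParams):
        self.params = params
        n0 = 0
        self.x = np.empty(n0)
        self.y = np.empty(n0)
        self.birth_step = np.empty(n0, dtype=np.int32)
        self.death_step = np.empty(n0, dtype=np.int32)
        self.mother = np.empty(n0, dtype=np.int64)
        self.father = np.empty(n0, dtype=np.int64)
        self.natal_d2 = np.empty(n0)
        self.f = np.empty(n0, dtype=np.int64)
        self.alive = np.empty(n0, dtype=bool)
        self.time = 0
        self.census_trace: list[int] = []
        self.nei_trace: list[float] = []
        self.extinct_at: Optional[int] = None
        self.streams = spawn_streams(params.seed, SIM_STREAMS)

    # -- bookkeeping ---------------------------------------------------
    @property
    def size(self) -> int:
        return self.x.shape[0]

    @property
    def alive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    @property
    def census(self) -> int:
        return int(self.alive.sum())

    @property
    def dispersal_sum_d2f(self) -> float:
        """Running sum of d_i^2 * f_i over individuals with known parents."""
        ok = ~np.isnan(self.natal_d2)
        return float(np.sum(self.natal_d2[ok] * self.f[ok]))

    @property
    def dispersal_sum_f(self) -> float:
        """Running sum of f_i over individuals with known parents."""
        ok = ~np.isnan(self.natal_d2)
        return float(self.f[ok].sum())

    def individual(self, i: int) -> Individual:
        return Individual(
            id=int(i),
            location=(float(self.x[i]), float(self.y[i])),
            age=int((self.time if self.alive[i] else self.death_step[i]) - self.birth_step[i]),
            mother_id=int(self.mother[i]),
            father_id=int(self.father[i]),
            natal_displacement_sq=float(self.natal_d2[i]),
            offspring_count=int(self.f[i]),
            alive=bool(self.alive[i]),
        )

    def _append(self, x, y, birth, mother, father, natal_d2) -> np.ndarray:
        n_new = len(x)
        start = self.size
        self.x = np.concatenate([self.x, x])
        self.y = np.concatenate([self.y, y])
        self.birth_step = np.concatenate([self.birth_step, np.full(n_new, birth, dtype=np.int32)])
        self.death_step = np.concatenate([self.death_step, np.full(n_new, -1, dtype=np.int32)])
        self.mother = np.concatenate([self.mother, np.asarray(mother, dtype=np.int64)])
        self.father = np.concatenate([self.father, np.asarray(father, dtype=np.int64)])
        self.natal_d2 = np.concatenate([self.natal_d2, natal_d2])
        self.f = np.concatenate([self.f, np.zeros(n_new, dtype=np.int64)])
        self.alive = np.concatenate([self.alive, np.ones(n_new, dtype=bool)])
        return np.arange(start, start + n_new)

    def in_habitat(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        W = self.params.W
        ok = (x >= 0) & (x <= W) & (y >= 0) & (y <= W)
        if self.params.habitat_mask is not None:
            ok &= np.asarray(self.params.habitat_mask(x, y), dtype=bool)
        return ok


def init_population(params: SimParams, n0: Optional[int] = None,
                    founders: Optional[tuple[np.ndarray, np.ndarray]] = None) -> PopulationState:
    """Create a population of founders distributed uniformly on the habitat.

    Founders have no recorded parents and do not contribute to the effective
    dispersal accumulators.
    """
    pop = PopulationState(params)
    rng = pop.streams["placement"]
    if founders is not None:
        fx, fy = np.asarray(founders[0], float), np.asarray(founders[1], float)
    else:
        if n0 is None:
            n0 = max(2, int(round(params.K * params.W**2)))
        fx = np.empty(0)
        fy = np.empty(0)
        # rejection-sample against the optional mask
        while fx.size < n0:
            cx = rng.uniform(0, params.W, size=n0 - fx.size)
            cy = rng.uniform(0, params.W, size=n0 - fx.size)
            ok = pop.in_habitat(cx, cy)
            fx = np.concatenate([fx, cx[ok]])
            fy = np.concatenate([fy, cy[ok]])
    pop._append(fx, fy, 0, np.full(fx.size, -1), np.full(fx.size, -1),
                np.full(fx.size, np.nan))
    pop.census_trace.append(pop.census)
    return pop


# -- scalar operations (contracts; the step uses vectorised equivalents) ---

def local_density(pop: PopulationState, focal: Individual | int, sigma_c: float) -> float:
    """Gaussian-kernel local density around ``focal``.

    ``n_i = sum_{j != i, d_ij <= 3 sigma_c} g(d_ij / sigma_c)`` with ``g``
    the standard normal density; the focal individual is excluded and an
    empty neighbourhood gives 0.
    """
    i = focal.id if isinstance(focal, Individual) else int(focal)
    idx = pop.alive_indices
    idx = idx[idx != i]
    if idx.size == 0:
        return 0.0
    d = np.hypot(pop.x[idx] - pop.x[i], pop.y[idx] - pop.y[i])
    d = d[d <= 3 * sigma_c]
    return float(np.sum(_gauss(d / sigma_c)))


def survival_probability(n_i: float, K: float, L: float,
                         edge_distance: float, sigma_c: float) -> float:
    """Density-dependent survival probability with edge penalty.

    ``min(0.95, 1/(1 + n_i/(K(1+L))))`` multiplied by
    ``min(1, sqrt(edge_distance/sigma_c))``.  Never exceeds 0.95.
    """
    if n_i < 0:
        raise ValueError("n_i must be nonnegative")
    if not K > 0 or not L >= 1:
        raise ValueError("require K > 0 and L >= 1")
    base = min(0.95, 1.0 / (1.0 + n_i / (K * (1.0 + L))))
    edge_factor = min(1.0, float(np.sqrt(max(edge_distance, 0.0) / sigma_c)))
    return base * edge_factor


def choose_mate(pop: PopulationState, focal: Individual | int, sigma_m: float,
                rng: np.random.Generator) -> Optional[Individual]:
    """Sample a mate within ``3*sigma_m``, weight ``g(d/sigma_m)``; selfing
    excluded.  Returns ``None`` when no candidate is in range."""
    i = focal.id if isinstance(focal, Individual) else int(focal)
    idx = pop.alive_indices
    idx = idx[idx != i]
    if idx.size == 0:
        return None
    d = np.hypot(pop.x[idx] - pop.x[i], pop.y[idx] - pop.y[i])
    inside = d <= 3 * sigma_m
    idx, d = idx[inside], d[inside]
    if idx.size == 0:
        return None
    w = _gauss(d / sigma_m)
    j = rng.choice(idx, p=w / w.sum())
    return pop.individual(int(j))


def reproduce(pop: PopulationState, mother: Individual | int, father: Individual | int,
              params: SimParams, rng: np.random.Generator) -> list[int]:
    """One mating: Poisson(1/L) offspring dispersed from the mother.

    Offspring proposed outside the habitat are discarded without
    replacement.  Returns the row indices of the offspring actually born;
    pedigree links, natal displacements and parental ``f`` counts are
    recorded.
    """
    mi = mother.id if isinstance(mother, Individual) else int(mother)
    fi = father.id if isinstance(father, Individual) else int(father)
    if mi == fi:
        raise ValueError("selfing is not allowed")
    count = rng.poisson(1.0 / params.L)
    if count == 0:
        return []
    dx = rng.normal(0.0, params.sigma_f, size=count)
    dy = rng.normal(0.0, params.sigma_f, size=count)
    cx, cy = pop.x[mi] + dx, pop.y[mi] + dy
    ok = pop.in_habitat(cx, cy)
    cx, cy = cx[ok], cy[ok]
    if cx.size == 0:
        return []
    d2 = _natal_d2(cx, cy, pop.x[mi], pop.y[mi], pop.x[fi], pop.y[fi])
    new = pop._append(cx, cy, pop.time + 1, np.full(cx.size, mi), np.full(cx.size, fi), d2)
    pop.f[mi] += cx.size
    pop.f[fi] += cx.size
    return list(new)


def _natal_d2(cx, cy, mx, my, fx, fy):
    # mean over the two parents and the two axes of the squared displacement
    return ((cx - mx) ** 2 + (cy - my) ** 2 + (cx - fx) ** 2 + (cy - fy) ** 2) / 4.0


def _edge_distance(x: np.ndarray, y: np.ndarray, W: float) -> np.ndarray:
    return np.minimum(np.minimum(x, W - x), np.minimum(y, W - y))


def step(pop: PopulationState, params: Optional[SimParams] = None,
         rng: Optional[dict[str, np.random.Generator]] = None) -> PopulationState:
    """Advance the population one time step in place (and return it).

    Reproduction (using start-of-step positions, mate pools and densities)
    precedes mortality; newborns join the population at the end of the step
    and are excluded from this step's mating, competition, and mortality.
    Extinction leaves ``pop.extinct_at`` set instead of raising.
    """
    params = params or pop.params
    rng = rng or pop.streams
    idx = pop.alive_indices
    if idx.size == 0:
        raise ValueError("step() requires a nonempty population")
    ax, ay = pop.x[idx], pop.y[idx]
    n_adults = idx.size

    # --- reproduction (start-of-step positions, mate pools, densities) ---
    counts = rng["counts"].poisson(1.0 / params.L, size=n_adults)
    u = rng["mating"].uniform(size=n_adults)
    dens_raw, mate = grid_density_and_mates(ax, ay, params.W, params.sigma_c,
                                            params.sigma_m, counts > 0, u)
    # area-normalised density fed to the survival rule (see module docstring)
    n_used = dens_raw / (2.0 * np.pi * params.sigma_c**2)

    mothers_local = np.flatnonzero((counts > 0) & (mate >= 0))
    fathers_local = mate[mothers_local]
    brood = counts[mothers_local]
    mom_rows = np.repeat(idx[mothers_local], brood)
    dad_rows = np.repeat(idx[fathers_local], brood)
    n_births = mom_rows.size
    if n_births:
        disp = rng["dispersal"].normal(0.0, params.sigma_f, size=(n_births, 2))
        cx = pop.x[mom_rows] + disp[:, 0]
        cy = pop.y[mom_rows] + disp[:, 1]
        ok = pop.in_habitat(cx, cy)
        cx, cy, mom_rows, dad_rows = cx[ok], cy[ok], mom_rows[ok], dad_rows[ok]
    if mom_rows.size:
        d2 = _natal_d2(cx, cy, pop.x[mom_rows], pop.y[mom_rows],
                       pop.x[dad_rows], pop.y[dad_rows])
        new = pop._append(cx, cy, pop.time + 1, mom_rows, dad_rows, d2)
        np.add.at(pop.f, mom_rows, 1)
        np.add.at(pop.f, dad_rows, 1)
    else:
        new = np.empty(0, dtype=np.int64)

    # --- mortality (start-of-step densities; newborns exempt this step) ---
    base = np.minimum(0.95, 1.0 / (1.0 + n_used / (params.K * (1.0 + params.L))))
    edge = _edge_distance(ax, ay, params.W)
    p_surv = base * np.minimum(1.0, np.sqrt(edge / params.sigma_c))
    died = rng["survival"].uniform(size=n_adults) >= p_surv
    dead_rows = idx[died]
    pop.alive[dead_rows] = False
    pop.death_step[dead_rows] = pop.time + 1

    # --- recorders ---
    if dead_rows.size:
        nei = _inbreeding_ne_or_nan(n_adults, pop.f[dead_rows])
    else:
        nei = np.nan
    pop.nei_trace.append(nei)
    pop.time += 1
    pop.census_trace.append(pop.census)
    if pop.census == 0:
        pop.extinct_at = pop.time
    return pop


def run_spatial_epoch(params: SimParams,
                      founders: Optional[tuple[np.ndarray, np.ndarray]] = None,
                      n0: Optional[int] = None) -> PopulationState:
    """Run ``T_spatial`` steps from uniform-random (or supplied) founders.

    Returns the final state with full pedigree and recorder data.  If the
    population goes extinct the state is returned immediately with
    ``extinct_at`` set to the fatal step index.
    """
    pop = init_population(params, n0=n0, founders=founders)
    for _ in range(params.T_spatial):
        step(pop)
        if pop.extinct_at is not None:
            break
    return pop


def effective_sigma(pop: PopulationState) -> float:
    """Tracked effective dispersal distance.

    ``sqrt( sum_i d_i^2 f_i / sum_i f_i )`` over all individuals ever alive
    with recorded parents (founders have no natal displacement and are
    excluded from both sums).
    """
    sum_f = pop.dispersal_sum_f
    if sum_f <= 0:
        raise ValueError("effective sigma undefined: no weighted births")
    return float(np.sqrt(pop.dispersal_sum_d2f / sum_f))


def effective_sigma_se(pop: PopulationState) -> float:
    """Approximate Monte-Carlo standard error of :func:`effective_sigma`.

    Delta-method SE of the f-weighted mean of d^2 (effective sample size
    ``(sum f)^2 / sum f^2``), propagated through the square root.
    """
    ok = ~np.isnan(pop.natal_d2)
    f = pop.f[ok].astype(float)
    d2 = pop.natal_d2[ok]
    sf = f.sum()
    if sf <= 0:
        raise ValueError("no weighted births")
    mean = np.sum(d2 * f) / sf
    var = np.sum(f * (d2 - mean) ** 2) / sf
    n_eff = sf**2 / np.sum(f**2)
    se_mean = np.sqrt(var / n_eff)
    return float(se_mean / (2.0 * np.sqrt(mean)))


def expected_natal_displacement_sq(sigma_f: float, sigma_m: float) -> float:
    """Expected squared per-axis child-to-random-parent displacement.

    The mother contributes ``sigma_f^2`` and the father
    ``sigma_f^2 + sigma_m^2``; averaging over the two parents gives
    ``sigma_f^2 + sigma_m^2/2`` — equal to ``(3/2) sigma_f^2`` when
    ``sigma_f == sigma_m``.
    """
    return sigma_f**2 + 0.5 * sigma_m**2


def inbreeding_Ne(N: int, k_values: Sequence[float] | np.ndarray) -> float:
    """Inbreeding effective size from census size and offspring counts.

    ``NeI = (N*kbar - 2) / (kbar - 1 + Vk/kbar)`` where ``kbar`` and ``Vk``
    are the mean and variance of the lifetime offspring counts ``k_values``
    (here: of individuals dying in the current cycle).
    """
    k = np.asarray(k_values, dtype=float)
    kbar = k.mean() if k.size else 0.0
    if kbar <= 0:
        raise ValueError("inbreeding Ne undefined: mean offspring count <= 0")
    vk = k.var()
    denom = kbar - 1.0 + vk / kbar
    if denom <= 0:
        raise ValueError("inbreeding Ne undefined: nonpositive denominator")
    return float((N * kbar - 2.0) / denom)


def _inbreeding_ne_or_nan(N: int, k_values: np.ndarray) -> float:
    try:
        return inbreeding_Ne(N, k_values)
    except ValueError:
        return np.nan


def mean_inbreeding_Ne(pop: PopulationState) -> float:
    """Per-step mean of the recorded inbreeding effective sizes."""
    trace = np.asarray(pop.nei_trace, dtype=float)
    trace = trace[~np.isnan(trace)]
    if trace.size == 0:
        raise ValueError("no defined per-step Ne values recorded")
    return float(trace.mean())
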