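"""Free-parameter optimization: dL fitness, brute-force grids, and the GA.

The four free parameters (D, Y_s, Y_a, A) are fitted against per-region
target traces by minimizing dL, the sum of absolute differences between the
target and the simulated activities over a 120-s window sampled at 0.1 s
(1201 samples) in all three regions.  Both sides are min-max scaled to
[0, 1] per region before comparison, so only the response shape matters.

Two optimizers are provided: an exhaustive brute-force (BF) sweep of a
discretized grid, and a binary-encoded genetic algorithm (GA) with
single-point crossover, bit-flip mutation and elitist truncation survival.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, GenomeError, GridOverflowError
from .model import (DEFAULT_MAX_STEP, DEFAULT_TOL, IntegrationPlan,
                    ModelParameters, SimulatedTraces, integrate_plan)
from .stimulus import StimulusProtocol

__all__ = [
    "FITNESS_DT", "FITNESS_HORIZON", "FITNESS_SAMPLES",
    "TargetTraces", "GridSpec", "GAConfig", "FitResult",
    "fitness_dL", "enumerate_grid", "grid_size", "brute_force_search",
    "pilot_screen", "decode_genome", "ga_optimize", "summarize_runs",
]

logger = logging.getLogger(__name__)

#: The fitness window: 120 s sampled every 0.1 s, endpoints inclusive.
FITNESS_DT = 0.1
FITNESS_HORIZON = 120.0
FITNESS_SAMPLES = 1201

FREE_PARAMS = ("D", "Y_s", "Y_a", "A")

_GRID_TOL = 1e-9


def minmax_unit(values: np.ndarray) -> np.ndarray:
    """Linear scaling to [0, 1]; an exactly constant trace maps to zeros."""
    values = np.asarray(values, dtype=float)
    lo = values.min()
    span = values.max() - lo
    if span == 0.0:
        return np.zeros_like(values)
    return (values - lo) / span


@dataclass(frozen=True)
class TargetTraces:
    """Per-region target activities sampled on the fitness grid.

    ``provenance`` records whether the traces came from measured imaging or
    from the synthetic-data generator.
    """

    time: np.ndarray
    f_d: np.ndarray
    f_s: np.ndarray
    f_a: np.ndarray
    provenance: str = "synthetic"

    def stacked(self) -> np.ndarray:
        return np.vstack([self.f_d, self.f_s, self.f_a])

    def scaled(self) -> "TargetTraces":
        """Min-max scale each region to [0, 1] (the form dL compares)."""
        return TargetTraces(self.time, minmax_unit(self.f_d),
                            minmax_unit(self.f_s), minmax_unit(self.f_a),
                            provenance=self.provenance)

    @classmethod
    def from_simulated(cls, traces: SimulatedTraces,
                       provenance: str = "synthetic") -> "TargetTraces":
        return cls(traces.time.copy(), traces.x_d.copy(), traces.x_s.copy(),
                   traces.x_a.copy(), provenance=provenance)


def _check_aligned(t1: np.ndarray, t2: np.ndarray):
    if t1.shape != t2.shape or not np.allclose(t1, t2, atol=1e-9, rtol=0):
        raise AlignmentError("target and simulated traces are on different grids")


def fitness_dL(target: TargetTraces, simulated: SimulatedTraces | TargetTraces) -> float:
    """Sum of absolute per-sample differences over the three regions.

    Both trace sets must already be on the same grid and scaled to [0, 1];
    on the default fitness grid (0..120 s at 0.1 s) the sum runs over
    3 x 1201 terms.  dL = 0 iff the traces agree at every sample.
    """
    sim = simulated.stacked()
    tgt = target.stacked()
    _check_aligned(target.time, simulated.time)
    return float(np.abs(tgt - sim).sum())


@dataclass(frozen=True)
class GridSpec:
    """Per-parameter ranges and steps of the brute-force search grid.

    The default grid is D in [0, 10] step 0.1, Y_s and Y_a in [-1, 1] step
    0.1, A in [0, 0.3] step 0.01.  Under the default half-open endpoint
    convention each axis contributes round((hi-lo)/step) points (the upper
    endpoint is excluded), giving 100*20*20*30 = 1,200,000 combinations.
    """

    D: tuple[float, float, float] = (0.0, 10.0, 0.1)
    Y_s: tuple[float, float, float] = (-1.0, 1.0, 0.1)
    Y_a: tuple[float, float, float] = (-1.0, 1.0, 0.1)
    A: tuple[float, float, float] = (0.0, 0.3, 0.01)
    endpoint: str = "half-open"  # or "inclusive"

    def __post_init__(self):
        for name in FREE_PARAMS:
            lo, hi, step = getattr(self, name)
            if step <= 0 or hi <= lo:
                raise GridOverflowError(f"invalid range for {name}: {lo, hi, step}")
        if self.endpoint not in ("half-open", "inclusive"):
            raise GridOverflowError(f"unknown endpoint convention {self.endpoint!r}")

    def axis_values(self, name: str) -> np.ndarray:
        lo, hi, step = getattr(self, name)
        n = int(round((hi - lo) / step))
        if self.endpoint == "inclusive":
            n += 1
        return lo + step * np.arange(n)

    def bounds(self, name: str) -> tuple[float, float]:
        lo, hi, _ = getattr(self, name)
        return lo, hi

    def snap(self, values: tuple) -> tuple:
        """Round a (D, Y_s, Y_a, A) tuple to the nearest grid step per axis."""
        out = []
        for name, v in zip(FREE_PARAMS, values):
            lo, _, step = getattr(self, name)
            out.append(lo + step * round((v - lo) / step))
        return tuple(out)

    @property
    def size(self) -> int:
        n = 1
        for name in FREE_PARAMS:
            n *= self.axis_values(name).size
        return n

    @classmethod
    def pilot(cls) -> "GridSpec":
        """The wide pilot-screen grid: D[0,50], Y_s/Y_a[-10,10], A[0,10].

        Per-axis resolutions (200, 20, 20, 100 points) make the half-open
        product 8,000,000 combinations.
        """
        return cls(D=(0.0, 50.0, 0.25), Y_s=(-10.0, 10.0, 1.0),
                   Y_a=(-10.0, 10.0, 1.0), A=(0.0, 10.0, 0.1))


def grid_size(spec: GridSpec) -> int:
    return spec.size


def enumerate_grid(spec: GridSpec, cap: int | None = 10_000_000):
    """Yield (D, Y_s, Y_a, A) tuples in lexicographic axis order.

    Raises :class:`GridOverflowError` if the grid exceeds ``cap`` points.
    """
    if cap is not None and spec.size > cap:
        raise GridOverflowError(f"grid has {spec.size} points, cap is {cap}")
    axes = [spec.axis_values(name) for name in FREE_PARAMS]
    return itertools.product(*axes)


@dataclass(frozen=True)
class FitResult:
    """One scored parameter combination, with its origin."""

    params: dict
    dL: float
    provenance: str

    def as_tuple(self) -> tuple:
        return tuple(self.params[name] for name in FREE_PARAMS)


class _Scorer:
    """Simulate-and-score closure shared by BF and GA.

    The integration plan is built once; every call integrates the model at
    the given free parameters, min-max scales each simulated region and
    returns dL against the (pre-scaled) target.  Integration failures score
    +inf so a single stiff grid point cannot abort a sweep.
    """

    def __init__(self, target: TargetTraces, protocol: StimulusProtocol,
                 base_params: ModelParameters | None = None,
                 tol: float = DEFAULT_TOL, max_step: float = DEFAULT_MAX_STEP):
        self.base = base_params or ModelParameters()
        dt = float(target.time[1] - target.time[0])
        self.plan = IntegrationPlan(protocol, t_end=float(target.time[-1]), dt_out=dt)
        _check_aligned(target.time, self.plan.sample_times)
        self.target = target.scaled().stacked()
        self.tol = tol
        self.max_step = max_step
        self.n_evaluations = 0

    def __call__(self, D: float, Y_s: float, Y_a: float, A: float) -> float:
        self.n_evaluations += 1
        try:
            out = integrate_plan(self.plan, self.base.with_free(D, Y_s, Y_a, A),
                                 tol=self.tol, max_step=self.max_step)
        except Exception:  # scored as unusable, sweep continues
            logger.warning("integration failed at D=%g Y_s=%g Y_a=%g A=%g",
                           D, Y_s, Y_a, A)
            return float("inf")
        sim = out[:, :3].T
        total = 0.0
        for r in range(3):
            total += float(np.abs(self.target[r] - minmax_unit(sim[r])).sum())
        return total


def _param_frame(results: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([r.params for r in results])


def _mean_sd(frame: pd.DataFrame) -> pd.DataFrame:
    mean = frame.mean()
    sd = frame.std(ddof=1).fillna(0.0) if len(frame) > 1 else mean * 0.0
    return pd.DataFrame({"mean": mean, "sd": sd})


@dataclass
class BruteForceResult:
    """Full ranking plus the best-100 / worst-100 parameter summaries."""

    ranking: list[FitResult]
    best_summary: pd.DataFrame
    worst_summary: pd.DataFrame
    n_evaluations: int

    @property
    def best(self) -> FitResult:
        return self.ranking[0]


def brute_force_search(spec: GridSpec, target: TargetTraces,
                       protocol: StimulusProtocol,
                       base_params: ModelParameters | None = None,
                       summary_n: int = 100, cap: int | None = 200_000,
                       ) -> BruteForceResult:
    """Score every grid point and rank by dL (ascending, ties stable).

    Returns the full ranking and mean +/- sample-SD of each parameter over
    the ``summary_n`` best and worst combinations.  ``cap`` guards against
    accidentally launching a multi-hour sweep; raise it deliberately for
    full-scale grids.
    """
    score = _Scorer(target, protocol, base_params)
    results = [
        FitResult({name: v for name, v in zip(FREE_PARAMS, combo)},
                  score(*combo), provenance=f"bf:{i}")
        for i, combo in enumerate(enumerate_grid(spec, cap=cap))
    ]
    ranking = sorted(results, key=lambda r: r.dL)
    k = min(summary_n, len(ranking))
    return BruteForceResult(
        ranking=ranking,
        best_summary=_mean_sd(_param_frame(ranking[:k])),
        worst_summary=_mean_sd(_param_frame(ranking[-k:])),
        n_evaluations=score.n_evaluations)


def pilot_screen(spec: GridSpec, target: TargetTraces,
                 protocol: StimulusProtocol, dL_threshold: float = 800.0,
                 base_params: ModelParameters | None = None,
                 cap: int | None = 200_000) -> dict:
    """Histogram, per parameter, of grid combinations with dL below threshold.

    Used to justify the narrower production search ranges: for each free
    parameter the counts of passing combinations per axis value show where
    good fits concentrate.
    """
    score = _Scorer(target, protocol, base_params)
    counts = {name: dict.fromkeys(np.round(spec.axis_values(name), 12), 0)
              for name in FREE_PARAMS}
    n_pass = 0
    for combo in enumerate_grid(spec, cap=cap):
        if score(*combo) < dL_threshold:
            n_pass += 1
            for name, v in zip(FREE_PARAMS, combo):
                counts[name][round(v, 12)] += 1
    return {
        "n_passing": n_pass,
        "histograms": {
            name: (np.array(list(c.keys())), np.array(list(c.values())))
            for name, c in counts.items()},
    }


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the published configuration: 100 individuals of 8 bits
    per parameter (32-bit genomes), single-point crossover with probability
    0.6, per-bit mutation probability 0.01, 500 generations, 18 repeats.

    ``restart_stall`` re-randomizes the population whenever the best-ever
    fitness has not improved for that many generations (the best-ever
    individual is kept aside as the running result); restarts let a run
    sample several convergence basins of the strongly correlated (D, Y_s,
    Y_a) fitness ridge instead of spending its whole budget in the first
    one.  ``snap_to_grid`` evaluates decoded genomes after rounding each
    parameter to its grid step, so converged runs report values on the same
    lattice as the brute-force search.  ``stall_generations`` optionally
    stops a run early once the best-ever fitness has not improved for that
    many consecutive generations (counted across restarts).
    """

    population: int = 100
    bits_per_param: int = 8
    p_crossover: float = 0.6
    p_mutation: float = 0.01
    generations: int = 500
    repeats: int = 18
    seed: int = 0
    stall_generations: int | None = None
    restart_stall: int | None = 40
    snap_to_grid: bool = True

    def __post_init__(self):
        if self.population < 2 or self.population % 2:
            raise GenomeError("population must be even and >= 2")
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise GenomeError("probabilities must lie in [0, 1]")

    @property
    def genome_length(self) -> int:
        return 4 * self.bits_per_param

    @property
    def total_evaluations(self) -> int:
        """Fitness evaluations in one full run (population x generations)."""
        return self.population * self.generations


def decode_genome(bits, spec: GridSpec, bits_per_param: int = 8) -> tuple:
    """Decode a binary genome into (D, Y_s, Y_a, A).

    Each ``bits_per_param``-wide field is read MSB-first as an integer k and
    mapped linearly onto its full search range: lo + k/(2^b - 1) * (hi - lo),
    so the all-zero and all-one genomes sit exactly at the range bounds.
    """
    if isinstance(bits, str):
        if set(bits) - {"0", "1"}:
            raise GenomeError("genome string must be binary")
        bits = np.fromiter((int(b) for b in bits), dtype=np.uint8)
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size != 4 * bits_per_param:
        raise GenomeError(
            f"genome must have {4 * bits_per_param} bits, got {bits.size}")
    levels = (1 << bits_per_param) - 1
    weights = 1 << np.arange(bits_per_param - 1, -1, -1)
    out = []
    for i, name in enumerate(FREE_PARAMS):
        field_bits = bits[i * bits_per_param:(i + 1) * bits_per_param]
        k = int(field_bits @ weights)
        lo, hi = spec.bounds(name)
        out.append(lo + k / levels * (hi - lo))
    return tuple(out)


@dataclass
class GAResult:
    """Best-ever individual of one GA run plus the fitness trajectory."""

    best: FitResult
    trajectory: np.ndarray  # best-so-far dL after each generation
    mean_trajectory: np.ndarray  # population-mean dL per generation
    n_evaluations: int
    generations_run: int
    seed: int


def ga_optimize(config: GAConfig, spec: GridSpec, target: TargetTraces,
                protocol: StimulusProtocol,
                base_params: ModelParameters | None = None) -> GAResult:
    """Run one seeded genetic-algorithm optimization.

    Each generation scores ``population`` candidates, so a full default run
    evaluates 100 x 500 = 50,000.  Generation 1 scores the random initial
    population.  An ordinary generation forms population/2 random parent
    pairs, applies single-point crossover with probability ``p_crossover``
    (cut drawn uniformly over the interior positions; first child = first
    parent's head + second parent's tail, and vice versa), flips each
    offspring bit with probability ``p_mutation``, scores the offspring, and
    keeps the best ``population`` of parents plus offspring (elitist
    truncation).  When the best-ever fitness stagnates for ``restart_stall``
    generations the next generation instead scores a fresh random population
    (the best-ever individual is retained as the running result, so the
    best-so-far trajectory never increases).  All randomness comes from a
    Mersenne-Twister generator seeded from ``config.seed``.
    """
    rng = np.random.RandomState(config.seed)
    score = _Scorer(target, protocol, base_params)
    n, L = config.population, config.genome_length

    def evaluate(g):
        params = decode_genome(g, spec, config.bits_per_param)
        if config.snap_to_grid:
            params = spec.snap(params)
        return score(*params)

    pop = rng.randint(0, 2, size=(n, L)).astype(np.uint8)
    fitness = np.array([evaluate(g) for g in pop])
    i0 = int(np.argmin(fitness))
    best_genome, best_fit = pop[i0].copy(), float(fitness[i0])
    best_traj = [best_fit]
    mean_traj = [fitness.mean()]
    stall = 0           # generations since the best-ever fitness improved
    restart_timer = 0   # like stall, but reset at each restart
    generations_run = 1

    while generations_run < config.generations:
        if (config.restart_stall is not None
                and restart_timer >= config.restart_stall):
            pop = rng.randint(0, 2, size=(n, L)).astype(np.uint8)
            fitness = np.array([evaluate(g) for g in pop])
            restart_timer = 0
        else:
            offspring = np.empty_like(pop)
            for p in range(0, n, 2):
                i, j = rng.choice(n, size=2, replace=False)
                a, b = pop[i].copy(), pop[j].copy()
                if rng.random_sample() < config.p_crossover:
                    cut = rng.randint(1, L)  # L-1 interior cut positions
                    a[cut:], b[cut:] = pop[j][cut:], pop[i][cut:]
                offspring[p], offspring[p + 1] = a, b
            flip = rng.random_sample(offspring.shape) < config.p_mutation
            offspring ^= flip.astype(np.uint8)
            off_fitness = np.array([evaluate(g) for g in offspring])
            combined = np.vstack([pop, offspring])
            combined_fit = np.concatenate([fitness, off_fitness])
            keep = np.argsort(combined_fit, kind="stable")[:n]
            pop, fitness = combined[keep], combined_fit[keep]
            if np.ptp(fitness) == 0.0:
                logger.info("GA population degenerate (zero fitness variance)")

        generations_run += 1
        i0 = int(np.argmin(fitness))
        if fitness[i0] < best_fit - 1e-12:
            best_fit = float(fitness[i0])
            best_genome = pop[i0].copy()
            stall = 0
            restart_timer = 0
        else:
            stall += 1
            restart_timer += 1
        best_traj.append(best_fit)
        mean_traj.append(fitness.mean())
        if (config.stall_generations is not None
                and stall >= config.stall_generations):
            break

    params = decode_genome(best_genome, spec, config.bits_per_param)
    if config.snap_to_grid:
        params = spec.snap(params)
    best = FitResult(dict(zip(FREE_PARAMS, params)), best_fit,
                     provenance=f"ga:seed={config.seed},gen={generations_run},"
                                f"bits={''.join(map(str, best_genome))}")
    return GAResult(best=best, trajectory=np.array(best_traj),
                    mean_trajectory=np.array(mean_traj),
                    n_evaluations=score.n_evaluations,
                    generations_run=generations_run, seed=config.seed)


def summarize_runs(results: list[FitResult]) -> pd.DataFrame:
    """Mean and sample SD of each free parameter over a set of fit results."""
    if not results:
        raise ValueError("need at least one fit result")
    frame = _param_frame(results)
    frame["dL"] = [r.dL for r in results]
    return _mean_sd(frame)
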