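"""Evolutionary search over demographic models (invasive-weed style).

Each candidate model is scored by simulating data under it and comparing
the simulation's fourfold joint SFS to the observed one through the
standardized squared error.  Candidates reproduce in inverse proportion
to their error — the best model leaves ``s_max`` (default 8) mutated
offspring, the worst ``s_min`` (default 2) — the pooled parents and
children are ranked, and the population is truncated back to its
original size (elitism: the best model always survives, so the best
error never increases).

Variation is mutation-only: event times move log-uniformly strictly
within the bracket set by neighbouring events in the model's partial
order, sizes and rates are jittered multiplicatively, and non-split
events may be added or removed.  The order and identity of the soft
splits — the topology — is never altered; topology competition happens
only through a mixed initial population, so the only inputs to the
search are the candidate topologies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .demography import (
    AdmixturePulse,
    DemeCountChange,
    DemographicModel,
    MigrationRateChange,
    NeChange,
    SoftSplit,
    is_valid,
)
from .sfs_stats import (
    JointSFS4,
    SigmaVector,
    compute_summary,
    fitness,
    normalize_sfs,
)
from .simulate import GenomeSpec, sim_to_counts2, simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_MUTATION_RATES = {
    "time": 0.6,
    "ne": 0.6,
    "admixture": 0.3,
    "migration": 0.4,
    "add_event": 0.15,
    "remove_event": 0.15,
}


@dataclass
class Candidate:
    model: DemographicModel
    fitness: float | None = None
    parent_id: int | None = None
    created_at: int = 0
    id: int = 0
    flagged: bool = False


@dataclass
class EngineConfig:
    population_size: int = 20
    iterations: int = 200
    s_min: int = 2
    s_max: int = 8
    mutation_rates: dict = field(default_factory=lambda: dict(DEFAULT_MUTATION_RATES))
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    n_eval_replicates: int = 1
    normalization: str = "per_quadruple"
    plateau_window: int = 0  # 0 disables early stopping
    plateau_tol: float = 0.0
    # Evaluate every candidate in a run on one shared simulation seed
    # (common random numbers): fitness differences then reflect model
    # differences rather than simulation noise, which matters at the
    # small genome sizes used for desk-scale search.
    paired_evaluation: bool = True

    def __post_init__(self):
        if not (1 <= self.s_min <= self.s_max):
            raise ValueError("need 1 <= s_min <= s_max")
        if self.iterations < 1 or self.population_size < 1:
            raise ValueError("iterations and population_size must be >= 1")


@dataclass
class RunResult:
    best: Candidate
    best_trace: list[float]
    mean_trace: list[float]
    selected_topology: str
    seed: int
    iterations_run: int


# ---- offspring allocation ---------------------------------------------------


def offspring_count(
    f: float, f_min: float, f_max: float, s_min: int = 2, s_max: int = 8
) -> int:
    """Number of offspring for a candidate with error ``f``.

    Linear and decreasing in error: the best candidate (f = f_min) gets
    ``s_max``, the worst (f = f_max) gets ``s_min``; ties in the
    degenerate all-equal population all get ``s_max``.  Rounding is
    round-half-to-even.
    """
    if not (f_min <= f <= f_max):
        raise ValueError("f outside [f_min, f_max]")
    if f_max == f_min:
        return s_max
    return int(round((s_max - s_min) * (f_max - f) / (f_max - f_min) + s_min))


# ---- mutation ---------------------------------------------------------------


def _time_bracket(model: DemographicModel, ev) -> tuple[float, float]:
    """Strict partial-order bounds for moving an event's time."""
    lo, hi = 0.0, math.inf
    if isinstance(ev, SoftSplit):
        hi = min(hi, model.origin_time(ev.parent))
        for c in (ev.child_a, ev.child_b):
            lo = max(lo, model.end_time(c))
        for other in model.events:
            if other is ev or isinstance(other, SoftSplit):
                continue
            names = (
                (other.source, other.target)
                if isinstance(other, AdmixturePulse)
                else (other.ecodeme,)
                if isinstance(other, (NeChange, DemeCountChange))
                else tuple(other.pair)
            )
            # events on the children must stay younger than the split,
            # events on the parent older
            if any(n in (ev.child_a, ev.child_b) for n in names):
                lo = max(lo, other.time)
            if ev.parent in names:
                hi = min(hi, other.time) if other.time < hi else hi
    else:
        names = (
            (ev.source, ev.target)
            if isinstance(ev, AdmixturePulse)
            else (ev.ecodeme,)
            if isinstance(ev, (NeChange, DemeCountChange))
            else tuple(ev.pair)
        )
        for n in names:
            lo = max(lo, model.end_time(n))
            hi = min(hi, model.origin_time(n))
    return lo, hi


def _draw_time(
    rng: np.random.Generator,
    lo: float,
    hi: float,
    current: float | None = None,
    local_sd: float = 0.35,
    p_local: float = 0.7,
) -> float | None:
    """Time proposal strictly inside (lo, hi).

    A mixture of a local multiplicative jitter around the current value
    (refinement) and a global log-uniform draw over the bracket
    (exploration); the pure log-uniform proposal concentrates far too
    much mass near the bracket's lower edge to refine times on the
    scale of thousands of generations.
    """
    if not math.isfinite(hi):
        base = current if current is not None else max(2 * lo, 1.0)
        hi = max(base, 1.0) * 4  # unbounded above: cap at 4x current scale
    lo_eff = max(lo, 1.0)
    if hi <= lo_eff * (1 + 1e-9):
        return None
    if current is not None and lo < current < hi and rng.random() < p_local:
        t = current * math.exp(rng.normal(0.0, local_sd))
    else:
        u = rng.uniform(0.0, 1.0)
        t = math.exp(math.log(lo_eff) + u * (math.log(hi) - math.log(lo_eff)))
    t = min(max(t, np.nextafter(lo, math.inf)), np.nextafter(hi, -math.inf))
    return float(t)


def _perturb_lognormal(rng, x, sd=0.3, lo=None, hi=None):
    y = x * math.exp(rng.normal(0.0, sd))
    if lo is not None:
        y = max(y, lo)
    if hi is not None:
        y = min(y, hi)
    return y


def _mutate_once(model: DemographicModel, rng: np.random.Generator, rates) -> DemographicModel:
    m = model.copy()
    events = list(m.events)

    if events and rng.random() < rates.get("time", 0.0):
        i = int(rng.integers(len(events)))
        ev = events[i]
        lo, hi = _time_bracket(m, ev)
        cap = rates.get("time_cap")
        if cap is not None:  # bounded search range for event times
            hi = min(hi, float(cap))
        t = _draw_time(rng, lo, hi, current=ev.time)
        if t is not None:
            if isinstance(ev, SoftSplit):
                events[i] = replace(ev, time=t, decay=replace(ev.decay, t_split=t))
            else:
                events[i] = replace(ev, time=t)
            logger.debug("mutate time %s: %.1f -> %.1f", type(ev).__name__, ev.time, t)

    m.events = events
    if rng.random() < rates.get("ne", 0.0):
        ne_targets = [("eco", i) for i in range(len(m.ecodemes))] + [
            ("ev", i) for i, ev in enumerate(m.events) if isinstance(ev, NeChange)
        ]
        kind, i = ne_targets[int(rng.integers(len(ne_targets)))]
        if kind == "eco":
            e = m.ecodemes[i]
            m.ecodemes[i] = replace(
                e, ne_per_topodeme=_perturb_lognormal(rng, e.ne_per_topodeme, lo=1.0)
            )
        else:
            ev = m.events[i]
            m.events[i] = replace(ev, new_ne=_perturb_lognormal(rng, ev.new_ne, lo=1.0))

    if rng.random() < rates.get("admixture", 0.0):
        pulses = [i for i, ev in enumerate(m.events) if isinstance(ev, AdmixturePulse)]
        if pulses:
            i = pulses[int(rng.integers(len(pulses)))]
            ev = m.events[i]
            p = min(max(_perturb_lognormal(rng, ev.proportion, sd=0.4), 1e-3), 0.999)
            m.events[i] = replace(ev, proportion=p)

    if rng.random() < rates.get("migration", 0.0):
        choice = rng.random()
        splits = [i for i, ev in enumerate(m.events) if isinstance(ev, SoftSplit)]
        if splits and choice < 0.7:
            i = splits[int(rng.integers(len(splits)))]
            ev = m.events[i]
            d = ev.decay
            which = rng.random()
            if which < 0.4:
                m_max = min(_perturb_lognormal(rng, max(d.m_max, 1e-6)), 0.5)
                d = replace(d, m_max=max(m_max, d.m_min))
            elif which < 0.7:
                m_min = min(_perturb_lognormal(rng, max(d.m_min, 1e-7)), d.m_max)
                d = replace(d, m_min=m_min if d.m_min > 0 or rng.random() < 0.5 else 0.0)
            else:
                d = replace(d, lambda_decay=_perturb_lognormal(rng, d.lambda_decay, lo=1e-3))
            m.events[i] = replace(ev, decay=d)
        else:
            if rng.random() < 0.5:
                m.internal_migration = min(
                    _perturb_lognormal(rng, max(m.internal_migration, 1e-6)), 0.5
                )
            else:
                m.inter_ecodeme_migration = min(
                    _perturb_lognormal(rng, max(m.inter_ecodeme_migration, 1e-6)), 0.5
                )

    if rng.random() < rates.get("add_event", 0.0):
        _add_random_event(m, rng)

    if rng.random() < rates.get("remove_event", 0.0):
        removable = [
            i for i, ev in enumerate(m.events) if not isinstance(ev, SoftSplit)
        ]
        if removable:
            del m.events[removable[int(rng.integers(len(removable)))]]

    return m


def _add_random_event(m: DemographicModel, rng: np.random.Generator) -> None:
    span = max(m.oldest_event_time(), 100.0)
    t = float(rng.uniform(1.0, span))
    alive = m.alive_at(t)
    if not alive:
        return
    kind = int(rng.integers(4))
    pick = lambda: alive[int(rng.integers(len(alive)))]
    if kind == 0 and len(alive) >= 2:
        a, b = rng.choice(len(alive), size=2, replace=False)
        m.events.append(
            AdmixturePulse(alive[a].name, alive[b].name, t, float(rng.uniform(0.01, 0.5)))
        )
    elif kind == 1:
        eco = pick()
        m.events.append(
            NeChange(eco.name, t, _perturb_lognormal(rng, m.ne_at(eco.name, t), sd=0.5, lo=1.0))
        )
    elif kind == 2:
        eco = pick()
        cur = m.n_topodemes_at(eco.name, t)
        new = max(1, cur + (1 if rng.random() < 0.5 else -1))
        m.events.append(DemeCountChange(eco.name, t, new))
    elif kind == 3 and len(alive) >= 2:
        a, b = rng.choice(len(alive), size=2, replace=False)
        m.events.append(
            MigrationRateChange(
                (alive[a].name, alive[b].name), t, float(rng.uniform(0, 0.01))
            )
        )


def mutate(
    model: DemographicModel,
    rng: np.random.Generator,
    rates: dict | None = None,
    max_retries: int = 20,
) -> DemographicModel:
    """Return a mutated copy that passes validation.

    Operators fire independently with their configured probabilities; if
    the mutant is invalid the draw is retried, and after ``max_retries``
    failures an unchanged copy of the parent is returned.  The split
    topology is never altered.
    """
    rates = DEFAULT_MUTATION_RATES if rates is None else rates
    if all(r == 0 for r in rates.values()):
        return model.copy()
    for _ in range(max_retries):
        m = _mutate_once(model, rng, rates)
        if is_valid(m):
            return m
    return model.copy()


# ---- evaluation -------------------------------------------------------------


def evaluate(
    model: DemographicModel,
    observed: JointSFS4,
    sigma: SigmaVector,
    genome: GenomeSpec,
    seed: int,
    n_replicates: int = 1,
) -> float:
    """Simulate under the model and score it against the observed summary.

    The simulated summary is normalized to match the observed vector's
    normalization before applying the standardized error, so simulated
    and observed genome sizes need not agree.
    """
    values = np.zeros_like(observed.values)
    ss = np.random.SeedSequence(seed)
    for rep_seed in ss.spawn(n_replicates):
        s = int(rep_seed.generate_state(1)[0] >> 1)
        res = sim_to_counts2(simulate_dataset(model, genome, s), seed=s)
        summary = compute_summary(res.sites, observed.populations)
        if observed.normalization == "proportions":
            summary = normalize_sfs(summary)
        values += summary.values
    sim = JointSFS4(
        populations=observed.populations,
        values=values / n_replicates,
        kind=observed.kind,
        normalization=observed.normalization,
    )
    return fitness(sim, observed, sigma).value


def evaluate_candidate(cand: Candidate, observed, sigma, config: EngineConfig, seed: int):
    try:
        cand.fitness = evaluate(
            cand.model, observed, sigma, config.genome, seed, config.n_eval_replicates
        )
    except Exception:  # simulation failure: flag, assign worst later
        logger.exception("evaluation failed for candidate %d", cand.id)
        cand.fitness = None
        cand.flagged = True
    return cand


# ---- generational step and run ----------------------------------------------


class _IdGen:
    def __init__(self):
        self.next = 0

    def __call__(self):
        i = self.next
        self.next += 1
        return i


def _assign_failed(population: list[Candidate]) -> None:
    finite = [c.fitness for c in population if c.fitness is not None]
    worst = max(finite) if finite else math.inf
    for c in population:
        if c.fitness is None:
            c.fitness = worst


def step(
    population: list[Candidate],
    config: EngineConfig,
    observed: JointSFS4,
    sigma: SigmaVector,
    rng: np.random.Generator,
    iteration: int = 0,
    idgen=None,
    eval_seed: int | None = None,
) -> list[Candidate]:
    """One generation: reproduce, mutate, evaluate, rank, truncate.

    Parents are pooled with their children (elitism), ranked by error
    ascending with creation order breaking ties, and truncated to the
    configured population size.
    """
    idgen = idgen or _IdGen()
    _assign_failed(population)
    fvals = [c.fitness for c in population]
    f_min, f_max = min(fvals), max(fvals)
    children = []
    for parent in population:
        k = offspring_count(parent.fitness, f_min, f_max, config.s_min, config.s_max)
        for _ in range(k):
            child = Candidate(
                model=mutate(parent.model, rng, config.mutation_rates),
                parent_id=parent.id,
                created_at=iteration,
                id=idgen(),
            )
            seed = eval_seed if eval_seed is not None else int(rng.integers(2**31 - 1))
            evaluate_candidate(child, observed, sigma, config, seed=seed)
            children.append(child)
    pool = population + children
    _assign_failed(pool)
    pool.sort(key=lambda c: (c.fitness, c.id))
    return pool[: config.population_size]


def run(
    initial_models: list[DemographicModel],
    config: EngineConfig,
    observed: JointSFS4,
    sigma: SigmaVector,
    seed: int,
) -> RunResult:
    """Full evolutionary run from a set of starting models.

    The initial population cycles through the provided models (so mixed
    topologies compete within one run).  Stops at the iteration budget,
    a perfect fit, or — when a plateau window is configured — after that
    many iterations without improvement beyond the tolerance.
    """
    if not initial_models:
        raise ValueError("need at least one initial model")
    rng = np.random.default_rng(seed)
    idgen = _IdGen()
    eval_seed = int(rng.integers(2**31 - 1)) if config.paired_evaluation else None
    population = []
    for i in range(config.population_size):
        base = initial_models[i % len(initial_models)]
        model = base.copy() if i < len(initial_models) else mutate(base, rng, config.mutation_rates)
        cand = Candidate(model=model, created_at=0, id=idgen())
        seed_i = eval_seed if eval_seed is not None else int(rng.integers(2**31 - 1))
        evaluate_candidate(cand, observed, sigma, config, seed=seed_i)
        population.append(cand)
    _assign_failed(population)
    population.sort(key=lambda c: (c.fitness, c.id))

    best_trace, mean_trace = [], []
    iterations_run = 0
    for it in range(config.iterations):
        population = step(
            population, config, observed, sigma, rng, it + 1, idgen, eval_seed
        )
        best_trace.append(population[0].fitness)
        mean_trace.append(float(np.mean([c.fitness for c in population])))
        iterations_run = it + 1
        if population[0].fitness == 0.0:
            break
        w = config.plateau_window
        if w and len(best_trace) > w:
            if best_trace[-w - 1] - best_trace[-1] <= config.plateau_tol:
                break
    best = population[0]
    return RunResult(
        best=best,
        best_trace=best_trace,
        mean_trace=mean_trace,
        selected_topology=best.model.topology_label,
        seed=seed,
        iterations_run=iterations_run,
    )


def run_replicates(
    topologies: list[DemographicModel],
    config: EngineConfig,
    observed: JointSFS4,
    sigma: SigmaVector,
    n_runs: int = 40,
    seed: int = 0,
) -> tuple[dict[str, int], list[RunResult]]:
    """Independent seeded runs; tally which topology wins each run.

    Every run starts from a population mixing all topology variants
    round-robin, so topologies compete within as well as across runs.
    """
    if not topologies:
        raise ValueError("need at least one topology")
    ss = np.random.SeedSequence(seed)
    results = []
    support: dict[str, int] = {}
    for child in ss.spawn(n_runs):
        run_seed = int(child.generate_state(1)[0] >> 1)
        res = run(topologies, config, observed, sigma, seed=run_seed)
        results.append(res)
        support[res.selected_topology] = support.get(res.selected_topology, 0) + 1
    return support, results


__all__ = [
    "Candidate",
    "EngineConfig",
    "RunResult",
    "DEFAULT_MUTATION_RATES",
    "offspring_count",
    "mutate",
    "evaluate",
    "step",
    "run",
    "run_replicates",
]
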