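"""Demographic models as event graphs over ecodemes and topodemes.

A model is a rooted binary tree of *ecodemes* (named population units).
Each ecodeme is internally structured as a chain of *topodemes* — local
demes exchanging migrants with their nearest neighbours (a 1-D
stepping-stone, the simplest isolation-by-distance layout).  Ecodemes sit
on a 1-D lattice ordered by their ``position``; adjacency on that lattice
gates migration between ecodemes.

Population divergence is modelled as a *soft split*: after the split
(forward in time) migration between the two daughter ecodemes decays
exponentially from ``m_max`` at the split towards an asymptote ``m_min``:

    m(t) = m_min + (m_max - m_min) * exp(-lambda * (T - t) / epoch)

with ``t`` in generations before present, ``T`` the split time and the
exponent expressed in migration-update epochs (default 200 generations).
Discrete events (admixture pulses, Ne changes, topodeme-count changes,
migration-rate overrides) are attached to the tree at stated times.

All times are generations before present; present is 0.  Events carry
backward-in-time semantics: an event at time ``T`` sets the value that
applies for every ``t >= T``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

# Module-wide defaults.
EPOCH_LENGTH = 200.0  # generations between migration-matrix updates
DEFAULT_MUTATION_RATE = 1.61e-8  # per bp per generation
DEFAULT_GENERATION_TIME = 29.0  # years
DEFAULT_INTERNAL_MIGRATION = 1e-3  # per generation, adjacent topodemes
SIGMA_EPSILON = 1.0  # count-equivalent floor used downstream


@dataclass(frozen=True)
class Ecodeme:
    """A named population unit on the 1-D lattice.

    ``n_topodemes`` and ``ne_per_topodeme`` are the values at present;
    both may vary in time through events.
    """

    name: str
    position: int
    n_topodemes: int = 1
    ne_per_topodeme: float = 1000.0


@dataclass(frozen=True)
class MigrationDecayParams:
    """Parameters of the post-split exponential migration decay.

    m_max is the per-generation migration proportion at the split,
    m_min the asymptote reached as the split recedes into the past
    (forward in time: long after the split).  ``lambda_decay`` is the
    decay constant per epoch of ``epoch`` generations.
    """

    m_max: float
    m_min: float
    t_split: float
    lambda_decay: float = 1.0


@dataclass(frozen=True)
class SoftSplit:
    parent: str
    child_a: str
    child_b: str
    time: float
    decay: MigrationDecayParams


@dataclass(frozen=True)
class AdmixturePulse:
    source: str
    target: str
    time: float
    proportion: float


@dataclass(frozen=True)
class NeChange:
    ecodeme: str
    time: float
    new_ne: float


@dataclass(frozen=True)
class DemeCountChange:
    ecodeme: str
    time: float
    new_count: int


@dataclass(frozen=True)
class MigrationRateChange:
    pair: tuple[str, str]
    time: float
    new_rate: float


DemographicEvent = (
    SoftSplit | AdmixturePulse | NeChange | DemeCountChange | MigrationRateChange
)

_EVENT_KINDS = {
    "soft_split": SoftSplit,
    "admixture_pulse": AdmixturePulse,
    "ne_change": NeChange,
    "deme_count_change": DemeCountChange,
    "migration_rate_change": MigrationRateChange,
}


@dataclass
class DemographicModel:
    """An event graph over ecodemes, with sampling and rate conventions."""

    ecodemes: list[Ecodeme]
    events: list[DemographicEvent] = field(default_factory=list)
    topology_label: str = ""
    sampling: dict[str, int] = field(default_factory=dict)
    mutation_rate: float = DEFAULT_MUTATION_RATE
    generation_time: float = DEFAULT_GENERATION_TIME
    internal_migration: float = DEFAULT_INTERNAL_MIGRATION
    inter_ecodeme_migration: float = 0.0
    epoch_length: float = EPOCH_LENGTH

    # ---- structural queries -------------------------------------------------

    def ecodeme(self, name: str) -> Ecodeme:
        for e in self.ecodemes:
            if e.name == name:
                return e
        raise KeyError(f"no ecodeme named {name!r}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.ecodemes]

    @property
    def splits(self) -> list[SoftSplit]:
        return sorted(
            (ev for ev in self.events if isinstance(ev, SoftSplit)),
            key=lambda s: s.time,
        )

    def origin_time(self, name: str) -> float:
        """Time of the split that created ``name`` (inf for the root)."""
        for s in self.splits:
            if name in (s.child_a, s.child_b):
                return s.time
        return math.inf

    def end_time(self, name: str) -> float:
        """Time at which ``name`` splits into its children (0 for a leaf)."""
        for s in self.splits:
            if s.parent == name:
                return s.time
        return 0.0

    def alive_at(self, t: float) -> list[Ecodeme]:
        """Ecodemes extant at time ``t``, ordered by lattice position."""
        alive = [
            e
            for e in self.ecodemes
            if self.end_time(e.name) <= t < self.origin_time(e.name)
        ]
        return sorted(alive, key=lambda e: e.position)

    def leaves(self) -> list[Ecodeme]:
        return self.alive_at(0.0)

    def sibling_decay(self, a: str, b: str) -> MigrationDecayParams | None:
        """Decay parameters if ``a`` and ``b`` are daughters of one split."""
        for s in self.splits:
            if {a, b} == {s.child_a, s.child_b}:
                return s.decay
        return None

    def oldest_event_time(self) -> float:
        return max((ev.time for ev in self.events), default=0.0)

    # ---- time-varying attributes (event at T applies for t >= T) ------------

    def ne_at(self, name: str, t: float) -> float:
        base = self.ecodeme(name).ne_per_topodeme
        applicable = [
            ev
            for ev in self.events
            if isinstance(ev, NeChange) and ev.ecodeme == name and ev.time <= t
        ]
        if not applicable:
            return base
        return max(applicable, key=lambda ev: ev.time).new_ne

    def n_topodemes_at(self, name: str, t: float) -> int:
        base = self.ecodeme(name).n_topodemes
        applicable = [
            ev
            for ev in self.events
            if isinstance(ev, DemeCountChange) and ev.ecodeme == name and ev.time <= t
        ]
        if not applicable:
            return base
        return max(applicable, key=lambda ev: ev.time).new_count

    def max_topodemes(self, name: str) -> int:
        counts = [self.ecodeme(name).n_topodemes] + [
            ev.new_count
            for ev in self.events
            if isinstance(ev, DemeCountChange) and ev.ecodeme == name
        ]
        return max(counts)

    def pair_rate_override(self, a: str, b: str, t: float) -> float | None:
        applicable = [
            ev
            for ev in self.events
            if isinstance(ev, MigrationRateChange)
            and {a, b} == set(ev.pair)
            and ev.time <= t
        ]
        if not applicable:
            return None
        return max(applicable, key=lambda ev: ev.time).new_rate

    def copy(self) -> "DemographicModel":
        return copy.deepcopy(self)

    # ---- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        def ev_dict(ev):
            kind = {v: k for k, v in _EVENT_KINDS.items()}[type(ev)]
            d = {"kind": kind}
            if isinstance(ev, SoftSplit):
                d.update(
                    parent=ev.parent,
                    child_a=ev.child_a,
                    child_b=ev.child_b,
                    time=ev.time,
                    decay=dict(
                        m_max=ev.decay.m_max,
                        m_min=ev.decay.m_min,
                        t_split=ev.decay.t_split,
                        lambda_decay=ev.decay.lambda_decay,
                    ),
                )
            elif isinstance(ev, AdmixturePulse):
                d.update(
                    source=ev.source,
                    target=ev.target,
                    time=ev.time,
                    proportion=ev.proportion,
                )
            elif isinstance(ev, NeChange):
                d.update(ecodeme=ev.ecodeme, time=ev.time, new_ne=ev.new_ne)
            elif isinstance(ev, DemeCountChange):
                d.update(ecodeme=ev.ecodeme, time=ev.time, new_count=ev.new_count)
            else:
                d.update(pair=list(ev.pair), time=ev.time, new_rate=ev.new_rate)
            return d

        return {
            "topology_label": self.topology_label,
            "ecodemes": [
                dict(
                    name=e.name,
                    position=e.position,
                    n_topodemes=e.n_topodemes,
                    ne_per_topodeme=e.ne_per_topodeme,
                )
                for e in self.ecodemes
            ],
            "events": [ev_dict(ev) for ev in self.events],
            "sampling": dict(self.sampling),
            "mutation_rate": self.mutation_rate,
            "generation_time": self.generation_time,
            "internal_migration": self.internal_migration,
            "inter_ecodeme_migration": self.inter_ecodeme_migration,
            "epoch_length": self.epoch_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        events: list[DemographicEvent] = []
        for ed in d.get("events", []):
            kind = ed["kind"]
            if kind == "soft_split":
                dec = ed["decay"]
                events.append(
                    SoftSplit(
                        parent=ed["parent"],
                        child_a=ed["child_a"],
                        child_b=ed["child_b"],
                        time=float(ed["time"]),
                        decay=MigrationDecayParams(
                            m_max=float(dec["m_max"]),
                            m_min=float(dec["m_min"]),
                            t_split=float(dec["t_split"]),
                            lambda_decay=float(dec.get("lambda_decay", 1.0)),
                        ),
                    )
                )
            elif kind == "admixture_pulse":
                events.append(
                    AdmixturePulse(
                        source=ed["source"],
                        target=ed["target"],
                        time=float(ed["time"]),
                        proportion=float(ed["proportion"]),
                    )
                )
            elif kind == "ne_change":
                events.append(
                    NeChange(ed["ecodeme"], float(ed["time"]), float(ed["new_ne"]))
                )
            elif kind == "deme_count_change":
                events.append(
                    DemeCountChange(ed["ecodeme"], float(ed["time"]), int(ed["new_count"]))
                )
            elif kind == "migration_rate_change":
                events.append(
                    MigrationRateChange(
                        tuple(ed["pair"]), float(ed["time"]), float(ed["new_rate"])
                    )
                )
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        return cls(
            ecodemes=[
                Ecodeme(
                    name=ed["name"],
                    position=int(ed["position"]),
                    n_topodemes=int(ed.get("n_topodemes", 1)),
                    ne_per_topodeme=float(ed.get("ne_per_topodeme", 1000.0)),
                )
                for ed in d["ecodemes"]
            ],
            events=events,
            topology_label=d.get("topology_label", ""),
            sampling={k: int(v) for k, v in d.get("sampling", {}).items()},
            mutation_rate=float(d.get("mutation_rate", DEFAULT_MUTATION_RATE)),
            generation_time=float(d.get("generation_time", DEFAULT_GENERATION_TIME)),
            internal_migration=float(
                d.get("internal_migration", DEFAULT_INTERNAL_MIGRATION)
            ),
            inter_ecodeme_migration=float(d.get("inter_ecodeme_migration", 0.0)),
            epoch_length=float(d.get("epoch_length", EPOCH_LENGTH)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---- validation -------------------------------------------------------------


def validate_model(model: DemographicModel) -> list[str]:
    """Check every structural invariant; return the list of violations.

    An empty list means the model is valid.  Violations are phrased so the
    offending event or ecodeme can be identified.
    """
    v: list[str] = []
    names = model.names
    if len(set(names)) != len(names):
        v.append("duplicate ecodeme names")
        return v
    positions = [e.position for e in model.ecodemes]
    if len(set(positions)) != len(positions):
        v.append("ecodeme positions are not distinct")
    for e in model.ecodemes:
        if e.n_topodemes < 1:
            v.append(f"ecodeme {e.name}: n_topodemes < 1")
        if e.ne_per_topodeme < 1:
            v.append(f"ecodeme {e.name}: ne_per_topodeme < 1")

    known = set(names)
    for ev in model.events:
        if ev.time <= 0:
            v.append(f"event {ev}: time must be > 0")
        referenced: tuple[str, ...]
        if isinstance(ev, SoftSplit):
            referenced = (ev.parent, ev.child_a, ev.child_b)
        elif isinstance(ev, AdmixturePulse):
            referenced = (ev.source, ev.target)
        elif isinstance(ev, (NeChange, DemeCountChange)):
            referenced = (ev.ecodeme,)
        else:
            referenced = tuple(ev.pair)
        for name in referenced:
            if name not in known:
                v.append(f"event {ev}: unknown ecodeme {name!r}")

    # Checks below need resolvable names.
    if any("unknown ecodeme" in s for s in v):
        return v

    splits = model.splits
    child_of: dict[str, list[SoftSplit]] = {}
    for s in splits:
        if s.child_a == s.child_b:
            v.append(f"split {s}: identical children")
        for c in (s.child_a, s.child_b):
            child_of.setdefault(c, []).append(s)
        if s.parent in (s.child_a, s.child_b):
            v.append(f"split {s}: parent cannot be its own child")
        d = s.decay
        if not (0 <= d.m_min <= d.m_max < 1):
            v.append(f"split {s}: decay requires 0 <= m_min <= m_max < 1")
        if d.t_split <= 0 or d.lambda_decay <= 0:
            v.append(f"split {s}: t_split and lambda_decay must be > 0")
        if not math.isclose(d.t_split, s.time):
            v.append(f"split {s}: decay t_split must equal the split time")

    for name, creating in child_of.items():
        if len(creating) > 1:
            v.append(f"ecodeme {name}: created by more than one split")
    roots = [n for n in names if n not in child_of]
    if len(roots) != 1:
        v.append(f"expected exactly one root ecodeme, found {roots}")

    # Partial order: an ecodeme's own split (as parent) is younger than the
    # split that created it.
    for s in splits:
        if s.time >= model.origin_time(s.parent):
            v.append(
                f"split {s}: occurs at or before the origin of its parent "
                f"{s.parent!r}"
            )

    for ev in model.events:
        if isinstance(ev, AdmixturePulse):
            if not (0 < ev.proportion < 1):
                v.append(f"pulse {ev}: proportion must be in (0,1)")
            for name in (ev.source, ev.target):
                if not (model.end_time(name) <= ev.time < model.origin_time(name)):
                    v.append(
                        f"pulse {ev}: ecodeme {name!r} is not extant at the "
                        f"pulse time (admixture predates split or postdates merge)"
                    )
            if ev.source == ev.target:
                v.append(f"pulse {ev}: source equals target")
        elif isinstance(ev, NeChange) and ev.new_ne < 1:
            v.append(f"event {ev}: new_ne < 1")
        elif isinstance(ev, DemeCountChange) and ev.new_count < 1:
            v.append(f"event {ev}: new_count < 1")
        elif isinstance(ev, MigrationRateChange) and not (0 <= ev.new_rate < 1):
            v.append(f"event {ev}: rate must be in [0,1)")

    for name, k in model.sampling.items():
        if name not in known:
            v.append(f"sampling: unknown ecodeme {name!r}")
        elif model.end_time(name) != 0.0:
            v.append(f"sampling: ecodeme {name!r} is not extant at present")
        if k < 1:
            v.append(f"sampling: ecodeme {name!r} needs >= 1 chromosome")
    return v


def is_valid(model: DemographicModel) -> bool:
    return not validate_model(model)


# ---- migration decay --------------------------------------------------------


def migration_rate_at(
    decay: MigrationDecayParams, t: float, epoch_length: float = EPOCH_LENGTH
) -> float:
    """Post-split migration rate at time ``t`` generations before present.

    Equals ``m_max`` at the split (t = T) and decays towards ``m_min`` as
    the time since the split, ``T - t``, grows.  Undefined for ``t`` older
    than the split, where the two ecodemes are a single ancestral unit.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if t > decay.t_split:
        raise ValueError("rate undefined before split")
    x = decay.lambda_decay * (decay.t_split - t) / epoch_length
    return decay.m_min + (decay.m_max - decay.m_min) * math.exp(-x)


# ---- topodeme indexing and the migration matrix -----------------------------


def topodeme_index(model: DemographicModel, t: float) -> list[tuple[str, int]]:
    """(ecodeme, topodeme) labels alive at ``t``, in lattice order."""
    out = []
    for eco in model.alive_at(t):
        for i in range(model.n_topodemes_at(eco.name, t)):
            out.append((eco.name, i))
    return out


def build_migration_matrix(model: DemographicModel, t: float) -> np.ndarray:
    """Symmetric per-generation migration matrix over topodemes alive at ``t``.

    Topodemes of all alive ecodemes form a single chain in lattice order.
    Within an ecodeme, adjacent topodemes exchange at the internal rate.
    Across an ecodeme boundary, only the two facing edge topodemes are
    connected; the rate is the decay value for sibling (split-pair)
    ecodemes, any explicit pairwise override, or the model's base
    inter-ecodeme rate for lattice-adjacent pairs (zero by default).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    alive = model.alive_at(t)
    labels = topodeme_index(model, t)
    n = len(labels)
    mat = np.zeros((n, n))
    pos = {lab: i for i, lab in enumerate(labels)}

    for eco in alive:
        k = model.n_topodemes_at(eco.name, t)
        for i in range(k - 1):
            a, b = pos[(eco.name, i)], pos[(eco.name, i + 1)]
            mat[a, b] = mat[b, a] = model.internal_migration

    for ia, eco_a in enumerate(alive):
        for ib in range(ia + 1, len(alive)):
            eco_b = alive[ib]
            decay = model.sibling_decay(eco_a.name, eco_b.name)
            override = model.pair_rate_override(eco_a.name, eco_b.name, t)
            adjacent = ib == ia + 1
            if decay is not None:
                rate = migration_rate_at(decay, t, model.epoch_length)
            elif override is not None:
                rate = override
            elif adjacent:
                rate = model.inter_ecodeme_migration
            else:
                continue
            if rate == 0:
                continue
            # facing edge topodemes of the two ecodemes (lattice order)
            left, right = (eco_a, eco_b) if eco_a.position < eco_b.position else (eco_b, eco_a)
            a = pos[(left.name, model.n_topodemes_at(left.name, t) - 1)]
            b = pos[(right.name, 0)]
            mat[a, b] = mat[b, a] = rate
    return mat


# ---- epoch schedule ---------------------------------------------------------


@dataclass
class EpochState:
    """Constant-rate interval [start, end) in generations before present."""

    start: float
    end: float
    demes: list[tuple[str, int]]
    migration: np.ndarray
    ne: np.ndarray


def epoch_schedule(
    model: DemographicModel, epoch_length: float | None = None
) -> list[EpochState]:
    """Discretize the model into piecewise-constant epochs.

    Boundaries are the regular epoch grid (default every 200 generations)
    plus every discrete event time; the decay rate is evaluated at each
    epoch's start (its younger edge).  A final open epoch extends beyond
    the oldest event.
    """
    if epoch_length is None:
        epoch_length = model.epoch_length
    oldest = model.oldest_event_time()
    bounds = {0.0}
    k = 1
    while k * epoch_length < oldest:
        bounds.add(float(k * epoch_length))
        k += 1
    for ev in model.events:
        bounds.add(float(ev.time))
    cuts = sorted(bounds)
    epochs = []
    for i, start in enumerate(cuts):
        end = cuts[i + 1] if i + 1 < len(cuts) else math.inf
        demes = topodeme_index(model, start)
        mat = build_migration_matrix(model, start)
        ne = np.array([model.ne_at(name, start) for name, _ in demes])
        epochs.append(EpochState(start=start, end=end, demes=demes, migration=mat, ne=ne))
    return epochs


def to_demes(model: DemographicModel):
    """Export to a demes graph, topodemes expanded to individual demes.

    The continuous migration decay is discretized per the epoch schedule:
    each epoch contributes constant-rate migrations over its interval.
    Models with topodeme-count changes cannot be expressed as a fixed
    deme set and are rejected.
    """
    import demes

    errors = validate_model(model)
    if errors:
        raise ValueError("invalid model: " + "; ".join(errors))
    if any(isinstance(ev, DemeCountChange) for ev in model.events):
        raise NotImplementedError(
            "demes export requires a time-invariant topodeme count"
        )

    b = demes.Builder(time_units="generations")
    name = lambda eco, i: f"{eco}_{i}"
    ecos = sorted(
        model.ecodemes, key=lambda e: (-model.origin_time(e.name), e.position)
    )
    for eco in ecos:
        origin = model.origin_time(eco.name)
        end = model.end_time(eco.name)
        k = eco.n_topodemes
        change_times = sorted(
            {
                ev.time
                for ev in model.events
                if isinstance(ev, NeChange)
                and ev.ecodeme == eco.name
                and end < ev.time < origin
            },
            reverse=True,
        )
        bounds = change_times + [end]
        epochs = []
        for j, end_time in enumerate(bounds):
            upper = origin if j == 0 else bounds[j - 1]
            probe = end_time if math.isinf(upper) else 0.5 * (end_time + upper)
            epochs.append(dict(end_time=end_time, start_size=model.ne_at(eco.name, probe)))
        parent_split = next(
            (s for s in model.splits if eco.name in (s.child_a, s.child_b)), None
        )
        for i in range(k):
            kwargs = dict(epochs=[dict(e) for e in epochs])
            if parent_split is not None:
                pk = model.ecodeme(parent_split.parent).n_topodemes
                kwargs["ancestors"] = [name(parent_split.parent, min(i, pk - 1))]
                kwargs["start_time"] = origin
            b.add_deme(name(eco.name, i), **kwargs)

    index_cache: dict[float, list[tuple[str, int]]] = {}
    for ep in epoch_schedule(model):
        demes_at = topodeme_index(model, ep.start)
        mat = ep.migration
        for a in range(len(demes_at)):
            for bb in range(a + 1, len(demes_at)):
                if mat[a, bb] > 0:
                    b.add_migration(
                        demes=[name(*demes_at[a]), name(*demes_at[bb])],
                        rate=float(mat[a, bb]),
                        start_time=ep.end,
                        end_time=ep.start,
                    )
    for ev in model.events:
        if isinstance(ev, AdmixturePulse):
            src_k = model.ecodeme(ev.source).n_topodemes
            for i in range(model.ecodeme(ev.target).n_topodemes):
                b.add_pulse(
                    sources=[name(ev.source, min(i, src_k - 1))],
                    dest=name(ev.target, i),
                    proportions=[ev.proportion],
                    time=ev.time,
                )
    return b.resolve()


__all__ = [
    "EPOCH_LENGTH",
    "DEFAULT_MUTATION_RATE",
    "DEFAULT_GENERATION_TIME",
    "Ecodeme",
    "MigrationDecayParams",
    "SoftSplit",
    "AdmixturePulse",
    "NeChange",
    "DemeCountChange",
    "MigrationRateChange",
    "DemographicEvent",
    "DemographicModel",
    "EpochState",
    "validate_model",
    "is_valid",
    "migration_rate_at",
    "topodeme_index",
    "build_migration_matrix",
    "epoch_schedule",
    "to_demes",
]
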