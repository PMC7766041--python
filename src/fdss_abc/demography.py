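"""Demographic model definitions, priors and event-list construction.

A model is a declarative description of a structured demography: named
demes, divergences (backward-in-time lineage merges), instantaneous
admixture pulses, continuous-migration windows, and post-bottleneck growth
phases.  Every numeric slot may reference a named free parameter (drawn
from a prior), a named fixed constant, or a literal.  Times are expressed
in years at the interface and converted to generations internally.

Two models ship with the package (:func:`builtin_model`): the
Single-Dispersal (SD) and Multiple-Dispersal (MD) out-of-Africa scenarios,
with 45 and 50 free parameters respectively.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PriorSpec",
    "SimulationConfig",
    "ModelDefinition",
    "EventList",
    "load_model",
    "builtin_model",
    "sample_prior",
    "build_event_list",
    "to_ms_command",
    "toy_constant_size_model",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one free parameter (uniform or log-uniform)."""

    dist: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unsupported prior distribution {self.dist!r}")
        if not self.low < self.high:
            raise ValueError(f"prior bounds must satisfy low < high, got {self}")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("loguniform prior requires low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))

    def quantile(self, q) -> float:
        q = np.asarray(q, dtype=float)
        if self.dist == "uniform":
            return self.low + q * (self.high - self.low)
        return float(np.exp(np.log(self.low) + q * (np.log(self.high) - np.log(self.low))))


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed simulation constants shared by both models.

    Defaults follow the study design: generation time 29 years, mutation
    rate 1.25e-8 /bp/generation, intra-locus recombination 1.12e-8
    /bp/generation, 10,000 fragments of 500 bp, one diploid sampled per
    population.
    """

    generation_time: float = 29.0
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1.12e-8
    fragment_length: int = 500
    n_fragments: int = 10_000
    intra_locus_recombination: bool = True

    def __post_init__(self) -> None:
        if self.generation_time <= 0 or self.mutation_rate <= 0:
            raise ValueError("generation time and mutation rate must be > 0")
        if self.recombination_rate < 0 or self.fragment_length < 1 or self.n_fragments < 1:
            raise ValueError("invalid fragment geometry")


# ---------------------------------------------------------------------------
# tiny expression evaluator: names, literals, max(...)/min(...)

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _split_args(text: str) -> list[str]:
    args, depth, cur = [], 0, []
    for ch in text:
        if ch == "," and depth == 0:
            args.append("".join(cur))
            cur = []
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        cur.append(ch)
    args.append("".join(cur))
    return args


def eval_expr(expr, env: Mapping[str, float]) -> float:
    """Evaluate a scalar model expression: literal, name, max()/min()."""
    if isinstance(expr, (int, float)):
        return float(expr)
    text = str(expr).strip()
    try:
        return float(text)
    except ValueError:
        pass
    if _NAME_RE.match(text):
        if text not in env:
            raise KeyError(f"undefined parameter {text!r}")
        return float(env[text])
    for fn, op in (("max", max), ("min", min)):
        if text.startswith(fn + "(") and text.endswith(")"):
            return float(op(eval_expr(a, env) for a in _split_args(text[len(fn) + 1 : -1])))
    raise ValueError(f"cannot evaluate expression {expr!r}")


def expr_names(expr) -> set[str]:
    """Free names referenced by an expression."""
    if isinstance(expr, (int, float)):
        return set()
    return {
        tok
        for tok in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", str(expr))
        if tok not in ("max", "min")
    }


_CONSTRAINT_RE = re.compile(r"^(.*?)(<=|<)(.*)$")


@dataclass(frozen=True)
class Constraint:
    lhs: str
    op: str
    rhs: str

    @classmethod
    def parse(cls, text: str) -> "Constraint":
        m = _CONSTRAINT_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse constraint {text!r} (expected 'a < b')")
        return cls(m.group(1).strip(), m.group(2), m.group(3).strip())

    def holds(self, env: Mapping[str, float]) -> bool:
        a, b = eval_expr(self.lhs, env), eval_expr(self.rhs, env)
        return a <= b if self.op == "<=" else a < b

    def names(self) -> set[str]:
        return expr_names(self.lhs) | expr_names(self.rhs)

    def __str__(self) -> str:
        return f"{self.lhs} {self.op} {self.rhs}"


# ---------------------------------------------------------------------------
# model definition


@dataclass
class ModelDefinition:
    """A declarative demographic model with priors and constraints."""

    name: str
    populations: list[str]
    sampled: dict[str, float]  # population -> sampling age (years)
    fixed: dict[str, float]
    priors: dict[str, PriorSpec]
    sizes: dict[str, object]  # population -> size expression
    events: list[dict]
    growth: list[dict] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        self.constraints = [
            c if isinstance(c, Constraint) else Constraint.parse(c) for c in self.constraints
        ]
        self._validate()

    # -- validation --------------------------------------------------------

    def _declared(self) -> set[str]:
        return set(self.priors) | set(self.fixed)

    def _validate(self) -> None:
        declared = self._declared()
        pops = set(self.populations)
        overlap = set(self.priors) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for pop in self.sampled:
            if pop not in pops:
                raise ValueError(f"sampled population {pop!r} not declared")
        for pop, expr in self.sizes.items():
            if pop not in pops:
                raise ValueError(f"size given for undeclared population {pop!r}")
            self._check_refs(f"size of {pop}", expr, declared)
        missing_sizes = pops - set(self.sizes)
        if missing_sizes:
            raise ValueError(f"populations without a size: {sorted(missing_sizes)}")
        for ev in self.events:
            kind = ev.get("type")
            if kind == "divergence":
                self._check_refs("divergence", ev["time"], declared)
                for p in list(ev["derived"]) + [ev["ancestral"]]:
                    if p not in pops:
                        raise ValueError(f"divergence references undeclared population {p!r}")
            elif kind == "pulse":
                for key in ("time", "proportion"):
                    self._check_refs("pulse", ev[key], declared)
                for p in (ev["source"], ev["dest"]):
                    if p not in pops:
                        raise ValueError(f"pulse references undeclared population {p!r}")
            elif kind == "migration":
                for key in ("rate", "start", "end"):
                    self._check_refs("migration", ev[key], declared)
                for p in (ev["source"], ev["dest"]):
                    if p not in pops:
                        raise ValueError(f"migration references undeclared population {p!r}")
            else:
                raise ValueError(f"unknown event type {kind!r}")
        for g in self.growth:
            if g["population"] not in pops:
                raise ValueError(f"growth references undeclared population {g['population']!r}")
            for key in ("rate", "modern_size", "bottleneck_time", "founder_size"):
                self._check_refs("growth", g[key], declared)
        for c in self.constraints:
            undeclared = c.names() - declared
            if undeclared:
                raise ValueError(f"constraint {c} references undeclared {sorted(undeclared)}")
        self._check_constraint_graph()

    @staticmethod
    def _check_refs(context: str, expr, declared: set[str]) -> None:
        undeclared = expr_names(expr) - declared
        if undeclared:
            raise ValueError(f"{context} references undeclared parameter(s) {sorted(undeclared)}")

    def _check_constraint_graph(self) -> None:
        """Strict orderings must be acyclic (a<b<...<a is unsatisfiable)."""
        edges: dict[str, set[str]] = {}
        for c in self.constraints:
            if _NAME_RE.match(c.lhs) and _NAME_RE.match(c.rhs):
                edges.setdefault(c.lhs, set()).add(c.rhs)
        seen: dict[str, int] = {}

        def visit(node: str) -> None:
            state = seen.get(node, 0)
            if state == 1:
                raise ValueError(f"cyclic ordering constraints involving {node!r}")
            if state == 2:
                return
            seen[node] = 1
            for nxt in edges.get(node, ()):
                visit(nxt)
            seen[node] = 2

        for node in list(edges):
            visit(node)

    # -- introspection ------------------------------------------------------

    @property
    def free_parameters(self) -> list[str]:
        return list(self.priors)

    @property
    def n_free_parameters(self) -> int:
        return len(self.priors)

    @property
    def sample_populations(self) -> list[str]:
        return list(self.sampled)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "populations": list(self.populations),
            "sampled": dict(self.sampled),
            "fixed": dict(self.fixed),
            "priors": {
                k: {"dist": p.dist, "low": p.low, "high": p.high} for k, p in self.priors.items()
            },
            "sizes": dict(self.sizes),
            "growth": [dict(g) for g in self.growth],
            "events": [dict(e) for e in self.events],
            "constraints": [str(c) for c in self.constraints],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelDefinition":
        priors = {
            k: PriorSpec(str(v.get("dist", "uniform")), float(v["low"]), float(v["high"]))
            for k, v in data.get("priors", {}).items()
        }
        return cls(
            name=str(data["name"]),
            description=str(data.get("description", "")),
            populations=list(data["populations"]),
            sampled={k: float(v) for k, v in data.get("sampled", {}).items()},
            fixed={k: float(v) for k, v in data.get("fixed", {}).items()},
            priors=priors,
            sizes=dict(data["sizes"]),
            growth=list(data.get("growth", [])),
            events=list(data["events"]),
            constraints=list(data.get("constraints", [])),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_model(path) -> ModelDefinition:
    """Load and validate a model definition from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ModelDefinition.from_dict(data)


def builtin_model(name: str) -> ModelDefinition:
    """Load a model shipped with the package (``"SD"`` or ``"MD"``)."""
    fname = {"SD": "sd.yaml", "MD": "md.yaml"}.get(name.upper())
    if fname is None:
        raise KeyError(f"no builtin model named {name!r}")
    ref = importlib.resources.files("fdss_abc.models") / fname
    return ModelDefinition.from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# prior sampling with constraint-aware rejection


MAX_CONSTRAINT_RETRIES = 10_000


def sample_prior(
    model: ModelDefinition,
    rng: np.random.Generator | int,
) -> dict[str, float]:
    """Draw one parameter vector satisfying all ordering constraints.

    Only the parameters involved in violated constraints are redrawn at
    each retry, which preserves the marginal priors of the remaining
    parameters better than whole-vector rejection.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params = {k: p.sample(rng) for k, p in model.priors.items()}
    env = {**model.fixed, **params}
    free = set(model.priors)
    for _ in range(MAX_CONSTRAINT_RETRIES):
        violated = [c for c in model.constraints if not c.holds(env)]
        if not violated:
            return params
        redraw = set().union(*(c.names() for c in violated)) & free
        for k in sorted(redraw):
            params[k] = model.priors[k].sample(rng)
            env[k] = params[k]
    raise RuntimeError(
        f"could not satisfy constraints of model {model.name} after "
        f"{MAX_CONSTRAINT_RETRIES} retries; prior ranges are likely inconsistent"
    )


def validate_params(model: ModelDefinition, params: Mapping[str, float]) -> None:
    missing = set(model.priors) - set(params)
    if missing:
        raise ValueError(f"parameter vector missing {sorted(missing)}")
    env = {**model.fixed, **params}
    for c in model.constraints:
        if not c.holds(env):
            raise ValueError(f"parameter vector violates constraint {c}")


# ---------------------------------------------------------------------------
# engine-agnostic event list (times in generations, backward in time)


@dataclass(frozen=True)
class PopulationInit:
    population: str
    size: float
    growth_rate: float = 0.0


@dataclass(frozen=True)
class Divergence:
    time: float
    derived: tuple[str, ...]
    ancestral: str
    label: str = ""


@dataclass(frozen=True)
class Pulse:
    time: float
    source: str  # forward-time donor
    dest: str  # forward-time recipient
    proportion: float


@dataclass(frozen=True)
class MigrationChange:
    time: float
    source: str  # forward-time donor
    dest: str  # forward-time recipient
    rate: float


@dataclass(frozen=True)
class SizeChange:
    time: float
    population: str
    size: float | None = None
    growth_rate: float | None = None


@dataclass
class EventList:
    """Backward-in-time demography, in generations, engine-agnostic."""

    populations: list[str]
    initial: list[PopulationInit]
    events: list  # Divergence | Pulse | MigrationChange | SizeChange, time-sorted
    sample_ages: dict[str, float]  # generations

    @property
    def root_time(self) -> float:
        return max(e.time for e in self.events if isinstance(e, Divergence))

    def divergences(self, label: str | None = None) -> list[Divergence]:
        out = [e for e in self.events if isinstance(e, Divergence)]
        if label is not None:
            out = [e for e in out if e.label == label]
        return out


def build_event_list(
    model: ModelDefinition,
    params: Mapping[str, float],
    config: SimulationConfig = SimulationConfig(),
    sample_ages: Mapping[str, float] | None = None,
) -> EventList:
    """Resolve all symbols and emit a time-sorted backward event list.

    Years are converted to generations with ``config.generation_time``.
    ``sample_ages`` (years) overrides the model's default sampling ages,
    e.g. for the archaic genomes.
    """
    validate_params(model, params)
    env = {**model.fixed, **params}
    gt = config.generation_time
    initial = []
    growth_by_pop = {g["population"]: g for g in model.growth}
    events: list = []
    for pop in model.populations:
        size = eval_expr(model.sizes[pop], env)
        if size <= 0:
            raise ValueError(f"population {pop} has non-positive size {size}")
        rate0 = 0.0
        if pop in growth_by_pop:
            g = growth_by_pop[pop]
            rate = eval_expr(g["rate"], env)
            modern = eval_expr(g["modern_size"], env)
            founder = eval_expr(g["founder_size"], env)
            onset = eval_expr(g["bottleneck_time"], env) / gt
            if founder <= 0 or modern <= 0 or rate <= 0:
                raise ValueError(f"invalid growth block for {pop}")
            # post-bottleneck recovery: founder size at the bottleneck,
            # exponential growth at `rate` until the modern size is reached
            span = math.log(modern / founder) / rate
            t_start = onset - span
            if t_start > 0:
                events.append(SizeChange(t_start, pop, growth_rate=rate))
            else:
                rate0 = rate
            events.append(SizeChange(onset, pop, size=founder, growth_rate=0.0))
            size = modern
        initial.append(PopulationInit(pop, size, rate0))
    for ev in model.events:
        kind = ev["type"]
        if kind == "divergence":
            events.append(
                Divergence(
                    eval_expr(ev["time"], env) / gt,
                    tuple(ev["derived"]),
                    ev["ancestral"],
                    str(ev.get("label", "")),
                )
            )
        elif kind == "pulse":
            prop = eval_expr(ev["proportion"], env)
            if not 0 <= prop <= 1:
                raise ValueError(f"pulse proportion {prop} outside [0, 1]")
            events.append(
                Pulse(eval_expr(ev["time"], env) / gt, ev["source"], ev["dest"], prop)
            )
        elif kind == "migration":
            rate = eval_expr(ev["rate"], env)
            start = eval_expr(ev["start"], env) / gt
            end = eval_expr(ev["end"], env) / gt
            if rate < 0:
                raise ValueError(f"negative migration rate in {ev}")
            if end <= start:
                raise ValueError(f"migration window empty in {ev}")
            events.append(MigrationChange(start, ev["source"], ev["dest"], rate))
            events.append(MigrationChange(end, ev["source"], ev["dest"], 0.0))
    events.sort(key=lambda e: e.time)
    out = EventList(
        populations=list(model.populations),
        initial=initial,
        events=events,
        sample_ages={},
    )
    root = out.root_time
    for e in events:
        if not isinstance(e, Divergence) and e.time > root:
            raise ValueError(f"event {e} scheduled older than the root merge at {root:.1f} gen")
    ages = dict(model.sampled)
    if sample_ages:
        ages.update(sample_ages)
    out.sample_ages = {p: ages.get(p, 0.0) / gt for p in model.sampled}
    return out


# ---------------------------------------------------------------------------
# ms command emission (parity checks against ms-based pipelines)


def to_ms_command(
    model: ModelDefinition,
    params: Mapping[str, float],
    config: SimulationConfig = SimulationConfig(),
    n0: float = 10_000.0,
    n_fragments: int | None = None,
) -> str:
    """Emit an ms-style command line equivalent to the event list.

    Provided for cross-checks against ms-based simulators; note that ms
    cannot express ancient sampling ages, so all samples are contemporary
    in the emitted command.
    """
    ev = build_event_list(model, params, config)
    pops = list(ev.populations)
    idx = {p: i + 1 for i, p in enumerate(pops)}  # ms numbers from 1
    four_n0 = 4.0 * n0
    L = config.fragment_length
    theta = four_n0 * config.mutation_rate * L
    rho = four_n0 * config.recombination_rate * L if config.intra_locus_recombination else 0.0
    nsam = 2 * len(ev.sample_ages)
    nreps = n_fragments if n_fragments is not None else config.n_fragments
    counts = [2 if p in ev.sample_ages else 0 for p in pops]
    parts = [f"ms {nsam} {nreps} -t {theta:.6g}"]
    if rho:
        parts.append(f"-r {rho:.6g} {L}")
    parts.append(f"-I {len(pops)} " + " ".join(str(c) for c in counts))
    for init in ev.initial:
        parts.append(f"-n {idx[init.population]} {init.size / n0:.6g}")
        if init.growth_rate:
            parts.append(f"-g {idx[init.population]} {init.growth_rate * four_n0:.6g}")
    next_pop = len(pops)
    for e in ev.events:
        t = e.time / four_n0
        if isinstance(e, Divergence):
            for d in e.derived:
                parts.append(f"-ej {t:.6g} {idx[d]} {idx[e.ancestral]}")
        elif isinstance(e, Pulse):
            # backward: with prob `proportion` a lineage of the recipient
            # moves to the donor: -es splits off that fraction, -ej merges it
            next_pop += 1
            parts.append(f"-es {t:.6g} {idx[e.dest]} {1 - e.proportion:.6g}")
            parts.append(f"-ej {t:.6g} {next_pop} {idx[e.source]}")
        elif isinstance(e, MigrationChange):
            # ms M[i][j]: fraction of deme i replaced by migrants from j
            parts.append(f"-em {t:.6g} {idx[e.dest]} {idx[e.source]} {e.rate * four_n0:.6g}")
        elif isinstance(e, SizeChange):
            if e.size is not None:
                parts.append(f"-en {t:.6g} {idx[e.population]} {e.size / n0:.6g}")
            if e.growth_rate is not None:
                parts.append(f"-eg {t:.6g} {idx[e.population]} {e.growth_rate * four_n0:.6g}")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# toy model used for calibration and recovery oracles


def toy_constant_size_model(
    low: float = 1_000.0,
    high: float = 30_000.0,
    split_time: float = 29.0,
) -> ModelDefinition:
    """One-parameter toy: a constant-size population observed as two
    'populations' that merge ``split_time`` years ago (one generation by
    default, i.e. effectively a single panmictic deme).  The single free
    parameter ``nC`` is the diploid effective size."""
    return ModelDefinition(
        name="TOY",
        description="single-parameter constant-size coalescent",
        populations=["pop1", "pop2", "anc"],
        sampled={"pop1": 0.0, "pop2": 0.0},
        fixed={"tsplit": split_time},
        priors={"nC": PriorSpec("uniform", low, high)},
        sizes={"pop1": "nC", "pop2": "nC", "anc": "nC"},
        growth=[],
        events=[
            {"type": "divergence", "time": "tsplit", "derived": ["pop1", "pop2"], "ancestral": "anc"}
        ],
        constraints=[],
    )
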