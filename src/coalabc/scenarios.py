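"""Demographic scenarios, parameter priors and the configuration grammar.

A *scenario* is an ordered list of events on a set of populations, read
backward in time (time 0 = most recent sampling, times in generations before
present).  Supported events:

``sample <time> <pop>``
    lineages of the sample taken from ``pop`` enter the genealogy at ``time``.
``merge <time> <sink> <source>``
    backward in time, every lineage of ``source`` moves into ``sink`` (forward
    in time: ``source`` diverged from ``sink`` at ``time``).
``admix <time> <pop> <parent1> <parent2> <rate>``
    backward in time each lineage of ``pop`` moves to ``parent1`` with
    probability ``rate``, else to ``parent2`` (forward: ``pop`` was founded at
    ``time`` by admixture).
``varNe <time> <pop> <size>``
    ``pop`` has effective size ``size`` for all times older than ``time``.

Times, admixture rates and sizes may be literals or names of prior-distributed
parameters.  Priors are uniform, log-uniform, or gamma parameterized by mean
and shape; inequality conditions between parameters are honoured by rejection
resampling of the whole parameter vector.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .loci import LocusSpec, parse_locus_line

__all__ = [
    "PriorSpec",
    "Condition",
    "Event",
    "Scenario",
    "SampleSpec",
    "Config",
    "ParseError",
    "UnsatisfiableConditions",
    "parse_config",
    "parse_scenario",
    "serialize_config",
    "draw_parameters",
    "validate_scenario",
]


class ParseError(ValueError):
    """Raised on a malformed configuration, with the offending line number."""

    def __init__(self, lineno: int | None, message: str):
        self.lineno = lineno
        where = f"line {lineno}: " if lineno is not None else ""
        super().__init__(f"{where}{message}")


class UnsatisfiableConditions(RuntimeError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Prior distribution of one scalar parameter.

    kind is one of ``uniform`` (U[a,b]), ``loguniform`` (exp of U[ln a, ln b])
    or ``gamma`` with ``a`` = mean and ``b`` = shape (scale = mean/shape).
    """

    name: str
    kind: str
    a: float
    b: float

    def __post_init__(self):
        if self.kind not in ("uniform", "loguniform", "gamma"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind in ("uniform", "loguniform") and not self.a <= self.b:
            raise ValueError(f"prior {self.name}: lower bound must be <= upper bound")
        if self.kind == "loguniform" and self.a <= 0:
            raise ValueError(f"prior {self.name}: log-uniform bounds must be positive")
        if self.kind == "gamma" and (self.a <= 0 or self.b <= 0):
            raise ValueError(f"prior {self.name}: gamma mean and shape must be positive")

    # -- sampling ---------------------------------------------------------
    def draw(self, rng: np.random.Generator, size=None):
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size)
        if self.kind == "loguniform":
            return np.exp(rng.uniform(math.log(self.a), math.log(self.b), size))
        return rng.gamma(self.b, self.a / self.b, size)

    # -- summaries --------------------------------------------------------
    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "gamma":
            return (0.0, math.inf)
        return (self.a, self.b)

    def mean(self) -> float:
        if self.kind == "uniform":
            return 0.5 * (self.a + self.b)
        if self.kind == "loguniform":
            return (self.b - self.a) / (math.log(self.b) - math.log(self.a))
        return self.a

    def median(self) -> float:
        if self.kind == "uniform":
            return 0.5 * (self.a + self.b)
        if self.kind == "loguniform":
            return math.sqrt(self.a * self.b)
        import scipy.stats

        return float(scipy.stats.gamma.median(self.b, scale=self.a / self.b))

    def cdf(self, x):
        import scipy.stats

        if self.kind == "uniform":
            return np.clip((np.asarray(x, float) - self.a) / (self.b - self.a), 0, 1)
        if self.kind == "loguniform":
            la, lb = math.log(self.a), math.log(self.b)
            return np.clip((np.log(x) - la) / (lb - la), 0, 1)
        return scipy.stats.gamma.cdf(x, self.b, scale=self.a / self.b)

    def serialize(self) -> str:
        if self.kind == "uniform":
            return f"{self.name} ~ U[{self.a!r},{self.b!r}]"
        if self.kind == "loguniform":
            return f"{self.name} ~ LU[{self.a!r},{self.b!r}]"
        return f"{self.name} ~ G({self.a!r},{self.b!r})"


@dataclass(frozen=True)
class Condition:
    """Inequality constraint between two prior-distributed parameters."""

    left: str
    op: str  # ">" or "<"
    right: str

    def holds(self, values: dict[str, float]) -> bool:
        l, r = values[self.left], values[self.right]
        return l > r if self.op == ">" else l < r

    def serialize(self) -> str:
        return f"{self.left} {self.op} {self.right}"


@dataclass(frozen=True)
class Event:
    kind: str  # sample | merge | admix | varNe
    time: float | str
    pop: str
    source: str | None = None          # merge: population absorbed into pop
    parents: tuple[str, str] | None = None  # admix
    rate: float | str | None = None    # admix: P(lineage -> parents[0])
    size: float | str | None = None    # varNe

    def serialize(self) -> str:
        t = self.time if isinstance(self.time, str) else repr(self.time)
        if self.kind == "sample":
            return f"sample {t} {self.pop}"
        if self.kind == "merge":
            return f"merge {t} {self.pop} {self.source}"
        if self.kind == "admix":
            r = self.rate if isinstance(self.rate, str) else repr(self.rate)
            return f"admix {t} {self.pop} {self.parents[0]} {self.parents[1]} {r}"
        s = self.size if isinstance(self.size, str) else repr(self.size)
        return f"varNe {t} {self.pop} {s}"


@dataclass(frozen=True)
class SampleSpec:
    """Size and composition of the sample taken from one population."""

    pop: str
    n_individuals: int
    female_fraction: float = 0.5

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("sample size must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female fraction must be in [0,1]")


@dataclass
class Scenario:
    """One population history: populations, initial sizes and ordered events."""

    id: int
    pops: list[str]
    initial_sizes: dict[str, float | str]
    events: list[Event] = field(default_factory=list)

    def param_names(self) -> set[str]:
        names = set()
        for v in self.initial_sizes.values():
            if isinstance(v, str):
                names.add(v)
        for e in self.events:
            for v in (e.time, e.rate, e.size):
                if isinstance(v, str):
                    names.add(v)
        return names

    def sampled_pops(self) -> list[str]:
        return [e.pop for e in self.events if e.kind == "sample"]

    def serialize(self) -> str:
        lines = [f"[scenario {self.id}]"]
        lines += [
            f"pop {p} {s if isinstance(s := self.initial_sizes[p], str) else repr(s)}"
            for p in self.pops
        ]
        lines += [e.serialize() for e in self.events]
        return "\n".join(lines)


@dataclass
class Config:
    """A full parsed study configuration."""

    scenarios: list[Scenario]
    priors: dict[str, PriorSpec]
    conditions: list[Condition]
    loci: list[LocusSpec]
    samples: dict[str, SampleSpec] = field(default_factory=dict)
    population_female_fraction: float = 0.5

    def scenario(self, sid: int) -> Scenario:
        for s in self.scenarios:
            if s.id == sid:
                return s
        raise KeyError(f"no scenario with id {sid}")


# ---------------------------------------------------------------------------
# Parsing

_PRIOR_RE = re.compile(
    r"^(?P<name>\w+)\s*~\s*(?P<kind>U|LU|G)\s*[\[\(]\s*"
    r"(?P<a>[^,\]\)]+)\s*,\s*(?P<b>[^,\]\)]+)\s*[\]\)]$"
)
_COND_RE = re.compile(r"^(?P<l>\w+)\s*(?P<op>[<>])\s*(?P<r>\w+)$")
_SECTION_RE = re.compile(r"^\[(?P<head>[^\]]+)\]$")


def _num_or_name(tok: str, lineno: int, priors: dict, what: str) -> float | str:
    try:
        return float(tok)
    except ValueError:
        if tok not in priors:
            raise ParseError(lineno, f"unknown parameter name {tok!r} used as {what}")
        return tok


def parse_config(text: str) -> Config:
    """Parse a configuration file into scenarios, priors, conditions and loci."""
    priors: dict[str, PriorSpec] = {}
    conditions: list[Condition] = []
    loci: list[LocusSpec] = []
    samples: dict[str, SampleSpec] = {}
    scenarios: list[Scenario] = []
    settings = {"female_fraction": 0.5}

    section: str | None = None
    current: Scenario | None = None
    # first pass collects priors so later sections can cross-reference them,
    # but the grammar requires [priors] to come before scenario sections anyway.
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _SECTION_RE.match(line)
        if m:
            head = m.group("head").strip()
            if head.startswith("scenario"):
                try:
                    sid = int(head.split()[1])
                except (IndexError, ValueError):
                    raise ParseError(lineno, f"malformed scenario header {head!r}")
                if any(s.id == sid for s in scenarios):
                    raise ParseError(lineno, f"duplicate scenario id {sid}")
                current = Scenario(id=sid, pops=[], initial_sizes={}, events=[])
                scenarios.append(current)
                section = "scenario"
            elif head in ("priors", "conditions", "loci", "samples", "settings"):
                section = head
                current = None
            else:
                raise ParseError(lineno, f"unknown section {head!r}")
            continue

        if section == "priors":
            m = _PRIOR_RE.match(line)
            if not m:
                raise ParseError(lineno, f"malformed prior line {line!r}")
            kind = {"U": "uniform", "LU": "loguniform", "G": "gamma"}[m.group("kind")]
            name = m.group("name")
            if name in priors:
                raise ParseError(lineno, f"duplicate prior {name!r}")
            try:
                priors[name] = PriorSpec(name, kind, float(m.group("a")), float(m.group("b")))
            except ValueError as exc:
                raise ParseError(lineno, str(exc))
        elif section == "conditions":
            m = _COND_RE.match(line)
            if not m:
                raise ParseError(lineno, f"malformed condition {line!r}")
            l, r = m.group("l"), m.group("r")
            for nm in (l, r):
                if nm not in priors:
                    raise ParseError(lineno, f"unknown parameter name {nm!r} in condition")
            conditions.append(Condition(l, m.group("op"), r))
        elif section == "loci":
            loci.extend(parse_locus_line(line, lineno, set(priors), n_existing=len(loci)))
        elif section == "samples":
            toks = line.split()
            if len(toks) < 2:
                raise ParseError(lineno, f"malformed sample line {line!r}")
            pop, n = toks[0], toks[1]
            kw = {}
            for tok in toks[2:]:
                if "=" not in tok:
                    raise ParseError(lineno, f"malformed sample option {tok!r}")
                k, v = tok.split("=", 1)
                if k != "females":
                    raise ParseError(lineno, f"unknown sample option {k!r}")
                kw["female_fraction"] = float(v)
            try:
                samples[pop] = SampleSpec(pop, int(n), **kw)
            except ValueError as exc:
                raise ParseError(lineno, str(exc))
        elif section == "settings":
            if "=" not in line:
                raise ParseError(lineno, f"malformed settings line {line!r}")
            k, v = (t.strip() for t in line.split("=", 1))
            if k != "female_fraction":
                raise ParseError(lineno, f"unknown setting {k!r}")
            settings["female_fraction"] = float(v)
        elif section == "scenario":
            _parse_event_line(line, lineno, current, priors)
        else:
            raise ParseError(lineno, f"content outside any section: {line!r}")

    for s in scenarios:
        if not s.events:
            raise ParseError(None, f"scenario {s.id}: empty event list, no root reachable")
    return Config(
        scenarios=scenarios,
        priors=priors,
        conditions=conditions,
        loci=loci,
        samples=samples,
        population_female_fraction=settings["female_fraction"],
    )


def _parse_event_line(line: str, lineno: int, sc: Scenario, priors: dict) -> None:
    toks = line.split()
    kw = toks[0]
    if kw == "pop":
        if len(toks) != 3:
            raise ParseError(lineno, f"malformed pop line {line!r}")
        name = toks[1]
        if name in sc.pops:
            raise ParseError(lineno, f"duplicate population {name!r}")
        sc.pops.append(name)
        sc.initial_sizes[name] = _num_or_name(toks[2], lineno, priors, "population size")
        return
    if kw not in ("sample", "merge", "admix", "varNe"):
        raise ParseError(lineno, f"malformed event line {line!r}")
    if len(toks) < 3:
        raise ParseError(lineno, f"malformed event line {line!r}")
    time = _num_or_name(toks[1], lineno, priors, "event time")

    def pop_ref(tok):
        if tok not in sc.pops:
            raise ParseError(lineno, f"event references undeclared population {tok!r}")
        return tok

    if kw == "sample":
        if len(toks) != 3:
            raise ParseError(lineno, f"sample takes <time> <pop>: {line!r}")
        sc.events.append(Event("sample", time, pop_ref(toks[2])))
    elif kw == "merge":
        if len(toks) != 4:
            raise ParseError(lineno, f"merge takes <time> <sink> <source>: {line!r}")
        sc.events.append(Event("merge", time, pop_ref(toks[2]), source=pop_ref(toks[3])))
    elif kw == "admix":
        if len(toks) != 6:
            raise ParseError(
                lineno, f"admix takes <time> <pop> <parent1> <parent2> <rate>: {line!r}"
            )
        rate = _num_or_name(toks[5], lineno, priors, "admixture rate")
        sc.events.append(
            Event(
                "admix",
                time,
                pop_ref(toks[2]),
                parents=(pop_ref(toks[3]), pop_ref(toks[4])),
                rate=rate,
            )
        )
    else:  # varNe
        if len(toks) != 4:
            raise ParseError(lineno, f"varNe takes <time> <pop> <size>: {line!r}")
        size = _num_or_name(toks[3], lineno, priors, "population size")
        sc.events.append(Event("varNe", time, pop_ref(toks[2]), size=size))


def parse_scenario(text: str):
    """Spec-level entry point: returns (scenarios, priors, conditions, loci)."""
    cfg = parse_config(text)
    return cfg.scenarios, list(cfg.priors.values()), cfg.conditions, cfg.loci


def serialize_config(cfg: Config) -> str:
    parts = []
    if cfg.priors:
        parts.append("[priors]")
        parts += [p.serialize() for p in cfg.priors.values()]
    if cfg.conditions:
        parts.append("[conditions]")
        parts += [c.serialize() for c in cfg.conditions]
    if cfg.loci:
        parts.append("[loci]")
        parts += [l.serialize() for l in cfg.loci]
    if cfg.samples:
        parts.append("[samples]")
        parts += [
            f"{s.pop} {s.n_individuals} females={s.female_fraction!r}"
            for s in cfg.samples.values()
        ]
    parts.append("[settings]")
    parts.append(f"female_fraction={cfg.population_female_fraction!r}")
    parts += [s.serialize() for s in cfg.scenarios]
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Prior sampling

def draw_parameters(
    priors: dict[str, PriorSpec] | list[PriorSpec],
    conditions: list[Condition],
    rng: np.random.Generator,
    max_rounds: int = 100_000,
) -> dict[str, float]:
    """Draw one joint parameter vector, rejection-resampling until all
    conditions hold (this preserves the joint prior restricted to the
    condition region exactly)."""
    if not isinstance(priors, dict):
        priors = {p.name: p for p in priors}
    for _ in range(max_rounds):
        values = {name: float(p.draw(rng)) for name, p in priors.items()}
        if all(c.holds(values) for c in conditions):
            return values
    raise UnsatisfiableConditions(
        f"unsatisfiable conditions: no draw satisfied {conditions} "
        f"after {max_rounds} rounds"
    )


# ---------------------------------------------------------------------------
# Validation

def _resolve(v, values):
    return values[v] if isinstance(v, str) else float(v)


def _replay(scenario: Scenario, values: dict[str, float]) -> list[str]:
    """Apply events of one scenario under one concrete parameter vector and
    return the list of violations found."""
    out: list[str] = []
    alive = set(scenario.pops)
    resolved = []
    for order, e in enumerate(scenario.events):
        t = _resolve(e.time, values)
        if t < 0:
            out.append(f"event {e.serialize()} has negative time")
        resolved.append((t, order, e))
    resolved.sort(key=lambda x: (x[0], x[1]))  # ties applied in file order
    sampled: set[str] = set()
    for t, _, e in resolved:
        if e.kind == "sample":
            if e.pop not in alive:
                out.append(
                    f"population {e.pop!r} is sampled at {t:g} after being removed"
                )
            sampled.add(e.pop)
        elif e.kind == "merge":
            if e.source not in alive:
                out.append(f"merge at {t:g}: source {e.source!r} already removed")
            if e.pop not in alive:
                out.append(f"merge at {t:g}: sink {e.pop!r} already removed")
            alive.discard(e.source)
        elif e.kind == "admix":
            if e.pop not in alive:
                out.append(f"admix at {t:g}: population {e.pop!r} already removed")
            for p in e.parents:
                if p not in alive or p == e.pop:
                    out.append(f"admix at {t:g}: parent {p!r} not available")
            alive.discard(e.pop)
        elif e.kind == "varNe":
            if e.pop not in alive:
                out.append(f"varNe at {t:g}: population {e.pop!r} already removed")
    if len(alive) > 1:
        out.append(f"multiple roots: populations {sorted(alive)} never merge")
    return out


def validate_scenario(
    scenario: Scenario,
    priors: dict[str, PriorSpec] | None = None,
    conditions: list[Condition] | None = None,
    n_draws: int = 50,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Return a list of violations (empty = valid).

    Structural checks are deterministic; time-ordering checks are replayed
    under ``n_draws`` parameter vectors drawn from the priors subject to the
    conditions (all literal scenarios need a single replay).
    """
    diags: list[str] = []
    if not scenario.events:
        return ["empty event list, no root reachable"]
    needed = scenario.param_names()
    priors = priors or {}
    if not isinstance(priors, dict):
        priors = {p.name: p for p in priors}
    missing = needed - set(priors)
    if missing:
        return [f"parameters without prior or literal value: {sorted(missing)}"]
    if not needed:
        return sorted(set(_replay(scenario, {})))
    rng = rng or np.random.default_rng(0)
    seen: set[str] = set()
    for _ in range(n_draws):
        values = draw_parameters(priors, conditions or [], rng)
        seen.update(_replay(scenario, values))
    diags.extend(sorted(seen))
    return diags
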