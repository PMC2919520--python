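"""Coalescent simulation of gene genealogies under a demographic scenario.

One call to :func:`simulate_genealogy` produces the genealogy of one locus:
lineages enter at their sampling times (serial sampling supported), coalesce
within populations at rate k(k-1)/(2C) per generation where C is the number
of gene copies governing the locus' inheritance category, move between
populations at divergence (merge) and admixture events, and the simulation
runs backward to a single common ancestor.

The number of transmitting gene copies depends on the inheritance category
and the population female fraction f: autosomal diploid 2N, autosomal
haploid N, X-linked (1+f)N, Y-linked (1-f)N, mitochondrial fN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .loci import LocusSpec
from .scenarios import SampleSpec, Scenario

__all__ = [
    "GeneTree",
    "effective_copies",
    "sample_copy_count",
    "simulate_genealogy",
]

_EV_CODE = {"sample": _kernels.EV_SAMPLE, "merge": _kernels.EV_MERGE,
            "admix": _kernels.EV_ADMIX, "varNe": _kernels.EV_VARNE}


class NoCarriersError(ValueError):
    """A locus category has no transmitting copies under the given sex ratio."""


def effective_copies(n_diploid: float, category: str, female_fraction: float = 0.5) -> float:
    """Haploid number of gene copies governing the coalescence rate.

    ``n_diploid`` is the diploid effective population size N.
    """
    if n_diploid < 1:
        raise ValueError("effective size must be >= 1")
    f = female_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError("female fraction must be in [0,1]")
    if category == "A":
        return 2.0 * n_diploid
    if category == "H":
        return float(n_diploid)
    if category == "X":
        return (1.0 + f) * n_diploid
    if category == "Y":
        if f >= 1.0:
            raise NoCarriersError("no carriers: Y-linked locus with an all-female population")
        return (1.0 - f) * n_diploid
    if category == "M":
        if f <= 0.0:
            raise NoCarriersError("no carriers: mitochondrial locus with an all-male population")
        return f * n_diploid
    raise ValueError(f"unknown category {category!r}")


def sample_copy_count(n_individuals: int, category: str, female_fraction: float = 0.5) -> int:
    """Number of sampled gene copies contributed by ``n_individuals``."""
    if n_individuals < 1:
        raise ValueError("sample size must be >= 1")
    n_f = int(round(female_fraction * n_individuals))
    n_m = n_individuals - n_f
    if category == "A":
        n = 2 * n_individuals
    elif category == "H":
        n = n_individuals
    elif category == "X":
        n = 2 * n_f + n_m
    elif category == "Y":
        n = n_m
    elif category == "M":
        n = n_individuals
    else:
        raise ValueError(f"unknown category {category!r}")
    if n == 0:
        raise NoCarriersError(f"no sampled copies for a {category}-linked locus")
    return n


@dataclass
class GeneTree:
    """A rooted binary genealogy stored as parent pointers.

    Nodes 0..n_leaves-1 are leaves; internal nodes follow in coalescence
    order; the root has parent -1.  Times are generations before present.
    """

    parent: np.ndarray      # int64[n_nodes]
    time: np.ndarray        # float64[n_nodes]
    n_leaves: int
    leaf_sample: np.ndarray  # int64[n_leaves]: sample index of each leaf
    sample_names: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time.max())

    def validate(self) -> None:
        bl = self.branch_lengths()
        if np.any(bl[np.flatnonzero(self.parent >= 0)] < 0):
            raise ValueError("node times must increase from leaves to root")
        if np.sum(self.parent < 0) != 1:
            raise ValueError("tree must have exactly one root")

    def to_newick(self) -> str:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        out = []

        def rec(node):
            if not children[node]:
                out.append(f"{self.sample_names[self.leaf_sample[node]]}_{node}")
            else:
                out.append("(")
                for j, c in enumerate(children[node]):
                    if j:
                        out.append(",")
                    rec(c)
                out.append(")")
            p = self.parent[node]
            if p >= 0:
                out.append(f":{self.time[p] - self.time[node]:g}")

        rec(self.root)
        return "".join(out) + ";"


def _resolve(v, params: dict[str, float]) -> float:
    return params[v] if isinstance(v, str) else float(v)


def simulate_genealogy(
    scenario: Scenario,
    params: dict[str, float],
    locus: LocusSpec,
    samples: dict[str, SampleSpec],
    rng: np.random.Generator,
    population_female_fraction: float = 0.5,
) -> GeneTree:
    """Simulate one gene genealogy for ``locus`` under ``scenario``.

    ``params`` maps every parameter name used by the scenario to a value;
    ``samples`` gives the sample composition per sampled population.
    """
    f = population_female_fraction
    cat = locus.category
    pop_index = {p: i for i, p in enumerate(scenario.pops)}
    n_pops = len(scenario.pops)
    init_copies = np.empty(n_pops)
    for p, i in pop_index.items():
        init_copies[i] = effective_copies(_resolve(scenario.initial_sizes[p], params), cat, f)

    # resolve events, sorted by time with file order breaking ties
    resolved = sorted(
        ((_resolve(e.time, params), order, e) for order, e in enumerate(scenario.events)),
        key=lambda x: (x[0], x[1]),
    )
    n_ev = len(resolved)
    ev_time = np.empty(n_ev)
    ev_kind = np.empty(n_ev, np.int64)
    ev_pop = np.zeros(n_ev, np.int64)
    ev_aux = np.zeros(n_ev, np.int64)
    ev_aux2 = np.zeros(n_ev, np.int64)
    ev_val = np.zeros(n_ev)
    ev_leaf_lo = np.zeros(n_ev, np.int64)
    ev_leaf_hi = np.zeros(n_ev, np.int64)

    # samples are numbered by the order of sample events in the scenario file
    sample_order = [e.pop for e in scenario.events if e.kind == "sample"]
    sample_index = {p: i for i, p in enumerate(sample_order)}
    leaf_sample: list[int] = []
    next_leaf = 0
    for j, (t, _, e) in enumerate(resolved):
        if t < 0:
            raise ValueError(f"negative event time {t} in scenario {scenario.id}")
        ev_time[j] = t
        ev_kind[j] = _EV_CODE[e.kind]
        ev_pop[j] = pop_index[e.pop]
        if e.kind == "sample":
            spec = samples[e.pop]
            n_copies = sample_copy_count(spec.n_individuals, cat, spec.female_fraction)
            ev_leaf_lo[j] = next_leaf
            next_leaf += n_copies
            ev_leaf_hi[j] = next_leaf
            leaf_sample.extend([sample_index[e.pop]] * n_copies)
        elif e.kind == "merge":
            ev_aux[j] = pop_index[e.source]
        elif e.kind == "admix":
            ev_aux[j] = pop_index[e.parents[0]]
            ev_aux2[j] = pop_index[e.parents[1]]
            ev_val[j] = _resolve(e.rate, params)
        else:  # varNe
            ev_val[j] = effective_copies(_resolve(e.size, params), cat, f)

    seed = int(rng.integers(1 << 31))
    parent, node_time, ok = _kernels.simulate_tree_kernel(
        seed, n_pops, init_copies, ev_time, ev_kind, ev_pop, ev_aux, ev_aux2,
        ev_val, ev_leaf_lo, ev_leaf_hi,
    )
    if not ok:
        raise RuntimeError(
            f"scenario {scenario.id}: lineages never reach a common ancestor "
            "(multiple roots); run validate_scenario"
        )
    return GeneTree(
        parent=parent,
        time=node_time,
        n_leaves=next_leaf,
        leaf_sample=np.asarray(leaf_sample, np.int64),
        sample_names=sample_order,
    )
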