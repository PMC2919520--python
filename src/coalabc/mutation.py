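"""Mutation models layered on a gene genealogy.

Microsatellites follow a generalized stepwise mutation model (GSM): mutations
arrive as a Poisson process at rate mu per generation along each branch, each
changes the repeat number by +-k with k ~ Geometric(P) on {1,2,...}
(P(k) = (1-P) P^(k-1)); alleles are confined to a fixed window of contiguous
repeat states (steps that would leave it are redrawn).  An independent
Poisson process of single-nucleotide indels (SNI) in the flanking region
shifts the reported allele length off the motif lattice by +-1 nucleotide.

DNA sequences evolve under one of the JC, K2P, HKY or TN substitution
models, with an optional fraction of invariant sites and gamma-distributed
rate heterogeneity across the remaining sites.  Sequence simulation uses
uniformization of the rate matrix Q: candidate events arrive at rate
lambda = max_i |Q_ii| and apply the jump kernel I + Q/lambda (self-loops
allowed), which reproduces exp(Qt) exactly while only visiting sites that
actually receive events.  Bases are coded A, C, G, T = 0..3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import _kernels
from .coalescent import GeneTree

__all__ = [
    "MicrosatModel",
    "SequenceModel",
    "draw_locus_rates",
    "mutate_microsat",
    "substitution_probability",
    "mutate_sequence",
    "BASES",
]

BASES = "ACGT"
_TRANSITION_PAIRS = ((0, 2), (1, 3))  # A<->G, C<->T


def draw_locus_rates(
    mean_rate: float, shape: float, n_loci: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-locus rates from a Gamma with the given mean and shape
    (scale = mean/shape), the hierarchy used for locus-to-locus rate
    variation around a dataset-level mean."""
    if mean_rate <= 0:
        raise ValueError("mean rate must be > 0")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    return rng.gamma(shape, mean_rate / shape, n_loci)


# ---------------------------------------------------------------------------
# Microsatellites

@dataclass(frozen=True)
class MicrosatModel:
    """Per-locus GSM parameters (already drawn from their hierarchy)."""

    mu: float                 # mutation rate per generation
    p: float                  # geometric parameter in [0,1)
    sni_rate: float = 0.0     # flanking single-nucleotide indel rate
    range_width: int = 40     # contiguous allelic states
    motif: int = 2            # nucleotides per repeat
    ancestral_repeats: int = 50  # nominal repeat count of the root allele

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0.0 <= self.p < 1.0:
            raise ValueError("geometric parameter must be in [0,1)")
        if self.range_width < 2:
            raise ValueError("range width must be >= 2")

    @property
    def bounds(self) -> tuple[int, int]:
        lo = self.ancestral_repeats - self.range_width // 2
        return lo, lo + self.range_width - 1


def mutate_microsat(
    tree: GeneTree, model: MicrosatModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Drop GSM + SNI mutations on ``tree``; returns per-leaf
    (repeat counts, flanking offsets in nucleotides).

    Reported allele length is ``motif * repeats + offset``.
    """
    # topological order (root first) — robust to tied node times
    children = _children_lists(tree)
    order = np.empty(tree.n_nodes, np.int64)
    order[0] = tree.root
    k = 1
    for i in range(tree.n_nodes):
        for c in children[order[i]]:
            order[k] = c
            k += 1
    lo, hi = model.bounds
    seed = int(rng.integers(1 << 31))
    rep, off = _kernels.mutate_microsat_kernel(
        seed, tree.parent, tree.time, order, tree.n_leaves,
        model.mu, model.p, model.sni_rate, lo, hi, model.ancestral_repeats,
    )
    return rep, off


def allele_lengths(rep: np.ndarray, off: np.ndarray, motif: int) -> np.ndarray:
    return motif * rep + off


# ---------------------------------------------------------------------------
# Sequences

@dataclass(frozen=True)
class SequenceModel:
    """Substitution model with invariant sites and gamma rate heterogeneity.

    ``rate`` is the expected number of substitutions per (variable) site per
    generation; the rate matrix is normalized so branch distance equals
    rate x branch length in generations.
    """

    kind: str                 # JC | K2P | HKY | TN
    rate: float
    kappa: float = 2.0        # ts/tv rate ratio (K2P, HKY)
    kappa1: float = 2.0       # TN: A<->G
    kappa2: float = 2.0       # TN: C<->T
    freqs: tuple[float, float, float, float] | None = None
    invariant: float = 0.0
    gamma_shape: float | None = None

    def __post_init__(self):
        if self.kind not in ("JC", "K2P", "HKY", "TN"):
            raise ValueError(f"unknown substitution model {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not 0.0 <= self.invariant < 1.0:
            raise ValueError("invariant fraction must be in [0,1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.freqs is not None:
            f = np.asarray(self.freqs, float)
            if len(f) != 4 or abs(f.sum() - 1.0) > 1e-8 or np.any(f < 0):
                raise ValueError("base frequencies must be 4 non-negatives summing to 1")

    @property
    def pi(self) -> np.ndarray:
        if self.kind in ("JC", "K2P") or self.freqs is None:
            return np.full(4, 0.25)
        return np.asarray(self.freqs, float)

    def rate_matrix(self) -> np.ndarray:
        """Normalized instantaneous rate matrix Q (mean rate 1 at
        stationarity), so exp(Q d) is the kernel at distance d substitutions
        per site."""
        pi = self.pi
        if self.kind == "JC":
            k1 = k2 = 1.0
        elif self.kind in ("K2P", "HKY"):
            k1 = k2 = self.kappa
        else:
            k1, k2 = self.kappa1, self.kappa2
        rel = np.ones((4, 4))
        rel[0, 2] = rel[2, 0] = k1
        rel[1, 3] = rel[3, 1] = k2
        Q = rel * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale


def substitution_probability(model: SequenceModel, t: float) -> np.ndarray:
    """4x4 transition kernel over evolutionary distance ``t`` (expected
    substitutions per site).  JC and K2P use their closed forms; HKY and TN
    use the matrix exponential of the normalized rate matrix."""
    if t < 0:
        raise ValueError("distance must be >= 0")
    if model.kind == "JC":
        # P(specific different base) = (1/4)(1 - exp(-4t/3))
        q = 0.25 * (1.0 - np.exp(-4.0 * t / 3.0))
        P = np.full((4, 4), q)
        np.fill_diagonal(P, 1.0 - 3.0 * q)
        return P
    if model.kind == "K2P":
        kappa = model.kappa
        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta
        e1 = np.exp(-4.0 * beta * t)
        e2 = np.exp(-2.0 * (alpha + beta) * t)
        p_tv = 0.25 * (1.0 - e1)                 # each of two transversions
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2       # the transition
        P = np.full((4, 4), p_tv)
        for i, j in _TRANSITION_PAIRS:
            P[i, j] = P[j, i] = p_ts
        np.fill_diagonal(P, 1.0 - p_ts - 2.0 * p_tv)
        return P
    return scipy.linalg.expm(model.rate_matrix() * t)


def _children_lists(tree: GeneTree) -> list[list[int]]:
    children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children[p].append(i)
    return children


def mutate_sequence(
    tree: GeneTree, model: SequenceModel, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate aligned sequences at the leaves of ``tree``.

    The ancestral sequence is drawn from the model's stationary frequencies;
    a fraction ``invariant`` of positions (chosen once) never mutates; the
    other sites carry independent Gamma(shape, mean 1) relative rates.
    Returns a uint8 array of shape (n_leaves, length) with bases 0..3.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    pi = model.pi
    anc = rng.choice(4, size=length, p=pi).astype(np.uint8)

    n_inv = int(round(model.invariant * length))
    perm = rng.permutation(length)
    var_sites = np.sort(perm[n_inv:])
    n_var = len(var_sites)
    if model.gamma_shape is not None:
        site_rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, n_var)
    else:
        site_rates = np.ones(n_var)

    leaves_seq = np.empty((tree.n_leaves, length), np.uint8)
    total_weight = site_rates.sum()
    if model.rate <= 0 or n_var == 0 or total_weight <= 0:
        leaves_seq[:] = anc
        return leaves_seq

    Q = model.rate_matrix()
    lam = float(np.max(-np.diag(Q)))
    jump = np.eye(4) + Q / lam
    cum_jump = np.cumsum(jump, axis=1)
    cum_jump[:, -1] = 1.0

    # Poisson number of candidate events per branch, sites weighted by rate
    blen = tree.branch_lengths()
    nu = lam * model.rate * blen * total_weight
    n_events = rng.poisson(nu)
    events_by_node: list[np.ndarray] = [np.empty(0, np.int64)] * tree.n_nodes
    total = int(n_events.sum())
    if total:
        # one weighted draw for all events; the split per branch is valid
        # because event sites are i.i.d. given the counts
        p_site = site_rates / total_weight
        sites_all = var_sites[rng.choice(n_var, size=total, p=p_site)]
        offsets = np.concatenate([[0], np.cumsum(n_events)])
        for node in np.flatnonzero(n_events):
            events_by_node[node] = sites_all[offsets[node]:offsets[node + 1]]
        u_all = iter(rng.random(total))

    # depth-first walk applying branch events on entry, undoing them on exit
    children = _children_lists(tree)
    seq = anc.copy()
    undo_by_node: dict[int, list[tuple[int, int]]] = {}
    stack: list[tuple[int, bool]] = [(tree.root, False)]
    while stack:
        node, exiting = stack.pop()
        if exiting:
            for site, old in reversed(undo_by_node.pop(node)):
                seq[site] = old
            continue
        undo: list[tuple[int, int]] = []
        for site in events_by_node[node]:
            old = seq[site]
            new = int(np.searchsorted(cum_jump[old], next(u_all), side="right"))
            undo.append((site, int(old)))
            seq[site] = new
        if children[node]:
            undo_by_node[node] = undo
            stack.append((node, True))
            for c in children[node]:
                stack.append((c, False))
        else:
            leaves_seq[node] = seq
            for site, old in reversed(undo):
                seq[site] = old
    return leaves_seq
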