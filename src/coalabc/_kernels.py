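"""Numba inner loops: event-driven coalescent and stepwise-mutation walks.

These are free functions on flat arrays so that they compile in nopython
mode; all orchestration (resolving scenario events to numeric arrays,
seeding, building GeneTree objects) lives in :mod:`coalabc.coalescent` and
:mod:`coalabc.mutation`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event kinds
EV_SAMPLE = 0
EV_MERGE = 1
EV_ADMIX = 2
EV_VARNE = 3


@njit(cache=True)
def simulate_tree_kernel(
    seed,
    n_pops,
    init_copies,   # float64[n_pops] gene copies per population at time 0
    ev_time,       # float64[n_ev] ascending (ties keep file order)
    ev_kind,       # int64[n_ev]
    ev_pop,        # int64[n_ev]
    ev_aux,        # int64[n_ev]  merge source / admix parent1
    ev_aux2,       # int64[n_ev]  admix parent2
    ev_val,        # float64[n_ev] admix rate / varNe copies
    ev_leaf_lo,    # int64[n_ev]  leaf range activated by a sample event
    ev_leaf_hi,
):
    """Simulate one genealogy; returns (parent, node_time, ok).

    Continuous-time coalescent within each inter-event epoch: with k lineages
    in a population of C gene copies, pairs coalesce at rate k(k-1)/(2C) per
    generation.  Lineages enter at sample events, move wholesale at merges,
    split by independent Bernoulli draws at admixtures, and the copy count
    jumps at varNe events.  After the last event the (single) remaining
    population is run to its most recent common ancestor.
    """
    np.random.seed(seed)
    n_leaves = 0
    for i in range(len(ev_kind)):
        if ev_kind[i] == EV_SAMPLE:
            n_leaves += ev_leaf_hi[i] - ev_leaf_lo[i]
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, np.int64)
    node_time = np.zeros(n_nodes, np.float64)

    copies = init_copies.copy()
    k = np.zeros(n_pops, np.int64)          # active lineages per population
    lin_node = np.empty(n_nodes, np.int64)  # active lineage -> node id
    lin_pop = np.empty(n_nodes, np.int64)
    n_act = 0
    next_node = n_leaves
    t = 0.0

    for iev in range(len(ev_kind) + 1):
        t_next = ev_time[iev] if iev < len(ev_kind) else np.inf
        # ---- coalescence phase on [t, t_next)
        while True:
            total = 0.0
            for p in range(n_pops):
                if k[p] > 1:
                    total += k[p] * (k[p] - 1) / (2.0 * copies[p])
            if total <= 0.0:
                t = t_next
                break
            dt = np.random.exponential(1.0 / total)
            if t + dt >= t_next:
                t = t_next
                break
            t += dt
            u = np.random.random() * total
            acc = 0.0
            pop = -1
            for p in range(n_pops):
                if k[p] > 1:
                    acc += k[p] * (k[p] - 1) / (2.0 * copies[p])
                    if u < acc:
                        pop = p
                        break
            if pop < 0:
                pop = n_pops - 1
            # choose two distinct lineages of `pop`
            i1 = np.random.randint(k[pop])
            i2 = np.random.randint(k[pop] - 1)
            if i2 >= i1:
                i2 += 1
            a = -1
            b = -1
            seen = 0
            for j in range(n_act):
                if lin_pop[j] == pop:
                    if seen == i1:
                        a = j
                    if seen == i2:
                        b = j
                    seen += 1
            node = next_node
            next_node += 1
            node_time[node] = t
            parent[lin_node[a]] = node
            parent[lin_node[b]] = node
            lin_node[a] = node
            lin_node[b] = lin_node[n_act - 1]
            lin_pop[b] = lin_pop[n_act - 1]
            n_act -= 1
            k[pop] -= 1
            if next_node == n_nodes:  # all coalescences done (serial samples included)
                return parent, node_time, True
        if iev == len(ev_kind):
            break
        # ---- apply the event
        kind = ev_kind[iev]
        p = ev_pop[iev]
        if kind == EV_SAMPLE:
            for leaf in range(ev_leaf_lo[iev], ev_leaf_hi[iev]):
                lin_node[n_act] = leaf
                lin_pop[n_act] = p
                node_time[leaf] = t
                n_act += 1
                k[p] += 1
        elif kind == EV_MERGE:
            src = ev_aux[iev]
            for j in range(n_act):
                if lin_pop[j] == src:
                    lin_pop[j] = p
                    k[src] -= 1
                    k[p] += 1
        elif kind == EV_ADMIX:
            p1 = ev_aux[iev]
            p2 = ev_aux2[iev]
            r = ev_val[iev]
            for j in range(n_act):
                if lin_pop[j] == p:
                    dst = p1 if np.random.random() < r else p2
                    lin_pop[j] = dst
                    k[p] -= 1
                    k[dst] += 1
        else:  # EV_VARNE
            copies[p] = ev_val[iev]
    # ran out of events without reaching a single lineage
    if next_node == n_nodes:
        return parent, node_time, True
    return parent, node_time, False


@njit(cache=True)
def mutate_microsat_kernel(
    seed,
    parent,       # int64[n_nodes]
    node_time,    # float64[n_nodes]
    order_desc,   # node ids in topological order (root first)
    n_leaves,
    mu,           # per-generation GSM rate for this locus
    p_geo,        # geometric parameter of the step-length distribution
    sni_rate,     # per-generation flanking-indel rate
    rep_lo,
    rep_hi,
    rep_anc,
):
    """Walk the tree root-to-leaves placing GSM and SNI mutations.

    GSM: Poisson(mu * branch) mutations, step length k ~ Geometric(p_geo) on
    {1,2,...} with P(k) = (1-p)p^(k-1), direction uniform; steps leaving
    [rep_lo, rep_hi] are redrawn.  SNI: Poisson(sni * branch) events each
    adding +-1 nucleotide to the flanking offset (unbounded).
    """
    np.random.seed(seed)
    n_nodes = len(parent)
    rep = np.empty(n_nodes, np.int64)
    off = np.zeros(n_nodes, np.int64)
    for idx in order_desc:
        pa = parent[idx]
        if pa < 0:
            rep[idx] = rep_anc
            off[idx] = 0
            continue
        blen = node_time[pa] - node_time[idx]
        r = rep[pa]
        o = off[pa]
        nmut = np.random.poisson(mu * blen)
        for _ in range(nmut):
            while True:
                step = np.random.geometric(1.0 - p_geo)
                if np.random.random() < 0.5:
                    step = -step
                nr = r + step
                if rep_lo <= nr <= rep_hi:
                    r = nr
                    break
        nsni = np.random.poisson(sni_rate * blen)
        for _ in range(nsni):
            if np.random.random() < 0.5:
                o += 1
            else:
                o -= 1
        rep[idx] = r
        off[idx] = o
    return rep[:n_leaves], off[:n_leaves]
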