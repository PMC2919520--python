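"""Independent brute-force reimplementations used as oracles in tests.

Everything here is written with plain double loops and dictionaries, on
purpose: these functions define the statistics directly from their
definitions and stay independent of the vectorized production code paths.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

MISSING = -1


def naive_within(alleles, motif):
    a = [x for x in alleles if x != MISSING]
    n = len(a)
    cnt = Counter(a)
    k = len(cnt)
    if k == 1:
        return {"NAL": 1.0, "HET": 0.0, "VAR": 0.0, "MGW": 1.0}
    het = (n / (n - 1)) * (1 - sum((c / n) ** 2 for c in cnt.values()))
    mean = sum(a) / n
    var = sum((x - mean) ** 2 for x in a) / (n - 1)
    span = (max(a) - min(a)) // motif + 1
    return {"NAL": float(k), "HET": het, "VAR": var, "MGW": k / span}


def naive_wc_fst_components(a, b):
    a = [x for x in a if x != MISSING]
    b = [x for x in b if x != MISSING]
    n1, n2 = len(a), len(b)
    ntot = n1 + n2
    nc = (ntot - (n1 ** 2 + n2 ** 2) / ntot) / 1
    num = den = 0.0
    for v in sorted(set(a) | set(b)):
        p1 = sum(1 for x in a if x == v) / n1
        p2 = sum(1 for x in b if x == v) / n2
        pbar = (n1 * p1 + n2 * p2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        num += msp - msg
        den += msp + (nc - 1) * msg
    return num, den


def naive_between(a, b, motif):
    a = [x for x in a if x != MISSING]
    b = [x for x in b if x != MISSING]
    n1, n2 = len(a), len(b)
    num, den = naive_wc_fst_components(a, b)
    dm2 = (sum(a) / n1 - sum(b) / n2) ** 2
    h2p = naive_within(a + b, motif)["HET"]
    # shared-allele proportion over all cross-sample copy pairs
    share = 0.0
    for x in a:
        for y in b:
            share += 1.0 if x == y else 0.0
    das = 1.0 - share / (n1 * n2)
    return {"FST_NUM": num, "FST_DEN": den, "DM2": dm2, "H2P": h2p, "DAS": das}


def naive_lik(individuals, ref_alleles, diploid):
    ref = [x for x in ref_alleles if x != MISSING]
    n_ref = len(ref)
    cnt = Counter(ref)

    def freq(al):
        c = cnt.get(al, 0)
        return c / n_ref if c > 0 else 1.0 / (n_ref + 1)

    tot = 0.0
    for ind in individuals:
        copies = [x for x in ind if x != MISSING]
        if not copies:
            continue
        if diploid and len(copies) == 2:
            x, y = copies
            lik = freq(x) ** 2 if x == y else 2 * freq(x) * freq(y)
            tot += -math.log(lik)
        else:
            for x in copies:
                tot += -math.log(freq(x))
    return tot / max(len(individuals), 1)


def naive_seq_within(seqs):
    n, L = seqs.shape
    nha = len({tuple(s) for s in map(tuple, seqs)})
    nss = sum(1 for j in range(L) if len({seqs[i, j] for i in range(n)}) > 1)
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int(np.sum(seqs[i] != seqs[j])))
    mpd = sum(diffs) / len(diffs)
    if len(diffs) > 1:
        m = mpd
        vpd = sum((d - m) ** 2 for d in diffs) / (len(diffs) - 1)
    else:
        vpd = 0.0
    return {"NHA": float(nha), "NSS": float(nss), "MPD": mpd, "VPD": vpd}


def naive_seq_between(sa, sb):
    pooled = np.concatenate([sa, sb])
    w = naive_seq_within(pooled)
    within = []
    for block in (sa, sb):
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                within.append(int(np.sum(block[i] != block[j])))
    between = [
        int(np.sum(x != y)) for x in sa for y in sb
    ]
    pi_b = sum(between) / len(between)
    fsq = 0.0 if pi_b <= 0 else max(0.0, 1.0 - (sum(within) / len(within)) / pi_b)
    return {"NHA2P": w["NHA"], "NSS2P": w["NSS"], "FSQ": fsq}


def naive_summarize(dataset, selection_names):
    """Recompute a named statistic vector directly from its definitions.

    ``selection_names`` must be fully-expanded names as produced by
    summarize_dataset; returns a dict name -> value.
    """
    sample_names = [s.name for s in dataset.samples]
    pos = {s: i for i, s in enumerate(sample_names)}
    groups = {}
    for loc in dataset.loci:
        groups.setdefault(loc.group, []).append(loc)
    out = {}
    for name in selection_names:
        parts = name.split("_")
        fam = parts[0]
        rest = parts[1:]
        group = "MIC"
        if rest and rest[-1] in groups and rest[-1] not in pos:
            group = rest[-1]
            rest = rest[:-1]
        samples = [pos[s] for s in rest]
        vals = []
        fst_num = fst_den = 0.0
        for loc in groups[group]:
            by_sample = {}
            for i in samples:
                by_sample[i] = [loc.data[c] for c in np.flatnonzero(loc.sample_index == i)]
            if fam in ("NAL", "HET", "VAR", "MGW"):
                vals.append(naive_within(by_sample[samples[0]], loc.motif)[fam])
            elif fam in ("FST", "DM2", "H2P", "DAS"):
                r = naive_between(by_sample[samples[0]], by_sample[samples[1]], loc.motif)
                if fam == "FST":
                    fst_num += r["FST_NUM"]
                    fst_den += r["FST_DEN"]
                else:
                    vals.append(r[fam])
            elif fam == "LIK":
                i, j = samples
                inds = _naive_individuals(loc, i, dataset)
                vals.append(
                    naive_lik(inds, by_sample[j], diploid=loc.category in ("A", "X"))
                )
            elif fam in ("NHA", "NSS", "MPD", "VPD"):
                rows = np.flatnonzero(loc.sample_index == samples[0])
                vals.append(naive_seq_within(loc.data[rows])[fam])
            elif fam in ("NHA2P", "NSS2P", "FSQ"):
                ra = np.flatnonzero(loc.sample_index == samples[0])
                rb = np.flatnonzero(loc.sample_index == samples[1])
                vals.append(naive_seq_between(loc.data[ra], loc.data[rb])[fam])
            else:
                raise ValueError(fam)
        if fam == "FST":
            out[name] = fst_num / fst_den if fst_den else 0.0
        elif fam == "LIK":
            out[name] = float(sum(vals))
        else:
            out[name] = float(np.mean(vals))
    return out


def _naive_individuals(loc, sample, dataset):
    idx = list(np.flatnonzero(loc.sample_index == sample))
    n_ind = dataset.samples[sample].n_individuals
    if loc.category == "A":
        return [[loc.data[idx[2 * i]], loc.data[idx[2 * i + 1]]] for i in range(len(idx) // 2)]
    if loc.category == "X":
        n_pairs = len(idx) - n_ind
        groups = [[loc.data[idx[2 * i]], loc.data[idx[2 * i + 1]]] for i in range(n_pairs)]
        groups += [[loc.data[c]] for c in idx[2 * n_pairs:]]
        return groups
    return [[loc.data[c]] for c in idx]


def wright_fisher_tmrca(n_sample, pop_size, rng, max_gen=10_000_000):
    """Discrete-generation haploid Wright-Fisher TMRCA for a sample of
    ``n_sample`` copies in a population of ``pop_size`` copies (oracle)."""
    lineages = list(range(n_sample))
    t = 0
    while len(lineages) > 1 and t < max_gen:
        t += 1
        parents = rng.integers(0, pop_size, size=len(lineages))
        lineages = list(set(parents.tolist()))
    return t
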