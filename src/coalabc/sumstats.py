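"""Summary statistics of multimarker genetic datasets.

Statistics are computed per locus and averaged over loci grouped by marker
category: ``MIC`` autosomal microsatellites (``MICX`` etc. for other
inheritance categories), ``NUC`` nuclear DNA sequences, ``MT`` the
mitochondrial sequence.  Families:

microsatellites
    within-sample: NAL (mean allele number), HET (unbiased expected
    heterozygosity), VAR (allele-length variance), MGW (Garza-Williamson
    ratio of allele number to the allelic span in motif units);
    between samples: FST (Weir-Cockerham variance components on gene
    copies), DM2 (squared difference of mean allele size, (delta mu)^2),
    H2P (pooled heterozygosity), DAS (1 - shared-allele proportion of
    cross-sample copy pairs), LIK (mean -ln multilocus genotype likelihood
    of one sample under the other's allele frequencies, directional);
    ADM (maximum-likelihood admixture proportion, needs an explicit
    parent1/parent2/admixed triplet).

sequences
    within-sample: NHA (distinct haplotypes), NSS (segregating sites), MPD
    (mean pairwise differences), VPD (variance of pairwise differences);
    by pooled pair: NHA2P, NSS2P, FSQ (1 - pi_within/pi_between, floored at
    0); ADM as for microsatellites, on haplotype frequencies.

Statistic names are ``FAMILY_sample[_sample...]`` plus a group suffix for
non-``MIC`` groups (e.g. ``MPD_1_MT``).  A selection may list bare families
(expanded over every group and sample combination), family+group tokens, or
fully qualified names; the emitted vector order is canonical and independent
of selection order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "Locus",
    "GenotypeDataset",
    "microsat_within",
    "microsat_between",
    "admixture_mle",
    "seq_within",
    "seq_between",
    "summarize_dataset",
    "AdmixtureEstimate",
]

MISSING = -1

_MIC_FAMILIES = ("NAL", "HET", "VAR", "MGW", "FST", "DM2", "H2P", "DAS", "LIK", "ADM")
_SEQ_FAMILIES = ("NHA", "NSS", "MPD", "VPD", "NHA2P", "NSS2P", "FSQ", "ADM")
_WITHIN = {"NAL", "HET", "VAR", "MGW", "NHA", "NSS", "MPD", "VPD"}
_PAIRED = {"FST", "DM2", "H2P", "DAS", "NHA2P", "NSS2P", "FSQ"}
_ORDERED_PAIR = {"LIK"}
_TRIPLET = {"ADM"}


@dataclass(frozen=True)
class SampleInfo:
    name: str
    time: float = 0.0
    n_individuals: int = 0
    female_fraction: float = 0.5


@dataclass
class Locus:
    """One locus of a dataset.

    ``data`` is an int array of allele lengths per gene copy (microsatellite,
    -1 = missing) or a uint8 matrix (copies x sites) of bases 0..3
    (sequence).  ``sample_index`` maps each copy to its sample.  For diploid
    categories consecutive copy pairs within a sample form one individual
    (X-linked: female pairs first, then single male copies).
    """

    name: str
    category: str
    kind: str
    data: np.ndarray
    sample_index: np.ndarray
    motif: int = 2

    @property
    def group(self) -> str:
        if self.kind == "microsat":
            return "MIC" if self.category == "A" else f"MIC{self.category}"
        return "MT" if self.category == "M" else "NUC"

    def copies_of(self, sample: int) -> np.ndarray:
        return np.flatnonzero(self.sample_index == sample)


@dataclass
class GenotypeDataset:
    """Per-sample, per-locus alleles and sequences."""

    samples: list[SampleInfo]
    loci: list[Locus] = field(default_factory=list)

    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def groups(self) -> dict[str, list[Locus]]:
        out: dict[str, list[Locus]] = {}
        for loc in self.loci:
            out.setdefault(loc.group, []).append(loc)
        return out


# ---------------------------------------------------------------------------
# Microsatellite statistics (single locus; callers average over loci)

def microsat_within(alleles: np.ndarray, motif: int = 2) -> dict[str, float]:
    """NAL, HET, VAR, MGW for the gene copies of one sample at one locus."""
    a = alleles[alleles != MISSING]
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    vals, counts = np.unique(a, return_counts=True)
    k = len(vals)
    if k == 1:
        return {"NAL": 1.0, "HET": 0.0, "VAR": 0.0, "MGW": 1.0}
    p = counts / n
    het = n / (n - 1) * (1.0 - np.sum(p * p))
    var = float(np.var(a, ddof=1))
    span = int(vals.max() - vals.min()) // motif + 1
    return {"NAL": float(k), "HET": float(het), "VAR": var, "MGW": k / span}


def _wc_components(a1: np.ndarray, a2: np.ndarray) -> tuple[float, float]:
    """Weir-Cockerham theta numerator/denominator sums over alleles for one
    locus, treating gene copies as haploid samples from 2 populations."""
    a1 = a1[a1 != MISSING]
    a2 = a2[a2 != MISSING]
    n1, n2 = len(a1), len(a2)
    ntot = n1 + n2
    r = 2
    nc = (ntot - (n1 * n1 + n2 * n2) / ntot) / (r - 1)
    vals = np.union1d(a1, a2)
    num = den = 0.0
    for v in vals:
        p1 = np.mean(a1 == v)
        p2 = np.mean(a2 == v)
        pbar = (n1 * p1 + n2 * p2) / ntot
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - r)
        num += msp - msg
        den += msp + (nc - 1) * msg
    return num, den


def _pair_freq_tables(a1, a2):
    a1 = a1[a1 != MISSING]
    a2 = a2[a2 != MISSING]
    vals = np.union1d(a1, a2)
    c1 = np.array([(a1 == v).sum() for v in vals])
    c2 = np.array([(a2 == v).sum() for v in vals])
    return vals, c1, c2


def _neg_log_genotype_lik(
    copies: np.ndarray, vals: np.ndarray, counts: np.ndarray, n_ref: int, diploid: bool
) -> float:
    """-ln likelihood of one individual's genotype at one locus under the
    reference frequencies (add-one pseudo-copy for unseen alleles)."""
    idx = {int(v): c for v, c in zip(vals, counts)}

    def freq(al):
        c = idx.get(int(al), 0)
        return c / n_ref if c > 0 else 1.0 / (n_ref + 1)

    copies = copies[copies != MISSING]
    if len(copies) == 0:
        return 0.0
    if diploid and len(copies) == 2:
        a, b = copies
        if a == b:
            return -math.log(freq(a) ** 2)
        return -math.log(2.0 * freq(a) * freq(b))
    return -sum(math.log(freq(a)) for a in copies)


def microsat_between(
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    motif: int = 2,
    individuals_a: list[np.ndarray] | None = None,
    individuals_b: list[np.ndarray] | None = None,
    diploid: bool = True,
) -> dict[str, float]:
    """Pairwise statistics for one locus: FST components, DM2, H2P, DAS and
    (if individual groupings are given) LIK in both directions.

    FST is returned as ``FST_NUM``/``FST_DEN`` variance-component sums so the
    caller can combine loci as a ratio of sums.
    """
    a = alleles_a[alleles_a != MISSING]
    b = alleles_b[alleles_b != MISSING]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 gene copies per sample")
    out: dict[str, float] = {}
    num, den = _wc_components(a, b)
    out["FST_NUM"], out["FST_DEN"] = num, den
    out["DM2"] = float((a.mean() - b.mean()) ** 2)
    pooled = np.concatenate([a, b])
    out["H2P"] = microsat_within(pooled, motif)["HET"]
    vals, c1, c2 = _pair_freq_tables(a, b)
    out["DAS"] = float(1.0 - np.sum((c1 / len(a)) * (c2 / len(b))))
    if individuals_a is not None:
        va, ca = np.unique(a, return_counts=True)
        vb, cb = np.unique(b, return_counts=True)
        out["LIK_AB"] = float(
            np.mean([
                _neg_log_genotype_lik(ind, vb, cb, len(b), diploid)
                for ind in individuals_a
            ])
        )
        out["LIK_BA"] = float(
            np.mean([
                _neg_log_genotype_lik(ind, va, ca, len(a), diploid)
                for ind in individuals_b
            ])
        )
    return out


class AdmixtureEstimate(NamedTuple):
    r: float
    degenerate: bool


def admixture_mle(
    parent1_freqs: list[tuple[np.ndarray, np.ndarray]],
    parent2_freqs: list[tuple[np.ndarray, np.ndarray]],
    admixed_counts: list[tuple[np.ndarray, np.ndarray]],
    grid: int = 1001,
    tol: float = 1e-6,
) -> AdmixtureEstimate:
    """Maximum-likelihood admixture proportion r of parent 1.

    Each argument is a per-locus list of ``(allele_values, counts)`` tables;
    the admixed sample's allele counts are modelled as multinomial with
    frequencies ``r p1 + (1-r) p2``.  Maximized by a dense grid followed by
    golden-section refinement.  If the parents are indistinguishable at
    every locus the MLE is undefined; returns 0.5 with ``degenerate=True``.
    """
    # align tables per locus on the union of observed alleles
    loci = []
    distinguishable = False
    for (v1, c1), (v2, c2), (vm, cm) in zip(parent1_freqs, parent2_freqs, admixed_counts):
        vals = np.union1d(np.union1d(v1, v2), vm)
        n1, n2 = max(c1.sum(), 1), max(c2.sum(), 1)

        def table(v, c, vals, n):
            out = np.zeros(len(vals))
            pos = np.searchsorted(vals, v)
            out[pos] = c / n
            return out

        p1 = table(v1, c1, vals, n1)
        p2 = table(v2, c2, vals, n2)
        m = table(vm, cm, vals, 1.0)  # raw counts
        # add-one pseudo-copy for alleles unseen in a parent but present in
        # the admixed sample, so the likelihood stays finite
        need = m > 0
        p1 = np.where(need & (p1 == 0), 1.0 / (n1 + 1), p1)
        p2 = np.where(need & (p2 == 0), 1.0 / (n2 + 1), p2)
        if np.any(np.abs(p1 - p2) > 1e-12):
            distinguishable = True
        loci.append((p1, p2, m))

    if not distinguishable:
        return AdmixtureEstimate(0.5, True)

    def loglik(r):
        ll = 0.0
        for p1, p2, m in loci:
            mix = r * p1 + (1.0 - r) * p2
            obs = m > 0
            ll += float(np.sum(m[obs] * np.log(mix[obs])))
        return ll

    rs = np.linspace(0.0, 1.0, grid)
    lls = np.array([loglik(r) for r in rs])
    i = int(np.argmax(lls))
    lo = rs[max(i - 1, 0)]
    hi = rs[min(i + 1, grid - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = loglik(c), loglik(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = loglik(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = loglik(d)
    return AdmixtureEstimate(0.5 * (a + b), False)


# ---------------------------------------------------------------------------
# Sequence statistics (single locus)

def _variable_columns(seqs: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.any(seqs != seqs[0], axis=0))


def _pairwise_diff_matrix(seqs: np.ndarray) -> np.ndarray:
    """Hamming distances between all sequence pairs, computed on the
    segregating columns only."""
    var = _variable_columns(seqs)
    if len(var) == 0:
        return np.zeros((len(seqs), len(seqs)), np.int64)
    sub = seqs[:, var]
    return (sub[:, None, :] != sub[None, :, :]).sum(axis=2)


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _upper(vals: np.ndarray) -> np.ndarray:
    n = len(vals)
    iu = _TRIU_CACHE.get(n)
    if iu is None:
        iu = _TRIU_CACHE[n] = np.triu_indices(n, k=1)
    return vals[iu]


def seq_within(seqs: np.ndarray) -> dict[str, float]:
    """NHA, NSS, MPD, VPD for one sample at one sequence locus."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    var = _variable_columns(seqs)
    nss = len(var)
    if nss == 0:
        return {"NHA": 1.0, "NSS": 0.0, "MPD": 0.0, "VPD": 0.0}
    sub = np.ascontiguousarray(seqs[:, var])
    nha = len(np.unique(sub, axis=0))
    diffs = _upper((sub[:, None, :] != sub[None, :, :]).sum(axis=2))
    mpd = float(diffs.mean())
    vpd = float(diffs.var(ddof=1)) if len(diffs) > 1 else 0.0
    return {"NHA": float(nha), "NSS": float(nss), "MPD": mpd, "VPD": vpd}


def seq_between(seqs_a: np.ndarray, seqs_b: np.ndarray) -> dict[str, float]:
    """Pooled NHA/NSS and Hudson-style FST for one pair of samples.

    FSQ = 1 - (mean within-sample pairwise differences, both samples pooled)
    / (mean between-sample pairwise differences), floored at 0; zero
    between-sample diversity gives 0 by convention.
    """
    if len(seqs_a) < 2 or len(seqs_b) < 2:
        raise ValueError("need at least 2 sequences per sample")
    pooled = np.concatenate([seqs_a, seqs_b], axis=0)
    w = seq_within(pooled)
    na = len(seqs_a)
    D = _pairwise_diff_matrix(pooled)
    within = np.concatenate([_upper(D[:na, :na]), _upper(D[na:, na:])])
    between = D[:na, na:].ravel()
    pi_b = between.mean()
    if pi_b <= 0:
        fsq = 0.0
    else:
        fsq = max(0.0, 1.0 - within.mean() / pi_b)
    return {"NHA2P": w["NHA"], "NSS2P": w["NSS"], "FSQ": float(fsq)}


# ---------------------------------------------------------------------------
# Dataset-level vector

def _individual_groups(locus: Locus, sample: int, n_individuals: int) -> list[np.ndarray]:
    """Copy indices grouped by individual for LIK (diploid pairs for A/X
    females, singletons for haploid categories)."""
    idx = locus.copies_of(sample)
    if locus.category == "A":
        return [idx[2 * i: 2 * i + 2] for i in range(len(idx) // 2)]
    if locus.category == "X":
        # female pairs first, then male singletons
        n_pairs = len(idx) - n_individuals
        groups = [idx[2 * i: 2 * i + 2] for i in range(n_pairs)]
        groups += [idx[2 * n_pairs + j: 2 * n_pairs + j + 1] for j in range(len(idx) - 2 * n_pairs)]
        return groups
    return [idx[i: i + 1] for i in range(len(idx))]


def _canonical_names(
    family: str, group: str, sample_names: list[str], requested: set | None
) -> list[tuple[str, tuple[int, ...]]]:
    """Expand one family within one group to (name, sample index tuple)."""
    suffix = "" if group == "MIC" else f"_{group}"
    out = []
    ns = len(sample_names)
    if family in _WITHIN:
        combos = [(i,) for i in range(ns)]
    elif family in _PAIRED:
        combos = list(itertools.combinations(range(ns), 2))
    elif family in _ORDERED_PAIR:
        combos = list(itertools.permutations(range(ns), 2))
    else:  # triplet families are only emitted when explicitly requested
        combos = []
    for combo in combos:
        name = family + "_" + "_".join(sample_names[i] for i in combo) + suffix
        if requested is None or name in requested or family in requested:
            out.append((name, combo))
    return out


def _parse_selection(
    selection: list[str], groups: list[str], sample_names: list[str]
) -> tuple[set, dict[str, list[tuple[str, str, tuple[int, ...]]]]]:
    """Resolve a selection into concrete statistics per group.

    Returns the set of loosely-requested tokens and an ordered mapping
    group -> list of (name, family, sample index combo).
    """
    sample_pos = {s: i for i, s in enumerate(sample_names)}
    loose: set[str] = set()
    explicit: list[tuple[str, str, tuple[int, ...]]] = []  # (family, group, combo)
    for token in selection:
        parts = token.split("_")
        family = parts[0]
        if family not in _MIC_FAMILIES and family not in _SEQ_FAMILIES:
            raise ValueError(f"unknown statistic family {family!r} in {token!r}")
        rest = parts[1:]
        group = None
        if rest and rest[-1] in groups and rest[-1] not in sample_pos:
            group = rest[-1]
            rest = rest[:-1]
        if not rest:
            # bare family (optionally group-qualified)
            applicable = []
            for g in [group] if group else groups:
                fams = _MIC_FAMILIES if g.startswith("MIC") else _SEQ_FAMILIES
                if family in fams and family not in _TRIPLET:
                    applicable.append(g)
            if not applicable:
                raise ValueError(
                    f"statistic {token!r} requires loci of a category absent "
                    "from this dataset"
                )
            loose.add(token if group else family)
            continue
        combo = []
        for s in rest:
            if s not in sample_pos:
                raise ValueError(f"statistic {token!r} references unknown sample {s!r}")
            combo.append(sample_pos[s])
        if group is None:
            group = "MIC"
        if group not in groups:
            raise ValueError(
                f"statistic {token!r} requires loci of group {group!r} absent "
                "from this dataset"
            )
        fams = _MIC_FAMILIES if group.startswith("MIC") else _SEQ_FAMILIES
        if family not in fams:
            raise ValueError(f"statistic family {family!r} not defined for group {group!r}")
        n_needed = 1 if family in _WITHIN else 2 if family in (_PAIRED | _ORDERED_PAIR) else 3
        if len(combo) != n_needed:
            raise ValueError(f"statistic {token!r}: expected {n_needed} sample names")
        explicit.append((family, group, tuple(combo)))
    per_group: dict[str, list[tuple[str, str, tuple[int, ...]]]] = {}
    for g in groups:
        fams = _MIC_FAMILIES if g.startswith("MIC") else _SEQ_FAMILIES
        suffix = "" if g == "MIC" else f"_{g}"
        entries = []
        for family in fams:
            req = {t for t in loose if t == family or t == f"{family}_{g}"}
            combos = []
            if req:
                combos = _canonical_names(family, g, sample_names, None)
            for fam2, g2, combo in explicit:
                if fam2 == family and g2 == g:
                    name = family + "_" + "_".join(sample_names[i] for i in combo) + suffix
                    if (name, combo) not in combos:
                        combos.append((name, combo))
            entries.extend((name, family, combo) for name, combo in combos)
        per_group[g] = entries
    return loose, per_group


def summarize_dataset(dataset: GenotypeDataset, selection: list[str]) -> pd.Series:
    """Compute the selected statistics, averaged over loci within each
    group, as a named vector with deterministic order."""
    sample_names = dataset.sample_names()
    groups = dataset.groups()
    _, per_group = _parse_selection(selection, list(groups), sample_names)

    values: dict[str, float] = {}
    order: list[str] = []
    for gname, entries in per_group.items():
        if not entries:
            continue
        loci = groups[gname]
        need_fams = {fam for _, fam, _ in entries}
        if (
            len(loci) > 1
            and all(l.kind == "microsat" and l.category == "A" for l in loci)
            and all(np.array_equal(l.sample_index, loci[0].sample_index) for l in loci)
            and not np.any(np.concatenate([l.data for l in loci]) == MISSING)
            and len({l.motif for l in loci}) == 1
        ):
            per_locus = _batch_microsat_stats(loci, need_fams, entries, dataset)
        else:
            per_locus = [_locus_stats(loc, need_fams, entries, dataset) for loc in loci]
        for name, family, combo in entries:
            if family == "FST":
                num = sum(d[("FST_NUM", combo)] for d in per_locus)
                den = sum(d[("FST_DEN", combo)] for d in per_locus)
                values[name] = num / den if den != 0 else 0.0
            elif family == "LIK":
                # multilocus -ln likelihood: summed over loci
                values[name] = float(np.sum([d[(family, combo)] for d in per_locus]))
            else:
                values[name] = float(np.mean([d[(family, combo)] for d in per_locus]))
            order.append(name)
    return pd.Series([values[n] for n in order], index=order, dtype=float)


def _batch_microsat_stats(loci, families, entries, dataset) -> list[dict]:
    """Vectorized equivalent of :func:`_locus_stats` for a block of
    complete autosomal microsatellite loci sharing one copy layout."""
    L = len(loci)
    motif = loci[0].motif
    A = np.stack([l.data for l in loci])          # (L, copies)
    amin = int(A.min())
    Aenc = A - amin
    W = int(Aenc.max()) + 1
    vals = (amin + np.arange(W)).astype(float)
    sample_ids = sorted({i for _, _, combo in entries for i in combo})
    sidx = {i: loci[0].copies_of(i) for i in sample_ids}
    counts: dict[int, np.ndarray] = {}
    nn: dict[int, int] = {}
    row_off = np.arange(L)[:, None] * W
    for i in sample_ids:
        sub = Aenc[:, sidx[i]]
        counts[i] = np.bincount((row_off + sub).ravel(), minlength=L * W).reshape(L, W)
        nn[i] = sub.shape[1]
    out = [dict() for _ in range(L)]

    def put(fam, combo, arr):
        for l in range(L):
            out[l][(fam, combo)] = float(arr[l])

    if families & {"NAL", "HET", "VAR", "MGW"}:
        for i in sample_ids:
            c, n = counts[i], nn[i]
            nz = c > 0
            k = nz.sum(1)
            p = c / n
            het = np.where(k > 1, n / (n - 1) * (1.0 - (p * p).sum(1)), 0.0)
            m = (c * vals).sum(1) / n
            var = np.where(k > 1, ((c * vals * vals).sum(1) - n * m * m) / (n - 1), 0.0)
            lo = nz.argmax(1)
            hi = W - 1 - nz[:, ::-1].argmax(1)
            span = (hi - lo) // motif + 1
            mgw = np.where(k > 1, k / span, 1.0)
            put("NAL", (i,), k.astype(float))
            put("HET", (i,), het)
            put("VAR", (i,), var)
            put("MGW", (i,), mgw)

    pair_needed = families & {"FST", "DM2", "H2P", "DAS", "LIK"}
    done = set()
    for _, fam, combo in entries:
        if fam not in pair_needed:
            continue
        pair = tuple(sorted(combo[:2]))
        if pair in done:
            continue
        done.add(pair)
        i, j = pair
        c1, c2 = counts[i], counts[j]
        n1, n2 = nn[i], nn[j]
        ntot = n1 + n2
        p1, p2 = c1 / n1, c2 / n2
        nc = ntot - (n1 * n1 + n2 * n2) / ntot
        pbar = (c1 + c2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        put("FST_NUM", (i, j), (msp - msg).sum(1))
        put("FST_DEN", (i, j), (msp + (nc - 1) * msg).sum(1))
        m1 = (c1 * vals).sum(1) / n1
        m2 = (c2 * vals).sum(1) / n2
        put("DM2", (i, j), (m1 - m2) ** 2)
        cp = c1 + c2
        pp = cp / ntot
        put("H2P", (i, j), ntot / (ntot - 1) * (1.0 - (pp * pp).sum(1)))
        put("DAS", (i, j), 1.0 - (p1 * p2).sum(1))
        for l in range(L):
            for f2 in ("FST_NUM", "FST_DEN", "DM2", "H2P", "DAS"):
                out[l][(f2, (j, i))] = out[l][(f2, (i, j))]
        if "LIK" in pair_needed:
            put("LIK", (i, j), _batch_lik(Aenc, sidx[i], counts[j], n2))
            put("LIK", (j, i), _batch_lik(Aenc, sidx[j], counts[i], n1))

    for _, fam, combo in entries:
        if fam == "ADM":
            for l, loc in enumerate(loci):
                if (fam, combo) not in out[l]:
                    out[l].update(_locus_stats(loc, {"ADM"}, [("", "ADM", combo)], dataset))
    return out


def _batch_lik(Aenc, idx, c_ref, n_ref) -> np.ndarray:
    """Per-locus mean over diploid individuals of -ln genotype likelihood
    under the reference counts (add-one for unseen alleles)."""
    f = np.where(c_ref > 0, c_ref / n_ref, 1.0 / (n_ref + 1))
    a = Aenc[:, idx[0::2]]
    b = Aenc[:, idx[1::2]]
    lf_a = -np.log(np.take_along_axis(f, a, axis=1))
    lf_b = -np.log(np.take_along_axis(f, b, axis=1))
    hom = a == b
    term = np.where(hom, 2.0 * lf_a, lf_a + lf_b - math.log(2.0))
    return term.sum(1) / a.shape[1]


def _mean_neg_loglik(
    locus: Locus,
    dataset: GenotypeDataset,
    sample: int,
    inv_full: np.ndarray,
    ref_counts: np.ndarray,
    n_ref: int,
    diploid: bool,
) -> float:
    """Mean over individuals of ``sample`` of the -ln multilocus genotype
    likelihood under the reference sample's allele frequencies (add-one
    pseudo-copy for alleles unseen in the reference)."""
    f = np.where(ref_counts > 0, ref_counts / n_ref, 1.0 / (n_ref + 1))
    groups = _individual_groups(locus, sample, dataset.samples[sample].n_individuals)
    tot = 0.0
    n_ind = 0
    for idx in groups:
        codes = inv_full[idx]
        codes = codes[codes >= 0]
        n_ind += 1
        if len(codes) == 0:
            continue
        if diploid and len(codes) == 2:
            a, b = codes
            if a == b:
                tot += -2.0 * math.log(f[a])
            else:
                tot += -(math.log(2.0) + math.log(f[a]) + math.log(f[b]))
        else:
            tot += -float(np.log(f[codes]).sum())
    return tot / max(n_ind, 1)


def _unbiased_het(counts: np.ndarray, n: int) -> float:
    if n < 2:
        return 0.0
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def _locus_stats(locus: Locus, families, entries, dataset: GenotypeDataset):
    out: dict[tuple[str, tuple[int, ...]], float] = {}
    sample_ids = sorted({i for _, _, combo in entries for i in combo})
    if locus.kind == "microsat":
        # one shared allele-count table per sample; every statistic below is
        # a function of these counts, which keeps the hot path vectorized
        data = locus.data
        present = data != MISSING
        vals, inv = np.unique(data[present], return_inverse=True)
        K = len(vals)
        inv_full = np.full(len(data), -1, np.int64)
        inv_full[present] = inv
        counts: dict[int, np.ndarray] = {}
        nn: dict[int, int] = {}
        for i in sample_ids:
            codes = inv_full[locus.copies_of(i)]
            codes = codes[codes >= 0]
            counts[i] = np.bincount(codes, minlength=K)
            nn[i] = len(codes)
        fvals = vals.astype(float)

        within_needed = families & {"NAL", "HET", "VAR", "MGW"}
        if within_needed:
            for i in sample_ids:
                c, n = counts[i], nn[i]
                k = int((c > 0).sum())
                if k <= 1:
                    w = {"NAL": 1.0, "HET": 0.0, "VAR": 0.0, "MGW": 1.0}
                else:
                    m = float((c * fvals).sum()) / n
                    var = (float((c * fvals * fvals).sum()) - n * m * m) / (n - 1)
                    lo = fvals[c > 0].min()
                    hi = fvals[c > 0].max()
                    span = int(hi - lo) // locus.motif + 1
                    w = {
                        "NAL": float(k),
                        "HET": _unbiased_het(c, n),
                        "VAR": var,
                        "MGW": k / span,
                    }
                for f2 in within_needed:
                    out[(f2, (i,))] = w[f2]

        pair_needed = families & {"FST", "DM2", "H2P", "DAS", "LIK"}
        done_pairs = set()
        for _, fam, combo in entries:
            if fam not in pair_needed:
                continue
            pair = tuple(sorted(combo[:2]))
            if pair in done_pairs:
                continue
            done_pairs.add(pair)
            i, j = pair
            c1, c2 = counts[i], counts[j]
            n1, n2 = nn[i], nn[j]
            ntot = n1 + n2
            p1 = c1 / n1
            p2 = c2 / n2
            nc = (ntot - (n1 * n1 + n2 * n2) / ntot)  # r - 1 == 1
            pbar = (c1 + c2) / ntot
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
            out[("FST_NUM", (i, j))] = float((msp - msg).sum())
            out[("FST_DEN", (i, j))] = float((msp + (nc - 1) * msg).sum())
            m1 = float((c1 * fvals).sum()) / n1
            m2 = float((c2 * fvals).sum()) / n2
            out[("DM2", (i, j))] = (m1 - m2) ** 2
            out[("H2P", (i, j))] = _unbiased_het(c1 + c2, ntot)
            out[("DAS", (i, j))] = float(1.0 - np.sum(p1 * p2))
            for f2 in ("FST_NUM", "FST_DEN", "DM2", "H2P", "DAS"):
                out[(f2, (j, i))] = out[(f2, (i, j))]
            if "LIK" in pair_needed:
                diploid = locus.category in ("A", "X")
                out[("LIK", (i, j))] = _mean_neg_loglik(
                    locus, dataset, i, inv_full, c2, n2, diploid
                )
                out[("LIK", (j, i))] = _mean_neg_loglik(
                    locus, dataset, j, inv_full, c1, n1, diploid
                )
        for _, fam, combo in entries:
            if fam == "ADM" and (fam, combo) not in out:
                p1s, p2s, mix = combo
                tables = {
                    k: (vals[counts[k] > 0], counts[k][counts[k] > 0])
                    for k in (p1s, p2s, mix)
                }
                est = admixture_mle([tables[p1s]], [tables[p2s]], [tables[mix]])
                out[("ADM", combo)] = est.r
    else:
        # shared per-locus precomputation: segregating columns, haplotype
        # codes and the full pairwise-difference matrix over all copies
        seqs = locus.data
        var = _variable_columns(seqs)
        if len(var):
            sub = np.ascontiguousarray(seqs[:, var])
        else:
            sub = np.zeros((len(seqs), 0), np.uint8)
        codes: dict[bytes, int] = {}
        hap = np.empty(len(sub), np.int64)
        for r in range(len(sub)):
            hap[r] = codes.setdefault(sub[r].tobytes(), len(codes))
        if len(var):
            # pairwise Hamming distances via one-hot matches (BLAS)
            onehot = (sub[:, :, None] == np.arange(4, dtype=np.uint8)).astype(np.float32)
            flat = onehot.reshape(len(seqs), -1)
            D = np.rint(len(var) - flat @ flat.T).astype(np.int64)
        else:
            D = np.zeros((len(seqs), len(seqs)), np.int64)
        idx = {i: locus.copies_of(i) for i in sample_ids}

        def block(rows_a, rows_b=None):
            # sample copies are contiguous in simulated data; basic slicing
            # then avoids fancy-index copies
            def as_slice(rows):
                if len(rows) and rows[-1] - rows[0] == len(rows) - 1:
                    return slice(rows[0], rows[-1] + 1)
                return rows
            a = as_slice(rows_a)
            b = as_slice(rows_b) if rows_b is not None else a
            return D[a][:, b] if isinstance(a, np.ndarray) or isinstance(b, np.ndarray) else D[a, b]

        def nss_of(rows):
            if len(var) == 0:
                return 0
            s = sub[rows]
            return int(np.any(s != s[0], axis=0).sum())

        for _, fam, combo in entries:
            if fam in ("NHA", "NSS", "MPD", "VPD") and (fam, combo) not in out:
                rows = idx[combo[0]]
                diffs = _upper(block(rows))
                out[("NHA", combo)] = float(len(np.unique(hap[rows])))
                out[("NSS", combo)] = float(nss_of(rows))
                out[("MPD", combo)] = float(diffs.mean()) if len(diffs) else 0.0
                out[("VPD", combo)] = float(diffs.var(ddof=1)) if len(diffs) > 1 else 0.0
            elif fam in ("NHA2P", "NSS2P", "FSQ") and (fam, combo) not in out:
                ra, rb = idx[combo[0]], idx[combo[1]]
                pooled = np.concatenate([ra, rb])
                within = np.concatenate([_upper(block(ra)), _upper(block(rb))])
                between = block(ra, rb).ravel()
                pi_b = between.mean() if len(between) else 0.0
                fsq = max(0.0, 1.0 - within.mean() / pi_b) if pi_b > 0 else 0.0
                vals_pair = {
                    "NHA2P": float(len(np.unique(hap[pooled]))),
                    "NSS2P": float(nss_of(pooled)),
                    "FSQ": float(fsq),
                }
                for f2, v in vals_pair.items():
                    out[(f2, combo)] = v
                    out[(f2, (combo[1], combo[0]))] = v
            elif fam == "ADM" and (fam, combo) not in out:
                # admixture MLE on shared haplotype frequencies
                tables = {
                    s: np.unique(hap[idx[s]], return_counts=True) for s in combo
                }
                est = admixture_mle([tables[combo[0]]], [tables[combo[1]]], [tables[combo[2]]])
                out[("ADM", combo)] = est.r
    return out
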