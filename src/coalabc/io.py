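"""Reading and writing multimarker dataset files.

The dialect is plain text:

* a free-form title line;
* ``SEXRATIO <female fraction>``;
* one ``LOCUS <name> <tag> <MIC motif|SEQ length>`` line per locus, with the
  inheritance tag in ``<A> <H> <X> <Y> <M>``;
* one ``POP <label> <time-offset>`` separator per sample (offset in
  generations before the most recent sample, default 0), followed by one
  genotype row per individual: ``<id> ,`` then per microsatellite locus a
  Genepop-style allele-length code (3 digits haploid, 6 digits diploid,
  ``0`` = missing);
* after the genotype sections, one ``SEQBLOCK <locus>`` FASTA block per
  sequence locus whose record ids are ``<individual id>_<copy index>``.
"""

from __future__ import annotations

import numpy as np

from .loci import CATEGORIES
from .mutation import BASES
from .scenarios import Config, Scenario, draw_parameters
from .sumstats import MISSING, GenotypeDataset, Locus, SampleInfo

__all__ = ["read_dataset", "write_dataset", "generate_pseudo_observed", "DatasetFileError"]

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


class DatasetFileError(ValueError):
    def __init__(self, lineno, message):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _is_diploid_column(category: str) -> bool:
    # X-linked genotype columns are written as diploid codes; males carry the
    # allele twice and the reader keeps one copy
    return category in ("A", "X")


def write_dataset(dataset: GenotypeDataset, path, title: str = "coalabc dataset") -> None:
    """Serialize a dataset; inverse of :func:`read_dataset`."""
    if not dataset.loci:
        raise ValueError("cannot write a dataset with no loci")
    if not dataset.samples:
        raise ValueError("cannot write a dataset with no samples")
    lines = [title]
    f = dataset.samples[0].female_fraction
    lines.append(f"SEXRATIO {f!r}")
    for loc in dataset.loci:
        if loc.kind == "microsat":
            lines.append(f"LOCUS {loc.name} <{loc.category}> MIC {loc.motif}")
        else:
            lines.append(f"LOCUS {loc.name} <{loc.category}> SEQ {loc.data.shape[1]}")

    t0 = min(s.time for s in dataset.samples)
    ind_ids: dict[int, list[str]] = {}
    for si, s in enumerate(dataset.samples):
        lines.append(f"POP {s.name} {s.time - t0:g}")
        ids = [f"{s.name}-{i + 1}" for i in range(s.n_individuals)]
        ind_ids[si] = ids
        for i, ind in enumerate(ids):
            codes = []
            for loc in dataset.loci:
                if loc.kind != "microsat":
                    continue
                copies = loc.copies_of(si)
                codes.append(_genotype_code(loc, copies, i, s))
            lines.append(f"{ind} , " + " ".join(codes))

    for loc in dataset.loci:
        if loc.kind != "seq":
            continue
        lines.append(f"SEQBLOCK {loc.name}")
        for si, s in enumerate(dataset.samples):
            copies = loc.copies_of(si)
            per_ind = _copies_per_individual(loc.category, s)
            k = 0
            for i, ind in enumerate(ind_ids[si]):
                for c in range(per_ind[i]):
                    seq = loc.data[copies[k]]
                    k += 1
                    lines.append(f">{ind}_{c + 1}")
                    lines.append("".join(BASES[b] for b in seq))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _copies_per_individual(category: str, s: SampleInfo) -> list[int]:
    n = s.n_individuals
    if category == "A":
        return [2] * n
    if category in ("H", "M", ):
        return [1] * n
    n_f = int(round(s.female_fraction * n))
    if category == "X":
        return [2] * n_f + [1] * (n - n_f)
    if category == "Y":
        return [0] * n_f + [1] * (n - n_f)
    raise ValueError(category)


def _genotype_code(loc: Locus, copies: np.ndarray, i: int, s: SampleInfo) -> str:
    per_ind = _copies_per_individual(loc.category, s)
    start = sum(per_ind[:i])
    mine = copies[start:start + per_ind[i]]

    def code(v):
        return f"{0 if v == MISSING else int(v):03d}"

    if _is_diploid_column(loc.category):
        if len(mine) == 2:
            return code(loc.data[mine[0]]) + code(loc.data[mine[1]])
        if len(mine) == 1:  # X-linked male: write the single allele twice
            c = code(loc.data[mine[0]])
            return c + c
        return "000000"
    if len(mine) == 1:
        return code(loc.data[mine[0]])
    return "000"


def read_dataset(path) -> GenotypeDataset:
    """Parse a dataset file; errors carry the offending line number."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise DatasetFileError(1, "truncated dataset file")
    i = 1
    if not lines[i].startswith("SEXRATIO"):
        raise DatasetFileError(2, "expected SEXRATIO line")
    female_fraction = float(lines[i].split()[1])
    i += 1

    locus_decl: list[tuple[str, str, str, int]] = []
    while i < len(lines) and lines[i].startswith("LOCUS"):
        toks = lines[i].split()
        if len(toks) != 5:
            raise DatasetFileError(i + 1, f"malformed LOCUS line {lines[i]!r}")
        _, name, tag, kind, arg = toks
        if not (tag.startswith("<") and tag.endswith(">") and tag[1:-1] in CATEGORIES):
            raise DatasetFileError(i + 1, f"unknown category tag {tag!r}")
        if kind not in ("MIC", "SEQ"):
            raise DatasetFileError(i + 1, f"unknown marker kind {kind!r}")
        locus_decl.append((name, tag[1:-1], kind, int(arg)))
        i += 1
    if not locus_decl:
        raise DatasetFileError(i + 1, "no LOCUS lines")

    mic_decl = [(j, d) for j, d in enumerate(locus_decl) if d[2] == "MIC"]
    samples: list[SampleInfo] = []
    genotype_rows: dict[int, list[tuple[str, list[str]]]] = {}
    while i < len(lines) and lines[i].startswith("POP"):
        toks = lines[i].split()
        if len(toks) != 3:
            raise DatasetFileError(i + 1, f"malformed POP line {lines[i]!r}")
        si = len(samples)
        pop_name, t = toks[1], float(toks[2])
        rows: list[tuple[str, list[str]]] = []
        i += 1
        while i < len(lines) and not lines[i].startswith(("POP", "SEQBLOCK")):
            if "," not in lines[i]:
                raise DatasetFileError(i + 1, f"malformed genotype row {lines[i]!r}")
            ind, codes = lines[i].split(",", 1)
            codes = codes.split()
            if len(codes) != len(mic_decl):
                raise DatasetFileError(
                    i + 1,
                    f"expected {len(mic_decl)} genotype columns, got {len(codes)}",
                )
            rows.append((ind.strip(), codes))
            i += 1
        samples.append(SampleInfo(pop_name, t, len(rows), female_fraction))
        genotype_rows[si] = rows
    if not samples:
        raise DatasetFileError(i + 1, "no POP sections")

    seq_records: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    rec_id = None
    while i < len(lines):
        line = lines[i]
        if line.startswith("SEQBLOCK"):
            name = line.split()[1]
            current = seq_records.setdefault(name, {})
            rec_id = None
        elif line.startswith(">"):
            if current is None:
                raise DatasetFileError(i + 1, "FASTA record outside SEQBLOCK")
            rec_id = line[1:].strip()
            current[rec_id] = ""
        elif line.strip():
            if rec_id is None:
                raise DatasetFileError(i + 1, f"unexpected content {line!r}")
            current[rec_id] += line.strip()
        i += 1

    dataset = GenotypeDataset(samples=samples)
    for col, (name, category, kind, arg) in enumerate(locus_decl):
        if kind == "MIC":
            mic_col = [j for j, (jj, _) in enumerate(mic_decl) if jj == col][0]
            alleles = []
            sample_index = []
            for si, s in enumerate(samples):
                per_ind = _copies_per_individual(category, s)
                for (ind, codes), n_cop in zip(genotype_rows[si], per_ind):
                    code = codes[mic_col]
                    vals = _decode_genotype(code, category, n_cop)
                    alleles.extend(vals)
                    sample_index.extend([si] * len(vals))
            dataset.loci.append(
                Locus(
                    name=name, category=category, kind="microsat",
                    data=np.asarray(alleles, np.int64),
                    sample_index=np.asarray(sample_index, np.int64),
                    motif=arg,
                )
            )
        else:
            if name not in seq_records:
                raise DatasetFileError(len(lines), f"missing SEQBLOCK for locus {name!r}")
            records = seq_records[name]
            seqs = []
            sample_index = []
            for si, s in enumerate(samples):
                per_ind = _copies_per_individual(category, s)
                for (ind, _), n_cop in zip(genotype_rows[si], per_ind):
                    for c in range(n_cop):
                        rid = f"{ind}_{c + 1}"
                        if rid not in records:
                            raise DatasetFileError(
                                len(lines), f"unresolved FASTA id {rid!r} in locus {name!r}"
                            )
                        seq = records[rid]
                        if len(seq) != arg:
                            raise DatasetFileError(
                                len(lines),
                                f"sequence {rid!r} has length {len(seq)}, expected {arg}",
                            )
                        seqs.append([_BASE_TO_CODE[b] for b in seq])
                        sample_index.append(si)
            dataset.loci.append(
                Locus(
                    name=name, category=category, kind="seq",
                    data=np.asarray(seqs, np.uint8),
                    sample_index=np.asarray(sample_index, np.int64),
                )
            )
    return dataset


def _decode_genotype(code: str, category: str, n_copies: int) -> list[int]:
    def val(c):
        v = int(c)
        return MISSING if v == 0 else v

    if _is_diploid_column(category):
        if len(code) != 6:
            raise ValueError(f"expected 6-digit diploid code, got {code!r}")
        a, b = val(code[:3]), val(code[3:])
        if category == "X" and n_copies == 1:
            return [a]
        return [a, b]
    if n_copies == 0:
        return []
    if len(code) != 3:
        raise ValueError(f"expected 3-digit haploid code, got {code!r}")
    return [val(code)]


# ---------------------------------------------------------------------------
# Pseudo-observed datasets

def generate_pseudo_observed(
    config: Config,
    scenario: Scenario,
    n_datasets: int,
    seed: int,
    fixed_params: dict[str, float] | None = None,
    outdir=None,
):
    """Simulate pseudo-observed datasets plus a truth table.

    Parameters are either drawn from the priors (default) or fixed via
    ``fixed_params`` (values given there override the prior draw).  Returns
    (datasets, truth DataFrame); if ``outdir`` is given, also writes
    ``pod_<i>.txt`` files and ``truth.tsv``.
    """
    import pandas as pd

    from .inference import _row_rng, simulate_dataset

    datasets = []
    truth_rows = []
    for i in range(n_datasets):
        rng = _row_rng(seed, 40_000 + scenario.id, i)
        params = draw_parameters(config.priors, config.conditions, rng)
        if fixed_params:
            params.update(fixed_params)
        ds = simulate_dataset(config, scenario, params, rng)
        datasets.append(ds)
        truth_rows.append({"dataset": i, **params})
    truth = pd.DataFrame(truth_rows)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for i, ds in enumerate(datasets):
            write_dataset(ds, os.path.join(outdir, f"pod_{i}.txt"),
                          title=f"pseudo-observed dataset {i} (scenario {scenario.id})")
        truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    return datasets, truth
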