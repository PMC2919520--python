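"""Locus specifications: inheritance category, marker kind, mutation settings.

Five inheritance categories are supported, tagged as in dataset files:
``<A>`` autosomal diploid, ``<H>`` autosomal haploid, ``<X>`` X-linked,
``<Y>`` Y-linked, ``<M>`` mitochondrial.  A locus is either a microsatellite
(generalized stepwise mutation with an optional single-nucleotide-indel
process in the flanking region) or a DNA sequence (JC/K2P/HKY/TN
substitution, optional invariant sites and gamma rate heterogeneity).

Mutation-rate fields may name a prior (a dataset-level mean, with per-locus
values drawn from a Gamma hierarchy at simulation time) or hold a literal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CATEGORIES = ("A", "H", "X", "Y", "M")
SEQ_MODELS = ("JC", "K2P", "HKY", "TN")


@dataclass(frozen=True)
class LocusSpec:
    name: str
    category: str               # one of CATEGORIES
    kind: str                   # "microsat" | "seq"
    # microsatellite fields
    motif: int = 2
    range_width: int = 40
    mu_param: str | float = 5e-4    # mean GSM rate (prior name or literal)
    p_param: str | float = 0.22     # mean geometric parameter
    sni_param: str | float | None = None  # mean flanking-indel rate
    # sequence fields
    length: int = 1000
    model: str = "K2P"
    rate_param: str | float = 1e-8  # mean substitution rate /site/generation
    kappa: float = 2.0              # ts/tv rate ratio (K2P, HKY)
    kappa1: float = 2.0             # TN: A<->G transition ratio
    kappa2: float = 2.0             # TN: C<->T transition ratio
    freqs: tuple[float, float, float, float] | None = None  # HKY/TN base freqs
    invariant: float = 0.0
    gamma_shape: float | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown locus category {self.category!r}")
        if self.kind not in ("microsat", "seq"):
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.kind == "microsat":
            if self.range_width < 2:
                raise ValueError("allelic range width must be >= 2")
            if self.motif < 1:
                raise ValueError("motif length must be >= 1")
        else:
            if self.length <= 0:
                raise ValueError("sequence length must be > 0")
            if self.model not in SEQ_MODELS:
                raise ValueError(f"unknown substitution model {self.model!r}")
            if not 0.0 <= self.invariant < 1.0:
                raise ValueError("invariant-site fraction must be in [0,1)")
            if self.gamma_shape is not None and self.gamma_shape <= 0:
                raise ValueError("gamma shape must be > 0")

    @property
    def group(self) -> str:
        """Statistic-averaging group: microsatellites, nuclear sequences, or
        mitochondrial sequences."""
        if self.kind == "microsat":
            return "MIC" if self.category == "A" else f"MIC{self.category}"
        return "MT" if self.category == "M" else "NUC"

    def serialize(self) -> str:
        def fmt(v):
            return v if isinstance(v, str) else repr(v)

        if self.kind == "microsat":
            s = (
                f"microsat 1 <{self.category}> motif={self.motif} "
                f"range={self.range_width} mu={fmt(self.mu_param)} P={fmt(self.p_param)}"
            )
            if self.sni_param is not None:
                s += f" sni={fmt(self.sni_param)}"
            return s
        s = (
            f"seq 1 <{self.category}> length={self.length} model={self.model} "
            f"rate={fmt(self.rate_param)}"
        )
        if self.model in ("K2P", "HKY"):
            s += f" kappa={self.kappa!r}"
        if self.model == "TN":
            s += f" kappa1={self.kappa1!r} kappa2={self.kappa2!r}"
        if self.freqs is not None:
            s += " freqs=" + ",".join(repr(f) for f in self.freqs)
        if self.invariant:
            s += f" invariant={self.invariant!r}"
        if self.gamma_shape is not None:
            s += f" shape={self.gamma_shape!r}"
        return s


def _rate_field(value: str, prior_names: set[str], lineno: int, what: str):
    from .scenarios import ParseError

    try:
        return float(value)
    except ValueError:
        if value not in prior_names:
            raise ParseError(lineno, f"unknown parameter name {value!r} used as {what}")
        return value


def parse_locus_line(
    line: str, lineno: int, prior_names: set[str], n_existing: int = 0
) -> list[LocusSpec]:
    """Parse one ``[loci]`` line into one or more LocusSpec objects.

    Grammar::

        microsat <n> <CAT> motif=<int> [range=<int>] mu=<prior|float>
                 P=<prior|float> [sni=<prior|float>]
        seq <n> <CAT> length=<int> model=<JC|K2P|HKY|TN> rate=<prior|float>
            [kappa=..] [kappa1=..] [kappa2=..] [freqs=a,c,g,t]
            [invariant=..] [shape=..]
    """
    from .scenarios import ParseError

    toks = line.split()
    if len(toks) < 3:
        raise ParseError(lineno, f"malformed locus line {line!r}")
    kind_tok, n_tok, cat_tok = toks[0], toks[1], toks[2]
    if kind_tok not in ("microsat", "seq"):
        raise ParseError(lineno, f"unknown marker kind {kind_tok!r}")
    try:
        n = int(n_tok)
    except ValueError:
        raise ParseError(lineno, f"malformed locus count {n_tok!r}")
    if not (cat_tok.startswith("<") and cat_tok.endswith(">")):
        raise ParseError(lineno, f"malformed category tag {cat_tok!r}")
    category = cat_tok[1:-1]
    if category not in CATEGORIES:
        raise ParseError(lineno, f"unknown category tag {cat_tok!r}")

    opts: dict[str, str] = {}
    for tok in toks[3:]:
        if "=" not in tok:
            raise ParseError(lineno, f"malformed locus option {tok!r}")
        k, v = tok.split("=", 1)
        opts[k] = v

    out = []
    for i in range(n):
        name = f"L{n_existing + i + 1:02d}"
        try:
            if kind_tok == "microsat":
                allowed = {"motif", "range", "mu", "P", "sni"}
                if set(opts) - allowed:
                    raise ParseError(lineno, f"unknown options {set(opts) - allowed}")
                spec = LocusSpec(
                    name=name,
                    category=category,
                    kind="microsat",
                    motif=int(opts.get("motif", 2)),
                    range_width=int(opts.get("range", 40)),
                    mu_param=_rate_field(opts["mu"], prior_names, lineno, "mutation rate")
                    if "mu" in opts
                    else 5e-4,
                    p_param=_rate_field(opts["P"], prior_names, lineno, "GSM parameter")
                    if "P" in opts
                    else 0.22,
                    sni_param=_rate_field(opts["sni"], prior_names, lineno, "SNI rate")
                    if "sni" in opts
                    else None,
                )
            else:
                allowed = {
                    "length", "model", "rate", "kappa", "kappa1", "kappa2",
                    "freqs", "invariant", "shape",
                }
                if set(opts) - allowed:
                    raise ParseError(lineno, f"unknown options {set(opts) - allowed}")
                freqs = None
                if "freqs" in opts:
                    freqs = tuple(float(x) for x in opts["freqs"].split(","))
                spec = LocusSpec(
                    name=name,
                    category=category,
                    kind="seq",
                    length=int(opts.get("length", 1000)),
                    model=opts.get("model", "K2P"),
                    rate_param=_rate_field(opts["rate"], prior_names, lineno, "rate")
                    if "rate" in opts
                    else 1e-8,
                    kappa=float(opts.get("kappa", 2.0)),
                    kappa1=float(opts.get("kappa1", opts.get("kappa", 2.0))),
                    kappa2=float(opts.get("kappa2", opts.get("kappa", 2.0))),
                    freqs=freqs,
                    invariant=float(opts.get("invariant", 0.0)),
                    gamma_shape=float(opts["shape"]) if "shape" in opts else None,
                )
        except ValueError as exc:
            raise ParseError(lineno, str(exc))
        out.append(spec)
    return out
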