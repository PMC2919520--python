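"""Built-in study designs used by the examples, tests and validation runs.

Two classic designs are bundled:

* :func:`marker_mix_config` — three competing histories for four sampled
  populations (30 diploids each, samples 3 and 4 collected 2 and 4
  generations before the others) that differ in their number of admixture
  events: scenario 1 has two admixed populations (samples 2 and 3, fed by
  two unsampled parental populations), scenario 2 one (sample 2, one
  unsampled parent), scenario 3 none.  Markers are any combination of 10
  autosomal microsatellites (GSM), one 1000-nt mitochondrial K2P sequence
  and five 1000-nt nuclear K2P sequences, used to study how marker types
  complement each other for scenario choice and parameter estimation.
  The published description fixes the population counts, which samples are
  admixed, and every prior; the event lists here are a concrete topology
  consistent with all of those constraints.

* :func:`invasion_config` — the three invasion-route scenarios for a source
  population S and two invasive populations 1 and 2 (20 autosomal
  microsatellites, 30 diploids per sample, introduction dates fixed at
  5/10/15 generations with 5-generation bottlenecks of size NFi after each
  introduction): independent introductions (scenario 1), serial
  introduction (scenario 2), and introductions from an unsampled
  population U itself introduced from S (scenario 3).
"""

from __future__ import annotations

from .scenarios import Config, parse_config

__all__ = [
    "marker_mix_config",
    "invasion_config",
    "MARKER_MIX_MICROSAT_STATS",
    "MARKER_MIX_SEQ_STATS",
    "INVASION_INFERENCE_STATS",
    "INVASION_CHECKING_STATS",
]

_MARKER_MIX_HEAD = """
[priors]
N ~ U[10,10000]
t1 ~ U[1,100]
t2 ~ U[100,1000]
t3 ~ U[5000,50000]
t3a ~ U[5000,50000]
t4 ~ U[5000,50000]
t5 ~ U[50000,500000]
r1 ~ U[0.1,0.9]
r2 ~ U[0.1,0.9]
MUMIC ~ U[1e-4,1e-3]
PMIC ~ U[0.1,0.3]
MUMT ~ U[1e-8,1e-7]
MUNUC ~ U[1e-9,1e-8]

[conditions]
t4 > t3

[samples]
1 30
2 30
3 30
4 30

[scenario 1]
pop 1 N
pop 2 N
pop 3 N
pop 4 N
pop 5 N
pop 6 N
sample 0 1
sample 0 2
sample 2 3
sample 4 4
admix t1 2 1 6 r1
admix t2 3 4 5 r2
merge t3 6 5
merge t4 4 6
merge t5 1 4

[scenario 2]
pop 1 N
pop 2 N
pop 3 N
pop 4 N
pop 5 N
sample 0 1
sample 0 2
sample 2 3
sample 4 4
admix t1 2 1 5 r1
merge t2 4 3
merge t3a 4 5
merge t5 1 4

[scenario 3]
pop 1 N
pop 2 N
pop 3 N
pop 4 N
sample 0 1
sample 0 2
sample 2 3
sample 4 4
merge t1 1 2
merge t2 4 3
merge t5 1 4
"""

MARKER_MIX_MICROSAT_STATS = ["NAL", "HET", "VAR", "FST", "DM2"]
MARKER_MIX_SEQ_STATS = ["NHA", "NSS", "MPD", "VPD", "NHA2P", "NSS2P", "FSQ"]


def marker_mix_config(
    microsats: int = 10, mtdna: bool = True, nuclear: int = 5
) -> Config:
    """The four-population marker-mixing design with a configurable marker
    panel (counts of microsatellite and sequence loci)."""
    loci_lines = ["[loci]"]
    if microsats:
        loci_lines.append(
            f"microsat {microsats} <A> motif=2 range=40 mu=MUMIC P=PMIC"
        )
    if mtdna:
        loci_lines.append(
            "seq 1 <M> length=1000 model=K2P rate=MUMT kappa=10 invariant=0.10 shape=2"
        )
    if nuclear:
        loci_lines.append(
            f"seq {nuclear} <A> length=1000 model=K2P rate=MUNUC kappa=4 "
            "invariant=0.10 shape=2"
        )
    return parse_config(_MARKER_MIX_HEAD + "\n".join(loci_lines) + "\n")


_INVASION_TEXT = """
[priors]
NS ~ U[1000,20000]
NFi ~ LU[2,100]
MUMIC ~ U[1e-4,1e-3]
PMIC ~ U[0.1,0.3]

[loci]
microsat 20 <A> motif=2 range=40 mu=MUMIC P=PMIC

[samples]
S 30
1 30
2 30

[scenario 1]
pop S NS
pop 1 NFi
pop 2 NS
sample 0 S
sample 0 1
sample 0 2
merge 5 S 1
varNe 5 2 NFi
merge 10 S 2

[scenario 2]
pop S NS
pop 1 NFi
pop 2 NS
sample 0 S
sample 0 1
sample 0 2
merge 5 2 1
varNe 5 2 NFi
merge 10 S 2

[scenario 3]
pop S NS
pop 1 NFi
pop 2 NS
pop U NS
sample 0 S
sample 0 1
sample 0 2
merge 5 U 1
varNe 5 2 NFi
merge 10 U 2
varNe 10 U NFi
merge 15 S U
"""

# statistics used for scenario discrimination and posterior estimation
INVASION_INFERENCE_STATS = ["NAL", "HET", "MGW", "FST"]
# statistics reserved for model checking (disjoint from the inference set)
INVASION_CHECKING_STATS = ["VAR", "LIK", "H2P", "DAS"]


def invasion_config() -> Config:
    """The three invasion-introduction scenarios (20 microsatellites)."""
    return parse_config(_INVASION_TEXT)
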