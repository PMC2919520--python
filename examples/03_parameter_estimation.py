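"""ABC posterior estimation of a divergence time (reduced scale).

Simulates a pseudo-observed dataset with a known divergence time, builds a
reference table, and reports the regression-adjusted posterior quantiles so
the estimate can be compared with the truth.
"""

import numpy as np

from coalabc import (
    build_reference_table,
    estimate_posteriors,
    nearest_fraction,
    parse_config,
    simulate_dataset,
    summarize_dataset,
)
from coalabc.scenarios import draw_parameters

CONFIG = """
[priors]
N ~ U[500,5000]
T ~ U[100,10000]
MU ~ U[1e-4,1e-3]
P ~ U[0.1,0.3]

[loci]
microsat 10 <A> motif=2 mu=MU P=P

[samples]
A 25
B 25

[scenario 1]
pop A N
pop B N
sample 0 A
sample 0 B
merge T A B
"""

SELECTION = ["NAL", "HET", "VAR", "FST", "DM2"]


def main():
    cfg = parse_config(CONFIG)
    rng = np.random.default_rng(5)
    truth = draw_parameters(cfg.priors, cfg.conditions, rng)
    truth.update(N=2000.0, T=3000.0)
    observed = simulate_dataset(cfg, cfg.scenario(1), truth, rng)
    obs_stats = summarize_dataset(observed, SELECTION)

    print("building reference table (4000 rows)...")
    table = build_reference_table(cfg, 4000, SELECTION, seed=2)
    retained = nearest_fraction(table, obs_stats, fraction=0.025)
    post = estimate_posteriors(retained, cfg.priors)
    q = post.quantiles([0.05, 0.5, 0.95]).round(1)
    print("\nposterior quantiles (rows: 5%, 50%, 95%):")
    print(q[["N", "T"]].to_string())
    print(
        f"\ntruth: N = {truth['N']:.0f}, T = {truth['T']:.0f}; the posterior "
        "median is the ABC point estimate and the 5-95% range its credible "
        "interval after local-linear adjustment on the retained 2.5%."
    )


if __name__ == "__main__":
    main()
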