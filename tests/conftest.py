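import numpy as np
import pytest

from coalabc.scenarios import parse_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


ONE_POP_TEXT = """
[priors]
MU ~ U[1e-4,1e-3]
P ~ U[0.1,0.3]
[loci]
microsat 5 <A> motif=2 range=40 mu=MU P=P
[samples]
A 10
[scenario 1]
pop A 1000
sample 0 A
"""

TWO_POP_TEXT = """
[priors]
N ~ U[200,2000]
T ~ U[50,5000]
MU ~ U[1e-4,1e-3]
P ~ U[0.1,0.3]
[loci]
microsat 4 <A> motif=2 range=40 mu=MU P=P
[samples]
A 8
B 8
[scenario 1]
pop A N
pop B N
sample 0 A
sample 0 B
merge T A B
"""


@pytest.fixture
def one_pop_config():
    return parse_config(ONE_POP_TEXT)


@pytest.fixture
def two_pop_config():
    return parse_config(TWO_POP_TEXT)


@pytest.fixture
def random_small_dataset(rng):
    """Factory for small random multimarker datasets (built directly, not
    through the simulator, so statistics tests are independent of it)."""
    from coalabc.sumstats import GenotypeDataset, Locus, SampleInfo

    def make(
        n_samples=2,
        n_ind=6,
        n_mic=3,
        n_seq=1,
        seq_len=30,
        categories=("A",),
        seed=None,
    ):
        r = np.random.default_rng(seed) if seed is not None else rng
        samples = [SampleInfo(f"P{i+1}", 0.0, n_ind) for i in range(n_samples)]
        ds = GenotypeDataset(samples=samples)
        sample_index = np.repeat(np.arange(n_samples), 2 * n_ind)
        for k in range(n_mic):
            alleles = 100 + 2 * r.integers(0, 6, size=2 * n_ind * n_samples)
            ds.loci.append(
                Locus(
                    name=f"M{k+1}", category="A", kind="microsat",
                    data=alleles.astype(np.int64), sample_index=sample_index.copy(),
                    motif=2,
                )
            )
        seq_index = np.repeat(np.arange(n_samples), n_ind)
        for k in range(n_seq):
            seqs = r.integers(0, 4, size=(n_ind * n_samples, seq_len)).astype(np.uint8)
            # make most columns monomorphic so the data look sequence-like
            keep = r.random(seq_len) < 0.25
            seqs[:, ~keep] = seqs[0, ~keep]
            ds.loci.append(
                Locus(
                    name=f"S{k+1}", category="M", kind="seq",
                    data=seqs, sample_index=seq_index.copy(),
                )
            )
        return ds

    return make
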