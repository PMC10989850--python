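import numpy as np
import pytest

from seqscrub.fastq import write_fastq_stream
from seqscrub.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_corpus():
    """2,000 synthetic pairs under default library conditions, with truth."""
    cfg = SimConfig(seed=11, n_pairs=2000)
    pairs, truth = simulate(cfg)
    return cfg, pairs, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def fastq_files(tmp_path):
    """Write a pair list to R1/R2 FASTQ files; returns the two paths."""

    def _write(pairs, prefix="reads", gz=False):
        suffix = ".fastq.gz" if gz else ".fastq"
        p1 = tmp_path / f"{prefix}_R1{suffix}"
        p2 = tmp_path / f"{prefix}_R2{suffix}"
        write_fastq_stream((p.r1 for p in pairs), p1, gzip_output=gz)
        write_fastq_stream((p.r2 for p in pairs), p2, gzip_output=gz)
        return p1, p2

    return _write


def random_read(rng, n, name="r", q_low=2, q_high=41):
    """Uniform random read of length n with uniform random qualities."""
    from seqscrub.fastq import ReadRecord

    seq = "".join(rng.choice(list("ACGT"), size=n))
    qual = "".join(chr(33 + int(q)) for q in rng.integers(q_low, q_high, size=n))
    return ReadRecord(name, seq, qual)
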