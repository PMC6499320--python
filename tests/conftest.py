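import numpy as np
import pytest

from svmosaic.core import SVCall


def make_call(start, end, svtype="DEL", chrom="chr1", sample="S0", caller="pindel",
              filt="PASS", length=None, seq=None):
    if svtype == "INS":
        return SVCall(chrom, start, start, "INS", length or (seq and len(seq)) or 50,
                      sample_id=sample, caller_id=caller, filter_status=filt,
                      inserted_seq=seq)
    return SVCall(chrom, start, end, svtype, end - start, sample_id=sample,
                  caller_id=caller, filter_status=filt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_callset(rng, n, chrom="chr1", span=100_000, min_len=50, max_len=2000,
                   svtype="DEL", n_samples=5):
    """Random interval calls for oracle-equivalence instances."""
    calls = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, span - length))
        calls.append(
            SVCall(chrom, start, start + length, svtype, length,
                   sample_id=f"S{int(rng.integers(0, n_samples)):02d}",
                   caller_id=f"c{i}")
        )
    return calls
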