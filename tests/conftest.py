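import numpy as np
import pandas as pd
import pytest

from crosstrait.ldref import LDBlock, LDReference, ar1_correlation
from crosstrait.sumstats import SumStats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sumstats(rsids, betas, ses, chrom=1, pos=None, a1="A", a2="G",
                  n=10_000, label="trait", trait_type="quantitative",
                  **extra):
    """Small SumStats builder for unit tests."""
    m = len(rsids)
    df = pd.DataFrame({
        "rsid": rsids,
        "chrom": chrom if np.isscalar(chrom) else list(chrom),
        "pos": list(range(1000, 1000 + 1000 * m, 1000)) if pos is None else pos,
        "a1": a1 if isinstance(a1, str) else list(a1),
        "a2": a2 if isinstance(a2, str) else list(a2),
        "beta": betas,
        "se": ses,
        "n": n,
    })
    for k, v in extra.items():
        df[k] = v
    return SumStats(df, trait_label=label, trait_type=trait_type)


@pytest.fixture
def tiny_ld():
    """Two blocks: a 3-SNP AR(1) rho=0.5 block and an independent pair."""
    b1 = LDBlock(chrom=1, rsids=["rs1", "rs2", "rs3"],
                 positions=np.array([1000, 2000, 3000]),
                 R=ar1_correlation(3, 0.5))
    b2 = LDBlock(chrom=2, rsids=["rs4", "rs5"],
                 positions=np.array([1000, 2000]),
                 R=np.eye(2))
    return LDReference([b1, b2])
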