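import numpy as np
import pandas as pd
import pytest

from rcmir.counts import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 miRNAs x 4 samples, two conditions, no zeros."""
    df = pd.DataFrame(
        {
            "c1": [10, 20, 30],
            "c2": [12, 18, 33],
            "t1": [40, 19, 31],
            "t2": [44, 21, 28],
        },
        index=["mmu-mir-a", "mmu-mir-b", "mmu-mir-c"],
    )
    groups = {"c1": "control", "c2": "control", "t1": "LTyr", "t2": "LTyr"}
    return CountMatrix(df, groups)


@pytest.fixture
def two_clique_similarity() -> pd.DataFrame:
    """Two disjoint 4-cliques at s=0.9 over a weak random background."""
    rng = np.random.default_rng(42)
    n = 12
    s = rng.uniform(0.0, 0.2, (n, n))
    s = (s + s.T) / 2
    for block in (range(0, 4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    s[i, j] = 0.9
    np.fill_diagonal(s, 1.0)
    ids = [f"m{i:02d}" for i in range(n)]
    return pd.DataFrame(s, index=ids, columns=ids)
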