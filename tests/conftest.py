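import numpy as np
import pandas as pd
import pytest

from coexcons.expr import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_fpkm():
    """3 genes x 4 samples FPKM matrix."""
    return ExpressionMatrix(
        values=pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [0.5, 1.5, 2.5, 3.5], [10.0, 0.0, 5.0, 2.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"],
        ),
        scale_tag="fpkm",
    )


def random_log2_matrix(rng, n_genes=20, n_samples=10, prefix="g"):
    """Continuous random matrix on the log2 scale (no ties)."""
    return ExpressionMatrix(
        values=pd.DataFrame(
            rng.normal(5.0, 2.0, size=(n_genes, n_samples)),
            index=[f"{prefix}{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        scale_tag="log2",
    )
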