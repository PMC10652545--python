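import numpy as np
import pandas as pd
import pytest

from dcnet.io import PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_expr():
    """8 samples × 5 genes, deterministic values."""
    g = np.random.default_rng(7)
    return pd.DataFrame(
        g.normal(size=(8, 5)),
        index=[f"s{i}" for i in range(1, 9)],
        columns=[f"g{j}" for j in range(1, 6)],
    )


@pytest.fixture
def tiny_pheno(tiny_expr):
    g = np.random.default_rng(8)
    df = pd.DataFrame(
        {
            "smoking": [0, 0, 0, 0, 1, 1, 1, 1],
            "age": g.normal(60, 5, size=8).round(1),
            "sex": ["F", "M", "F", "M", "M", "F", "M", "F"],
        },
        index=tiny_expr.index,
    )
    return PhenotypeTable(data=df, group_variable="smoking")


@pytest.fixture
def expr_file(tmp_path, tiny_expr):
    path = tmp_path / "expr.tsv"
    tiny_expr.to_csv(path, sep="\t", index_label="sample")
    return path


@pytest.fixture
def pheno_file(tmp_path, tiny_pheno):
    path = tmp_path / "pheno.tsv"
    tiny_pheno.data.to_csv(path, sep="\t", index_label="sample")
    return path
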