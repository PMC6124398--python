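import numpy as np
import pytest

from drugrepo import SyntheticConfig, generate


@pytest.fixture
def tiny_dgi_tsv(tmp_path):
    """4 rows with one duplicate pair: (D1,101) x2, (D1,102), (D2,101)."""
    path = tmp_path / "dgi.tsv"
    path.write_text(
        "drug_id\tname\tatc\tmesh\tentrez_id\tsymbol\n"
        "D1\tdrug one\tN06AB06\tDepression\t101\tGA\n"
        "D1\tdrug one\tN06AB06\tDepression\t101\tGA\n"
        "D1\tdrug one\tN06AB06\tDepression\t102\tGB\n"
        "D2\tdrug two\t\t\t101\tGA\n"
    )
    return path


@pytest.fixture
def tiny_gda_tsv(tmp_path):
    """Pairs {(101,A),(101,A),(102,A),(101,B)} -> 3 unique edges."""
    path = tmp_path / "gda.tsv"
    path.write_text(
        "entrez_id\tsymbol\tmesh_id\tmesh_name\tsource\n"
        "101\tGA\tMESH:A\tDisease A\tomim\n"
        "101\tGA\tMESH:A\tDisease A\tctd\n"
        "102\tGB\tMESH:A\tDisease A\tomim\n"
        "101\tGA\tMESH:B\tDisease B\thuge\n"
    )
    return path


@pytest.fixture(scope="session")
def small_planted():
    """Small planted network with maximal overlap fraction: every planted
    drug draws all targets from its disease's gene set."""
    cfg = SyntheticConfig(n_genes=500, n_drugs=40, n_diseases=8,
                          targets_per_drug=5, genes_per_disease=30,
                          n_planted=5, planted_overlap_fraction=1.0, seed=7)
    dgi, gda, truth = generate(cfg)
    return cfg, dgi, gda, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
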