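import numpy as np
import pandas as pd
import pytest

from cchepnet import ExpressionDataset, PhenotypeTable, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset with planted modules, shared across tests."""
    cfg = SimulationConfig(
        n_genes=400, module_sizes=(50, 40), module_loading=1.2,
        module_diet_shifts=(1.0, 0.0),
        phenotype_module_loadings=(2.5, 0.0), seed=101,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_dataset():
    """3 genes x 6 samples, hand-constructed."""
    meta = pd.DataFrame(
        {
            "strain": ["A", "A", "B", "B", "C", "C"],
            "diet": ["HP", "HS"] * 3,
            "week": ["wk1", "wk1", "wk2", "wk2", "wk1", "wk2"],
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    values = np.arange(18, dtype=float).reshape(3, 6)
    return ExpressionDataset(
        values=values,
        feature_ids=["TC1", "TC2", "TC3"],
        gene_symbols=["g1", "g2", "g3"],
        sample_ids=list(meta.index),
        metadata=meta,
    )


@pytest.fixture()
def toy_phenotypes(toy_dataset):
    return PhenotypeTable(pd.DataFrame(
        {"body_fat_pct": [20.0, 25.0, 22.0, 28.0, 21.0, np.nan]},
        index=pd.Index(toy_dataset.sample_ids, name="sample_id"),
    ))


def write_trio(tmp_path, dataset, phenotypes=None):
    from cchepnet import write_dataset
    e, m, p = tmp_path / "e.tsv", tmp_path / "m.tsv", tmp_path / "p.tsv"
    write_dataset(dataset, e, m, phenotypes, p if phenotypes is not None else None)
    return e, m, (p if phenotypes is not None else None)
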