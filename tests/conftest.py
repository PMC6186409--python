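import numpy as np
import pandas as pd
import pytest

from phenonet import ExpressionDataset, GeneSet, GeneSetCatalog, StudyConfig


def make_dataset(values, groups, dataset_id="DS1", view="rma-like",
                 scale="log2", detection=None):
    """Small expression dataset from a dict of gene -> sample values."""
    df = pd.DataFrame(values).T
    df.columns = [f"s{i + 1}" for i in range(df.shape[1])]
    groups = pd.Series(groups, index=df.columns)
    det = None
    if detection is not None:
        det = pd.DataFrame(detection).T
        det.columns = df.columns
    return ExpressionDataset(dataset_id, view, df, scale, groups, detection=det)


@pytest.fixture
def toy_catalog():
    cat = GeneSetCatalog()
    cat.add(GeneSet("A", "set A", {"g1", "g2", "g3", "g4"},
                    category="immune system", functional_tag="process"))
    cat.add(GeneSet("B", "set B", {"g3", "g4", "g5", "g6"},
                    category="signal transduction", functional_tag="signaling"))
    cat.add(GeneSet("C", "set C", {"g7", "g8"},
                    category="human diseases", functional_tag="other"))
    return cat


@pytest.fixture
def small_study():
    cfg = StudyConfig(n_genes=300, n_datasets=2, samples_per_group=[(4, 4), (4, 4)],
                      de_fraction_up=0.05, de_fraction_down=0.05, seed=7)
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
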