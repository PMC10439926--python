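import numpy as np
import pandas as pd
import pytest

from mitopath.datamodel import FeatureTable, LabeledDataset, Status, VariantRecord
from mitopath.synth import SynthTableSpec, ToyStructureSpec, gen_feature_table, gen_toy_structure


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """200-variant synthetic dataset, complete shape but cheap to model."""
    return gen_feature_table(SynthTableSpec(n_variants=200, seed=11))


@pytest.fixture(scope="session")
def helix_field():
    """Toy helix with a smooth logistic score ramp and its high-risk mask."""
    return gen_toy_structure(ToyStructureSpec(n_residues=80, seed=7))


@pytest.fixture()
def tiny_table() -> FeatureTable:
    df = pd.DataFrame(
        {"a": [1.0, 2.0, 3.0], "b": [0.5, np.nan, 1.5]},
        index=["v1", "v2", "v3"],
    )
    return FeatureTable(df)


def make_variant(pos, ref="A", alt="G", status=Status.none, codes=(), syn=False, af=None):
    return VariantRecord(
        mt_position=pos,
        ref_allele=ref,
        alt_allele=alt,
        status=status,
        clingen_codes=frozenset(codes),
        synergistic_or_conflicting=syn,
        af=af or {},
    )
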