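import numpy as np
import pandas as pd
import pytest

from toxinfer import (
    Dialect,
    ExpressionDataset,
    FixtureConfig,
    InteractionTable,
    generate_bundle,
)

TINY_OBO = """\
format-version: 1.2

[Term]
id: DOID:1
name: disease

[Term]
id: DOID:2
name: kidney disease
is_a: DOID:1 ! disease

[Term]
id: DOID:3
name: urinary system disease
synonym: "renal tract illness" EXACT []
is_a: DOID:1 ! disease

[Term]
id: DOID:4
name: chronic kidney failure
is_a: DOID:2 ! kidney disease
is_a: DOID:3 ! urinary system disease

[Term]
id: DOID:5
name: brain disease
is_a: DOID:1 ! disease

[Term]
id: DOID:9
name: retired disorder
is_obsolete: true
"""


@pytest.fixture
def tiny_obo(tmp_path):
    path = tmp_path / "tiny.obo"
    path.write_text(TINY_OBO)
    return path


@pytest.fixture
def rna_dataset():
    """3 genes x 2 tissues TPM matrix with one unmeasured cell."""
    values = pd.DataFrame(
        {
            "kidney": [0.2, 0.7, 6.0],
            "brain": [1.5, np.nan, 0.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="GeneID"),
    )
    return ExpressionDataset("TEST-RNA", Dialect.RNA_TPM, values)


@pytest.fixture
def interaction_table():
    table = InteractionTable()
    for chem, prot, score in [
        ("c1", "g1", 900),
        ("c1", "g2", 400),
        ("c1", "g3", 750),
        ("c2", "g1", 100),
        ("c2", "g4", 999),
    ]:
        table.add(chem, prot, score)
    return table


@pytest.fixture(scope="session")
def bundle():
    """Default planted-signal bundle, shared read-only across tests."""
    return generate_bundle(FixtureConfig(seed=1))
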