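import numpy as np
import pandas as pd
import pytest

from mirmeth import (
    OmicsMatrix,
    SampleAnnotationTable,
    TargetMap,
    assemble_study,
)


def make_tiny_study():
    """Two regions, two subjects, six genes, two miRNAs — values chosen so
    per-gene deltas are known in closed form."""
    genes = [f"g{i}" for i in range(1, 7)]
    mirnas_targets = {"m1": frozenset({"g1", "g2", "g3"}), "m2": frozenset({"g4"})}
    samples = ["s1_A", "s1_B", "s2_A", "s2_B"]
    rng = np.random.default_rng(42)
    base = rng.uniform(1.0, 10.0, size=(6, 1))
    # s1: region A = e * region B for every gene -> delta = 1
    # s2: region A = region B -> delta = 0
    mrna = pd.DataFrame(
        np.column_stack([base[:, 0] * np.e, base[:, 0], base[:, 0], base[:, 0]]),
        index=genes,
        columns=samples,
    )
    mirna = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(2, 4)), index=["m1", "m2"], columns=samples
    )
    meth = pd.DataFrame(
        np.column_stack(
            [np.full(6, 0.8), np.full(6, 0.3), np.full(6, 0.5), np.full(6, 0.5)]
        ),
        index=genes,
        columns=samples,
    )
    annotation = SampleAnnotationTable(
        table=pd.DataFrame(
            {
                "sample_id": samples,
                "subject_id": ["s1", "s1", "s2", "s2"],
                "region": ["A", "B", "A", "B"],
                "age": [60.0, 60.0, 45.0, 45.0],
                "gender": ["female", "female", "male", "male"],
            }
        )
    )
    return assemble_study(
        OmicsMatrix("mrna", mrna),
        OmicsMatrix("mirna", mirna),
        OmicsMatrix("methylation", meth),
        annotation,
        TargetMap(targets=mirnas_targets),
    )


@pytest.fixture
def tiny_study():
    return make_tiny_study()


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
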