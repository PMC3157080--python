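import numpy as np
import pandas as pd
import pytest

from nodalrisk.io import ExpressionMatrix, ReferenceCohort


def matrix_from(values, sample_ids=None, probe_ids=None, **kw) -> ExpressionMatrix:
    values = np.asarray(values, float)
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[0])]
    probe_ids = probe_ids or [f"P{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=probe_ids), **kw
    )


@pytest.fixture
def small_cohort() -> ReferenceCohort:
    """Four reference profiles over four probes with both nodal classes."""
    m = matrix_from(
        [[1, 2, 3, 4], [2, 1, 4, 3], [4, 3, 2, 1], [1, 3, 2, 4]],
        sample_ids=["R1", "R2", "R3", "R4"],
    )
    labels = pd.Series([1, 0, 1, 0], index=["R1", "R2", "R3", "R4"])
    return ReferenceCohort(matrix=m, labels=labels)
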