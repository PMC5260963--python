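import numpy as np
import pytest

from lfqdiff import IntensityMatrix, StudyDesign


@pytest.fixture
def small_design() -> StudyDesign:
    """15 patients (8 treated, 7 control), duplicate runs: 30 samples."""
    records = []
    for i in range(8):
        p = f"T{i + 1:02d}"
        records += [(f"{p}_r1", p, "treated", 1), (f"{p}_r2", p, "treated", 2)]
    for i in range(7):
        p = f"C{i + 1:02d}"
        records += [(f"{p}_r1", p, "control", 1), (f"{p}_r2", p, "control", 2)]
    return StudyDesign.from_records(records)


def make_matrix(values, samples=None, scale="linear", protein_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return IntensityMatrix(
        protein_ids=protein_ids or [f"P{i:03d}" for i in range(n)],
        samples=samples or [f"S{j:02d}" for j in range(m)],
        values=values,
        scale=scale,
    )


@pytest.fixture
def tiny_design() -> StudyDesign:
    """7 single-replicate patients: 4 treated, 3 control."""
    records = [(f"T{i}", f"T{i}", "treated", 1) for i in range(4)]
    records += [(f"C{i}", f"C{i}", "control", 1) for i in range(3)]
    return StudyDesign.from_records(records)
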