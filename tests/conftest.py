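import numpy as np
import pytest
from hypothesis import settings

from ductmap import (
    CellMeta,
    CtMatrix,
    GenePanel,
    ct_to_expression,
    generate_cohort,
    scaled_study_design,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_ct():
    """3 cells x 2 genes with one non-detect; values exact at 2 decimals."""
    panel = GenePanel(("Eln", "Vegfa"))
    cells = (
        CellMeta("c1", "littermate_control"),
        CellMeta("c2", "day1"),
        CellMeta("c3", "day7"),
    )
    ct = np.array([[20.00, 25.50], [18.25, 999.0], [24.00, 30.75]])
    return CtMatrix(cells=cells, panel=panel, ct=ct)


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled synthetic cohort (150 cells) with ground truth."""
    design, programs = scaled_study_design(n_cells=150)
    ct, truth = generate_cohort(design, programs, seed=11)
    return ct, truth


@pytest.fixture(scope="session")
def small_expression(small_cohort):
    ct, truth = small_cohort
    return ct_to_expression(ct), truth
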