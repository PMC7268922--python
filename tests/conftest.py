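import numpy as np
import pandas as pd
import pytest

from megalfc import ExpressionStudy


def make_study(case_by_gene, control_by_gene, study_id="S1", region="Spain",
               year=2012, gene_prefix="G", log_transformed=True):
    """Build a log2-scale study from per-gene case/control value lists."""
    genes = [f"{gene_prefix}{i + 1}" for i in range(len(case_by_gene))]
    case = np.atleast_2d(np.asarray(case_by_gene, dtype=float))
    ctrl = np.atleast_2d(np.asarray(control_by_gene, dtype=float))
    n_case, n_ctrl = case.shape[1], ctrl.shape[1]
    cols = ([f"{study_id}_C{j}" for j in range(n_ctrl)]
            + [f"{study_id}_P{j}" for j in range(n_case)])
    matrix = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=cols)
    groups = pd.Series(["control"] * n_ctrl + ["case"] * n_case, index=cols)
    return ExpressionStudy(study_id=study_id, matrix=matrix,
                           sample_groups=groups, region=region, year=year,
                           log_transformed=log_transformed)


@pytest.fixture
def toy_study():
    """3 genes x 4 samples (2 case / 2 control), log2 scale."""
    return make_study(
        case_by_gene=[[3.0, 5.0], [1.0, 1.0], [2.0, 2.0]],
        control_by_gene=[[2.0, 2.0], [1.0, 1.0], [1.0, 1.0]],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
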