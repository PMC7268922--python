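"""Per-(gene, study) effect sizes and QQ diagnostics.

The effect-size index is the log2 fold change (LFC): the difference of mean
log2 expression between the case and control arms of one study.  Its
standard error is the Welch-type two-sample estimate
``sqrt(s2_case/n_case + s2_control/n_control)`` with unbiased per-arm sample
variances, floored at ``SE_FLOOR`` so that degenerate (zero-variance) arms
cannot produce infinite meta-analytic weights.  z = LFC / SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .studies import ExpressionStudy

#: Lower bound on the standard error (log2 scale).  Only degenerate inputs
#: (identical values within both arms) ever reach it; it keeps weights finite.
SE_FLOOR = 1e-6


@dataclass(frozen=True)
class EffectRecord:
    """Log2-fold-change effect of one gene in one study."""

    gene: str
    study_id: str
    y: float       # log2 fold change, case minus control
    se: float      # Welch-type standard error of y
    z: float       # y / se
    n_case: int
    n_control: int


def _study_effects(study: ExpressionStudy) -> pd.DataFrame:
    """Vectorised LFC/SE/z for every gene of one (preprocessed) study."""
    case = study.case_matrix().to_numpy()
    ctrl = study.control_matrix().to_numpy()
    n_case, n_ctrl = case.shape[1], ctrl.shape[1]
    y = case.mean(axis=1) - ctrl.mean(axis=1)
    var_case = case.var(axis=1, ddof=1) if n_case > 1 else np.zeros(len(y))
    var_ctrl = ctrl.var(axis=1, ddof=1) if n_ctrl > 1 else np.zeros(len(y))
    se = np.sqrt(var_case / n_case + var_ctrl / n_ctrl)
    se = np.maximum(se, SE_FLOOR)
    return pd.DataFrame(
        {"y": y, "se": se, "z": y / se,
         "n_case": n_case, "n_control": n_ctrl},
        index=study.matrix.index,
    )


def effect_for_gene(study: ExpressionStudy, gene: str) -> EffectRecord | None:
    """Effect record for one gene, or None when the study does not measure it.

    The study is expected to be on the log2 scale (see
    :func:`megalfc.studies.preprocess`).
    """
    gene = gene.upper()
    if gene not in study.matrix.index:
        return None
    case = study.case_matrix().loc[gene].to_numpy(dtype=float)
    ctrl = study.control_matrix().loc[gene].to_numpy(dtype=float)
    y = float(case.mean() - ctrl.mean())
    var_case = float(case.var(ddof=1)) if case.size > 1 else 0.0
    var_ctrl = float(ctrl.var(ddof=1)) if ctrl.size > 1 else 0.0
    se = max(float(np.sqrt(var_case / case.size + var_ctrl / ctrl.size)),
             SE_FLOOR)
    return EffectRecord(gene=gene, study_id=study.study_id, y=y, se=se,
                        z=y / se, n_case=case.size, n_control=ctrl.size)


def effects_table(studies: list[ExpressionStudy],
                  genes) -> list[EffectRecord]:
    """One record per (gene, study) where the gene is measured.

    Ordering is deterministic: genes in the order given, studies in manifest
    order.  Genes absent from a study simply contribute no record, so their
    per-gene study count k shrinks.
    """
    genes = [g.upper() for g in genes]
    if not genes:
        raise ValueError("empty gene list")
    if not studies:
        raise ValueError("need at least one study")
    per_study = [(s, _study_effects(s)) for s in studies]
    records: list[EffectRecord] = []
    for gene in genes:
        for study, table in per_study:
            if gene not in table.index:
                continue
            row = table.loc[gene]
            records.append(EffectRecord(
                gene=gene, study_id=study.study_id,
                y=float(row["y"]), se=float(row["se"]), z=float(row["z"]),
                n_case=int(row["n_case"]), n_control=int(row["n_control"]),
            ))
    return records


def effects_frame(records: list[EffectRecord]) -> pd.DataFrame:
    """Records as a DataFrame (the TSV export layout)."""
    return pd.DataFrame([r.__dict__ for r in records],
                        columns=["gene", "study_id", "y", "se", "z",
                                 "n_case", "n_control"])


def qq_points_from_z(z) -> pd.DataFrame:
    """Pair sorted z-scores with standard-normal quantiles.

    Plotting positions are ``(i - 0.5) / m`` for i = 1..m.
    """
    z = np.sort(np.asarray(z, dtype=float))
    m = z.size
    if m < 2:
        raise ValueError("need at least two z-scores for a QQ table")
    theoretical = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
    return pd.DataFrame({"theoretical": theoretical, "observed": z})


def qq_points(study: ExpressionStudy) -> pd.DataFrame:
    """QQ table (theoretical normal quantile, observed z) over all genes of
    one study, for diagnosing the spread of per-gene z-scores."""
    if study.n_genes < 2:
        raise ValueError("need at least two genes for a QQ table")
    return qq_points_from_z(_study_effects(study)["z"].to_numpy())
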