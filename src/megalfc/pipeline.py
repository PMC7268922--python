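"""End-to-end orchestration: studies -> effects -> pooled per-gene report.

`run_mega_analysis` produces the four-rows-per-gene style report (full and
partial mega-analysis per gene) plus, on request, per-study forest tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import meta
from .effects import EffectRecord, effects_table
from .meta import MetaAnalysis, MetaAnalysisResults, significance_filter
from .studies import ExpressionStudy

RESULT_COLUMNS = ["gene", "analysis", "significant", "model", "k",
                  "pooled_lfc", "se_pooled", "ci_low", "ci_high", "p",
                  "Q", "df", "isq", "p_q", "tau2"]


@dataclass(frozen=True)
class MegaAnalysisReport:
    """Pooled results for a gene panel across a study collection."""

    results: tuple          # MetaAnalysisResults, full + partial per gene
    alpha: float
    lfc_up: float
    lfc_down: float

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            d = r.to_dict()
            d["significant"] = significance_filter(
                r, self.alpha, self.lfc_up, self.lfc_down)
            rows.append(d)
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    def significant_genes(self) -> list[str]:
        """Genes passing the filter in the full or the partial analysis."""
        hits = {
            r.gene for r in self.results
            if significance_filter(r, self.alpha, self.lfc_up, self.lfc_down)
        }
        return sorted(hits)

    def forest_frame(self) -> pd.DataFrame:
        frames = []
        for r in self.results:
            f = r.forest_frame()
            f.insert(0, "analysis", r.analysis)
            f.insert(0, "gene", r.gene)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def group_records(records: list[EffectRecord]) -> dict:
    """Records grouped per gene, preserving order."""
    by_gene: dict[str, list[EffectRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    return by_gene


def run_mega_analysis(studies: list[ExpressionStudy], genes,
                      mode: str = "auto", partial: bool = True,
                      alpha: float = meta.ALPHA,
                      lfc_up: float = meta.LFC_UP,
                      lfc_down: float = meta.LFC_DOWN) -> MegaAnalysisReport:
    """Pool every gene across the studies.

    Emits one full mega-analysis result per gene and, with
    ``partial=True``, also the partial (top-50% studies) result, mirroring
    how discordant genes — significant under one analysis only — are
    reported side by side.
    Genes measured in no study are silently omitted (k would be 0).
    """
    records = effects_table(studies, genes)
    results: list[MetaAnalysisResults] = []
    for gene, recs in group_records(records).items():
        model = MetaAnalysis.from_records(recs)
        results.append(model.fit(mode))
        if partial:
            results.append(model.fit_partial(mode))
    return MegaAnalysisReport(results=tuple(results), alpha=alpha,
                              lfc_up=lfc_up, lfc_down=lfc_down)
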