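"""Study-level moderator regression of per-study effect sizes.

For one gene, the per-study log2 fold changes are regressed (OLS, optionally
inverse-variance weighted) on three study-level moderators: total sample
size, study year, and region.  Region enters as treatment-coded dummies
against the most frequent level and is tested as a whole factor with the
nested-model F-test; numeric moderators get t-based 95% confidence
intervals.  With many small studies the region factor easily exhausts the
degrees of freedom, so levels are merged into a coarser grouping (by
default a continent map) whenever there are too many levels or any level
contains a single study; every merge is recorded in the design note.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .effects import EffectRecord

#: default coarse grouping for the reference collection's countries
DEFAULT_REGION_MERGE = {
    "SPAIN": "Europe",
    "UNITED KINGDOM": "Europe",
    "HUNGARY": "Europe",
    "NETHERLANDS": "Europe",
    "FRANCE": "Europe",
    "GERMANY": "Europe",
    "ITALY": "Europe",
    "UNITED STATES": "North America",
    "CANADA": "North America",
    "AUSTRALIA": "Oceania",
    "NEW ZEALAND": "Oceania",
    "CHINA": "Asia",
    "JAPAN": "Asia",
    "KOREA": "Asia",
    "RUSSIA": "Europe",
}

MAX_REGION_LEVELS = 3


def region_encode(regions, max_levels: int = MAX_REGION_LEVELS,
                  merge_map: dict | None = None
                  ) -> tuple[pd.DataFrame, str]:
    """Treatment-coded dummy columns for the region factor.

    The most frequent level (ties broken lexicographically) is the
    reference.  If there are more than ``max_levels`` distinct levels, or
    any level holds a single study, levels are first merged through
    ``merge_map`` (default: continent grouping; unmapped labels become
    "Other").  Returns ``(dummies, design_note)``; one distinct level yields
    zero columns.
    """
    regions = [str(r) for r in regions]
    if not regions:
        raise ValueError("need at least one region label")
    merge_map = DEFAULT_REGION_MERGE if merge_map is None else merge_map

    counts = Counter(regions)
    merged = False
    if len(counts) > 1 and (len(counts) > max_levels
                            or min(counts.values()) == 1):
        coarse = [merge_map.get(r.upper(), "Other") for r in regions]
        # only adopt the coarser grouping if it keeps the factor alive
        if 1 < len(set(coarse)) < len(counts):
            regions = coarse
            counts = Counter(regions)
            merged = True

    reference = min(counts, key=lambda lv: (-counts[lv], lv))
    levels = sorted(lv for lv in counts if lv != reference)
    dummies = pd.DataFrame(
        {f"region[{lv}]": [1.0 if r == lv else 0.0 for r in regions]
         for lv in levels},
        index=range(len(regions)),
    )
    note = (f"region coding: treatment vs reference {reference!r}, "
            f"levels {sorted(counts)}")
    if merged:
        note += " (levels merged to coarser grouping)"
    return dummies, note


@dataclass(frozen=True)
class ModeratorFitResults:
    """Coefficients, CIs and per-factor p-values of the moderator fit."""

    gene: str
    coefficients: dict
    ci_low: dict
    ci_high: dict
    p_values: dict           # sample_size, year, region (factor-level F)
    n_studies_used: int
    design_note: str

    def to_frame(self) -> pd.DataFrame:
        """One row per factor (the TSV export layout)."""
        rows = []
        for factor in ("sample_size", "year", "region"):
            rows.append({
                "gene": self.gene,
                "factor": factor,
                "estimate": self.coefficients.get(factor, np.nan),
                "ci_low": self.ci_low.get(factor, np.nan),
                "ci_high": self.ci_high.get(factor, np.nan),
                "p": self.p_values.get(factor, np.nan),
                "n_studies_used": self.n_studies_used,
                "design_note": self.design_note,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Moderator regression for {self.gene or 'effect'} "
                 f"(n={self.n_studies_used} studies)"]
        for factor in ("sample_size", "year"):
            if factor in self.coefficients:
                lines.append(
                    f"  {factor:<12} {self.coefficients[factor]:+.4g}  "
                    f"95% CI [{self.ci_low[factor]:+.4g}, "
                    f"{self.ci_high[factor]:+.4g}]  "
                    f"p={self.p_values[factor]:.3g}"
                )
        lines.append(f"  {'region':<12} (factor F-test)  "
                     f"p={self.p_values['region']:.3g}")
        lines.append(f"  {self.design_note}")
        return "\n".join(lines)


class ModeratorRegression:
    """OLS of one gene's per-study effects on study-level moderators."""

    def __init__(self, y, sample_sizes, years, regions, se=None,
                 study_ids=None, gene: str = "",
                 max_levels: int = MAX_REGION_LEVELS,
                 merge_map: dict | None = None):
        self.y = np.asarray(y, dtype=float)
        self.sample_sizes = np.asarray(sample_sizes, dtype=float)
        self.years = np.asarray(years, dtype=float)
        self.regions = [str(r) for r in regions]
        self.se = None if se is None else np.asarray(se, dtype=float)
        n = self.y.size
        if not (len(self.regions) == self.sample_sizes.size
                == self.years.size == n):
            raise ValueError("moderator arrays must have equal length")
        self.study_ids = (tuple(study_ids) if study_ids is not None
                          else tuple(f"study{i + 1}" for i in range(n)))
        self.gene = gene
        self.max_levels = max_levels
        self.merge_map = merge_map

    @classmethod
    def from_records(cls, records: list[EffectRecord],
                     studies) -> "ModeratorRegression":
        """Build from one gene's effect records plus the study objects
        (which carry region/year metadata)."""
        if not records:
            raise ValueError("no effect records")
        genes = {r.gene for r in records}
        if len(genes) > 1:
            raise ValueError(f"records mix genes: {sorted(genes)}")
        meta = {s.study_id: s for s in studies}
        missing = [r.study_id for r in records if r.study_id not in meta]
        if missing:
            raise ValueError(f"no metadata for studies {missing}")
        return cls(
            y=[r.y for r in records],
            sample_sizes=[r.n_case + r.n_control for r in records],
            years=[meta[r.study_id].year for r in records],
            regions=[meta[r.study_id].region for r in records],
            se=[r.se for r in records],
            study_ids=[r.study_id for r in records],
            gene=records[0].gene,
        )

    def _design(self) -> tuple[pd.DataFrame, str]:
        dummies, note = region_encode(self.regions, self.max_levels,
                                      self.merge_map)
        X = pd.DataFrame({
            "const": 1.0,
            "sample_size": self.sample_sizes,
            "year": self.years,
        }, index=range(self.y.size))
        X = pd.concat([X, dummies], axis=1)
        return X, note

    def fit(self, weighted: bool = False) -> ModeratorFitResults:
        """Fit the moderator regression.

        ``weighted=True`` uses inverse-variance weights 1/se^2 (WLS);
        the default is plain OLS.  Requires at least two more studies than
        fitted parameters and a full-rank design.
        """
        X, note = self._design()
        n, p = X.shape
        if n < p + 2:
            raise ValueError(
                f"{n} studies cannot support {p} parameters; need at least "
                f"{p + 2} studies (merge region levels or drop moderators)"
            )
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < p:
            offender = self._diagnose_rank(X)
            raise ValueError(
                f"rank-deficient design (rank {rank} < {p} parameters); "
                f"offending factor: {offender}; merge its levels or remove it"
            )
        if weighted:
            if self.se is None:
                raise ValueError("weighted fit needs per-study standard "
                                 "errors")
            model = sm.WLS(self.y, X, weights=1.0 / self.se**2)
        else:
            model = sm.OLS(self.y, X)
        res = model.fit()

        region_cols = [c for c in X.columns if c.startswith("region[")]
        if region_cols:
            contrast = np.zeros((len(region_cols), p))
            for i, col in enumerate(region_cols):
                contrast[i, X.columns.get_loc(col)] = 1.0
            p_region = float(res.f_test(contrast).pvalue)
        else:
            p_region = 1.0  # single region level: nothing to test
            note += "; single region level, factor untestable"

        conf = res.conf_int(alpha=0.05)
        coefficients = dict(res.params)
        return ModeratorFitResults(
            gene=self.gene,
            coefficients=coefficients,
            ci_low={k: float(conf.loc[k, 0]) for k in X.columns},
            ci_high={k: float(conf.loc[k, 1]) for k in X.columns},
            p_values={
                "sample_size": float(res.pvalues["sample_size"]),
                "year": float(res.pvalues["year"]),
                "region": p_region,
            },
            n_studies_used=n,
            design_note=note,
        )

    def _diagnose_rank(self, X: pd.DataFrame) -> str:
        base_cols = ["const", "sample_size", "year"]
        base = X[base_cols].to_numpy()
        if np.linalg.matrix_rank(base) == base.shape[1]:
            return "region (e.g. one study per level)"
        if np.unique(self.years).size == 1:
            return "year (constant)"
        if np.unique(self.sample_sizes).size == 1:
            return "sample_size (constant)"
        return "numeric moderators (collinear)"


def fit_moderators(records: list[EffectRecord], studies,
                   weighted: bool = False) -> ModeratorFitResults:
    """Study-level moderator regression for one gene's effect records."""
    return ModeratorRegression.from_records(records, studies).fit(weighted)
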