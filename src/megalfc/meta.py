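"""Per-gene pooling of study effects: fixed- and random-effects models,
heterogeneity, model selection, the partial (top-50%) variant and the
asymmetric fold-change significance filter.

Model
-----
For one gene with effects y_i and standard errors se_i from k studies:

* fixed effect: weights w_i = 1/se_i^2, pooled = sum(w y)/sum(w),
  se_pooled = sum(w)^(-1/2);
* heterogeneity: Cochran's Q = sum w_i (y_i - pooled_fe)^2 with df = k - 1;
  ISq = 100 x (Q - df)/Q truncated at 0; p_Q is the upper chi-square tail
  of Q at df (the probability that within-study variance alone explains the
  total variance), 1 when k = 1;
* random effects (DerSimonian-Laird): tau2 = max(0, (Q - df)/C) with
  C = sum(w) - sum(w^2)/sum(w); star weights 1/(se_i^2 + tau2).

Model selection ("auto"): ISq = 0 selects the fixed-effects model, anything
else the random-effects model.  Heterogeneity statistics are always reported
from the fixed-effect weights, whichever model is returned.

The partial mega-analysis re-pools, per gene, only the floor(k/2) studies
with the largest |y| (at least one), a sensitivity variant that surfaces
genes altered in some but not all studies.

Significance uses a raw p threshold with an asymmetric fold-change gate:
p < 1e-7 and LFC > 0.49 or < -0.74 (roughly a >40% increase or decrease on
the linear scale).  No multiple-testing correction is applied at this
stage — the raw threshold is deliberately stringent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectRecord

#: default significance thresholds
ALPHA = 1e-7
LFC_UP = 0.49
LFC_DOWN = -0.74

#: two-sided 95% normal critical value
Z_95 = stats.norm.ppf(0.975)


def significance_filter(result: "MetaAnalysisResults", alpha: float = ALPHA,
                        up: float = LFC_UP, down: float = LFC_DOWN) -> bool:
    """True iff p < alpha and pooled LFC > up or < down (all strict)."""
    if not (math.isfinite(up) and math.isfinite(down) and up > 0 > down):
        raise ValueError("need finite thresholds with up > 0 > down")
    return bool(result.p < alpha
                and (result.pooled_lfc > up or result.pooled_lfc < down))


def partial_select(effects: list[EffectRecord]) -> list[EffectRecord]:
    """Per-gene top-50% study selection for the partial mega-analysis.

    Keeps the floor(k/2) records with largest |y| (at least one).  Ties on
    |y| are broken by smaller se, then by study_id, so the selected set does
    not depend on input order.  Records are returned in their input order.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("no effect records")
    n_keep = max(1, k // 2)
    ranked = sorted(effects, key=lambda r: (-abs(r.y), r.se, r.study_id))
    chosen = set(id(r) for r in ranked[:n_keep])
    return [r for r in effects if id(r) in chosen]


@dataclass(frozen=True)
class MetaAnalysisResults:
    """Pooled per-gene result (one row of the mega-analysis report).

    ``weights`` are the per-study normalized weights of the model actually
    used (they sum to 1); heterogeneity fields (Q, df, isq, p_q) always come
    from the fixed-effect weights.
    """

    gene: str
    analysis: str            # "MA" or "partial-MA"
    model: str               # "fixed" or "random"
    k: int
    pooled_lfc: float
    se_pooled: float
    ci_low: float
    ci_high: float
    p: float
    Q: float
    df: int
    isq: float
    p_q: float
    tau2: float
    study_ids: tuple
    weights: tuple           # normalized, parallel to study_ids
    y: tuple                 # per-study effects, parallel to study_ids
    se: tuple

    @property
    def significant(self) -> bool:
        return significance_filter(self)

    def forest_frame(self) -> pd.DataFrame:
        """Per-study effects, 95% CIs and normalized weights (the quantities
        a forest plot displays)."""
        y = np.asarray(self.y)
        se = np.asarray(self.se)
        return pd.DataFrame({
            "study_id": self.study_ids,
            "y": y,
            "ci_low": y - Z_95 * se,
            "ci_high": y + Z_95 * se,
            "normalized_weight": self.weights,
        })

    def to_dict(self) -> dict:
        return {
            "gene": self.gene, "analysis": self.analysis,
            "significant": self.significant, "model": self.model,
            "k": self.k, "pooled_lfc": self.pooled_lfc,
            "se_pooled": self.se_pooled, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p, "Q": self.Q,
            "df": self.df, "isq": self.isq, "p_q": self.p_q,
            "tau2": self.tau2,
        }

    def summary(self) -> str:
        lines = [
            f"Meta-analysis of {self.gene or 'effect'} "
            f"({self.analysis}, {self.model}-effects model, k={self.k})",
            f"  pooled LFC {self.pooled_lfc:+.4f}  "
            f"95% CI [{self.ci_low:+.4f}, {self.ci_high:+.4f}]  "
            f"p={self.p:.3g}",
            f"  heterogeneity: Q={self.Q:.4f} (df={self.df}), "
            f"ISq={self.isq:.2f}%, p-Q={self.p_q:.3g}, tau2={self.tau2:.4g}",
            f"  significant (p<{ALPHA:g}, LFC>{LFC_UP} or <{LFC_DOWN}): "
            f"{'Yes' if self.significant else 'No'}",
        ]
        return "\n".join(lines)


class MetaAnalysis:
    """Inverse-variance meta-analysis of one gene's per-study effects.

    Parameters
    ----------
    y, se : array-like
        Per-study log2 fold changes and their standard errors (se > 0).
    study_ids : sequence of str, optional
    gene : str, optional

    ``fit(method=...)`` pools the studies; ``fit_partial`` first applies the
    per-gene top-50% selection.
    """

    def __init__(self, y, se, study_ids=None, gene: str = ""):
        self.y = np.asarray(y, dtype=float)
        self.se = np.asarray(se, dtype=float)
        if self.y.ndim != 1 or self.y.shape != self.se.shape:
            raise ValueError("y and se must be 1-d arrays of equal length")
        if self.y.size == 0:
            raise ValueError("no effect records")
        if not (np.isfinite(self.y).all() and np.isfinite(self.se).all()):
            raise ValueError("non-finite effect or standard error")
        if (self.se <= 0).any():
            raise ValueError("standard errors must be > 0")
        if study_ids is None:
            study_ids = [f"study{i + 1}" for i in range(self.y.size)]
        if len(study_ids) != self.y.size:
            raise ValueError("study_ids length mismatch")
        self.study_ids = tuple(str(s) for s in study_ids)
        self.gene = gene

    @classmethod
    def from_records(cls, records: list[EffectRecord]) -> "MetaAnalysis":
        if not records:
            raise ValueError("no effect records")
        genes = {r.gene for r in records}
        if len(genes) > 1:
            raise ValueError(f"records mix genes: {sorted(genes)}")
        return cls([r.y for r in records], [r.se for r in records],
                   study_ids=[r.study_id for r in records],
                   gene=records[0].gene)

    @property
    def k(self) -> int:
        return self.y.size

    # -- internals -----------------------------------------------------------

    def _heterogeneity(self) -> tuple[float, int, float, float, np.ndarray]:
        """(Q, df, isq, p_q, fixed-effect weights)."""
        w = 1.0 / self.se**2
        pooled = float(np.sum(w * self.y) / np.sum(w))
        Q = float(np.sum(w * (self.y - pooled) ** 2))
        df = self.k - 1
        if Q <= df or Q <= 0.0:
            isq = 0.0
        else:
            isq = 100.0 * (Q - df) / Q
        p_q = float(stats.chi2.sf(Q, df)) if df >= 1 else 1.0
        return Q, df, isq, p_q, w

    def _pooled(self, w: np.ndarray, model: str, tau2: float,
                analysis: str) -> MetaAnalysisResults:
        s = float(np.sum(w))
        pooled = float(np.sum(w * self.y) / s)
        se_pooled = float(1.0 / math.sqrt(s))
        z = pooled / se_pooled
        p = float(2.0 * stats.norm.sf(abs(z)))
        Q, df, isq, p_q, _ = self._heterogeneity()
        return MetaAnalysisResults(
            gene=self.gene, analysis=analysis, model=model, k=self.k,
            pooled_lfc=pooled, se_pooled=se_pooled,
            ci_low=pooled - Z_95 * se_pooled,
            ci_high=pooled + Z_95 * se_pooled,
            p=p, Q=Q, df=df, isq=isq, p_q=p_q, tau2=tau2,
            study_ids=self.study_ids,
            weights=tuple(w / s),
            y=tuple(self.y), se=tuple(self.se),
        )

    # -- fitting -------------------------------------------------------------

    def fit_fixed(self, analysis: str = "MA") -> MetaAnalysisResults:
        """Fixed-effects (common-effect) inverse-variance pooling."""
        w = 1.0 / self.se**2
        return self._pooled(w, "fixed", 0.0, analysis)

    def fit_random(self, analysis: str = "MA") -> MetaAnalysisResults:
        """DerSimonian-Laird random-effects pooling (k >= 2)."""
        if self.k < 2:
            raise ValueError("random-effects model needs at least 2 studies")
        Q, df, _, _, w = self._heterogeneity()
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
        w_star = 1.0 / (self.se**2 + tau2)
        return self._pooled(w_star, "random", tau2, analysis)

    def fit(self, method: str = "auto",
            analysis: str = "MA") -> MetaAnalysisResults:
        """Pool the studies.

        ``method="auto"`` applies the heterogeneity-driven selection rule:
        the fixed-effects model whenever ISq = 0 (i.e. Q <= df), otherwise
        the random-effects model.  ``"fixed"``/``"random"`` force a model.
        """
        if method == "fixed":
            return self.fit_fixed(analysis)
        if method == "random":
            return self.fit_random(analysis)
        if method != "auto":
            raise ValueError(f"unknown method {method!r}")
        _, _, isq, _, _ = self._heterogeneity()
        if isq == 0.0:
            return self.fit_fixed(analysis)
        return self.fit_random(analysis)

    # -- partial mega-analysis ----------------------------------------------

    def _records(self) -> list[EffectRecord]:
        return [
            EffectRecord(gene=self.gene, study_id=sid, y=float(y),
                         se=float(se), z=float(y / se), n_case=0, n_control=0)
            for sid, y, se in zip(self.study_ids, self.y, self.se)
        ]

    def top_half(self) -> "MetaAnalysis":
        """Submodel restricted to the top-50% studies by |y|."""
        chosen = partial_select(self._records())
        return MetaAnalysis([r.y for r in chosen], [r.se for r in chosen],
                            study_ids=[r.study_id for r in chosen],
                            gene=self.gene)

    def fit_partial(self, method: str = "auto") -> MetaAnalysisResults:
        """Partial mega-analysis: pool only the top-50% studies by |y|."""
        return self.top_half().fit(method, analysis="partial-MA")


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fixed_effect(effects: list[EffectRecord]) -> MetaAnalysisResults:
    """Fixed-effects pooling of a gene's effect records."""
    return MetaAnalysis.from_records(effects).fit_fixed()


def random_effect(effects: list[EffectRecord]) -> MetaAnalysisResults:
    """DerSimonian-Laird random-effects pooling of a gene's effect records."""
    return MetaAnalysis.from_records(effects).fit_random()


def mega(effects: list[EffectRecord],
         mode: str = "auto") -> MetaAnalysisResults:
    """Mega-analysis with heterogeneity-driven model selection."""
    return MetaAnalysis.from_records(effects).fit(mode)


def partial_mega(effects: list[EffectRecord],
                 mode: str = "auto") -> MetaAnalysisResults:
    """Partial mega-analysis: top-50% studies by |effect|, then pool."""
    return MetaAnalysis.from_records(effects).fit_partial(mode)
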