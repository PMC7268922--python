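"""Synthetic multi-study case/control expression collections.

The generator emulates a collection of independent case/control microarray
studies of the kind pooled by a cross-study mega-analysis: per-gene log2
baselines, planted true log2 fold changes theta_g, optional between-study
heterogeneity tau2_g (study-specific effect deviations), Gaussian
within-arm noise on the log2 scale, and study metadata (country/region,
year, per-arm sample sizes).  Matrices are exported on the *linear* scale
(2**x) so the pipeline's own log2 step is exercised.

Defaults mirror the nine-study COPD/senescence collection that motivated the
pipeline: nine studies with the published per-arm sample sizes, six source
countries, study years spanning 2008-2016.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .studies import ExpressionStudy

#: (n_control, n_case) pairs of the nine reference COPD case/control
#: datasets; used as the default per-study arm sizes.
REFERENCE_ARM_SIZES = (
    (20, 18), (6, 10), (24, 30), (9, 23), (135, 22),
    (6, 6), (10, 10), (27, 36), (19, 16),
)

#: Distinct source countries of the reference collection.
REFERENCE_REGIONS = (
    "Spain", "United Kingdom", "United States", "Hungary",
    "Australia", "Netherlands",
)

REFERENCE_YEAR_RANGE = (2008, 2016)


def _as_gene_array(value, n_genes: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_genes,)).copy()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of a synthetic multi-study collection.

    ``true_lfc`` (theta_g), ``tau2`` (between-study variance of the
    study-specific effect) and ``baseline_mean`` may be scalars or per-gene
    arrays of length ``n_genes``.  ``n_case_per_study``/``n_control_per_study``
    may be scalars or per-study sequences; when left at None the nine
    reference arm-size pairs are used (cycled if ``n_studies != 9``).
    ``dropout`` is the per-(gene, study) probability that a gene is not
    measured in a study, exercising variable per-gene study counts.
    """

    n_studies: int = 9
    n_genes: int = 200
    n_case_per_study: object = None
    n_control_per_study: object = None
    true_lfc: object = 0.0
    tau2: object = 0.0
    sigma: float = 0.5
    baseline_mean: object = 7.0
    dropout: float = 0.0
    regions: tuple = REFERENCE_REGIONS
    year_range: tuple = REFERENCE_YEAR_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_genes < 1:
            raise ValueError("n_studies and n_genes must be >= 1")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if (self.theta < -50).any() or (self.theta > 50).any():
            raise ValueError("true_lfc out of plausible log2 range")
        if (self.tau2_per_gene < 0).any():
            raise ValueError("tau2 must be >= 0 elementwise")
        for n in (*self.case_sizes, *self.control_sizes):
            if n < 1:
                raise ValueError("per-study arm sizes must be >= 1")
        if len(self.regions) < 1:
            raise ValueError("regions pool must be non-empty")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (low, high)")

    # -- resolved per-gene / per-study arrays --------------------------------

    @property
    def theta(self) -> np.ndarray:
        return _as_gene_array(self.true_lfc, self.n_genes, "true_lfc")

    @property
    def tau2_per_gene(self) -> np.ndarray:
        return _as_gene_array(self.tau2, self.n_genes, "tau2")

    @property
    def baseline(self) -> np.ndarray:
        return _as_gene_array(self.baseline_mean, self.n_genes,
                              "baseline_mean")

    def _arm(self, value, which: int) -> tuple:
        if value is None:
            ref = [REFERENCE_ARM_SIZES[i % len(REFERENCE_ARM_SIZES)][which]
                   for i in range(self.n_studies)]
            return tuple(ref)
        if np.isscalar(value):
            return (int(value),) * self.n_studies
        sizes = tuple(int(v) for v in value)
        if len(sizes) != self.n_studies:
            raise ValueError("per-study sample sizes must have length "
                             f"n_studies={self.n_studies}")
        return sizes

    @property
    def control_sizes(self) -> tuple:
        return self._arm(self.n_control_per_study, 0)

    @property
    def case_sizes(self) -> tuple:
        return self._arm(self.n_case_per_study, 1)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    def true_effects(self) -> pd.DataFrame:
        """Planted ground truth (theta_g, tau2_g) for recovery tests."""
        return pd.DataFrame({
            "gene": self.gene_ids,
            "true_lfc": self.theta,
            "tau2": self.tau2_per_gene,
        }).set_index("gene")


def _study_rng(config: SimulationConfig, study_index: int) -> np.random.Generator:
    # per-study stream keyed on (seed, index): generate_study(i) is
    # reproducible in isolation and collections are order-independent
    return np.random.default_rng([int(config.seed), int(study_index)])


def generate_study(config: SimulationConfig, study_index: int) -> ExpressionStudy:
    """Simulate one study of the collection.

    Control samples are drawn N(baseline_g, sigma^2) on the log2 scale; case
    samples N(baseline_g + theta_g + delta_gs, sigma^2) where the study-level
    deviation delta_gs ~ N(0, tau2_g).  The exported matrix is linear-scale
    (2**x, hence strictly positive).  With ``dropout`` > 0 a Bernoulli mask
    removes genes from this study entirely.
    """
    if not 0 <= study_index < config.n_studies:
        raise ValueError(
            f"study_index {study_index} out of range [0, {config.n_studies})"
        )
    rng = _study_rng(config, study_index)
    n_ctrl = config.control_sizes[study_index]
    n_case = config.case_sizes[study_index]
    g = config.n_genes

    delta = np.where(
        config.tau2_per_gene > 0,
        rng.normal(0.0, np.sqrt(np.maximum(config.tau2_per_gene, 0.0))),
        0.0,
    )
    base = config.baseline[:, None]
    ctrl = rng.normal(base, config.sigma, size=(g, n_ctrl))
    case = rng.normal(base + (config.theta + delta)[:, None], config.sigma,
                      size=(g, n_case))

    study_id = f"SYN{study_index + 1:02d}"
    ctrl_ids = [f"{study_id}_C{j + 1:03d}" for j in range(n_ctrl)]
    case_ids = [f"{study_id}_P{j + 1:03d}" for j in range(n_case)]
    matrix = pd.DataFrame(
        np.power(2.0, np.hstack([ctrl, case])),
        index=config.gene_ids,
        columns=ctrl_ids + case_ids,
    )
    groups = pd.Series(
        ["control"] * n_ctrl + ["case"] * n_case,
        index=matrix.columns, name="group",
    )

    if config.dropout > 0:
        keep = rng.random(g) >= config.dropout
        if not keep.any():  # a study must measure something
            keep[rng.integers(g)] = True
        matrix = matrix.loc[keep]

    region = config.regions[rng.integers(len(config.regions))]
    year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))

    return ExpressionStudy(
        study_id=study_id,
        matrix=matrix,
        sample_groups=groups,
        region=region,
        year=year,
        size_compliant=(n_ctrl + n_case) >= 10,
    )


def generate_collection(config: SimulationConfig) -> list[ExpressionStudy]:
    """Simulate the full collection of ``config.n_studies`` studies."""
    return [generate_study(config, i) for i in range(config.n_studies)]


@dataclass(frozen=True)
class GeneSetPair:
    """Two synthetic annotated gene lists over a common universe."""

    a: frozenset
    b: frozenset
    universe: frozenset

    @property
    def overlap(self) -> frozenset:
        return self.a & self.b


def generate_genesets(n_universe: int, n_a: int, n_b: int, n_overlap: int,
                      seed: int = 0) -> GeneSetPair:
    """Draw two gene sets with an exact intersection size from a universe.

    Raises ``ValueError`` for infeasible sizes
    (``n_overlap > min(n_a, n_b)`` or ``n_a + n_b - n_overlap > n_universe``).
    """
    if n_overlap > min(n_a, n_b):
        raise ValueError("n_overlap cannot exceed min(n_a, n_b)")
    if n_a + n_b - n_overlap > n_universe:
        raise ValueError("universe too small for the requested union")
    if min(n_universe, n_a, n_b) < 1 or n_overlap < 0:
        raise ValueError("set sizes must be positive (overlap >= 0)")
    rng = np.random.default_rng(seed)
    universe = np.array([f"U{i + 1:06d}" for i in range(n_universe)])
    picked = rng.choice(n_universe, size=n_a + n_b - n_overlap, replace=False)
    common = universe[picked[:n_overlap]]
    a_only = universe[picked[n_overlap:n_a]]
    b_only = universe[picked[n_a:]]
    return GeneSetPair(
        a=frozenset(common) | frozenset(a_only),
        b=frozenset(common) | frozenset(b_only),
        universe=frozenset(universe),
    )


def write_collection(config: SimulationConfig, out_dir) -> "Path":
    """Write every study, the planted truth and a manifest TSV; returns the
    manifest path."""
    from pathlib import Path

    from .studies import write_manifest, write_study

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in generate_collection(config):
        paths = write_study(study, out_dir)
        rows.append({"study_id": study.study_id,
                     **{k: p.name for k, p in paths.items()}})
    config.true_effects().to_csv(out_dir / "true_effects.tsv", sep="\t")
    manifest = out_dir / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest
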