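"""Case/control expression studies: container, file I/O and preprocessing.

A study is a gene x sample expression matrix with a case/control label per
sample plus study-level metadata (region, year, arm sizes).  Matrices are
exchanged as TSV/CSV with genes as rows and samples as columns; phenotype and
metadata travel in separate tab-separated tables so that a collection of
studies can be described by a plain manifest file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("megalfc")

#: Studies with fewer total samples than this are flagged (not rejected):
#: the dataset-inclusion rule requires at least 10 samples per study.
MIN_SAMPLES = 10

#: If the largest matrix value exceeds this, the data are judged to be on the
#: linear scale and log2(x + 1) is applied; log2-scale expression data
#: essentially never exceed 50 while linear-scale intensities routinely do.
LOG_DETECT_THRESHOLD = 50.0

NORMALIZATION_METHODS = ("median-scale", "quantile", "none")


@dataclass(frozen=True)
class ExpressionStudy:
    """One case/control expression study.

    Parameters
    ----------
    study_id : str
        Unique label for the study.
    matrix : pandas.DataFrame
        Expression values, genes as rows (index = gene symbols, upper-cased)
        and samples as columns.
    sample_groups : pandas.Series
        ``"case"`` / ``"control"`` label per sample; index must equal the
        matrix columns.
    region : str
        Country or region where the study was performed.
    year : int
        Study year.
    size_compliant : bool
        False when the study has fewer than 10 samples in total.
    log_transformed : bool
        Whether the matrix is on the log2 scale (set by :func:`preprocess`).
    normalization : str
        Cross-sample normalization applied, one of ``NORMALIZATION_METHODS``
        or ``"raw"`` before preprocessing.
    dropped_genes : tuple of str
        Genes removed from this study because of missing values.
    """

    study_id: str
    matrix: pd.DataFrame
    sample_groups: pd.Series
    region: str = "NA"
    year: int = 0
    size_compliant: bool = True
    log_transformed: bool = False
    normalization: str = "raw"
    dropped_genes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.matrix.index.is_unique:
            raise ValueError(
                f"study {self.study_id!r}: duplicate gene identifiers"
            )
        if list(self.matrix.columns) != list(self.sample_groups.index):
            raise ValueError(
                f"study {self.study_id!r}: sample_groups index does not "
                "match matrix columns"
            )
        groups = set(self.sample_groups.unique())
        if not groups <= {"case", "control"}:
            raise ValueError(
                f"study {self.study_id!r}: phenotype labels must be "
                f"'case'/'control', got {sorted(groups)}"
            )
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError(
                f"study {self.study_id!r}: needs at least one case and one "
                f"control sample (n_case={self.n_case}, "
                f"n_control={self.n_control})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_case(self) -> int:
        return int((self.sample_groups == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.sample_groups == "control").sum())

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def case_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[:, self.sample_groups == "case"]

    def control_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[:, self.sample_groups == "control"]

    def metadata(self) -> dict:
        return {
            "study_id": self.study_id,
            "region": self.region,
            "year": self.year,
            "n_case": self.n_case,
            "n_control": self.n_control,
        }


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_study(matrix_path, phenotype_path, metadata_path) -> ExpressionStudy:
    """Load one study from a matrix, a phenotype table and a metadata table.

    The phenotype table has columns ``sample_id`` and ``group`` (case or
    control); the metadata table has ``study_id``, ``region``, ``year``,
    ``n_case``, ``n_control``.  Sample ids must match the matrix columns
    exactly (any mismatch is a hard error).  Genes with a missing value are
    dropped from the study and logged.  Studies with fewer than 10 samples
    are loaded but flagged ``size_compliant=False``.
    """
    matrix = _read_table(matrix_path)
    matrix.index = matrix.index.astype(str).str.upper()

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(pheno.columns):
        raise ValueError(
            f"{phenotype_path}: phenotype table needs columns "
            "'sample_id' and 'group'"
        )
    pheno = pheno.set_index("sample_id")["group"].str.lower()

    matrix_samples = set(map(str, matrix.columns))
    pheno_samples = set(pheno.index)
    if matrix_samples != pheno_samples:
        missing = sorted(pheno_samples - matrix_samples)
        extra = sorted(matrix_samples - pheno_samples)
        raise ValueError(
            f"sample id mismatch between {matrix_path} and {phenotype_path}: "
            f"absent from matrix={missing}, unlabelled={extra}"
        )
    pheno = pheno.reindex(matrix.columns.astype(str))
    pheno.index = matrix.columns

    meta = pd.read_csv(metadata_path, sep="\t").iloc[0]

    # Duplicate gene rows (e.g. residual multi-probe genes): keep the row
    # with the highest mean expression.
    if not matrix.index.is_unique:
        dup = matrix.index.duplicated().sum()
        logger.info("%s: collapsed %d duplicate gene rows (kept highest mean)",
                    meta["study_id"], dup)
        matrix = matrix.groupby(level=0, sort=False).apply(
            lambda df: df.iloc[df.mean(axis=1).to_numpy().argmax()]
        )

    na_genes = tuple(matrix.index[matrix.isna().any(axis=1)])
    if na_genes:
        logger.info("%s: dropped %d genes with missing values: %s",
                    meta["study_id"], len(na_genes), ", ".join(na_genes[:10]))
        matrix = matrix.drop(index=list(na_genes))

    n_total = matrix.shape[1]
    compliant = n_total >= MIN_SAMPLES
    if not compliant:
        logger.warning(
            "%s: only %d samples (< %d); study flagged non-compliant with "
            "the sample-size inclusion rule", meta["study_id"], n_total,
            MIN_SAMPLES,
        )

    return ExpressionStudy(
        study_id=str(meta["study_id"]),
        matrix=matrix.astype(float),
        sample_groups=pheno,
        region=str(meta["region"]),
        year=int(meta["year"]),
        size_compliant=compliant,
        dropped_genes=na_genes,
    )


def write_study(study: ExpressionStudy, out_dir) -> dict:
    """Write a study as matrix/phenotype/metadata TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{study.study_id}_matrix.tsv",
        "phenotype": out_dir / f"{study.study_id}_phenotype.tsv",
        "metadata": out_dir / f"{study.study_id}_metadata.tsv",
    }
    study.matrix.to_csv(paths["matrix"], sep="\t", index_label="gene",
                        float_format="%.6f")
    pheno = study.sample_groups.rename("group").rename_axis("sample_id")
    pheno.to_frame().to_csv(paths["phenotype"], sep="\t")
    pd.DataFrame([study.metadata()]).to_csv(paths["metadata"], sep="\t",
                                            index=False)
    return paths


def _median_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    medians = matrix.median(axis=0)
    return matrix - medians + medians.mean()

def _quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    ranked = matrix.rank(axis=0, method="average")
    means = np.sort(matrix.values, axis=0).mean(axis=1)
    # interpolate mean quantiles at (possibly tied) average ranks
    grid = np.arange(1, matrix.shape[0] + 1, dtype=float)
    out = matrix.copy()
    for col in matrix.columns:
        out[col] = np.interp(ranked[col].values, grid, means)
    return out


def preprocess(study: ExpressionStudy, method: str = "median-scale",
               log_detect_threshold: float = LOG_DETECT_THRESHOLD,
               force_log: bool | None = None) -> ExpressionStudy:
    """Log2-transform (if the data look linear-scale) and normalize.

    Scale detection: a maximum value above ``log_detect_threshold`` marks
    the matrix as linear-scale and log2(x + 1) is applied; already-logged
    matrices pass through unchanged, making the step idempotent.  Detection
    can be overridden with ``force_log``.  Normalization is one of
    ``median-scale`` (per-sample median alignment, the default), ``quantile``
    or ``none``.
    """
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    matrix = study.matrix
    if not np.isfinite(matrix.values).all():
        raise ValueError(f"study {study.study_id!r}: non-finite values; "
                         "drop or impute before preprocessing")

    apply_log = (
        force_log if force_log is not None
        else (not study.log_transformed
              and float(matrix.values.max(initial=0.0)) > log_detect_threshold)
    )
    logged = study.log_transformed
    if apply_log:
        if (matrix.values < 0).any():
            raise ValueError(
                f"study {study.study_id!r}: negative values cannot be "
                "log2-transformed"
            )
        logger.info("%s: max value %.3g > %.3g, applying log2(x+1)",
                    study.study_id, matrix.values.max(initial=0.0),
                    log_detect_threshold)
        matrix = np.log2(matrix + 1.0)
        logged = True

    if method == "median-scale":
        matrix = _median_scale(matrix)
    elif method == "quantile":
        matrix = _quantile_normalize(matrix)

    return replace(study, matrix=matrix, log_transformed=logged,
                   normalization=method)


# ---------------------------------------------------------------------------
# Gene lists and GMT collections
# ---------------------------------------------------------------------------

def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list into an upper-cased set."""
    symbols = {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }
    if not symbols:
        raise ValueError(f"{path}: empty gene list")
    return symbols


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(g.upper() for g in genes)) + "\n")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT): term -> members, with term descriptions."""

    sets: dict
    descriptions: dict

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> frozenset:
        return self.sets[term]

    def terms(self) -> list[str]:
        return sorted(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (term <tab> description <tab> member genes...)."""
    sets, descriptions = {}, {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT rows need term, description and "
                             f"at least one member (got {line!r})")
        term, desc, members = fields[0], fields[1], fields[2:]
        sets[term] = frozenset(m.strip().upper() for m in members if m.strip())
        descriptions[term] = desc
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for term in collection.terms():
        members = sorted(collection.sets[term])
        desc = collection.descriptions.get(term, "")
        lines.append("\t".join([term, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GEO series-matrix reader (experimental)
# ---------------------------------------------------------------------------

def read_series_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best-effort parser for GEO series-matrix text files.  EXPERIMENTAL.

    Extracts the expression block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` and the ``!Sample_characteristics_ch1``
    lines.  Returns ``(matrix, characteristics)`` where characteristics has
    one row per sample.  Case/control assignment from the free-text
    characteristics is left to the caller.
    """
    lines = Path(path).read_text().splitlines()
    char_rows: list[list[str]] = []
    sample_ids: list[str] | None = None
    table: list[str] = []
    in_table = False
    for line in lines:
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table.append(line)
        elif line.startswith("!Sample_geo_accession"):
            sample_ids = [f.strip('"') for f in line.split("\t")[1:]]
        elif line.startswith("!Sample_characteristics_ch1"):
            char_rows.append([f.strip('"') for f in line.split("\t")[1:]])
    if not table:
        raise ValueError(f"{path}: no series_matrix_table block found")
    from io import StringIO

    matrix = pd.read_csv(StringIO("\n".join(table)), sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str).str.strip('"')
    matrix.columns = [str(c).strip('"') for c in matrix.columns]
    if sample_ids is None:
        sample_ids = list(matrix.columns)
    chars = pd.DataFrame(
        {f"characteristics_{i}": row for i, row in enumerate(char_rows)},
        index=sample_ids,
    )
    return matrix, chars


# ---------------------------------------------------------------------------
# Study manifests
# ---------------------------------------------------------------------------

def write_manifest(paths_per_study: list[dict], path) -> None:
    """Write a manifest TSV (study_id, matrix, phenotype, metadata paths)."""
    pd.DataFrame(paths_per_study).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> list[ExpressionStudy]:
    """Load every study listed in a manifest TSV."""
    base = Path(path).parent
    manifest = pd.read_csv(path, sep="\t")
    studies = []
    for _, row in manifest.iterrows():
        resolve = lambda p: p if Path(p).is_absolute() else base / p
        studies.append(read_study(resolve(row["matrix"]),
                                  resolve(row["phenotype"]),
                                  resolve(row["metadata"])))
    return studies
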