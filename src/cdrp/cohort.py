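"""Cohort I/O, feature filtering, and leakage-free standardization.

Expression matrices are samples × genes, log2-normalized continuous values,
read from delimited text with sample identifiers in the first column (an
orientation flag handles transposed files).  Gene annotation (Entrez IDs)
lives in a sidecar table.  Clinical annotation follows the conventional
neuroblastoma cohort schema: binary High-Risk (HR), Event-Free Survival (EFS)
and Overall Survival (OS) labels, event times in days, INSS tumor stage, and
optional confounders (age, gender, country).

Feature filtering mirrors the nsFilter convention: drop genes without an
Entrez annotation, then drop genes whose interquartile range (IQR) falls
below a variability cutoff (low-IQR genes carry no usable signal).  Both the
filter gene list and the standardization parameters are estimated on training
data only and re-applied verbatim to held-out data, so no held-out statistic
ever leaks into preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "SplitSpec",
    "StandardizationParams",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_split",
    "write_split",
    "filter_features",
    "fit_standardizer",
    "apply_standardizer",
]

#: floor applied to per-gene standard deviations; a gene constant on the
#: training set is mapped to zero rather than dividing by zero
SD_FLOOR = 1e-12

CLINICAL_COLUMNS = {
    "sample": "sample_id",
    "hr": "hr",
    "efs": "efs",
    "os": "os",
    "efs (days)": "efs_days",
    "os (days)": "os_days",
    "inss": "inss",
    "age (days)": "age_days",
    "gender": "gender",
    "country": "country",
}


class CohortError(ValueError):
    """Raised on malformed cohort inputs (duplicate ids, bad values, ...)."""


@dataclass
class ExpressionMatrix:
    """Samples × genes continuous expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Log2-scale expression values; must be finite.
    sample_ids, gene_ids : sequence of str
        Ordered, unique identifiers matching the matrix axes.
    entrez_id : sequence of (str or None), optional
        Per-gene Entrez annotation; ``None`` marks an unannotated gene.
    """

    values: np.ndarray
    sample_ids: list
    gene_ids: list
    entrez_id: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise CohortError("expression values must be a 2-d matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise CohortError(
                f"{n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.gene_ids):
            raise CohortError(f"{p} columns but {len(self.gene_ids)} gene ids")
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise CohortError(f"duplicated {name} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if self.entrez_id is not None and len(self.entrez_id) != p:
            raise CohortError("entrez_id length does not match gene count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, ids) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise CohortError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in ids]
        return ExpressionMatrix(
            self.values[rows], list(ids), list(self.gene_ids),
            None if self.entrez_id is None else list(self.entrez_id),
        )

    def subset_genes(self, ids) -> "ExpressionMatrix":
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in index]
        if missing:
            raise CohortError(f"unknown gene ids: {missing[:5]}")
        cols = [index[g] for g in ids]
        return ExpressionMatrix(
            self.values[:, cols], list(self.sample_ids), list(ids),
            None if self.entrez_id is None
            else [self.entrez_id[j] for j in cols],
        )


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# clinical table


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation (one row per sample).

    Wraps a DataFrame with normalized column names: sample_id, hr, efs, os,
    efs_days, os_days, inss, age_days, gender, country.  Binary fields are
    strictly 0/1; times and stage may be missing and are excluded
    per-analysis, never imputed.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        if "sample_id" not in df.columns:
            raise CohortError("clinical table needs a sample_id column")
        df["sample_id"] = df["sample_id"].astype(str)
        dup = _first_duplicate(list(df["sample_id"]))
        if dup is not None:
            raise CohortError(f"duplicated sample id in clinical table: {dup!r}")
        for col in ("hr", "efs", "os"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = ~vals.isin([0, 1]) & vals.notna()
                if bad.any():
                    raise CohortError(
                        f"column {col!r} must be binary 0/1; offending sample "
                        f"{df.loc[bad, 'sample_id'].iloc[0]!r}"
                    )
                df[col] = vals.astype("Int64")
        for col in ("efs_days", "os_days", "age_days"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                if (vals.dropna() < 0).any():
                    raise CohortError(f"negative values in {col!r}")
                df[col] = vals
        if "inss" in df.columns:
            df["inss"] = df["inss"].astype("string").str.upper()
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    def aligned_to(self, sample_ids) -> "ClinicalTable":
        """Reorder rows to match `sample_ids` (all must be present)."""
        df = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise CohortError(f"samples missing from clinical table: {missing[:5]}")
        out = df.loc[list(sample_ids)].reset_index()
        return ClinicalTable(out)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


@dataclass
class SplitSpec:
    """Disjoint train/test sample-id sets."""

    train_ids: list
    test_ids: list

    def __post_init__(self):
        self.train_ids = [str(s) for s in self.train_ids]
        self.test_ids = [str(s) for s in self.test_ids]
        if not self.train_ids or not self.test_ids:
            raise CohortError("both split halves must be nonempty")
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise CohortError(f"train/test overlap: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, orientation: str = "samples_in_rows",
                    gene_annotation=None) -> ExpressionMatrix:
    """Read a delimited expression table.

    Parameters
    ----------
    path : str or Path
        TSV/CSV file; first column holds row identifiers, header holds column
        identifiers. Delimiter inferred from the extension ('.csv' → comma).
    orientation : {"samples_in_rows", "genes_in_rows"}
        Layout of the file; output is always samples × genes.
    gene_annotation : str or Path, optional
        Sidecar TSV with columns gene_id, entrez_id (empty cell = missing).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = _first_duplicate(header)
    if dup is not None:
        kind = "sample" if orientation == "genes_in_rows" else "gene"
        raise CohortError(f"duplicated {kind} id in header: {dup!r}")
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise CohortError(
            f"missing/ragged cell near row {row!r}, column {col!r} in {path.name}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise CohortError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path.name}"
                ) from None
        raise
    if orientation == "genes_in_rows":
        values = values.T
        sample_ids, gene_ids = list(df.columns), list(df.index)
    elif orientation == "samples_in_rows":
        sample_ids, gene_ids = list(df.index), list(df.columns)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    entrez = None
    if gene_annotation is not None:
        ann = pd.read_csv(gene_annotation, sep="\t", dtype=str)
        ann_map = dict(zip(ann["gene_id"], ann["entrez_id"]))
        entrez = [
            None if pd.isna(ann_map.get(g)) or ann_map.get(g) in (None, "")
            else str(ann_map[g])
            for g in gene_ids
        ]
    return ExpressionMatrix(values, sample_ids, gene_ids, entrez)


def write_expression(x: ExpressionMatrix, path, gene_annotation=None) -> None:
    """Write samples × genes TSV/CSV; optional gene-annotation sidecar."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(x.values, index=x.sample_ids, columns=x.gene_ids)
    df.index.name = "sample_id"
    # default (shortest round-trip) float formatting keeps read∘write lossless
    df.to_csv(path, sep=sep)
    if gene_annotation is not None:
        ann = pd.DataFrame({
            "gene_id": x.gene_ids,
            "entrez_id": ["" if e is None else e for e in x.entrez_id]
            if x.entrez_id is not None else [""] * x.n_genes,
        })
        ann.to_csv(gene_annotation, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV/CSV with case-insensitive conventional headers."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in CLINICAL_COLUMNS:
            rename[col] = CLINICAL_COLUMNS[key]
    df = df.rename(columns=rename)
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path) -> None:
    inverse = {v: k for k, v in CLINICAL_COLUMNS.items()}
    pretty = {
        "sample_id": "Sample", "hr": "HR", "efs": "EFS", "os": "OS",
        "efs_days": "EFS (days)", "os_days": "OS (days)", "inss": "INSS",
        "age_days": "Age (days)", "gender": "Gender", "country": "Country",
    }
    df = t.data.rename(columns={c: pretty.get(c, c) for c in t.data.columns})
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def read_split(path) -> SplitSpec:
    """Read a YAML SplitSpec ({train: [...], test: [...]})."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SplitSpec(train_ids=doc["train"], test_ids=doc["test"])


def write_split(split: SplitSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"train": list(split.train_ids), "test": list(split.test_ids)}, fh
        )


# ---------------------------------------------------------------------------
# feature filter


def filter_features(x: ExpressionMatrix, iqr_cutoff: float = 0.5,
                    require_entrez: bool = True,
                    direction: str = "remove_low") -> ExpressionMatrix:
    """Annotation + variability gene filter (nsFilter-style).

    Genes without an Entrez ID are removed when `require_entrez`.  The IQR
    rule (type-7 linear-interpolation quantiles) then removes low-variability
    genes: with the default ``direction="remove_low"`` a gene survives iff
    IQR > `iqr_cutoff`; ``"remove_high"`` inverts the rule.  Survivor order is
    preserved.  The returned matrix's `gene_ids` is the survivor list to
    re-apply verbatim to a held-out matrix via
    :meth:`ExpressionMatrix.subset_genes`.
    """
    if iqr_cutoff < 0:
        raise ValueError("iqr_cutoff must be nonnegative")
    keep = np.ones(x.n_genes, dtype=bool)
    if require_entrez:
        if x.entrez_id is None:
            raise CohortError(
                "require_entrez=True but the matrix carries no Entrez annotation"
            )
        keep &= np.array([e is not None for e in x.entrez_id])
    q75, q25 = np.percentile(x.values, [75, 25], axis=0)  # type-7 quantiles
    iqr = q75 - q25
    if direction == "remove_low":
        keep &= iqr > iqr_cutoff
    elif direction == "remove_high":
        keep &= iqr <= iqr_cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    survivors = [g for g, k in zip(x.gene_ids, keep) if k]
    if not survivors:
        raise CohortError("feature filter removed every gene")
    return x.subset_genes(survivors)


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizationParams:
    """Per-gene mean/sd estimated on a training set."""

    gene_ids: list
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.gene_ids) == self.mean.size == self.sd.size):
            raise CohortError("gene ids, means and sds must align")
        if (self.sd < 0).any():
            raise CohortError("negative standard deviation")


def fit_standardizer(x_train: ExpressionMatrix) -> StandardizationParams:
    """Estimate per-gene mean and sd (population, ddof=0) on training data."""
    if x_train.n_samples < 2:
        raise CohortError("standardization needs at least 2 training samples")
    mean = x_train.values.mean(axis=0)
    sd = x_train.values.std(axis=0)
    zero = sd < SD_FLOOR
    if zero.any():
        names = [g for g, z in zip(x_train.gene_ids, zero) if z][:5]
        warnings.warn(
            f"{int(zero.sum())} gene(s) constant on the training set "
            f"(e.g. {names}); standardized to 0", stacklevel=2
        )
    return StandardizationParams(list(x_train.gene_ids), mean, sd)


def apply_standardizer(params: StandardizationParams,
                       x: ExpressionMatrix) -> ExpressionMatrix:
    """Transform `x` with training-derived parameters (never refit)."""
    if list(x.gene_ids) != list(params.gene_ids):
        raise CohortError(
            "gene set mismatch between standardization parameters and matrix"
        )
    sd = np.maximum(params.sd, SD_FLOOR)
    values = (x.values - params.mean) / sd
    values[:, params.sd < SD_FLOOR] = 0.0
    return ExpressionMatrix(values, list(x.sample_ids), list(x.gene_ids),
                            None if x.entrez_id is None else list(x.entrez_id))
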