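"""Expression-matrix and clinical-table containers and their on-disk formats.

The expression container is a thin wrapper around a pandas DataFrame
(rows = probes or gene symbols, columns = sample ids) that tracks whether
rows have been z-normalized.  Formats are deliberately plain: tab-delimited
matrices with a ``probe_id`` first column, a two-column probe→gene
annotation TSV, and a CSV clinical table in which NA is the empty string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "CLINICAL_COLUMNS",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
    "z_normalize_rows",
    "collapse_probes_by_iqr",
]

#: Column vocabulary of the per-sample clinical table.  ``outcome`` is the
#: neoadjuvant endpoint (pCR vs residual disease); DFS/OS columns carry
#: follow-up in months plus 0/1 event flags; ``response_score`` is a 0-5
#: pathologic-response grade used for validation-style groupings.
CLINICAL_COLUMNS = [
    "sample_id",
    "outcome",
    "size_class",
    "grade",
    "nodal",
    "age_class",
    "her2",
    "pr",
    "treatment",
    "dfs_months",
    "dfs_event",
    "os_months",
    "os_event",
    "response_score",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A probes-or-genes × samples real-valued matrix.

    Parameters
    ----------
    data
        DataFrame with unique row ids as index and unique sample ids as
        columns; all values finite floats.
    normalized
        True once rows have been z-normalized (mean 0, sd 1 per row).
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate row ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains NA/non-finite values")
        if self.normalized:
            self._check_row_moments()

    def _check_row_moments(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.shape[1] < 2:
            return
        means = values.mean(axis=1)
        sds = values.std(axis=1, ddof=1)
        if not (np.abs(means) < 1e-9).all() or not (np.abs(sds - 1) < 1e-9).all():
            raise ValueError("normalized flag set but rows are not mean-0/sd-1")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, row_id: str) -> np.ndarray:
        if row_id not in self.data.index:
            raise KeyError(f"row id {row_id!r} not in matrix")
        return self.data.loc[row_id].to_numpy(dtype=float)

    def subset_rows(self, row_ids: list[str]) -> "ExpressionMatrix":
        missing = [r for r in row_ids if r not in self.data.index]
        if missing:
            raise KeyError(f"rows missing from matrix: {missing}")
        return replace(self, data=self.data.loc[row_ids])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples missing from matrix: {missing}")
        # Subsetting columns invalidates the per-row moments, so the
        # normalized flag is dropped.
        return ExpressionMatrix(self.data[sample_ids], normalized=False)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Many-to-one probe → gene-symbol map (each probe maps once)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def gene_for(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def probes_for(self, gene: str) -> list[str]:
        return [p for p, g in self.mapping.items() if g == gene]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited matrix with header ``probe_id<TAB>sample...``.

    Raises ``ValueError`` naming the offending row/column for ragged rows,
    duplicate ids, or non-numeric cells; NA cells are rejected.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must contain at least one sample id")
        sample_ids = header[1:]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: ragged row {parts[0]!r} "
                    f"({len(parts) - 1} values, expected {len(sample_ids)})"
                )
            values = []
            for col, cell in zip(sample_ids, parts[1:]):
                try:
                    value = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell in row {parts[0]!r}, "
                        f"column {col!r}: {cell!r}"
                    ) from None
                if not np.isfinite(value):
                    raise ValueError(
                        f"{path}:{lineno}: NA/non-finite cell in row {parts[0]!r}, "
                        f"column {col!r}"
                    )
                values.append(value)
            row_ids.append(parts[0])
            rows.append(values)
    frame = pd.DataFrame(rows, index=row_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(frame, normalized=False)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.data.copy()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation_tsv(path: str | Path) -> ProbeAnnotation:
    """Read a two-column ``probe_id<TAB>gene_symbol`` table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns)[:2] != ["probe_id", "gene_symbol"]:
        raise ValueError(f"{path}: expected columns probe_id, gene_symbol")
    if frame["probe_id"].duplicated().any():
        dupes = sorted(frame.loc[frame["probe_id"].duplicated(), "probe_id"])
        raise ValueError(f"{path}: duplicate probe ids: {dupes}")
    return ProbeAnnotation(dict(zip(frame["probe_id"], frame["gene_symbol"])))


def write_annotation_tsv(annotation: ProbeAnnotation, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(annotation.mapping.items()), columns=["probe_id", "gene_symbol"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Read the clinical table; empty strings become NA, sample_id is kept
    as a column and must be unique."""
    frame = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
    frame = frame.where(frame != "", other=np.nan)
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns: {missing}")
    if frame["sample_id"].duplicated().any():
        dupes = sorted(frame.loc[frame["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"{path}: duplicate sample ids: {dupes}")
    for col in ("dfs_months", "dfs_event", "os_months", "os_event", "response_score"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    for time_col, event_col in (("dfs_months", "dfs_event"), ("os_months", "os_event")):
        bad = frame[time_col].notna() & frame[event_col].isna()
        if bad.any():
            raise ValueError(
                f"{path}: {event_col} missing where {time_col} is present "
                f"(samples {sorted(frame.loc[bad, 'sample_id'])})"
            )
    return frame


def write_clinical_csv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False, na_rep="")


def z_normalize_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each row x by (x − mean)/sd with the sample (n−1) sd.

    Constant rows cannot be scaled and are dropped with a logged warning
    rather than zero-filled, so NaNs never propagate into downstream
    correlation or clustering.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    values = matrix.data.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-normalize")
    sds = values.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        dropped = [rid for rid, c in zip(matrix.row_ids, constant) if c]
        logger.warning("dropping %d constant row(s): %s", len(dropped), dropped)
    keep = ~constant
    kept = values[keep]
    normed = (kept - kept.mean(axis=1, keepdims=True)) / kept.std(
        axis=1, ddof=1, keepdims=True
    )
    frame = pd.DataFrame(
        normed,
        index=matrix.data.index[keep],
        columns=matrix.data.columns,
        dtype=float,
    )
    return ExpressionMatrix(frame, normalized=True)


def _iqr(values: np.ndarray) -> float:
    # Type-7 (linear-interpolation) quartiles; fixed so probe selection
    # is reproducible across platforms.
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    return float(q3 - q1)


def collapse_probes_by_iqr(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation
) -> ExpressionMatrix:
    """Collapse a probe-keyed matrix to one row per gene symbol.

    For genes measured by several probes the probe with the largest
    interquartile range is kept; single-probe genes pass through.  Runs on
    the raw (unnormalized) scale — IQR comparisons on z-scores are
    meaningless because every row then has the same spread by construction.
    """
    if matrix.normalized:
        raise ValueError("collapse must run on unnormalized data")
    unannotated = [p for p in matrix.row_ids if p not in annotation.mapping]
    if unannotated:
        raise ValueError(f"probes without annotation: {unannotated}")
    by_gene: dict[str, list[str]] = {}
    for probe in matrix.row_ids:
        by_gene.setdefault(annotation.mapping[probe], []).append(probe)
    chosen_rows = []
    gene_order = []
    for gene, probes in by_gene.items():
        if len(probes) == 1:
            best = probes[0]
        else:
            iqrs = [_iqr(matrix.row(p)) for p in probes]
            best = probes[int(np.argmax(iqrs))]
        chosen_rows.append(matrix.data.loc[best].to_numpy(dtype=float))
        gene_order.append(gene)
    frame = pd.DataFrame(
        chosen_rows, index=gene_order, columns=matrix.data.columns, dtype=float
    )
    return ExpressionMatrix(frame, normalized=False)
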