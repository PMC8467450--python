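"""Expression-matrix I/O, quality control, and probeset→gene mapping.

Matrices are probesets × samples tables of log2 intensities with optional
per-sample annotations (cohort, patient id, timepoint, calibration label).
Two text dialects are supported: a plain TSV (header row of sample ids,
first column the probeset id) and the GEO series-matrix dialect, where
"!"-prefixed metadata lines surround the table between
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.

QC is deliberately minimal: a missingness gate per sample and a
median-intensity scale heuristic.  Array-level QC (RNA degradation metrics,
probe-level diagnostics) is out of scope; surviving values are never
modified and missing values are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, QCError, ValidationError

ANNOTATION_COLUMNS = ("cohort", "patient_id", "timepoint", "label")

_MISSING_TOKENS = {"", "na", "nan", "null"}


@dataclass
class ExpressionMatrix:
    """Probesets × samples log2 intensity table with sample annotations."""

    data: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probeset ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.annotations is not None:
            unknown = [
                s for s in self.annotations.index if s not in set(self.data.columns)
            ]
            if unknown:
                raise ValidationError(
                    f"annotations reference unknown sample ids: {unknown}"
                )

    @property
    def probeset_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def profile(self, sample_id: str) -> dict[str, float]:
        """Probeset → intensity mapping for one sample column."""
        return dict(zip(self.data.index, self.data[sample_id].to_numpy()))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ann = None
        if self.annotations is not None:
            keep = [s for s in self.annotations.index if s in set(sample_ids)]
            ann = self.annotations.loc[keep]
        return ExpressionMatrix(self.data[list(sample_ids)], ann)


@dataclass(frozen=True)
class ProbesetAnnotation:
    """Probeset → gene-symbol map (many probesets may share a symbol)."""

    mapping: Mapping[str, str]

    def symbols(self) -> list[str]:
        out: list[str] = []
        for sym in self.mapping.values():
            if sym not in out:
                out.append(sym)
        return out

    def probesets_for(self, symbol: str) -> list[str]:
        return [p for p, s in self.mapping.items() if s == symbol]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbesetAnnotation":
        mapping: dict[str, str] = {}
        for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                raise ParseError(f"line {lineno}: expected 2 fields, got {len(fields)}")
            pid, sym = fields
            if pid == "probeset_id":  # optional header
                continue
            if pid in mapping:
                raise ParseError(f"line {lineno}: probeset {pid} mapped twice")
            mapping[pid] = sym
        return cls(mapping)

    @classmethod
    def from_synthetic_ids(cls, probeset_ids: Sequence[str]) -> "ProbesetAnnotation":
        """Derive the map from ``SYMBOL_ps<k>``-style synthetic identifiers."""
        mapping = {}
        for pid in probeset_ids:
            sym = pid.rsplit("_ps", 1)[0] if "_ps" in pid else pid
            mapping[pid] = sym
        return cls(mapping)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _parse_value(token: str, lineno: int, pid: str) -> float:
    if token.strip().lower() in _MISSING_TOKENS:
        return math_nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"line {lineno}: unparseable value {token!r} in row {pid!r}"
        ) from None


math_nan = float("nan")


def _parse_table(lines: list[tuple[int, str]]) -> pd.DataFrame:
    """Parse (lineno, text) pairs: header of sample ids then data rows."""
    if not lines:
        raise ParseError("no table rows found")
    head_no, head = lines[0]
    header = [f.strip().strip('"') for f in head.split("\t")]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"line {head_no}: duplicate sample ids {dups}")
    rows: dict[str, list[float]] = {}
    for lineno, ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        pid = fields[0].strip().strip('"')
        if pid in rows:
            raise ParseError(f"line {lineno}: duplicate probeset id {pid!r}")
        rows[pid] = [_parse_value(tok, lineno, pid) for tok in fields[1:]]
    return pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)


def read_matrix(
    path: str | Path,
    dialect: str = "plain_tsv",
    *,
    annotations_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from text.

    ``dialect="plain_tsv"`` expects a header row of sample ids and one row
    per probeset; lines starting with ``#`` are treated as comments.
    ``dialect="series_matrix"`` reads the table bracketed by the GEO
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers and
    ignores all other ``!``-prefixed metadata lines.
    """
    raw = Path(path).read_text().splitlines()
    numbered = list(enumerate(raw, start=1))
    if dialect == "plain_tsv":
        table = [
            (n, ln) for n, ln in numbered if ln.strip() and not ln.startswith("#")
        ]
    elif dialect == "series_matrix":
        begins = [n for n, ln in numbered if ln.startswith("!series_matrix_table_begin")]
        ends = [n for n, ln in numbered if ln.startswith("!series_matrix_table_end")]
        if not begins or not ends:
            raise ParseError("series_matrix table markers not found")
        lo, hi = begins[0], ends[0]
        table = [(n, ln) for n, ln in numbered if lo < n < hi and ln.strip()]
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    data = _parse_table(table)
    annotations = (
        read_annotations(annotations_path) if annotations_path is not None else None
    )
    return ExpressionMatrix(data, annotations)


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    *,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the plain TSV dialect; floats use ``repr`` for exact round trips."""
    out = [f"# {h}" for h in header_lines]
    out.append("\t".join(["probeset_id", *matrix.sample_ids]))
    for pid, row in zip(matrix.data.index, matrix.data.to_numpy()):
        out.append(
            "\t".join([str(pid)] + ["NA" if np.isnan(v) else repr(float(v)) for v in row])
        )
    Path(path).write_text("\n".join(out) + "\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation TSV (first column ``sample_id``)."""
    lines = [
        (n, ln)
        for n, ln in enumerate(Path(path).read_text().splitlines(), start=1)
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError("empty annotation file")
    header = lines[0][1].split("\t")
    if header[0] != "sample_id":
        raise ParseError("annotation file must start with a 'sample_id' column")
    records = {}
    for lineno, ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        if fields[0] in records:
            raise ParseError(f"line {lineno}: duplicate sample id {fields[0]!r}")
        records[fields[0]] = fields[1:]
    return pd.DataFrame.from_dict(
        records, orient="index", columns=header[1:]
    ).rename_axis("sample_id")


def write_annotations(
    annotations: pd.DataFrame, path: str | Path, *, header_lines: Sequence[str] = ()
) -> None:
    out = [f"# {h}" for h in header_lines]
    out.append("\t".join(["sample_id", *annotations.columns]))
    for sid, row in annotations.iterrows():
        out.append("\t".join([str(sid)] + [str(v) for v in row]))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Record of every action the QC gate took."""

    dropped_samples: list[str] = field(default_factory=list)
    flagged_samples: dict[str, str] = field(default_factory=dict)
    actions: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.dropped_samples or self.flagged_samples or self.actions)


def qc_matrix(
    matrix: ExpressionMatrix,
    max_missing_fraction: float = 0.0,
    intensity_range: tuple[float, float] = (2.0, 16.0),
) -> tuple[ExpressionMatrix, QCReport]:
    """Missingness and scale gate before scoring.

    Samples whose fraction of missing values exceeds ``max_missing_fraction``
    are dropped (and reported).  Any missing value remaining in a surviving
    sample is a hard error — imputation is never performed.  Samples whose
    median intensity falls outside ``intensity_range`` are flagged but kept;
    a median above the upper bound is annotated as a suspected non-log2
    scale.  Surviving values are returned unchanged.
    """
    report = QCReport()
    data = matrix.data
    keep = []
    for sid in data.columns:
        frac = float(data[sid].isna().mean()) if len(data) else 0.0
        if frac > max_missing_fraction:
            report.dropped_samples.append(str(sid))
            report.actions.append(
                f"dropped sample {sid}: missing fraction {frac:.3f} > "
                f"{max_missing_fraction}"
            )
        else:
            keep.append(sid)
    if not keep:
        raise QCError("QC dropped every sample")
    surviving = data[keep]
    if surviving.isna().any().any():
        bad = [str(c) for c in surviving.columns[surviving.isna().any()]]
        raise QCError(
            f"missing values remain in samples {bad}; imputation is not performed"
        )
    lo, hi = intensity_range
    for sid in keep:
        med = float(surviving[sid].median()) if len(surviving) else 0.0
        if med > hi:
            report.flagged_samples[str(sid)] = (
                f"median intensity {med:.2f} > {hi}: suspected non-log2 scale"
            )
        elif med < lo:
            report.flagged_samples[str(sid)] = (
                f"median intensity {med:.2f} < {lo}: suspiciously low"
            )
    for sid, msg in report.flagged_samples.items():
        report.actions.append(f"flagged sample {sid}: {msg}")
    ann = None
    if matrix.annotations is not None:
        keep_ann = [s for s in matrix.annotations.index if s in set(map(str, keep))]
        ann = matrix.annotations.loc[keep_ann]
    return ExpressionMatrix(surviving, ann), report


# ---------------------------------------------------------------------------
# probeset → gene mapping
# ---------------------------------------------------------------------------


def map_probesets(
    matrix: ExpressionMatrix,
    annotation: ProbesetAnnotation,
    rule: str = "max_mean",
    *,
    genes: Sequence[str] | None = None,
    specific: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Collapse a probeset-level matrix to one row per gene symbol.

    ``rule="max_mean"`` keeps, per gene, the probeset with the highest mean
    intensity across samples (a common single-probeset convention);
    ``rule="specific"`` uses a caller-supplied probeset id per gene.
    """
    if rule not in ("max_mean", "specific"):
        raise ValidationError(f"unknown mapping rule {rule!r}")
    requested = list(genes) if genes is not None else annotation.symbols()
    index = set(map(str, matrix.data.index))
    rows = {}
    for sym in requested:
        if rule == "specific":
            if specific is None or sym not in specific:
                raise ValidationError(f"no specific probeset supplied for gene {sym}")
            pid = specific[sym]
            if pid not in index:
                raise ValidationError(
                    f"probeset {pid!r} for gene {sym} absent from the matrix"
                )
        else:
            candidates = [p for p in annotation.probesets_for(sym) if p in index]
            if not candidates:
                raise ValidationError(f"gene {sym} has no probeset in the matrix")
            means = matrix.data.loc[candidates].mean(axis=1)
            pid = str(means.idxmax())
        rows[sym] = matrix.data.loc[pid]
    gene_data = pd.DataFrame(rows).T
    gene_data.columns = matrix.data.columns
    return ExpressionMatrix(gene_data, matrix.annotations)
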