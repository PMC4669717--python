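"""Expression matrix I/O, validation, normalization and platform restriction.

The pipeline consumes log2-scale expression values as a probes x samples
table with a binary case/control label per sample.  Two on-disk dialects are
supported: a plain TSV (first column header ``probe_id``) with a companion
two-column label file, and GCT v1.2.

Full RMA preprocessing is deliberately not reproduced here; the packaged
substitute is :func:`quantile_normalize_log2`, which equalizes the per-sample
value distributions (column-wise mean of sorted columns) after an optional
log2 transform.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ParseError, ValidationError

CASE = "case"
CONTROL = "control"
_GROUPS = frozenset({CASE, CONTROL})

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_probe_list",
    "write_probe_list",
    "quantile_normalize_log2",
    "restrict_to_platform",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) plus sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.
    labels
        Mapping ``sample_id -> "case" | "control"`` covering every sample.
    """

    values: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            raise DomainError("expression values must all be finite")
        missing = [s for s in cols if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        bad = {s: g for s, g in self.labels.items() if g not in _GROUPS}
        if bad:
            raise ValidationError(
                f"labels must be 'case' or 'control', got {bad}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == group]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = list(sample_ids)
        return ExpressionMatrix(
            self.values[keep].copy(),
            {s: self.labels[s] for s in keep},
        )


# ---------------------------------------------------------------------------
# I/O


def _to_float_table(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Convert a string table to floats, reporting bad-cell coordinates."""
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            for i, raw in enumerate(df[col]):
                try:
                    float(raw)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {raw!r} at probe row "
                        f"{i + 1}, sample column {col!r} (column {j + 1})"
                    ) from None
        raise  # pragma: no cover - conversion failed but no cell located


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>group`` label file.

    A header line ``sample_id\\tgroup`` is optional; groups must be ``case``
    or ``control``.
    """
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            sample, group = parts[0].strip(), parts[1].strip()
            if lineno == 1 and (sample, group) == ("sample_id", "group"):
                continue
            if group not in _GROUPS:
                raise ValidationError(
                    f"{path}:{lineno}: group must be 'case' or 'control', "
                    f"got {group!r}"
                )
            if sample in labels:
                raise ValidationError(f"{path}: duplicate sample id {sample!r}")
            labels[sample] = group
    if not labels:
        raise FormatError(f"{path}: empty label file")
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns.empty or df.columns[0] != "probe_id":
        raise FormatError(
            f"{path}: first column header must be 'probe_id', "
            f"got {df.columns[0] if len(df.columns) else 'nothing'!r}"
        )
    df = df.set_index("probe_id")
    df.index = df.index.astype(str)
    return _to_float_table(df, str(path))


def _read_gct(path: str | Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().rstrip("\n")
        if version != "#1.2":
            raise FormatError(f"{path}: expected '#1.2' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        try:
            nrow, ncol = int(dims[0]), int(dims[1])
        except ValueError:
            raise FormatError(f"{path}: malformed GCT dimension line") from None
        body = fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str)
    if list(df.columns[:2]) != ["NAME", "Description"]:
        raise FormatError(
            f"{path}: GCT header must start with NAME\\tDescription"
        )
    df = df.drop(columns="Description").set_index("NAME")
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    if df.shape != (nrow, ncol):
        raise FormatError(
            f"{path}: size line says {nrow}x{ncol} but table is "
            f"{df.shape[0]}x{df.shape[1]}"
        )
    return _to_float_table(df, str(path))


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    labels: str | Path | Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a probes x samples matrix from TSV or GCT v1.2.

    ``labels`` is either a mapping or the path of a companion label file;
    it is required because every sample must carry a case/control label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        values = _read_tsv(path)
    elif format == "gct":
        values = _read_gct(path)
    else:
        raise FormatError(f"unknown format {format!r}; expected 'tsv' or 'gct'")
    if labels is None:
        raise ValidationError("a label file or mapping is required")
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    return ExpressionMatrix(values, dict(labels))


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv",
    labels_path: str | Path | None = None,
) -> None:
    """Write a matrix as TSV or GCT v1.2 (full ``%.17g`` precision)."""
    if format == "tsv":
        out = matrix.values.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_probes}\t{matrix.n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for probe, row in zip(matrix.probe_ids, matrix.values.to_numpy()):
                vals = "\t".join(f"{v:.17g}" for v in row)
                fh.write(f"{probe}\tna\t{vals}\n")
    else:
        raise FormatError(f"unknown format {format!r}; expected 'tsv' or 'gct'")
    if labels_path is not None:
        write_labels(matrix.labels, labels_path)


def read_probe_list(path: str | Path) -> list[str]:
    """Read a platform probe list: one id per line, ``#`` comments ignored."""
    probes: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            pid = line.split("#", 1)[0].strip()
            if not pid:
                continue
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate probe id {pid!r}")
            seen.add(pid)
            probes.append(pid)
    if not probes:
        raise ValidationError(f"{path}: empty probe list")
    return probes


def write_probe_list(probes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in probes:
            fh.write(f"{pid}\n")


# ---------------------------------------------------------------------------
# Transformations


def quantile_normalize_log2(
    matrix: ExpressionMatrix, already_log2: bool = True
) -> ExpressionMatrix:
    """Quantile-normalize so every sample shares one value distribution.

    The target distribution is the column-wise mean of the sorted columns;
    ties within a column receive the average of the target values over the
    tied rank span.  When ``already_log2`` is false a log2 transform is
    applied first (all values must then be strictly positive).
    """
    X = matrix.values.to_numpy(dtype=float, copy=True)
    if not already_log2:
        if (X <= 0).any():
            raise DomainError(
                "non-positive values cannot be log2-transformed; "
                "pass already_log2=True if the data are on the log scale"
            )
        X = np.log2(X)
    if X.shape[1] > 0 and X.shape[0] > 0:
        target = np.sort(X, axis=0).mean(axis=1)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="mergesort")
            sc = X[order, j]
            grp = np.concatenate(([0], np.cumsum(sc[1:] != sc[:-1])))
            means = np.bincount(grp, weights=target) / np.bincount(grp)
            out[order, j] = means[grp]
        X = out
    values = pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, dict(matrix.labels))


def restrict_to_platform(
    matrix: ExpressionMatrix, platform: Iterable[str]
) -> ExpressionMatrix:
    """Keep only probes present on the query platform, preserving order."""
    universe = set(platform)
    keep = [p for p in matrix.probe_ids if p in universe]
    if not keep:
        raise ValidationError(
            "no matrix probes are present on the platform probe list"
        )
    return ExpressionMatrix(matrix.values.loc[keep].copy(), dict(matrix.labels))
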