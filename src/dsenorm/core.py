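"""Data containers, TSV I/O and elementary transforms.

The central container is :class:`IntensityMatrix`: a variables-by-samples
matrix of array intensities, either on the raw (strictly positive) scale or
on the log2 scale, together with an optional block structure describing
contiguous runs of genomically ordered variables (e.g. one block per
chromosome).  :class:`GroupDesign` maps samples to the treatment or
reference arm of a two-group comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"

TREATMENT = "treatment"
REFERENCE = "reference"


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class IntensityMatrix:
    """A variables x samples intensity table.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_variables, n_samples)``.
    variable_ids
        Unique identifiers, one per row.
    sample_ids
        Identifiers, one per column.
    scale
        ``"raw"`` (strictly positive intensities) or ``"log2"``.
    blocks
        Optional list of ``(start, stop)`` half-open index ranges that
        partition ``range(n_variables)`` into contiguous, ordered runs.
        ``None`` means a single block covering all variables.
    n_dropped
        Number of variables removed during parsing (missing values).
    """

    values: np.ndarray
    variable_ids: np.ndarray
    sample_ids: list[str]
    scale: str = LOG2
    blocks: list[tuple[int, int]] | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.variable_ids = np.asarray(self.variable_ids, dtype=object)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d matrix")
        n, s = self.values.shape
        if len(self.variable_ids) != n:
            raise ValidationError(
                f"{len(self.variable_ids)} variable ids for {n} rows"
            )
        if len(self.sample_ids) != s:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {s} columns"
            )
        if len(set(self.variable_ids)) != n:
            raise ValidationError("variable ids must be unique")
        if len(set(self.sample_ids)) != s:
            raise ValidationError("sample ids must be unique")
        if self.scale not in (RAW, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.scale == RAW and not np.all(self.values > 0):
            raise ValidationError("raw-scale matrix must be strictly positive")
        if self.blocks is not None:
            self._check_blocks(self.blocks, n)

    @staticmethod
    def _check_blocks(blocks: Sequence[tuple[int, int]], n: int) -> None:
        pos = 0
        for start, stop in blocks:
            if start != pos or stop <= start:
                raise ValidationError(
                    "blocks must be contiguous non-empty runs covering all rows"
                )
            pos = stop
        if pos != n:
            raise ValidationError("blocks must cover the full variable range")

    # -- basic geometry -------------------------------------------------
    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def block_spans(self) -> list[tuple[int, int]]:
        """Blocks, defaulting to one run over all variables."""
        if self.blocks is None:
            return [(0, self.n_variables)]
        return list(self.blocks)

    def column_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "IntensityMatrix":
        return replace(self, values=np.asarray(values, float),
                       scale=self.scale if scale is None else scale)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.variable_ids, name="id"),
                            columns=self.sample_ids)


@dataclass
class GroupDesign:
    """Assignment of each sample to the treatment or reference arm."""

    arms: dict[str, str]

    def __post_init__(self) -> None:
        bad = {a for a in self.arms.values() if a not in (TREATMENT, REFERENCE)}
        if bad:
            raise ValidationError(f"unknown arm labels: {sorted(bad)}")
        if self.n_treatment < 1 or self.n_reference < 1:
            raise ValidationError("each arm needs at least one sample")

    @property
    def treatment(self) -> list[str]:
        return sorted(s for s, a in self.arms.items() if a == TREATMENT)

    @property
    def reference(self) -> list[str]:
        return sorted(s for s, a in self.arms.items() if a == REFERENCE)

    @property
    def n_treatment(self) -> int:
        return sum(1 for a in self.arms.values() if a == TREATMENT)

    @property
    def n_reference(self) -> int:
        return sum(1 for a in self.arms.values() if a == REFERENCE)

    def validate_against(self, m: IntensityMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.arms]
        if missing:
            raise ValidationError(f"samples without arm assignment: {missing}")

    def arm_indices(self, m: IntensityMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of the treatment and reference samples in *m*."""
        self.validate_against(m)
        t = [s for s in self.treatment if s in m.sample_ids]
        r = [s for s in self.reference if s in m.sample_ids]
        if not t or not r:
            raise ValidationError("matrix must contain samples from both arms")
        return m.column_indices(t), m.column_indices(r)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, scale: str = RAW) -> IntensityMatrix:
    """Read a tab-separated intensity matrix.

    Layout: header row of sample ids; first column holds variable ids;
    optional ``chrom`` and ``pos`` columns immediately after the id column
    define the genomic order (rows are sorted by ``(chrom, pos)`` and each
    chromosome becomes one contiguous block).  Rows containing any missing
    intensity are dropped; the count is recorded in ``n_dropped``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need an id column and at least one sample")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate variable id {dup!r}")

    meta_cols = [c for c in ("chrom", "pos") if c in df.columns[1:3]]
    sample_cols = [c for c in df.columns[1:] if c not in meta_cols]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns")

    numeric = pd.DataFrame(index=df.index)
    for col in sample_cols:
        raw = df[col]
        conv = pd.to_numeric(raw, errors="coerce")
        bad = conv.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path}: non-numeric value {raw.iloc[i]!r} "
                f"(variable {ids.iloc[i]!r}, sample column {col!r})"
            )
        numeric[col] = conv

    keep = ~numeric.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    numeric = numeric[keep]
    ids = ids[keep]

    blocks = None
    if meta_cols:
        chrom = df.loc[keep, "chrom"].astype(str) if "chrom" in meta_cols else pd.Series("", index=ids.index)
        pos = pd.to_numeric(df.loc[keep, "pos"], errors="coerce") if "pos" in meta_cols else pd.Series(0, index=ids.index)
        order = np.lexsort((pos.to_numpy(), chrom.to_numpy()))
        numeric = numeric.iloc[order]
        ids = ids.iloc[order]
        chrom = chrom.iloc[order].to_numpy()
        blocks = []
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[i - 1]:
                blocks.append((start, i))
                start = i
    if len(ids) == 0:
        raise ValidationError(f"{path}: all rows dropped (missing values)")
    return IntensityMatrix(
        values=numeric.to_numpy(float),
        variable_ids=ids.to_numpy(),
        sample_ids=list(numeric.columns),
        scale=scale,
        blocks=blocks,
        n_dropped=n_dropped,
    )


def write_matrix(m: IntensityMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full double precision (round-trip safe)."""
    m.to_dataframe().to_csv(path, sep="\t", float_format="%.17g")


def read_design(path: str | Path) -> GroupDesign:
    """Read a two-column TSV (sample_id, arm); a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: design file must have exactly two columns")
    rows = df.itertuples(index=False)
    first = df.iloc[0]
    if str(first.iloc[1]).lower() not in (TREATMENT, REFERENCE):
        next(rows)  # header
    arms = {str(s): str(a).lower() for s, a in rows}
    return GroupDesign(arms)


def write_design(d: GroupDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(d.arms):
            fh.write(f"{s}\t{d.arms[s]}\n")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def to_log2(m: IntensityMatrix) -> IntensityMatrix:
    """Elementwise base-2 logarithm of a raw-scale matrix."""
    if m.scale == LOG2:
        raise ValidationError("matrix is already log2")
    if not np.all(m.values > 0):
        raise ValidationError("log2 transform requires strictly positive values")
    return m.with_values(np.log2(m.values), scale=LOG2)


@dataclass
class ResultRecord:
    """Free-form keyed results with provenance (method, parameters, seed)."""

    method: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    results: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(
            {"method": self.method, "params": self.params,
             "seed": self.seed, "results": self.results},
            default=default,
        )

    @classmethod
    def from_json(cls, text: str) -> "ResultRecord":
        obj = json.loads(text)
        return cls(method=obj["method"], params=obj.get("params", {}),
                   seed=obj.get("seed"), results=obj.get("results", {}))
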