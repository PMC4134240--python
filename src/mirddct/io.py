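"""Readers and writers for the plain-text files the pipeline touches.

Three delimited-text contracts are defined here:

* **Ct table** — long form, one row per well:
  ``sample_id,pair_id,tissue_class,assay_id,ct``. ``tissue_class`` is
  ``lesion`` or ``control``; ``ct`` is a positive cycle number or a
  censoring token (empty cell, ``Undetermined`` or ``N/A``) meaning the
  reaction never crossed threshold.
* **ddCt matrix** — wide form, rows are assays, columns are sample pairs,
  ``N/A`` marks cells where no paired value could be computed. This is the
  layout of published supplementary ddCt matrices, so such a file can be
  fed straight into the downstream statistics.
* **annotation map** — ``assay_id,status,current_id`` where status is
  ``valid``, ``renamed`` (current_id gives the replacement) or ``dead``.
  Used to bring array-era miRNA identifiers up to a chosen miRBase release.

All round-trips are lossless: a censored cell is never silently coerced to
a number, and missing is always written back as ``N/A``.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "TissueClass",
    "AnnotationStatus",
    "AnnotationEntry",
    "AnnotationMap",
    "read_ct_table",
    "write_ct_table",
    "validate_ct_table",
    "read_ddct_matrix",
    "write_ddct_matrix",
    "read_annotation_map",
    "write_annotation_map",
    "write_de_report",
]

PathType = Union[str, PathLike]

#: Canonical column order of the long-form Ct table.
CT_COLUMNS = ("sample_id", "pair_id", "tissue_class", "assay_id", "ct")

#: Tokens that parse as a censored (undetected) Ct on input, lower-cased.
CENSOR_TOKENS = frozenset({"", "undetermined", "n/a", "na"})

#: Token written for a missing value on output (matches the supplementary
#: matrix convention).
MISSING_OUT = "N/A"


class TissueClass(str, enum.Enum):
    LESION = "lesion"
    CONTROL = "control"


class AnnotationStatus(str, enum.Enum):
    VALID = "valid"
    RENAMED = "renamed"
    DEAD = "dead"


def _sniff_sep(path: PathType) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _parse_ct(token: str, lineno: int) -> float:
    if token.strip().lower() in CENSOR_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise ValueError(
            f"line {lineno}: ct value {token!r} is neither numeric nor a "
            f"censoring token (empty, 'Undetermined', 'N/A')"
        ) from None
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"line {lineno}: ct value {value} must be finite and > 0")
    return value


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the Ct-table invariants; returns the table unchanged.

    Raises ``ValueError`` on a duplicate (pair, tissue class, assay)
    triple, more than one sample id for a pair/class slot, an unknown
    tissue class, or a non-positive detected Ct.
    """
    missing_cols = [c for c in CT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"Ct table lacks required columns: {missing_cols}")

    bad_class = set(table["tissue_class"].unique()) - {t.value for t in TissueClass}
    if bad_class:
        raise ValueError(f"unknown tissue_class values: {sorted(bad_class)}")

    ct = table["ct"].to_numpy(dtype=float)
    detected = ~np.isnan(ct)
    if np.any(ct[detected] <= 0) or np.any(~np.isfinite(ct[detected])):
        raise ValueError("detected ct values must be finite and > 0")

    dup = table.duplicated(subset=["pair_id", "tissue_class", "assay_id"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(
            "duplicate measurement for (pair_id={0}, tissue_class={1}, "
            "assay_id={2})".format(row["pair_id"], row["tissue_class"], row["assay_id"])
        )

    n_samples = table.groupby(["pair_id", "tissue_class"], sort=False)["sample_id"].nunique()
    if (n_samples > 1).any():
        pair, klass = n_samples[n_samples > 1].index[0]
        raise ValueError(
            f"pair {pair!r} has multiple sample_ids for tissue_class {klass!r}"
        )
    return table


def read_ct_table(path: PathType, sep: Optional[str] = None) -> pd.DataFrame:
    """Read a long-form Ct table; censored wells become ``NaN``.

    Parameters
    ----------
    path:
        Delimited text file whose header names the five columns of
        :data:`CT_COLUMNS` (comma default, tab accepted).
    sep:
        Field delimiter; autodetected from the header line when ``None``.
    """
    sep = sep or _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing_cols = [c for c in CT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path}: header lacks required columns {missing_cols}")

    table = raw.loc[:, list(CT_COLUMNS)].copy()
    for col in CT_COLUMNS[:-1]:
        table[col] = table[col].str.strip()
    # header is line 1, first data row line 2
    table["ct"] = [
        _parse_ct(tok, lineno) for lineno, tok in enumerate(raw["ct"], start=2)
    ]
    return validate_ct_table(table)


def write_ct_table(table: pd.DataFrame, path: PathType, sep: str = ",") -> None:
    """Write a Ct table; ``NaN`` cts are written as ``N/A``."""
    out = table.loc[:, list(CT_COLUMNS)].copy()
    out["ct"] = out["ct"].map(lambda v: MISSING_OUT if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep=sep, index=False)


def read_ddct_matrix(path: PathType, sep: Optional[str] = None) -> pd.DataFrame:
    """Read an assay x pair ddCt matrix; ``N/A`` cells become ``NaN``.

    The first column carries assay ids, the remaining header tokens are
    pair/sample ids taken verbatim (no numbering scheme is assumed).
    Column order is preserved. Ragged rows raise ``ValueError`` naming the
    offending row index.
    """
    sep = sep or _sniff_sep(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    header = [tok.strip() for tok in rows[0]]
    pair_ids = header[1:]
    if len(pair_ids) != len(set(pair_ids)):
        raise ValueError(f"{path}: duplicate pair/sample column ids")
    width = len(header)

    assay_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(pair_ids)), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != width:
            raise ValueError(
                f"{path}: row {i + 1} has {len(row)} fields, expected {width}"
            )
        assay_ids.append(row[0].strip())
        for j, tok in enumerate(row[1:]):
            tok = tok.strip()
            if tok.lower() in CENSOR_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}: row {i + 1}, column {header[j + 1]!r}: "
                        f"cell {tok!r} is neither numeric nor 'N/A'"
                    ) from None
    if len(assay_ids) != len(set(assay_ids)):
        raise ValueError(f"{path}: duplicate assay row ids")
    matrix = pd.DataFrame(values, index=assay_ids, columns=pair_ids)
    matrix.index.name = "assay_id"
    return matrix


def write_ddct_matrix(matrix: pd.DataFrame, path: PathType, sep: str = ",") -> None:
    """Write a ddCt matrix in the supplementary-file layout (``N/A`` missing)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["assay_id", *matrix.columns])
        for assay_id, row in matrix.iterrows():
            writer.writerow(
                [assay_id]
                + [MISSING_OUT if pd.isna(v) else repr(float(v)) for v in row]
            )


@dataclass(frozen=True)
class AnnotationEntry:
    assay_id: str
    status: AnnotationStatus
    current_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status is AnnotationStatus.RENAMED:
            if not self.current_id or self.current_id == self.assay_id:
                raise ValueError(
                    f"renamed assay {self.assay_id!r} needs a distinct current_id"
                )
        elif self.current_id:
            raise ValueError(
                f"assay {self.assay_id!r} with status {self.status.value} "
                "must not carry a current_id"
            )


@dataclass
class AnnotationMap:
    """Assay-id validity relation between two annotation releases.

    ``resolve`` returns the up-to-date id for an assay, or ``None`` when
    the assay is dead or absent from the map (both are dropped downstream).
    """

    entries: dict[str, AnnotationEntry] = field(default_factory=dict)

    @classmethod
    def from_entries(cls, entries: Iterable[AnnotationEntry]) -> "AnnotationMap":
        out: dict[str, AnnotationEntry] = {}
        for e in entries:
            if e.assay_id in out:
                raise ValueError(f"duplicate assay_id {e.assay_id!r} in annotation map")
            out[e.assay_id] = e
        return cls(out)

    @classmethod
    def all_valid(cls, assay_ids: Iterable[str]) -> "AnnotationMap":
        return cls.from_entries(
            AnnotationEntry(a, AnnotationStatus.VALID) for a in assay_ids
        )

    def resolve(self, assay_id: str) -> Optional[str]:
        entry = self.entries.get(assay_id)
        if entry is None or entry.status is AnnotationStatus.DEAD:
            return None
        if entry.status is AnnotationStatus.RENAMED:
            return entry.current_id
        return assay_id

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, assay_id: str) -> bool:
        return assay_id in self.entries


def read_annotation_map(path: PathType, sep: Optional[str] = None) -> AnnotationMap:
    """Read a three-column ``assay_id,status,current_id`` map."""
    sep = sep or _sniff_sep(path)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None:
            return AnnotationMap()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not tok.strip() for tok in row):
                continue
            row = [tok.strip() for tok in row] + [""] * (3 - len(row))
            assay_id, status_tok, current = row[0], row[1].lower(), row[2]
            try:
                status = AnnotationStatus(status_tok)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: unknown status {status_tok!r}"
                ) from None
            entries.append(AnnotationEntry(assay_id, status, current or None))
    return AnnotationMap.from_entries(entries)


def write_annotation_map(amap: AnnotationMap, path: PathType, sep: str = ",") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["assay_id", "status", "current_id"])
        for e in amap.entries.values():
            writer.writerow([e.assay_id, e.status.value, e.current_id or ""])


DE_REPORT_COLUMNS = (
    "assay_id",
    "n_pairs",
    "mean_ddct",
    "median_ddct",
    "direction",
    "t",
    "df",
    "p",
    "bh_significant",
    "fold_change",
)


def write_de_report(results: Sequence, path: PathType, sep: str = ",") -> None:
    """Write per-assay differential-expression results sorted by ascending p.

    ``results`` is a sequence of :class:`mirddct.diffexpr.DirectionalTestResult`.
    Untested assays (direction tie or degenerate variance) are written with
    blank t/df/p and sort after every tested assay.
    """
    if not results:
        raise ValueError("empty result list: nothing to report")
    ordered = sorted(
        results, key=lambda r: (np.inf if r.p is None else r.p, r.assay_id)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(DE_REPORT_COLUMNS)
        for r in ordered:
            writer.writerow(
                [
                    r.assay_id,
                    r.n,
                    f"{r.mean_ddct:.6g}",
                    f"{r.median_ddct:.6g}",
                    r.direction,
                    "" if r.t is None else f"{r.t:.6g}",
                    "" if r.df is None else r.df,
                    "" if r.p is None else f"{r.p:.6g}",
                    int(bool(r.bh_significant)),
                    f"{r.fold:.6g}",
                ]
            )
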