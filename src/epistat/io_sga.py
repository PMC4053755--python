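"""Reading, validation, filtering and deduplication of raw SGA-style fitness tables.

The raw input is a tab-separated table with one row per query-gene x
array-gene double mutant, carrying the relative growth rates of the two
single mutants (``g01``, ``g10``), of the double mutant (``g11``), and
per-measurement uncertainty estimates (``sd01``, ``sd10``, ``sd11``).
Growth rates are relative to wild type (``g00 = 1``) and are never
renormalized here.

Column layouts differ between sources, so the mapping from logical fields
to column names or 0-based positions is carried by a :class:`Dialect`.
Two dialects ship with the package: the package's own ``native`` layout
(also written by :func:`write_table`) and a best-effort ``costanzo2010``
layout for the published genome-scale yeast double-knockout release.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "FitnessRecord",
    "Dataset",
    "NATIVE_DIALECT",
    "COSTANZO_DIALECT",
    "read_raw_table",
    "apply_filters",
    "deduplicate_pairs",
    "write_table",
]

#: canonical column order used internally and by the native TSV layout
FIELDS = ("query_id", "array_id", "g01", "g10", "g11", "sd01", "sd10", "sd11", "n_reps")
NUMERIC_FIELDS = ("g01", "g10", "g11", "sd01", "sd10", "sd11", "n_reps")
REQUIRED_FIELDS = ("query_id", "array_id", "g01", "g10", "g11")


@dataclass(frozen=True)
class Dialect:
    """Mapping from logical record fields to columns of a TSV file.

    ``columns`` maps each logical field name to either a header name
    (``str``) or a 0-based column index (``int``).  Fields absent from the
    mapping are treated as missing in every record.  ``header`` states
    whether the file carries a header line.
    """

    columns: Mapping[str, str | int]
    header: bool = True
    sep: str = "\t"
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise ValueError(f"dialect {self.name!r} lacks required fields: {missing}")


NATIVE_DIALECT = Dialect(
    columns={f: f for f in FIELDS},
    header=True,
    name="native",
)

# Best-effort mapping for the published raw SGA release (tab-delimited, no
# header): query ORF/name, array ORF/name, interaction score + sd + p-value,
# then query/array single-mutant fitness with sd, then double-mutant fitness
# with sd.  Overridable because the upstream layout is not formally documented.
COSTANZO_DIALECT = Dialect(
    columns={
        "query_id": 0,
        "array_id": 2,
        "g01": 7,
        "sd01": 8,
        "g10": 9,
        "sd10": 10,
        "g11": 11,
        "sd11": 12,
    },
    header=False,
    name="costanzo2010",
)


class FitnessRecord(NamedTuple):
    """One query x array double-mutant measurement (relative growth rates)."""

    query_id: str
    array_id: str
    g01: float
    g10: float
    g11: float
    sd01: float
    sd10: float
    sd11: float
    n_reps: float


@dataclass
class Dataset:
    """A collection of double-mutant fitness records plus bookkeeping.

    ``frame`` holds one row per record with the canonical columns of
    :data:`FIELDS`; missing numeric values are NaN (never silently 0).
    ``filter_log`` counts records removed per filter rule; its values sum
    to ``raw rows - retained rows`` after :func:`apply_filters` /
    :func:`deduplicate_pairs`.
    """

    frame: pd.DataFrame
    provenance: str = ""
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[FitnessRecord]:
        for row in self.frame.itertuples(index=False):
            yield FitnessRecord(*row)

    def copy_with(self, frame: pd.DataFrame, **log: int) -> "Dataset":
        merged = dict(self.filter_log)
        for k, v in log.items():
            merged[k] = merged.get(k, 0) + int(v)
        return Dataset(frame=frame, provenance=self.provenance, filter_log=merged)


def _normalize_frame(raw: pd.DataFrame, dialect: Dialect, path: str) -> pd.DataFrame:
    cols: dict[str, pd.Series] = {}
    for fieldname in FIELDS:
        ref = dialect.columns.get(fieldname)
        if ref is None:
            cols[fieldname] = pd.Series(np.nan, index=raw.index)
            continue
        if isinstance(ref, int):
            if ref >= raw.shape[1]:
                raise KeyError(
                    f"dialect {dialect.name!r}: column index {ref} for field "
                    f"{fieldname!r} out of range for {path!r} "
                    f"({raw.shape[1]} columns)"
                )
            col = raw.iloc[:, ref]
        else:
            if ref not in raw.columns:
                raise KeyError(
                    f"dialect {dialect.name!r}: column {ref!r} for field "
                    f"{fieldname!r} not present in {path!r}"
                )
            col = raw[ref]
        cols[fieldname] = col
    out = pd.DataFrame(cols)
    for fieldname in NUMERIC_FIELDS:
        # unparseable numeric fields become NaN, not zeros
        out[fieldname] = pd.to_numeric(out[fieldname], errors="coerce")
    out["query_id"] = out["query_id"].astype(str)
    out["array_id"] = out["array_id"].astype(str)
    return out.reset_index(drop=True)


def read_raw_table(path, dialect: Dialect = NATIVE_DIALECT) -> Dataset:
    """Parse a (possibly gzipped) TSV of double-mutant fitness measurements.

    Returns one record per parseable row, in file order.  Numeric fields
    that fail to parse are recorded as NaN and removed later by
    :func:`apply_filters`, never coerced to zero.
    """
    raw = pd.read_csv(
        path,
        sep=dialect.sep,
        header=0 if dialect.header else None,
        dtype=str,
        compression="infer",
        keep_default_na=False,
    )
    frame = _normalize_frame(raw, dialect, str(path))
    return Dataset(frame=frame, provenance=str(path))


def apply_filters(ds: Dataset) -> Dataset:
    """Restrict to analyzable double mutants, logging every removal.

    Retained rows have finite single-mutant growth rates and a finite,
    strictly positive double-mutant growth rate.  Rows are logged under
    exactly one key, checked in order: ``nonnumeric_single`` (g01 or g10
    not a number), ``lethal_double`` (g11 == 0, counted but not analyzed),
    ``negative_double`` (g11 < 0, corrupt), ``nonnumeric_double``.
    Idempotent: filtering a filtered dataset changes nothing.
    """
    f = ds.frame
    g01, g10, g11 = (f[c].to_numpy(float) for c in ("g01", "g10", "g11"))
    singles_ok = np.isfinite(g01) & np.isfinite(g10)
    lethal = singles_ok & (g11 == 0)
    negative = singles_ok & np.isfinite(g11) & (g11 < 0)
    nonnum_double = singles_ok & ~np.isfinite(g11)
    keep = singles_ok & np.isfinite(g11) & (g11 > 0)
    return ds.copy_with(
        f.loc[keep].reset_index(drop=True),
        nonnumeric_single=int((~singles_ok).sum()),
        lethal_double=int(lethal.sum()),
        negative_double=int(negative.sum()),
        nonnumeric_double=int(nonnum_double.sum()),
    )


def _mean_sd(frame: pd.DataFrame) -> np.ndarray:
    sds = frame[["sd01", "sd10", "sd11"]].to_numpy(float)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(sds, axis=1)
    # records without any uncertainty lose ties against measured ones
    return np.where(np.isfinite(m), m, np.inf)


def deduplicate_pairs(ds: Dataset, policy: str = "min_sd") -> Dataset:
    """Keep at most one record per unordered gene pair.

    The default ``min_sd`` policy keeps the record with the smaller mean
    reported uncertainty; ties go to the lexicographically smaller query
    id, then array id.  ``first`` keeps the first occurrence in row order.
    With ``min_sd`` the output is invariant under row permutations of the
    input.  Removals are logged under ``duplicate_pair``.
    """
    f = ds.frame
    if len(f) == 0:
        return ds.copy_with(f, duplicate_pair=0)
    a = f["query_id"].to_numpy()
    b = f["array_id"].to_numpy()
    swap = a > b
    lo = np.where(swap, b, a)
    hi = np.where(swap, a, b)
    work = f.assign(_lo=lo, _hi=hi)
    if policy == "min_sd":
        work = work.assign(_msd=_mean_sd(f))
        work = work.sort_values(
            ["_lo", "_hi", "_msd", "query_id", "array_id"], kind="mergesort"
        )
    elif policy == "first":
        pass  # stable groupby keeps file order
    else:
        raise ValueError(f"unknown deduplication policy: {policy!r}")
    kept = work.groupby(["_lo", "_hi"], sort=False).head(1)
    if policy == "min_sd":
        kept = kept.sort_values(["_lo", "_hi"], kind="mergesort")
        kept = kept.drop(columns="_msd")
    kept = kept.drop(columns=["_lo", "_hi"]).reset_index(drop=True)
    return ds.copy_with(kept, duplicate_pair=len(f) - len(kept))


def write_table(ds: Dataset, path, dialect: Dialect = NATIVE_DIALECT) -> None:
    """Write a dataset back to TSV in the given dialect (gzip by suffix).

    Only name-mapped dialects with a header can be written; NaN becomes an
    empty field, so a read/write round trip preserves the numeric payload.
    """
    if any(isinstance(v, int) for v in dialect.columns.values()) or not dialect.header:
        raise ValueError("writing requires a header dialect with name-mapped columns")
    out = pd.DataFrame(
        {str(dialect.columns[f]): ds.frame[f] for f in FIELDS if f in dialect.columns}
    )
    text = out.to_csv(sep=dialect.sep, index=False, na_rep="")
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        with io.open(path, "w") as fh:
            fh.write(text)
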