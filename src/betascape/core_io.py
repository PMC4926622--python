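"""Domain containers and CSV/JSON plumbing.

Three table kinds move through the pipeline: a binary site x species
occurrence matrix, a per-site predictor table (area, spatial position,
climate), and square pairwise dissimilarity / similarity matrices.  Sites
are rows everywhere; site order fixed at load time is preserved through
every downstream stage.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceMatrix",
    "SiteTable",
    "DissimilarityMatrix",
    "read_occurrences",
    "read_site_table",
    "write_occurrences",
    "write_site_table",
    "write_dissimilarity",
    "read_dissimilarity",
    "write_report",
    "SITE_TABLE_NUMERIC_COLUMNS",
    "RANGE_TRIPLES",
]

# canonical predictor schema: (mean, min, max, range) column families
RANGE_TRIPLES = {
    "Long_ran": ("Long_min", "Long_max"),
    "Lat_ran": ("Lat_min", "Lat_max"),
}

SITE_TABLE_NUMERIC_COLUMNS = [
    "Area",
    "Long", "Long_min", "Long_max", "Long_ran",
    "Lat", "Lat_min", "Lat_max", "Lat_ran",
    "Alt", "Alt_ran",
    "T_ann", "T_ran", "T_max", "T_min",
    "P_ann", "P_ran", "P_dri", "P_drn",
]

_TRUTHY_DEFAULT = {"1": 1, "0": 0, "true": 1, "false": 0, "x": 1, "": 0}


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary incidence table: sites as rows, species (taxa) as columns."""

    site_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    incidence: np.ndarray  # int8 [n_sites, n_species], entries in {0, 1}

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2:
            raise ValueError("incidence must be a 2-D matrix")
        if inc.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        _check_unique(self.site_ids, "site")
        _check_unique(self.species_ids, "species")
        bad = (inc != 0) & (inc != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at site {self.site_ids[i]!r}, "
                f"species {self.species_ids[j]!r}: {inc[i, j]!r}"
            )
        object.__setattr__(self, "incidence", inc.astype(np.int8))

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness(self) -> np.ndarray:
        """Species count per site, in site order."""
        return self.incidence.sum(axis=1).astype(np.int64)

    def empty_sites(self) -> list[str]:
        r = self.richness()
        return [s for s, k in zip(self.site_ids, r) if k == 0]

    def empty_species(self) -> list[str]:
        k = self.incidence.sum(axis=0)
        return [s for s, c in zip(self.species_ids, k) if c == 0]

    def drop_empty_sites(self) -> "OccurrenceMatrix":
        keep = self.richness() > 0
        return OccurrenceMatrix(
            tuple(s for s, k in zip(self.site_ids, keep) if k),
            self.species_ids,
            self.incidence[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=list(self.site_ids), columns=list(self.species_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceMatrix":
        return cls(
            tuple(str(s) for s in df.index),
            tuple(str(s) for s in df.columns),
            df.to_numpy(),
        )


@dataclass(frozen=True)
class SiteTable:
    """Per-site predictors: area (km^2), spatial position (decimal degrees,
    WGS84 assumed), altitude (m), temperature (deg C) and precipitation (mm)
    summaries.  Extra columns are carried through as generic predictors."""

    data: pd.DataFrame  # index = site_id
    missing_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.data
        _check_unique([str(i) for i in df.index], "site")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValueError(f"non-numeric predictor column: {col!r}")
        if "Area" in df.columns and (df["Area"] <= 0).any():
            bad = df.index[df["Area"] <= 0][0]
            raise ValueError(f"non-positive area for site {bad!r}")
        for mean_col, (lo, hi) in {
            "Long": ("Long_min", "Long_max"),
            "Lat": ("Lat_min", "Lat_max"),
        }.items():
            if {mean_col, lo, hi} <= set(df.columns):
                if (df[lo] - df[mean_col] > 1e-9).any() or (df[mean_col] - df[hi] > 1e-9).any():
                    raise ValueError(
                        f"{lo} <= {mean_col} <= {hi} violated for some site"
                    )
        for ran_col, (lo, hi) in RANGE_TRIPLES.items():
            if {lo, hi} <= set(df.columns):
                if (df[hi] < df[lo]).any():
                    raise ValueError(f"{lo} > {hi} for some site")

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.data.index)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col].to_numpy(dtype=float)

    def align_to(self, occ: OccurrenceMatrix) -> "SiteTable":
        """Reorder rows to the occurrence matrix's site order; error on any
        mismatch between the two site sets."""
        mine, theirs = set(self.site_ids), set(occ.site_ids)
        if mine != theirs:
            orphans = sorted(mine ^ theirs)
            raise ValueError(f"site tables do not align; orphan sites: {orphans}")
        return SiteTable(self.data.loc[list(occ.site_ids)], self.missing_columns)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric pairwise matrix with zero (dissimilarity) or unit
    (similarity) diagonal; values in [0, 1]."""

    site_ids: tuple[str, ...]
    values: np.ndarray
    kind: str = "dissimilarity"  # or "similarity"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        _check_unique(self.site_ids, "site")
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} sites")
        if np.isnan(v).any():
            raise ValueError("NaN in dissimilarity matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        diag = 1.0 if self.kind == "similarity" else 0.0
        if not np.allclose(np.diag(v), diag, atol=1e-12):
            raise ValueError(f"diagonal of a {self.kind} matrix must be {diag}")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("values outside [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) values in scipy condensed order."""
        iu = np.triu_indices(self.n_sites, k=1)
        return self.values[iu]

    def submatrix(self, sites: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.site_ids.index(s) for s in sites]
        return DissimilarityMatrix(
            tuple(sites), self.values[np.ix_(idx, idx)], self.kind
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_occurrences(
    path: str | Path,
    truthy: Mapping[str, int] | None = None,
    drop_empty_sites: bool = False,
) -> OccurrenceMatrix:
    """Read a site x species CSV (first column site labels, header species
    labels).  Empty sites are a hard error by default because pairwise
    turnover is undefined for them; ``drop_empty_sites=True`` drops them
    with a warning instead."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty occurrence file: {path}")
    tokens = dict(_TRUTHY_DEFAULT)
    if truthy:
        tokens.update({k.lower(): v for k, v in truthy.items()})
    inc = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            tok = str(raw[i, j]).strip().lower()
            if tok not in tokens:
                raise ValueError(
                    f"non-binary cell at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}: {raw[i, j]!r}"
                )
            inc[i, j] = tokens[tok]
    occ = OccurrenceMatrix(
        tuple(str(s) for s in df.index), tuple(str(s) for s in df.columns), inc
    )
    empties = occ.empty_sites()
    if empties:
        if drop_empty_sites:
            warnings.warn(f"dropping empty sites: {empties}")
            occ = occ.drop_empty_sites()
        else:
            raise ValueError(
                f"sites with zero species (turnover undefined): {empties}; "
                "pass drop_empty_sites=True to drop them"
            )
    return occ


def write_occurrences(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index_label="site")


def read_site_table(path: str | Path) -> SiteTable:
    """Read the per-site predictor CSV.  Missing optional columns are
    recorded; Lat_ran/Long_ran are recomputed from min/max when absent."""
    df = pd.read_csv(path, index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric predictor column: {col!r}")
    for ran_col, (lo, hi) in RANGE_TRIPLES.items():
        if ran_col not in df.columns and {lo, hi} <= set(df.columns):
            df[ran_col] = df[hi] - df[lo]
    missing = tuple(c for c in SITE_TABLE_NUMERIC_COLUMNS if c not in df.columns)
    df.index = df.index.map(str)
    return SiteTable(df, missing)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="site")


def write_dissimilarity(d: DissimilarityMatrix, path: str | Path, long_format: bool = False) -> None:
    if long_format:
        iu = np.triu_indices(d.n_sites, k=1)
        rows = pd.DataFrame(
            {
                "site_i": [d.site_ids[i] for i in iu[0]],
                "site_j": [d.site_ids[j] for j in iu[1]],
                "value": d.values[iu],
            }
        )
        rows.to_csv(path, index=False)
    else:
        pd.DataFrame(d.values, index=list(d.site_ids), columns=list(d.site_ids)).to_csv(
            path, index_label="site"
        )


def read_dissimilarity(path: str | Path, kind: str = "dissimilarity") -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.map(str)) != [str(c) for c in df.columns]:
        raise ValueError("row and column site labels differ")
    return DissimilarityMatrix(tuple(str(i) for i in df.index), df.to_numpy(float), kind)


# ---------------------------------------------------------------------------
# reports


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return [_jsonify(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(x) for x in obj]
    if hasattr(obj, "to_report_rows"):
        return _jsonify(obj.to_report_rows())
    if hasattr(obj, "__dict__") and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in vars(obj).items()}
    return obj


def _fmt6(x) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return ""
        return f"{x:.6g}"
    return str(x)


def write_report(result, path: str | Path, rows: Iterable[Mapping] | None = None) -> None:
    """Write a stage result as deterministic JSON; if tabular rows are given
    (or the result exposes ``to_report_rows``) also write a CSV shaped like
    the published variance tables (Variable, Function, Variance %, F, d.f., p),
    floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(_jsonify(result), fh, sort_keys=True, indent=1)
        fh.write("\n")
    if rows is None and hasattr(result, "to_report_rows"):
        rows = result.to_report_rows()
    if rows is not None:
        rows = list(rows)
        cols: list[str] = []
        for r in rows:
            for k in r:
                if k not in cols:
                    cols.append(k)
        with open(path.with_suffix(".csv"), "w") as fh:
            fh.write(",".join(cols) + "\n")
            for r in rows:
                fh.write(",".join(_fmt6(r.get(k, "")) for k in cols) + "\n")
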