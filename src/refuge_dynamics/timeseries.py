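"""Annual winter count series for the three populations.

The data model is one row per winter (a "winter" spans November-April and
is indexed by its starting calendar year) with three columns: elk counted
in the townsite refuge, elk in the adjacent valley, and valley wolves.
Two survey conventions from the source monitoring program are provided as
operations: summation of two wolf packs into a single valley total for the
early winters, and a fixed-percentage sightability correction applied to
aerial elk counts to offset observer undercounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountSeries",
    "read_counts",
    "write_counts",
    "apply_sightability",
    "invert_sightability",
    "merge_pack_counts",
    "COLUMNS",
]

COLUMNS = ("winter_start_year", "banff_elk", "bow_elk", "bow_wolves")
SERIES_COLUMNS = COLUMNS[1:]


@dataclass(frozen=True)
class CountSeries:
    """Aligned annual counts for refuge elk, valley elk and valley wolves.

    Counts may be fractional (after sightability adjustment) and are
    treated as continuous observations.  ``n_obs`` is the total number of
    scalar observations, 3 per winter.
    """

    winter_start_year: np.ndarray
    banff_elk: np.ndarray
    bow_elk: np.ndarray
    bow_wolves: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.winter_start_year)
        arrays = {c: np.asarray(getattr(self, c), dtype=float) for c in SERIES_COLUMNS}
        n = len(years)
        if n < 3:
            raise ValueError(f"need at least 3 winters to fit, got {n}")
        for c, a in arrays.items():
            if len(a) != n:
                raise ValueError(f"column {c!r} has length {len(a)}, expected {n}")
            if not np.all(np.isfinite(a)):
                bad = int(np.flatnonzero(~np.isfinite(a))[0])
                raise ValueError(f"non-finite count in {c!r} at row {bad}")
            if np.any(a < 0):
                bad = int(np.flatnonzero(a < 0)[0])
                raise ValueError(
                    f"negative count in {c!r} at row {bad} "
                    f"(winter {int(years[bad])}): {a[bad]}"
                )
        if np.any(np.diff(years) != 1):
            raise ValueError("winter_start_year must increase by exactly 1 per row")
        object.__setattr__(self, "winter_start_year", years.astype(int))
        for c, a in arrays.items():
            object.__setattr__(self, c, a)

    @property
    def n_years(self) -> int:
        return len(self.winter_start_year)

    @property
    def n_obs(self) -> int:
        return 3 * self.n_years

    @property
    def t_index(self) -> np.ndarray:
        """Years since the first winter (0, 1, ...)."""
        return self.winter_start_year - self.winter_start_year[0]

    def stacked(self) -> np.ndarray:
        """(n_years, 3) array in (banff_elk, bow_elk, bow_wolves) order."""
        return np.column_stack([self.banff_elk, self.bow_elk, self.bow_wolves])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in COLUMNS})

    def __eq__(self, other):
        if not isinstance(other, CountSeries):
            return NotImplemented
        return all(np.array_equal(getattr(self, c), getattr(other, c)) for c in COLUMNS)


def read_counts(path, dialect: dict | None = None) -> CountSeries:
    """Read a header-plus-rows CSV of annual counts.

    ``dialect`` optionally maps the canonical column names to the names
    used in the file, e.g. ``{"banff_elk": "refuge_elk"}``.  Rows are
    sorted by winter before validation; duplicate winters, missing
    columns, gaps and non-numeric cells are rejected with row/column
    context.
    """
    df = pd.read_csv(path)
    mapping = {c: c for c in COLUMNS}
    if dialect:
        mapping.update(dialect)
    missing = [mapping[c] for c in COLUMNS if mapping[c] not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    out = {}
    for canon in COLUMNS:
        col = df[mapping[canon]]
        vals = pd.to_numeric(col, errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(
                f"non-numeric cell in column {mapping[canon]!r}, row {row}: "
                f"{col.iloc[row]!r}"
            )
        out[canon] = vals.to_numpy()
    order = np.argsort(out["winter_start_year"], kind="stable")
    out = {c: v[order] for c, v in out.items()}
    years = out["winter_start_year"]
    dup = np.flatnonzero(np.diff(years) == 0)
    if dup.size:
        raise ValueError(f"duplicate winter {int(years[dup[0]])} in {path}")
    return CountSeries(**out)


def write_counts(series: CountSeries, path) -> None:
    """Write a CountSeries as CSV with fixed column order and 6-decimal
    precision, so that ``read_counts(write_counts(s)) == s`` for counts
    stored at that precision."""
    df = series.to_frame()
    df[list(SERIES_COLUMNS)] = df[list(SERIES_COLUMNS)].round(6)
    df.to_csv(path, index=False, float_format="%.6f")


def apply_sightability(raw_elk, rate: float = 0.13) -> np.ndarray:
    """Correct elk counts upward for observer undercounting.

    ``adjusted = raw * (1 + rate)``: an aerial count misses a fraction of
    animals, so the survey total is inflated by the sightability rate
    (13% by default).  Applies to elk only; wolf counts are never
    adjusted.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"sightability rate must be in [0, 1), got {rate}")
    return np.asarray(raw_elk, dtype=float) * (1.0 + rate)


def invert_sightability(adjusted_elk, rate: float = 0.13) -> np.ndarray:
    """Exact inverse of :func:`apply_sightability`."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"sightability rate must be in [0, 1), got {rate}")
    return np.asarray(adjusted_elk, dtype=float) / (1.0 + rate)


def merge_pack_counts(castle, spray) -> np.ndarray:
    """Elementwise sum of two pack count sequences (early-period winters
    when the valley supported two wolf packs)."""
    a = np.asarray(castle, dtype=float)
    b = np.asarray(spray, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"pack series lengths differ: {a.shape} vs {b.shape}")
    return a + b
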