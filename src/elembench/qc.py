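"""Sample-table I/O and data-cleaning rules for hair element panels.

A sample table is a :class:`pandas.DataFrame` with one row per hair sample:

* metadata columns ``sample_id, population, growth_year, trend, collection,
  age_class, sex`` (``trend`` is an ordered categorical
  declining < stable < increasing);
* one float column per panel element (concentration, µg/g; NaN = missing);
* one boolean column ``<element>_below_loq`` per element.

Cleaning applies, in order: half-LOQ substitution for below-LOQ values with
removal of any element mostly (>50%) below LOQ; exclusion of records with
missing required metadata; and a single-pass two-sided outlier screen that
removes samples further than ``k`` standard deviations from an element mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ElementPanel, PanelConfigError

METADATA_COLUMNS = (
    "sample_id", "population", "growth_year", "trend",
    "collection", "age_class", "sex",
)
TREND_LEVELS = ("declining", "stable", "increasing")
COLLECTION_LEVELS = ("hunted", "capture", "shed")
DEFAULT_SENTINEL = "<LOQ"

#: metadata a record must carry to enter any analysis
DEFAULT_REQUIRED_FIELDS = ("sample_id", "population", "growth_year", "trend", "collection")


class TableFormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


def flag_col(element: str) -> str:
    return f"{element}_below_loq"


@dataclass
class QCReport:
    """Bookkeeping for the cleaning steps.

    Satisfies ``n_input == n_missing_excluded + n_outlier_excluded + n_retained``.
    """

    n_input: int
    n_missing_excluded: int
    n_outlier_excluded: int
    n_retained: int
    dropped_elements: list[tuple[str, float]] = field(default_factory=list)
    outlier_detail: list[tuple[str, str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_missing_excluded + self.n_outlier_excluded + self.n_retained:
            raise ValueError("QC counts do not add up")

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_missing_excluded": self.n_missing_excluded,
            "n_outlier_excluded": self.n_outlier_excluded,
            "n_retained": self.n_retained,
            "dropped_elements": [list(t) for t in self.dropped_elements],
            "outlier_detail": [list(t) for t in self.outlier_detail],
        }


def _elements_in(table: pd.DataFrame, panel: ElementPanel) -> list[str]:
    return [el for el in panel.names if el in table.columns]


def read_samples(path, panel: ElementPanel, sentinel: str = DEFAULT_SENTINEL) -> pd.DataFrame:
    """Read a delimited sample table.

    Concentration cells equal to ``sentinel`` are recorded as below-LOQ
    (value missing until substitution); unparseable cells become missing.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise TableFormatError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    elements = [el for el in panel.names if el in raw.columns]

    out = pd.DataFrame(index=raw.index)
    for c in METADATA_COLUMNS:
        col = raw[c].mask(raw[c] == "", np.nan)
        if c == "growth_year":
            out[c] = pd.to_numeric(col, errors="coerce").astype("Int64")
        else:
            out[c] = col
    bad_trend = out["trend"].dropna()[~out["trend"].dropna().isin(TREND_LEVELS)]
    if len(bad_trend):
        raise ValueError(
            f"unknown trend label(s): {sorted(bad_trend.unique())}; "
            f"expected one of {TREND_LEVELS}"
        )
    out["trend"] = pd.Categorical(out["trend"], categories=TREND_LEVELS, ordered=True)

    for el in elements:
        cells = raw[el].str.strip()
        flagged = cells == sentinel
        vals = pd.to_numeric(cells.where(~flagged, ""), errors="coerce")
        out[el] = vals.astype(float)
        out[flag_col(el)] = flagged.to_numpy(dtype=bool)
    return out


def write_samples(table: pd.DataFrame, path, panel: ElementPanel,
                  sentinel: str = DEFAULT_SENTINEL) -> None:
    """Write a sample table to CSV in the dialect :func:`read_samples` reads.

    Below-LOQ cells whose value has not been substituted yet (NaN with the
    flag set) are written as the sentinel; substituted cells keep their
    numeric value and the flag is not round-tripped for them.
    """
    elements = _elements_in(table, panel)
    out = table[list(METADATA_COLUMNS)].copy()
    for el in elements:
        vals = table[el]
        col = vals.map(lambda v: "" if pd.isna(v) else repr(float(v)))
        if flag_col(el) in table.columns:
            flagged_unfilled = table[flag_col(el)].to_numpy(dtype=bool) & vals.isna().to_numpy()
            col = col.mask(pd.Series(flagged_unfilled, index=table.index), sentinel)
        out[el] = col
    out.to_csv(path, index=False)


def substitute_below_loq(table: pd.DataFrame, panel: ElementPanel
                         ) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Replace below-LOQ values by LOQ/2; drop elements mostly below LOQ.

    Every below-LOQ cell of a retained element gets the value ``LOQ/2``.
    An element whose below-LOQ fraction over non-missing entries exceeds 0.5
    is removed from the table entirely and returned in ``dropped`` together
    with that fraction. Idempotent.
    """
    table = table.copy()
    dropped: list[tuple[str, float]] = []
    for el in _elements_in(table, panel):
        fc = flag_col(el)
        flags = table[fc].to_numpy(dtype=bool) if fc in table.columns else np.zeros(len(table), bool)
        if not flags.any():
            continue
        if el not in panel.loq:
            raise PanelConfigError(f"element {el!r} has below-LOQ flags but no LOQ configured")
        n_nonmissing = int((table[el].notna() | flags).sum())
        frac = flags.sum() / n_nonmissing if n_nonmissing else 0.0
        if frac > 0.5:
            table = table.drop(columns=[el, fc])
            dropped.append((el, float(frac)))
        else:
            table.loc[flags, el] = panel.loq[el] / 2.0
    return table, dropped


def exclude_incomplete(table: pd.DataFrame, required_fields=DEFAULT_REQUIRED_FIELDS
                       ) -> tuple[pd.DataFrame, int]:
    """Drop records missing any required metadata field."""
    bad = [f for f in required_fields if f not in METADATA_COLUMNS]
    if bad:
        raise ValueError(f"unknown required field(s): {bad}")
    if not required_fields:
        return table.copy(), 0
    keep = table[list(required_fields)].notna().all(axis=1)
    return table.loc[keep].copy(), int((~keep).sum())


def remove_outliers(table: pd.DataFrame, panel: ElementPanel, k: float = 3.0
                    ) -> tuple[pd.DataFrame, QCReport]:
    """Single-pass two-sided outlier screen.

    For each element, samples with ``|x - mean| > k * SD`` (mean and sample
    SD over the non-missing values of the input table, not recomputed after
    removals) are flagged; flagged samples are removed. An element with zero
    SD yields no removals.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    n_input = len(table)
    detail: list[tuple[str, str, float, float]] = []
    drop = pd.Series(False, index=table.index)
    for el in _elements_in(table, panel):
        vals = table[el]
        ok = vals.notna()
        if ok.sum() < 3:
            continue
        mean = float(vals[ok].mean())
        sd = float(vals[ok].std(ddof=1))
        if sd == 0.0:
            continue
        thresh = k * sd
        out = ok & ((vals - mean).abs() > thresh)
        for idx in table.index[out]:
            detail.append((str(table.at[idx, "sample_id"]), el,
                           float(table.at[idx, el]), float(thresh)))
        drop |= out
    cleaned = table.loc[~drop].copy()
    report = QCReport(
        n_input=n_input,
        n_missing_excluded=0,
        n_outlier_excluded=int(drop.sum()),
        n_retained=len(cleaned),
        outlier_detail=detail,
    )
    return cleaned, report


def run_qc(table: pd.DataFrame, panel: ElementPanel,
           required_fields=DEFAULT_REQUIRED_FIELDS, k: float = 3.0
           ) -> tuple[pd.DataFrame, QCReport]:
    """LOQ substitution -> completeness exclusion -> outlier screen."""
    n_input = len(table)
    table, dropped = substitute_below_loq(table, panel)
    table, n_missing = exclude_incomplete(table, required_fields)
    cleaned, orep = remove_outliers(table, panel, k=k)
    report = QCReport(
        n_input=n_input,
        n_missing_excluded=n_missing,
        n_outlier_excluded=orep.n_outlier_excluded,
        n_retained=orep.n_retained,
        dropped_elements=dropped,
        outlier_detail=orep.outlier_detail,
    )
    return cleaned, report
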