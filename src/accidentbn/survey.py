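"""Survey tables: categorical worker records bound to a codebook.

On-disk format is UTF-8 comma-separated text with a header row of
variable ids; cells hold 1-based integer category codes, with DK/NA
non-response stored as the sentinel code 0 (never as an empty cell, so
structural missingness is distinguishable from file corruption).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import DKNA_CODE, Codebook, CodebookError


class SurveyError(ValueError):
    """Raised on malformed survey data."""


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, as in the published report tables.

    numpy/python banker's rounding maps 0.5 ties to even; survey reports
    use the conventional half-up rule (e.g. 2.5 -> 3 on a 1..5 scale).
    """
    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(float(x))).quantize(
            q, rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass
class SurveyTable:
    """n categorical records over the variables of a codebook.

    ``data`` is an integer DataFrame with one column per codebook
    variable; row order is stable and meaningful (fold assignment,
    provenance).
    """

    codebook: Codebook
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [v for v in self.codebook.ids if v not in self.data.columns]
        if missing:
            raise SurveyError(f"missing column(s): {missing}")
        self.data = self.data[self.codebook.ids].astype(np.int64)
        self._validate()

    def _validate(self) -> None:
        # Raw tables may carry the DK/NA sentinel 0 on any variable
        # (non-response exists in the field even where the codebook does
        # not model it as a category); out-of-range positive codes are
        # always rejected. Whether DK/NA is *modelled* is decided by the
        # codebook at estimation time.
        for var in self.codebook:
            col = self.data[var.id].to_numpy()
            bad = (col < 0) | (col > var.n_categories)
            if bad.any():
                row = int(np.argmax(bad))
                raise SurveyError(
                    f"invalid code {col[row]} for {var.id} at row {row}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def column(self, var_id: str) -> np.ndarray:
        if var_id not in self.codebook:
            raise CodebookError(f"unknown variable {var_id!r}")
        return self.data[var_id].to_numpy()

    def equals(self, other: "SurveyTable") -> bool:
        return self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True)
        )


def read_survey(source, codebook: Codebook) -> SurveyTable:
    """Read a delimited survey file into a :class:`SurveyTable`.

    Cells may hold integer category codes or category labels (including
    the literal ``DK/NA``); every value is validated against the
    codebook and rejected with row/column coordinates otherwise.
    """
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [v for v in codebook.ids if v not in raw.columns]
    if missing:
        raise SurveyError(f"missing column(s): {missing}")
    out = {}
    for var in codebook:
        cells = raw[var.id]
        codes = np.empty(len(cells), dtype=np.int64)
        for i, cell in enumerate(cells):
            text = cell.strip()
            try:
                code = int(text)
            except ValueError:
                try:
                    code = var.code_of(text)
                except CodebookError:
                    raise SurveyError(
                        f"invalid value {text!r} for {var.id} at row {i}"
                    ) from None
            if not (0 <= code <= var.n_categories):
                raise SurveyError(
                    f"invalid code {code} for {var.id} at row {i}"
                )
            codes[i] = code
        out[var.id] = codes
    return SurveyTable(codebook, pd.DataFrame(out))


def write_survey(table: SurveyTable, path) -> None:
    """Write a survey table as comma-separated integer codes."""
    table.data.to_csv(path, index=False)


def filter_target_nonresponse(table: SurveyTable, target: str) -> SurveyTable:
    """Drop records whose *target* value is the DK/NA non-response code.

    Only the target column is inspected; all other variables are left
    untouched. Applying the filter twice is a no-op.
    """
    col = table.column(target)
    keep = col != DKNA_CODE
    return SurveyTable(table.codebook, table.data.loc[keep].reset_index(drop=True))


def category_counts(table: SurveyTable, var_id: str) -> pd.Series:
    """Per-category counts for one variable, DK/NA included; sums to n."""
    var = table.codebook[var_id]
    col = table.column(var_id)
    with_dkna = var.dkna or bool((col == DKNA_CODE).any())
    labels = list(var.categories) + (["DK/NA"] if with_dkna else [])
    codes = list(range(1, var.n_categories + 1)) + (
        [DKNA_CODE] if with_dkna else []
    )
    counts = [int((col == c).sum()) for c in codes]
    return pd.Series(counts, index=labels, name=var_id)


def sector_percentage_table(table: SurveyTable, sector: str = "V2") -> pd.DataFrame:
    """Counts and percentages of workers by sector of activity.

    Percentages are ``100*count/n`` rounded half-up to one decimal,
    matching the published survey-composition table.
    """
    if table.n == 0:
        raise SurveyError("percentages undefined for an empty table")
    counts = category_counts(table, sector)
    pct = [round_half_up(100.0 * c / table.n, 1) for c in counts]
    return pd.DataFrame({"count": counts, "percent": pct})


def incidence_index(
    accidents_with_sick_leave: int, average_workers_exposed: float
) -> float:
    """Accident incidence index: accidents with sick leave per 10^5
    average exposed workers."""
    if accidents_with_sick_leave < 0:
        raise ValueError("accident count must be non-negative")
    if average_workers_exposed <= 0:
        raise ValueError("average exposed workers must be positive")
    return accidents_with_sick_leave / average_workers_exposed * 1e5
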