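"""Benchmark datasets and CSV I/O.

Two classic outlier benchmarks ship with the package:

``telephone``
    Yearly number of international phone calls from Belgium, 1950-1973
    (tens of millions).  The 1964-1969 block was recorded in a different
    unit (total minutes instead of number of calls), with 1963 and 1970
    partially affected — a contiguous run of gross y-outliers.

``china``
    Nine annual average price growth rates in China, 1940-1948 (percent).
    Hyperinflation makes the last two responses (15.50, 364.00) gross
    outliers.

Years are coded as two-digit numbers (50…73, 40…48) by default, matching
how the benchmark regressions are usually reported; pass
``full_years=True`` for calendar years.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import RegressionData

__all__ = ["Fixture", "load_fixture", "read_csv", "write_csv", "FIXTURE_NAMES"]

_TELEPHONE_Y = (
    0.44, 0.47, 0.47, 0.59, 0.66, 0.73, 0.81, 0.88, 1.06, 1.2, 1.35, 1.49,
    1.61, 2.12, 11.9, 12.4, 14.2, 15.9, 18.2, 21.2, 4.3, 2.4, 2.7, 2.9,
)
_CHINA_Y = (1.62, 1.63, 1.90, 2.64, 2.05, 2.13, 1.94, 15.50, 364.00)

FIXTURE_NAMES = ("telephone", "china")


class FixtureNotFoundError(KeyError):
    pass


@dataclass
class Fixture:
    name: str
    data: RegressionData
    known_outlier_indices: np.ndarray
    citation: str


def load_fixture(name: str, full_years: bool = False) -> Fixture:
    """Load a packaged benchmark dataset by name ("telephone" or "china")."""
    if name == "telephone":
        years = np.arange(1950, 1974, dtype=float)
        y = np.array(_TELEPHONE_Y)
        outliers = np.arange(13, 21)  # 1963-1970, the corrupted block
        cite = ("Belgium international phone calls 1950-1973 "
                "(Belgian Statistical Survey), tens of millions")
    elif name == "china":
        years = np.arange(1940, 1949, dtype=float)
        y = np.array(_CHINA_Y)
        outliers = np.array([7, 8])
        cite = "Annual average price growth rate in China 1940-1948, percent"
    else:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    x = years if full_years else years - 1900
    return Fixture(
        name=name,
        data=RegressionData(x=x, y=y, label=name),
        known_outlier_indices=outliers,
        citation=cite,
    )


def read_csv(path) -> RegressionData:
    """Read a two-column (x, y) CSV into RegressionData.

    The file must have a header with numeric columns named ``x`` and
    ``y``; any missing or non-numeric cell raises a ValueError naming the
    offending row.
    """
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"at row {int(bad[0]) + 2} (1-based, counting the header)"
            )
        df[col] = vals
    return RegressionData(df["x"].to_numpy(), df["y"].to_numpy(), label=str(path))


def write_csv(data: RegressionData, path) -> None:
    """Write RegressionData as an x,y CSV at full precision.

    Uses the shortest-round-trip float representation, so write→read
    preserves every value bit for bit.
    """
    pd.DataFrame({"x": data.x, "y": data.y}).to_csv(path, index=False)
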