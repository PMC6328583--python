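"""Gene-expression time-course trends in cultured myocardium.

Expression change is measured as the log2 ratio of transcript counts in
cultured vs uncultured tissue of the same patient, sampled at culture days
8, 14, 24 and 35.  Each gene's time course is summarised by ordinary least
squares: the intercept extrapolates the expression change to day 0 (the
early transcriptional response), and slope x 35 gives the cumulative trend
over a 35-day culture (long-term alteration).  Reference tables of both
summaries for curated marker genes ship with the package.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CULTURE_DAYS = (8.0, 14.0, 24.0, 35.0)
TREND_SPAN_DAYS = 35.0
#: |slope x 35| at or above one doubling over the span counts as a trend
TREND_THRESHOLD = 1.0
PSEUDOCOUNT = 0.5

DAY_COLUMNS = {8.0: "d8", 14.0: "d14", 24.0: "d24", 35.0: "d35"}


def log2_ratio(count_cultured: float, count_fresh: float,
               pseudocount: float = PSEUDOCOUNT) -> float:
    """log2(cultured) - log2(fresh); zero counts get a pseudocount."""
    if count_cultured < 0 or count_fresh < 0:
        raise ValueError("counts must be non-negative")
    c = count_cultured if count_cultured > 0 else pseudocount
    f = count_fresh if count_fresh > 0 else pseudocount
    return math.log2(c) - math.log2(f)


def ols_trend(days, log2_ratios) -> tuple[float, float, float]:
    """(intercept, slope per day, slope x 35) by ordinary least squares."""
    x = np.asarray(days, dtype=float)
    y = np.asarray(log2_ratios, dtype=float)
    if x.shape != y.shape:
        raise ValueError("days and ratios must have matching lengths")
    if np.unique(x).size < 2:
        raise ValueError("slope undefined: need >= 2 distinct days")
    coeffs, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), y, rcond=None)
    intercept, slope = float(coeffs[0]), float(coeffs[1])
    return intercept, slope, slope * TREND_SPAN_DAYS


@dataclass
class GeneTimecourse:
    """Per-gene log2 expression ratios over culture days with trend summary."""

    gene: str
    ratios: dict          #: day -> log2 ratio
    protein: str = ""
    intercept: float | None = None
    slope_x35: float | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.ratios):
            raise ValueError("culture days must be strictly positive")
        if len(set(self.ratios)) < 2:
            raise ValueError("need >= 2 distinct culture days")

    def fit(self) -> "GeneTimecourse":
        days = sorted(self.ratios)
        intercept, _, slope_x35 = ols_trend(days, [self.ratios[d] for d in days])
        self.intercept = intercept
        self.slope_x35 = slope_x35
        return self


def classify_trend(slope_x35: float, threshold: float = TREND_THRESHOLD) -> str:
    if slope_x35 >= threshold:
        return "positive"
    if slope_x35 <= -threshold:
        return "negative"
    return "flat"


def trend_table(table: pd.DataFrame, days=CULTURE_DAYS,
                threshold: float = TREND_THRESHOLD) -> pd.DataFrame:
    """Fit the linear trend for every gene row and classify it.

    `table` needs a ``gene`` column plus one ratio column per culture day
    (``d8``/``d14``/``d24``/``d35`` by default).  Returns the table with
    recomputed ``intercept``, ``slope_x35`` and ``trend`` columns, sorted by
    slope_x35 (descending).
    """
    cols = [DAY_COLUMNS.get(d, f"d{d:g}") for d in days]
    if table.empty:
        return table.assign(intercept=pd.Series(dtype=float),
                            slope_x35=pd.Series(dtype=float),
                            trend=pd.Series(dtype=str))
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks ratio columns: {missing}")
    out = table.copy()
    fits = [ols_trend(days, row) for row in out[cols].to_numpy(dtype=float)]
    out["intercept"] = [f[0] for f in fits]
    out["slope_x35"] = [f[2] for f in fits]
    out["trend"] = [classify_trend(s, threshold) for s in out["slope_x35"]]
    return out.sort_values("slope_x35", ascending=False, ignore_index=True)


def load_reference_table(which: int = 1) -> pd.DataFrame:
    """Shipped reference tables of marker-gene time courses (1 or 2).

    Table 1 covers cardiomyocyte differentiation / pathology markers,
    table 2 remodelling markers (growth factors, matrix, hypoxia, extreme
    trends).  Columns: function, protein, gene, d8, d14, d24, d35, plus the
    printed intercept and slope_x35 for cross-checking.
    """
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    ref = importlib.resources.files("myoslice.data") / f"table{which}.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4g")
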