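"""Survey-weighted frequency tables and chi-square contrasts.

Cross-tabulates a covariate against current-use status, accumulating
sampling weights per cell, and contrasts users vs non-users with a Pearson
chi-square computed on the weighted table rescaled to the unweighted sample
size.  The rescaling is a first-order weight adjustment: percentages are
weighted, but no design-effect (Rao-Scott) correction is applied, so the
statistic is descriptive rather than design-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from types import SimpleNamespace

import numpy as np
from scipy import stats

from .records import CODEBOOK
from . import table1

COL_LABELS = ("current_user", "non_user")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (display convention of the survey tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class WeightedTable:
    """A covariate x use-status table with unweighted and weighted counts.

    ``col_pct`` holds full-precision weighted column percentages; use
    :meth:`display_pct` for the printed (half-up, one-decimal) convention.
    """

    covariate: str
    row_labels: list[str]
    col_labels: tuple[str, str]
    unweighted_n: np.ndarray
    weighted_N: np.ndarray
    col_pct: np.ndarray

    def display_pct(self) -> np.ndarray:
        return np.vectorize(round_half_up)(self.col_pct)

    def to_frame(self):
        import pandas as pd

        data = {}
        for j, col in enumerate(self.col_labels):
            data[f"{col}_n"] = self.unweighted_n[:, j]
            data[f"{col}_N"] = self.weighted_N[:, j]
            data[f"{col}_pct"] = self.display_pct()[:, j]
        return pd.DataFrame(data, index=pd.Index(self.row_labels, name=self.covariate))


def weighted_crosstab(students, covariate: str, outcome: str = "outcome") -> WeightedTable:
    """Survey-weighted covariate x current-use cross-tabulation.

    Parameters
    ----------
    students : sequence
        Records exposing ``samp_weight``, the covariate attribute, and the
        binary outcome attribute (1 = current user).
    covariate, outcome : str
        Attribute names on the records.

    Column percentages are 100 * weighted_N / weighted column total.
    """
    if not students:
        raise ValueError("no records")
    if not hasattr(students[0], covariate):
        raise ValueError(f"unknown covariate {covariate!r}")
    if not hasattr(students[0], outcome):
        raise ValueError(f"unknown outcome {outcome!r}")

    if covariate in CODEBOOK:
        row_labels = list(CODEBOOK[covariate])
    else:
        row_labels = list(dict.fromkeys(getattr(s, covariate) for s in students))
    row_index = {lab: i for i, lab in enumerate(row_labels)}

    R = len(row_labels)
    unweighted = np.zeros((R, 2), dtype=int)
    weighted = np.zeros((R, 2), dtype=float)
    for s in students:
        cat = getattr(s, covariate)
        y = getattr(s, outcome)
        if cat is None or y is None:
            raise ValueError(
                f"missing {covariate!r}/{outcome!r} on record; filter first"
            )
        if cat not in row_index:
            raise ValueError(f"unknown category {cat!r} for {covariate!r}")
        w = float(s.samp_weight)
        if not w > 0:
            raise ValueError(f"non-positive weight {w!r}")
        j = 0 if int(y) == 1 else 1
        unweighted[row_index[cat], j] += 1
        weighted[row_index[cat], j] += w

    # drop categories absent from the data (printed tables never show them)
    present = unweighted.sum(axis=1) > 0
    row_labels = [lab for lab, keep in zip(row_labels, present) if keep]
    unweighted = unweighted[present]
    weighted = weighted[present]

    # a column with no records (e.g. a user-free stratum) gets NaN
    # percentages; downstream tests like the chi-square reject such tables
    col_tot = weighted.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_pct = np.where(col_tot > 0, 100.0 * weighted / np.where(col_tot > 0, col_tot, 1.0), np.nan)

    return WeightedTable(
        covariate=covariate,
        row_labels=row_labels,
        col_labels=COL_LABELS,
        unweighted_n=unweighted,
        weighted_N=weighted,
        col_pct=col_pct,
    )


def weighted_chisq(table: WeightedTable) -> tuple[float, int, float]:
    """Pearson chi-square on the weighted table rescaled to unweighted n.

    The weighted counts are rescaled so their grand total equals the total
    unweighted sample size (making the statistic invariant to uniform weight
    rescaling), then the ordinary Pearson X^2 with (R-1)(C-1) degrees of
    freedom is computed.  Returns (statistic, df, p).
    """
    n_total = int(table.unweighted_n.sum())
    grand_w = float(table.weighted_N.sum())
    if grand_w <= 0 or n_total <= 0:
        raise ValueError("empty table")
    counts = table.weighted_N * (n_total / grand_w)

    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    if np.any(row_m == 0) or np.any(col_m == 0):
        raise ValueError("zero marginal in rescaled table")
    expected = np.outer(row_m, col_m) / counts.sum()
    if np.any(expected <= 0):
        raise ValueError("non-positive expected count")
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def printed_pseudo_records(outcome: str, covariate: str) -> list[SimpleNamespace]:
    """Expand the published table's printed cells into weighted pseudo-records.

    Each printed cell (unweighted n, weighted N) becomes n records of weight
    N / n, so a cross-tabulation of the pseudo-records reproduces both the
    printed unweighted and weighted counts.  Used to recompute the printed
    column percentages from the printed weighted counts alone.
    """
    recs: list[SimpleNamespace] = []
    for cell in table1.cells_for(outcome, covariate):
        y = 1 if cell.column == "current_user" else 0
        w = cell.N / cell.n
        recs.extend(
            SimpleNamespace(samp_weight=w, outcome=y, **{covariate: cell.category})
            for _ in range(cell.n)
        )
    return recs


def reproduce_printed_table(outcome: str, covariate: str) -> tuple[WeightedTable, list]:
    """Recompute one printed covariate block and compare with the printed %.

    Returns the recomputed table and a list of
    (category, column, printed_pct, recomputed_pct, consistent_flag)
    comparison rows.  Cells flagged inconsistent in the source data are
    reported but expected to differ.
    """
    recs = printed_pseudo_records(outcome, covariate)
    tab = weighted_crosstab(recs, covariate)
    disp = tab.display_pct()
    comparisons = []
    for cell in table1.cells_for(outcome, covariate):
        i = tab.row_labels.index(cell.category)
        j = 0 if cell.column == "current_user" else 1
        comparisons.append(
            (cell.category, cell.column, cell.pct, float(disp[i, j]), cell.consistent)
        )
    return tab, comparisons
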