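"""Published county-wide descriptive table: weighted counts and percentages.

The source study prints, for current users and non-current-users of
cigarettes and of e-cigarettes, the unweighted sample size n, the weighted
sample size N, and the weighted column percentage of every covariate
category.  Those printed numbers are data for two purposes here:

* ``printed_cells`` feeds the survey-descriptives machinery so the printed
  column percentages can be recomputed from the printed weighted counts
  (each cell expands to one pseudo-record whose weight is the printed N);
* ``table1_marginals`` turns the e-cigarette non-current-user column into
  the default covariate category frequencies of the synthetic-county
  generator, so simulated populations resemble the surveyed one.

A handful of printed cells do not self-validate (recomputing the percentage
from the printed weighted counts does not reproduce the printed value at
one-decimal half-up rounding); those carry ``consistent=False`` and are
excluded from exact-reproduction checks.  The known cases are the cigarette
non-user TRO rows, whose two percentages are evidently swapped relative to
their weighted counts; the cigarette current-user family-standard-of-living
column, whose N values disagree with two of its three percentages; and four
cells that miss by exactly 0.1 (the printed N's are themselves rounded).
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import CODEBOOK

OUTCOMES = ("cigarette", "ecigarette")
COLUMNS = ("current_user", "non_user")


@dataclass(frozen=True)
class PrintedCell:
    """One printed table cell: unweighted n, weighted N, printed column %."""

    outcome: str
    covariate: str
    category: str
    column: str
    n: int
    N: float
    pct: float
    consistent: bool = True


def _rows(outcome, covariate, cats, cur, non, bad_cur=(), bad_non=()):
    out = []
    for idx, cat in enumerate(cats):
        n_c, N_c, p_c = cur[idx]
        n_n, N_n, p_n = non[idx]
        out.append(
            PrintedCell(outcome, covariate, cat, "current_user", n_c, N_c, p_c,
                        consistent=idx not in bad_cur)
        )
        out.append(
            PrintedCell(outcome, covariate, cat, "non_user", n_n, N_n, p_n,
                        consistent=idx not in bad_non)
        )
    return out


def printed_cells() -> list[PrintedCell]:
    """All printed cells of the published descriptive table."""
    cells: list[PrintedCell] = []
    # --- cigarettes: current n=80 (N=14249), non-current n=3661 (N=418014)
    cells += _rows("cigarette", "sex", ("boys", "girls"),
                   [(41, 7159, 50.2), (39, 7092, 49.8)],
                   [(1609, 216363, 51.8), (2052, 201651, 48.2)])
    cells += _rows("cigarette", "race3", ("black", "hispanic", "white_other"),
                   [(11, 2384, 16.7), (43, 9179, 64.4), (26, 2685, 18.9)],
                   [(604, 76273, 18.2), (1319, 216850, 51.9), (1738, 124891, 29.9)],
                   bad_cur=(2,))
    cells += _rows("cigarette", "grade", ("6th", "8th", "10th"),
                   [(6, 1208, 8.5), (17, 3932, 27.6), (57, 9109, 63.9)],
                   [(1099, 139692, 33.4), (1217, 140863, 33.7), (1345, 137458, 32.9)])
    # non-user TRO percentages are swapped relative to their weighted counts
    cells += _rows("cigarette", "tro", ("1+", "0"),
                   [(57, 12772, 89.6), (23, 1477, 10.4)],
                   [(1831, 105860, 74.7), (1830, 312154, 25.3)],
                   bad_non=(0, 1))
    # current-user column percentages disagree with the printed N's
    cells += _rows("cigarette", "family_sol",
                   ("living_comfortably", "very_well_off", "just_getting_by_poor"),
                   [(8, 805, 5.7), (44, 7865, 55.2), (28, 5579, 39.1)],
                   [(849, 86801, 20.8), (2280, 260783, 62.4), (532, 70431, 16.8)],
                   bad_cur=(0, 2))
    cells += _rows("cigarette", "visited_stores", ("yes", "no"),
                   [(76, 14006, 98.3), (4, 243, 1.7)],
                   [(3600, 412445, 98.7), (61, 5569, 1.3)])
    cells += _rows("cigarette", "recall_warning", ("yes", "no"),
                   [(37, 6449, 45.3), (43, 7800, 54.7)],
                   [(2093, 237640, 56.8), (1568, 180373, 43.2)])
    cells += _rows("cigarette", "recall_marketing", ("yes", "no"),
                   [(65, 11962, 83.9), (15, 2287, 16.1)],
                   [(3146, 345128, 82.6), (515, 72886, 17.4)])
    # --- e-cigarettes: current n=245 (N=31126), non-current n=3499 (N=401293)
    cells += _rows("ecigarette", "sex", ("boys", "girls"),
                   [(134, 17018, 54.7), (111, 14108, 45.3)],
                   [(1516, 206610, 51.5), (1983, 194683, 48.5)])
    cells += _rows("ecigarette", "race3", ("black", "hispanic", "white_other"),
                   [(46, 4855, 15.6), (113, 18983, 61.0), (86, 7288, 23.4)],
                   [(567, 73366, 18.3), (1256, 207737, 51.8), (1676, 120190, 29.9)],
                   bad_non=(2,))
    cells += _rows("ecigarette", "grade", ("6th", "8th", "10th"),
                   [(15, 2938, 9.4), (54, 8612, 27.7), (176, 19575, 62.9)],
                   [(1093, 138061, 34.4), (1180, 136348, 33.9), (1226, 126883, 31.7)],
                   bad_non=(1, 2))
    cells += _rows("ecigarette", "tro", ("1+", "0"),
                   [(148, 25023, 80.4), (97, 6103, 19.6)],
                   [(1740, 299922, 74.7), (1759, 101370, 25.3)])
    cells += _rows("ecigarette", "family_sol",
                   ("living_comfortably", "very_well_off", "just_getting_by_poor"),
                   [(45, 5228, 16.8), (140, 17391, 55.9), (60, 8506, 27.3)],
                   [(813, 82732, 20.6), (2182, 250778, 62.5), (504, 67783, 16.9)])
    cells += _rows("ecigarette", "visited_stores", ("yes", "no"),
                   [(238, 30498, 98.0), (7, 628, 2.0)],
                   [(3442, 396147, 98.7), (57, 5146, 1.3)])
    cells += _rows("ecigarette", "recall_warning", ("yes", "no"),
                   [(136, 16056, 51.6), (109, 15069, 48.4)],
                   [(2001, 228706, 57.0), (1498, 172587, 43.0)])
    cells += _rows("ecigarette", "recall_marketing", ("yes", "no"),
                   [(156, 20878, 67.1), (89, 10248, 32.9)],
                   [(1742, 200482, 50.0), (1757, 200811, 50.0)])
    return cells


def covariates(outcome: str = "cigarette") -> list[str]:
    """Covariate row-blocks of the printed table, in printed order."""
    seen: list[str] = []
    for c in printed_cells():
        if c.outcome == outcome and c.covariate not in seen:
            seen.append(c.covariate)
    return seen


def cells_for(outcome: str, covariate: str) -> list[PrintedCell]:
    return [
        c for c in printed_cells()
        if c.outcome == outcome and c.covariate == covariate
    ]


def table1_marginals() -> dict[str, dict[str, float]]:
    """Default covariate category probabilities for the synthetic county.

    Taken from the e-cigarette non-current-user weighted column percentages
    (the largest printed column), renormalised to sum to exactly 1 per
    covariate.  Categories follow the fixed codebook.
    """
    raw = {
        "sex": {"boys": 51.5, "girls": 48.5},
        "race3": {"black": 18.3, "hispanic": 51.8, "white_other": 29.9},
        "grade": {"6th": 34.4, "8th": 33.9, "10th": 31.7},
        "family_sol": {
            "living_comfortably": 20.6,
            "very_well_off": 62.5,
            "just_getting_by_poor": 16.9,
        },
        "visited_stores": {"yes": 98.7, "no": 1.3},
        "recall_marketing": {"yes": 50.0, "no": 50.0},
        "recall_warning": {"yes": 57.0, "no": 43.0},
    }
    out: dict[str, dict[str, float]] = {}
    for cov, cats in raw.items():
        assert set(cats) == set(CODEBOOK[cov])
        total = sum(cats.values())
        out[cov] = {k: v / total for k, v in cats.items()}
    return out
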