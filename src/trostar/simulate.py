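"""Seeded synthetic county generator with known ground truth.

Emulates a county-scale school-based tobacco survey: ~20-32 schools at
planar locations, ~75% of them with at least one tobacco retail outlet
(TRO) nearby, student covariates drawn from the published non-user
marginals, and binary current-use outcomes drawn from the geoadditive
logistic model

    logit P(y_ij = 1) = alpha + beta' x_i + gamma' z_j + TRO_j * f(j)

with f a smooth latent field drawn from the intrinsic-CAR prior on the
Delaunay graph of the school locations.  Because alpha, beta, gamma and f
are recorded, every downstream stage can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .graph import SpatialGraph, build_graph
from .records import CODEBOOK, SchoolRecord, StudentRecord, ZIP_COVARIATES
from .table1 import table1_marginals

#: dummy-expanded covariate columns, in codebook order, reference levels omitted
DUMMY_COLUMNS: tuple[str, ...] = tuple(
    f"{cov}_{cat}"
    for cov, cats in CODEBOOK.items()
    for cat in cats[1:]
)

#: plausible coefficients for a low-prevalence youth tobacco outcome:
#: strong grade gradient, elevated use with lower family standard of living
#: and marketing recall, modest sex/ethnicity contrasts
DEFAULT_TRUE_BETA: dict[str, float] = {
    "sex_boys": 0.1,
    "race3_hispanic": 0.3,
    "race3_white_other": 0.2,
    "grade_8th": 0.6,
    "grade_10th": 1.1,
    "family_sol_very_well_off": -0.1,
    "family_sol_just_getting_by_poor": 0.5,
    "visited_stores_yes": 0.3,
    "recall_marketing_yes": 0.4,
    "recall_warning_yes": 0.0,
}

#: zip-code covariate means/sds: high-school-graduate %, median household
#: income (USD), poverty % — urban-Texas-like values
DEFAULT_ZIP_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "zip_hs_grad_pct": (80.0, 8.0),
    "zip_med_income": (55000.0, 12000.0),
    "zip_poverty_pct": (18.0, 6.0),
}


@dataclass
class SimulationConfig:
    """Ground-truth parameters and sampling knobs for one synthetic county."""

    n_schools: int = 24
    n_students_per_school: tuple[int, int] = (80, 200)
    frac_tro_schools: float = 0.75
    true_alpha: float = -3.0
    true_beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETA)
    )
    true_gamma: tuple[float, float, float] = (0.2, -0.2, 0.1)
    tau2_true: float = 1.0
    domain_extent_km: float = 50.0
    seed: int = 0
    marginals: dict[str, dict[str, float]] = field(default_factory=table1_marginals)
    zip_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ZIP_DISTRIBUTIONS)
    )
    graph_method: str = "delaunay"
    knn_k: int = 4
    school_selection_prob: float = 1.0
    student_weight_factor: float = 1.0
    miss_rate_family_sol: float = 0.0
    miss_rate_outcome: float = 0.0
    county: Optional[str] = None

    def validate(self) -> None:
        if self.n_schools < 4:
            raise ValueError(
                "n_schools must be >= 4 (Delaunay triangulation degenerate below)"
            )
        if not 0.0 <= self.frac_tro_schools <= 1.0:
            raise ValueError("frac_tro_schools must lie in [0, 1]")
        if round(self.frac_tro_schools * self.n_schools) < 1:
            raise ValueError(
                "frac_tro_schools yields zero TRO schools; "
                "the spatial effect would be unidentified"
            )
        if self.tau2_true <= 0:
            raise ValueError("tau2_true must be positive")
        if self.domain_extent_km <= 0:
            raise ValueError("domain_extent_km must be positive")
        lo, hi = self.n_students_per_school
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_students_per_school range")
        if not 0 < self.school_selection_prob <= 1:
            raise ValueError("school_selection_prob must lie in (0, 1]")
        unknown = set(self.true_beta) - set(DUMMY_COLUMNS)
        if unknown:
            raise ValueError(f"unknown true_beta entries: {sorted(unknown)}")
        for cov, cats in self.marginals.items():
            if abs(sum(cats.values()) - 1.0) > 1e-9:
                raise ValueError(f"marginals for {cov!r} do not sum to 1")


@dataclass
class GroundTruth:
    """The generative parameters a recovery test compares against."""

    true_alpha: float
    true_beta: dict[str, float]
    true_gamma: tuple[float, float, float]
    tau2_true: float
    f_true: np.ndarray  # per school, sum-zero
    school_ids: list[str]

    def as_dict(self) -> dict:
        return {
            "true_alpha": self.true_alpha,
            "true_beta": dict(self.true_beta),
            "true_gamma": list(self.true_gamma),
            "tau2_true": self.tau2_true,
            "f_true": self.f_true.tolist(),
            "school_ids": list(self.school_ids),
        }


@dataclass
class SyntheticCounty:
    schools: list[SchoolRecord]
    students: list[StudentRecord]
    truth: GroundTruth
    graph: SpatialGraph
    missing_log: dict[str, list[str]]
    config: SimulationConfig

    def write(self, outdir) -> dict:
        """Write students.csv / schools.csv / truth.json / schools.geojson."""
        from . import io

        return io.write_county(self, outdir)


def draw_icar_field(graph: SpatialGraph, tau2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic-CAR prior restricted to its proper subspace.

    The ICAR precision Q/tau2 is rank n-1; the draw is taken in the
    eigenspace of Q with the null (constant) eigenvector removed, giving the
    unique sum-to-zero Gaussian with covariance tau2 * pinv(Q).
    """
    evals, evecs = np.linalg.eigh(graph.Q)
    keep = evals > 1e-10 * max(float(evals.max()), 1.0)
    z = rng.standard_normal(int(keep.sum()))
    f = evecs[:, keep] @ (z / np.sqrt(evals[keep])) * np.sqrt(tau2)
    return f - f.mean()


def simulate_county(cfg: SimulationConfig) -> SyntheticCounty:
    """Generate one synthetic county from the geoadditive logistic model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_schools
    xy = rng.uniform(0.0, cfg.domain_extent_km, size=(n, 2))
    school_ids = [f"S{i:03d}" for i in range(n)]

    n_tro = int(round(cfg.frac_tro_schools * n))
    tro = np.zeros(n, dtype=int)
    tro[rng.choice(n, size=n_tro, replace=False)] = 1

    zmat = np.column_stack(
        [
            rng.normal(*cfg.zip_distributions[name], size=n)
            for name in ZIP_COVARIATES
        ]
    )

    lo, hi = cfg.n_students_per_school
    n_students = rng.integers(lo, hi + 1, size=n)

    class _Pt:
        def __init__(self, sid, x, y):
            self.school_id, self.x_km, self.y_km = sid, x, y

    graph = build_graph(
        [_Pt(s, *p) for s, p in zip(school_ids, xy)],
        method=cfg.graph_method,
        k=cfg.knn_k,
    )
    f_true = draw_icar_field(graph, cfg.tau2_true, rng)

    # gamma applies to within-county standardized zip covariates, matching
    # the design matrix the model builds
    z_std = (zmat - zmat.mean(axis=0)) / zmat.std(axis=0, ddof=0)
    gamma = np.asarray(cfg.true_gamma, dtype=float)
    eta_school = cfg.true_alpha + z_std @ gamma + tro * f_true

    beta = np.array([cfg.true_beta.get(c, 0.0) for c in DUMMY_COLUMNS])
    dummy_of = {c: i for i, c in enumerate(DUMMY_COLUMNS)}

    schools = [
        SchoolRecord(
            school_id=school_ids[j],
            x_km=float(xy[j, 0]),
            y_km=float(xy[j, 1]),
            tro=int(tro[j]),
            zip_hs_grad_pct=float(zmat[j, 0]),
            zip_med_income=float(zmat[j, 1]),
            zip_poverty_pct=float(zmat[j, 2]),
            n_students=int(n_students[j]),
        )
        for j in range(n)
    ]

    students: list[StudentRecord] = []
    samp_weight = cfg.student_weight_factor / cfg.school_selection_prob
    sid_counter = 0
    for j in range(n):
        for _ in range(int(n_students[j])):
            cats = {}
            x = np.zeros(len(DUMMY_COLUMNS))
            for cov, probs in cfg.marginals.items():
                labels = list(CODEBOOK[cov])
                p = np.array([probs[c] for c in labels])
                cat = labels[rng.choice(len(labels), p=p / p.sum())]
                cats[cov] = cat
                if cat != labels[0]:
                    x[dummy_of[f"{cov}_{cat}"]] = 1.0
            eta = eta_school[j] + float(x @ beta)
            y = int(rng.random() < expit(eta))
            students.append(
                StudentRecord(
                    student_id=f"T{sid_counter:05d}",
                    school_id=school_ids[j],
                    outcome=y,
                    samp_weight=samp_weight,
                    county=cfg.county,
                    **cats,
                )
            )
            sid_counter += 1

    missing_log: dict[str, list[str]] = {"family_sol": [], "outcome": []}
    for fname, rate in (
        ("family_sol", cfg.miss_rate_family_sol),
        ("outcome", cfg.miss_rate_outcome),
    ):
        if rate > 0:
            mask = rng.random(len(students)) < rate
            for s, m in zip(students, mask):
                if m:
                    setattr(s, fname, None)
                    missing_log[fname].append(s.student_id)

    truth = GroundTruth(
        true_alpha=cfg.true_alpha,
        true_beta={c: cfg.true_beta.get(c, 0.0) for c in DUMMY_COLUMNS},
        true_gamma=tuple(cfg.true_gamma),
        tau2_true=cfg.tau2_true,
        f_true=f_true,
        school_ids=school_ids,
    )
    return SyntheticCounty(
        schools=schools,
        students=students,
        truth=truth,
        graph=graph,
        missing_log=missing_log,
        config=replace(cfg),
    )
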