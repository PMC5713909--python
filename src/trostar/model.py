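"""Bayesian geoadditive logistic (STAR) model with a TRO-interacted ICAR field.

The linear predictor for student i in school j is

    logit P(y_ij = 1) = alpha + beta' x_i + gamma' z_j + TRO_j * f(j)

where x_i are dummy-expanded individual covariates, z_j standardized
zip-code socioeconomic covariates, TRO_j the tobacco-retail-outlet presence
indicator and f an intrinsic-CAR spatial field over the school graph.  The
spatial effect enters only through its interaction with TRO_j: at TRO-free
schools f is informed by the ICAR prior alone.

Estimation is Gibbs sampling with Pólya-Gamma augmentation.  Observation
weights (sampling weight times the reciprocal of the school's student
count, normalized to sum to the number of records) enter the Bernoulli
pseudo-likelihood as powers, i.e. as the PG shape parameter — a weighted
pseudo-likelihood, not design-based inference.  A random-walk Metropolis
fallback for the same posterior is available for sampler cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .graph import SpatialGraph
from .polya_gamma import pg_draw
from .records import CODEBOOK, ZIP_COVARIATES

logger = logging.getLogger(__name__)

ALL_COVARIATES: tuple[str, ...] = tuple(CODEBOOK)


@dataclass
class ModelConfig:
    """Priors, sampler settings, and weighting switches."""

    covariate_set: tuple[str, ...] = ALL_COVARIATES
    include_zip_covariates: bool = True
    prior_sd_fixed: float = 100.0
    tau2_prior: tuple[float, float] = (0.001, 0.001)
    n_iter: int = 2000
    n_burn: int = 500
    thin: int = 1
    seed: int = 0
    use_school_weighting: bool = True
    use_sampling_weights: bool = True
    sampler: str = "pg"  # or "rwm"
    pg_trunc: int = 50
    rwm_scale: float = 0.05

    def validate(self) -> None:
        if not self.n_iter > self.n_burn >= 0:
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_sd_fixed <= 0:
            raise ValueError("prior_sd_fixed must be positive")
        if any(a <= 0 for a in self.tau2_prior):
            raise ValueError("tau2_prior hyperparameters must be positive")
        unknown = set(self.covariate_set) - set(ALL_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        if self.sampler not in ("pg", "rwm"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class DesignBundle:
    """Model-ready arrays: one row per retained student record."""

    y: np.ndarray
    X: np.ndarray  # intercept + dummies + standardized zip covariates
    term_names: list[str]
    n_beta: int
    n_gamma: int
    tro: np.ndarray  # per record
    school_index: np.ndarray  # per record, into school_ids
    weights: np.ndarray  # normalized to sum to n records
    school_ids: list[str]

    @property
    def n_records(self) -> int:
        return self.y.shape[0]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for all model parameters."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    f: Optional[np.ndarray]  # (draws, n_schools), each row sum-zero
    tau2: Optional[np.ndarray]
    beta_names: list[str]
    gamma_names: list[str]
    school_ids: list[str]
    accept_info: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    def fixed_effect_draws(self) -> tuple[list[str], np.ndarray]:
        """All fixed-effect chains as (names, draws matrix)."""
        names = ["intercept"] + list(self.beta_names) + list(self.gamma_names)
        cols = [self.alpha[:, None]]
        if self.beta.shape[1]:
            cols.append(self.beta)
        if self.gamma.shape[1]:
            cols.append(self.gamma)
        return names, np.hstack(cols)


@dataclass
class FixedEffectSummary:
    """One Table-2-style row: adjusted odds ratio with 95% credible interval."""

    term: str
    aor: float
    cri_low: float
    cri_high: float
    significant: bool


def dummy_columns(covariate_set=ALL_COVARIATES) -> list[str]:
    """Dummy-expanded column names (reference level first in the codebook)."""
    return [
        f"{cov}_{cat}"
        for cov in covariate_set
        for cat in CODEBOOK[cov][1:]
    ]


def build_design(students, schools, cfg: ModelConfig) -> DesignBundle:
    """Assemble response, design matrix, TRO indicator and weights.

    Reference levels (all-zero dummy row): girls, Black, 6th grade, living
    comfortably, never-visited, no recall.  Zip covariates are standardized
    to mean 0, sd 1 within the county.  The record weight is
    samp_weight * (1 / n_j) under the default switches, where n_j is the
    number of retained records in school j, then normalized so the weights
    sum to the number of records.
    """
    cfg.validate()
    school_by_id = {s.school_id: s for s in schools}
    for s in schools:
        s.validate()
        if s.tro not in (0, 1):
            raise ValueError(f"school {s.school_id}: tro missing or invalid")

    school_ids = [s.school_id for s in schools]
    school_pos = {sid: i for i, sid in enumerate(school_ids)}

    n = len(students)
    if n == 0:
        raise ValueError("no student records")
    cols = dummy_columns(cfg.covariate_set)

    y = np.empty(n)
    Xd = np.zeros((n, len(cols)))
    col_pos = {c: i for i, c in enumerate(cols)}
    sch_idx = np.empty(n, dtype=int)
    w = np.ones(n)

    for r, s in enumerate(students):
        s.validate()
        if s.school_id not in school_pos:
            raise ValueError(f"student {s.student_id}: unknown school {s.school_id}")
        if s.outcome is None or s.family_sol is None:
            raise ValueError(
                f"student {s.student_id}: missing outcome/family_sol; "
                "apply exclusions before building the design"
            )
        y[r] = float(s.outcome)
        sch_idx[r] = school_pos[s.school_id]
        for cov in cfg.covariate_set:
            cat = getattr(s, cov)
            key = f"{cov}_{cat}"
            if key in col_pos:
                Xd[r, col_pos[key]] = 1.0
        if cfg.use_sampling_weights:
            w[r] = float(s.samp_weight)

    if cfg.use_school_weighting:
        counts = np.bincount(sch_idx, minlength=len(school_ids)).astype(float)
        w = w / counts[sch_idx]
    w *= n / w.sum()

    gamma_names: list[str] = []
    if cfg.include_zip_covariates:
        Z = np.array(
            [
                [getattr(school_by_id[sid], zc) for zc in ZIP_COVARIATES]
                for sid in school_ids
            ]
        )
        sd = Z.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("constant zip covariate; cannot standardize")
        Zs = (Z - Z.mean(axis=0)) / sd
        Zrec = Zs[sch_idx]
        gamma_names = list(ZIP_COVARIATES)
    else:
        Zrec = np.empty((n, 0))

    X = np.hstack([np.ones((n, 1)), Xd, Zrec])
    tro_vec = np.array([school_by_id[sid].tro for sid in school_ids])[sch_idx].astype(float)

    return DesignBundle(
        y=y,
        X=X,
        term_names=["intercept"] + cols + gamma_names,
        n_beta=len(cols),
        n_gamma=len(gamma_names),
        tro=tro_vec,
        school_index=sch_idx,
        weights=w,
        school_ids=school_ids,
    )


def _sample_mvn_from_precision(rng, precision, linear):
    """Draw N(P^{-1} m, P^{-1}) given precision P and linear term m."""
    L, low = cho_factor(precision, lower=True)
    mean = cho_solve((L, low), linear)
    z = rng.standard_normal(len(linear))
    return mean + solve_triangular(L, z, lower=True, trans="T")


def _weighted_loglik(y, w, eta):
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_star(design: DesignBundle, graph: Optional[SpatialGraph], cfg: ModelConfig) -> PosteriorDraws:
    """Sample the posterior of the geoadditive logistic model.

    If no record has TRO = 1 the spatial term is unidentified by the data and
    is dropped entirely (``draws.f`` is ``None``), with a warning; the fit is
    then an ordinary weighted Bayesian logistic regression.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    y, X, w = design.y, design.X, design.weights
    n, p = X.shape
    has_spatial = bool(np.any(design.tro == 1))
    if not has_spatial:
        warnings.warn(
            "no TRO-exposed records: spatial term dropped (unidentified)",
            stacklevel=2,
        )
    if has_spatial:
        if graph is None:
            raise ValueError("TRO-exposed records present but no graph supplied")
        if list(graph.node_ids) != list(design.school_ids):
            raise ValueError("graph node order does not match design school order")

    n_sch = len(design.school_ids)
    a0, b0 = cfg.tau2_prior
    prior_prec = np.eye(p) / cfg.prior_sd_fixed**2

    theta = np.zeros(p)
    pbar = np.clip(np.average(y, weights=w), 1e-3, 1 - 1e-3)
    theta[0] = np.log(pbar / (1 - pbar))
    f = np.zeros(n_sch)
    tau2 = 1.0

    sch = design.school_index
    tro_rec = design.tro
    exposed = tro_rec == 1

    n_keep = (cfg.n_iter - cfg.n_burn) // cfg.thin
    alpha_d = np.empty(n_keep)
    beta_d = np.empty((n_keep, design.n_beta))
    gamma_d = np.empty((n_keep, design.n_gamma))
    f_d = np.empty((n_keep, n_sch)) if has_spatial else None
    tau2_d = np.empty(n_keep) if has_spatial else None

    use_pg = cfg.sampler == "pg"
    n_accept = 0
    kappa = w * (y - 0.5)

    for it in range(cfg.n_iter):
        f_rec = tro_rec * f[sch] if has_spatial else 0.0
        eta = X @ theta + f_rec

        if use_pg:
            omega = pg_draw(rng, w, eta, trunc=cfg.pg_trunc)
            # (alpha, beta, gamma) | omega, f
            P = X.T @ (X * omega[:, None]) + prior_prec
            r = X.T @ (kappa - omega * f_rec)
            theta = _sample_mvn_from_precision(rng, P, r)
            if has_spatial:
                # f | omega, theta: GMRF with data terms from exposed records
                resid = kappa - omega * (X @ theta)
                prec_add = np.bincount(
                    sch[exposed], weights=omega[exposed], minlength=n_sch
                )
                lin = np.bincount(
                    sch[exposed], weights=resid[exposed], minlength=n_sch
                )
                Pf = graph.Q / tau2 + np.diag(prec_add)
                f = _sample_mvn_from_precision(rng, Pf, lin)
        else:
            # random-walk Metropolis fallback on theta (and f), same posterior
            cur_lp = _weighted_loglik(y, w, eta) - 0.5 * float(
                theta @ prior_prec @ theta
            )
            prop = theta + cfg.rwm_scale * rng.standard_normal(p)
            eta_p = X @ prop + (tro_rec * f[sch] if has_spatial else 0.0)
            prop_lp = _weighted_loglik(y, w, eta_p) - 0.5 * float(
                prop @ prior_prec @ prop
            )
            if np.log(rng.random()) < prop_lp - cur_lp:
                theta = prop
                n_accept += 1
            if has_spatial:
                cur_eta = X @ theta + tro_rec * f[sch]
                cur_lp = _weighted_loglik(y, w, cur_eta) - graph.quadratic_form(f) / (
                    2 * tau2
                )
                f_prop = f + cfg.rwm_scale * rng.standard_normal(n_sch)
                prop_eta = X @ theta + tro_rec * f_prop[sch]
                prop_lp = _weighted_loglik(y, w, prop_eta) - graph.quadratic_form(
                    f_prop
                ) / (2 * tau2)
                if np.log(rng.random()) < prop_lp - cur_lp:
                    f = f_prop

        if has_spatial:
            # sum-to-zero re-centring; the intercept absorbs the shift so the
            # linear predictor of TRO-exposed records is unchanged
            shift = f.mean()
            f = f - shift
            theta[0] += shift
            tau2 = 1.0 / rng.gamma(
                a0 + 0.5 * (n_sch - 1),
                1.0 / (b0 + 0.5 * graph.quadratic_form(f)),
            )

        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            k = (it - cfg.n_burn) // cfg.thin
            alpha_d[k] = theta[0]
            beta_d[k] = theta[1 : 1 + design.n_beta]
            gamma_d[k] = theta[1 + design.n_beta :]
            if has_spatial:
                f_d[k] = f
                tau2_d[k] = tau2
        if (it + 1) % 500 == 0:
            logger.info("iteration %d / %d", it + 1, cfg.n_iter)

    draws = PosteriorDraws(
        alpha=alpha_d,
        beta=beta_d,
        gamma=gamma_d,
        f=f_d,
        tau2=tau2_d,
        beta_names=design.term_names[1 : 1 + design.n_beta],
        gamma_names=design.term_names[1 + design.n_beta :],
        school_ids=list(design.school_ids),
        accept_info={
            "sampler": cfg.sampler,
            "accept_rate": (n_accept / cfg.n_iter) if not use_pg else None,
        },
    )
    draws.accept_info.update(_diagnostics(draws))
    return draws


def _diagnostics(draws: PosteriorDraws) -> dict:
    """Effective sample size and split-Rhat per fixed effect (via arviz)."""
    import arviz as az

    names, mat = draws.fixed_effect_draws()
    ess, rhat = {}, {}
    for name, chain in zip(names, mat.T):
        half = chain[: 2 * (len(chain) // 2)].reshape(2, -1)  # split chain
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[name] = float(az.ess(half))
            rhat[name] = float(az.rhat(half))
    worst = max(rhat.values()) if rhat else float("nan")
    if worst > 1.1:
        warnings.warn(
            f"possible non-convergence: max split-Rhat {worst:.3f} > 1.1",
            stacklevel=3,
        )
    return {"ess": ess, "rhat": rhat, "max_rhat": worst}


def summarize_fixed(draws: PosteriorDraws, include_intercept: bool = False) -> list[FixedEffectSummary]:
    """Adjusted odds ratios with 95% credible intervals per fixed effect.

    The AOR is exp(posterior mean coefficient); the interval is the 2.5 and
    97.5 empirical percentiles of the exponentiated draws; a term is flagged
    significant when the interval excludes 1.
    """
    if draws.n_draws == 0:
        raise ValueError("empty chains")
    if draws.n_draws < 100:
        warnings.warn(
            f"only {draws.n_draws} retained draws; summaries are unstable",
            stacklevel=2,
        )
    names, mat = draws.fixed_effect_draws()
    out = []
    for name, chain in zip(names, mat.T):
        if name == "intercept" and not include_intercept:
            continue
        ors = np.exp(chain)
        lo, hi = np.percentile(ors, [2.5, 97.5])
        out.append(
            FixedEffectSummary(
                term=name,
                aor=float(np.exp(chain.mean())),
                cri_low=float(lo),
                cri_high=float(hi),
                significant=bool(lo > 1.0 or hi < 1.0),
            )
        )
    return out
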