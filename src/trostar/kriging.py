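"""Relative-risk surfaces: posterior RR per school and ordinary kriging.

The sum-to-zero spatial effect f(j) of the fitted model is exponentiated
into a relative risk per school — the risk of current use associated with
TRO presence at school j relative to the all-schools (geometric-mean)
baseline.  To say something about locations between the surveyed schools,
the posterior-mean log-RR is interpolated over the county by univariate
ordinary kriging: an empirical semivariogram is binned from the school
values, a parametric model (exponential by default) is fitted by weighted
least squares, and the kriging system (unbiasedness constraint, weights
summing to 1) is solved per grid node.  Kriging on the log scale keeps the
exponentiated surface positive.  Cells whose kriged RR exceeds a threshold
(default 1: above-baseline risk) are flagged as hot-spots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import distance_matrix

from .model import PosteriorDraws


@dataclass
class SpatialRRSummary:
    """Posterior relative risk of one school's TRO-associated spatial effect."""

    school_id: str
    rr_mean: float
    rr_low: float
    rr_high: float
    x_km: float
    y_km: float


def spatial_rr(draws: PosteriorDraws, schools) -> list[SpatialRRSummary]:
    """Per-school posterior relative risks, exp of the spatial-effect draws.

    Because each retained f draw sums to zero, exp(f_j) is the risk at
    school j relative to the geometric mean over all schools.
    """
    if draws.f is None or draws.f.size == 0:
        raise ValueError("no spatial-effect draws in the posterior")
    by_id = {s.school_id: s for s in schools}
    out = []
    for k, sid in enumerate(draws.school_ids):
        rr = np.exp(draws.f[:, k])
        lo, hi = np.percentile(rr, [2.5, 97.5])
        s = by_id[sid]
        out.append(
            SpatialRRSummary(
                school_id=sid,
                rr_mean=float(rr.mean()),
                rr_low=float(lo),
                rr_high=float(hi),
                x_km=float(s.x_km),
                y_km=float(s.y_km),
            )
        )
    return out


@dataclass
class Variogram:
    """Empirical semivariogram bins plus (optionally fitted) model parameters.

    Semivariance models, h >= 0:
      exponential: nugget + partial_sill * (1 - exp(-h / range_param))
      spherical:   nugget + partial_sill * (1.5 h/a - 0.5 (h/a)^3), capped at
                   nugget + partial_sill beyond h = a
    """

    bin_centers: np.ndarray
    gamma_hat: np.ndarray
    pair_counts: np.ndarray
    model: str = "exponential"
    nugget: Optional[float] = None
    partial_sill: Optional[float] = None
    range_param: Optional[float] = None
    degenerate: bool = False  # all input values identical (pure zero field)

    @property
    def fitted(self) -> bool:
        return self.range_param is not None or self.degenerate

    def model_gamma(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.degenerate:
            return np.zeros_like(h)
        if not self.fitted:
            raise ValueError("variogram not fitted")
        return _model_gamma(
            h, self.model, self.nugget, self.partial_sill, self.range_param
        )


def _model_gamma(h, model, nugget, psill, rng_):
    h = np.asarray(h, dtype=float)
    if model == "exponential":
        g = nugget + psill * (1.0 - np.exp(-h / rng_))
    elif model == "spherical":
        hr = np.minimum(h / rng_, 1.0)
        g = nugget + psill * (1.5 * hr - 0.5 * hr**3)
    else:
        raise ValueError(f"unknown variogram model {model!r}")
    return np.where(h == 0.0, 0.0, g)  # gamma(0) = 0 by definition


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray([[p[0], p[1]] for p in points], dtype=float)
    vals = np.asarray([p[2] for p in points], dtype=float)
    return pts, vals


def empirical_variogram(
    points: Sequence[tuple[float, float, float]],
    n_bins: int = 10,
    max_dist_frac: float = 0.5,
    model: str = "exponential",
) -> Variogram:
    """Classical (Matheron) binned semivariogram estimator.

    gamma_hat(bin) = (1 / (2 |N|)) * sum over pairs in the bin of
    (v_i - v_j)^2, over equal-width distance bins up to
    ``max_dist_frac`` times the maximum pairwise distance.  Empty bins are
    dropped.
    """
    pts, vals = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    d = distance_matrix(pts, pts)
    iu = np.triu_indices(n, k=1)
    pd_, dv2 = d[iu], (vals[iu[0]] - vals[iu[1]]) ** 2
    if np.any(pd_ == 0.0):
        raise ValueError("distinct coordinates required")

    degenerate = bool(np.all(vals == vals[0]))
    hmax = max_dist_frac * pd_.max()
    edges = np.linspace(0.0, hmax, n_bins + 1)
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        sel = (pd_ > lo) & (pd_ <= hi) if b else (pd_ >= lo) & (pd_ <= hi)
        if not sel.any():
            continue
        centers.append(0.5 * (lo + hi))
        gammas.append(dv2[sel].sum() / (2.0 * sel.sum()))
        counts.append(int(sel.sum()))
    return Variogram(
        bin_centers=np.asarray(centers),
        gamma_hat=np.asarray(gammas),
        pair_counts=np.asarray(counts),
        model=model,
        degenerate=degenerate,
    )


def fit_variogram(vg: Variogram) -> Variogram:
    """Weighted least squares fit of the parametric semivariogram.

    Weights are the per-bin pair counts; parameters (nugget, partial sill,
    range) are constrained nonnegative and optimized from a fixed grid of
    method-of-moments-style starts, keeping the best solution, so the fit
    is deterministic.  If the optimizer fails, the best starting values are
    kept with a warning.
    """
    if vg.degenerate:
        return replace(vg, nugget=0.0, partial_sill=0.0,
                       range_param=float(vg.bin_centers[-1]) if len(vg.bin_centers) else 1.0)
    if len(vg.bin_centers) < 3:
        raise ValueError("need at least 3 nonempty bins to fit")

    h, g, w = vg.bin_centers, vg.gamma_hat, vg.pair_counts.astype(float)
    sqw = np.sqrt(w)
    sill0 = max(g.max(), 1e-12)
    hmax = h.max()

    def resid(p):
        return sqw * (_model_gamma(h, vg.model, *p) - g)

    # range capped at 10x the largest lag: anything beyond is on the
    # locally-linear ridge and not resolvable from these bins
    lower = np.zeros(3)
    upper = np.array([2.0 * sill0, 5.0 * sill0, 10.0 * hmax])
    starts = [
        (0.0, sill0, frac * hmax)
        for frac in (0.1, 0.25, 0.5, 1.0)
    ] + [
        (0.5 * g[0], max(sill0 - 0.5 * g[0], 1e-12), frac * hmax)
        for frac in (0.25, 0.5)
    ]

    best, best_cost = None, np.inf
    failed = True
    for p0 in starts:
        try:
            sol = least_squares(
                resid, x0=np.asarray(p0), bounds=(lower, upper), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
            )
        except Exception:
            continue
        failed = False
        if sol.cost < best_cost:
            best, best_cost = sol.x, sol.cost
    if failed or best is None:
        import warnings

        warnings.warn("variogram optimizer failed; keeping moment starts")
        best = np.asarray(starts[0])
    nugget, psill, rng_ = (float(v) for v in best)
    # tie-break on the pure-nugget ridge: a range far below the smallest bin
    # distance (exp(-h_min/range) ~ 0) is indistinguishable from extra
    # nugget at all observed lags
    if rng_ < float(h.min()) / 5.0:
        nugget, psill, rng_ = nugget + psill, 0.0, float(h.max())
    return replace(vg, nugget=nugget, partial_sill=max(psill, 1e-12),
                   range_param=max(rng_, 1e-12))


@dataclass
class KrigedSurface:
    """Regular-grid interpolation of relative risk with kriging variances.

    Cells outside the county boundary (convex hull of the schools, or a
    supplied polygon) are masked NaN; ``hotspot`` flags in-boundary cells
    whose kriged RR exceeds the threshold.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    rr: np.ndarray  # (ny, nx), NaN outside the boundary
    krig_var: np.ndarray
    hotspot: np.ndarray
    threshold: float
    max_weight_sum_error: float = 0.0  # max |sum(w) - 1| over solved nodes

    def in_bounds(self) -> np.ndarray:
        return ~np.isnan(self.rr)


def _kriging_weights(gamma_mat_ext, gamma_vec):
    """Solve the ordinary-kriging system; returns (weights, lagrange mu)."""
    n = gamma_mat_ext.shape[0] - 1
    rhs = np.append(gamma_vec, 1.0)
    sol = np.linalg.solve(gamma_mat_ext, rhs)
    return sol[:n], sol[n]


def _extended_gamma_matrix(pts, vg):
    n = len(pts)
    gmat = vg.model_gamma(distance_matrix(pts, pts))
    ext = np.zeros((n + 1, n + 1))
    ext[:n, :n] = gmat + np.eye(n) * 1e-12  # jitter guards the nugget-0 path
    ext[:n, n] = 1.0
    ext[n, :n] = 1.0
    return ext


def krige_points(
    points: Sequence[tuple[float, float, float]],
    vg: Variogram,
    targets: Sequence[tuple[float, float]],
    return_weights: bool = False,
):
    """Ordinary-kriging predictions at arbitrary target locations.

    Returns (predictions, kriging variances) — on the scale of the input
    values — and, with ``return_weights``, the per-target weight vectors.
    Accepts as few as 2 data points (the minimal solvable system).
    """
    pts, vals = _as_points(points)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    if not vg.fitted:
        raise ValueError("variogram must be fitted first")
    ext = _extended_gamma_matrix(pts, vg)
    preds, kvars, wlist = [], [], []
    for tx, ty in targets:
        gv = vg.model_gamma(np.hypot(pts[:, 0] - tx, pts[:, 1] - ty))
        wts, mu = _kriging_weights(ext, gv)
        preds.append(float(wts @ vals))
        kvars.append(max(float(wts @ gv + mu), 0.0))
        wlist.append(wts)
    preds, kvars = np.asarray(preds), np.asarray(kvars)
    if return_weights:
        return preds, kvars, np.asarray(wlist)
    return preds, kvars


def ordinary_krige(
    points: Sequence[tuple[float, float, float]],
    vg: Variogram,
    grid_res: int = 100,
    threshold: float = 1.0,
    log_scale: bool = True,
    boundary=None,
    expand_frac: float = 0.0,
) -> KrigedSurface:
    """Ordinary kriging of (log) relative risks onto a regular grid.

    Per grid node the semivariance system with the unbiasedness constraint
    (Lagrange multiplier, weights summing to 1) is solved; the prediction is
    the weighted sum of observed values and the kriging variance is
    sum w_i gamma(h_i0) + mu.  With ``log_scale`` (default) the values are
    interpolated as given (posterior-mean log-RR) and the surface is
    exponentiated, keeping predictions positive; kriging variances are on
    the log scale.

    ``boundary`` may be a shapely polygon; by default the convex hull of
    the points clips the grid.
    """
    from shapely import contains_xy
    from shapely.geometry import MultiPoint

    pts, vals = _as_points(points)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to krige")
    d = distance_matrix(pts, pts)
    off = d[np.triu_indices(n, k=1)]
    if np.any(off == 0.0):
        i, j = np.argwhere((d == 0.0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(f"duplicate points at indices {int(i)} and {int(j)}")
    if not vg.fitted:
        raise ValueError("variogram must be fitted first")

    ext = _extended_gamma_matrix(pts, vg)

    x0, x1 = pts[:, 0].min(), pts[:, 0].max()
    y0, y1 = pts[:, 1].min(), pts[:, 1].max()
    mx, my = expand_frac * (x1 - x0), expand_frac * (y1 - y0)
    grid_x = np.linspace(x0 - mx, x1 + mx, grid_res)
    grid_y = np.linspace(y0 - my, y1 + my, grid_res)
    gx, gy = np.meshgrid(grid_x, grid_y)

    if boundary is None:
        boundary = MultiPoint([tuple(p) for p in pts]).convex_hull
    inside = contains_xy(boundary.buffer(1e-9), gx.ravel(), gy.ravel()).reshape(gx.shape)

    pred = np.full(gx.shape, np.nan)
    kvar = np.full(gx.shape, np.nan)
    wsum_err = 0.0
    idx = np.argwhere(inside)
    for iy, ix in idx:
        h0 = np.hypot(pts[:, 0] - gx[iy, ix], pts[:, 1] - gy[iy, ix])
        if vg.degenerate:
            pred[iy, ix], kvar[iy, ix] = vals[0], 0.0
            continue
        gv = vg.model_gamma(h0)
        wts, mu = _kriging_weights(ext, gv)
        pred[iy, ix] = wts @ vals
        kvar[iy, ix] = max(float(wts @ gv + mu), 0.0)
        wsum_err = max(wsum_err, abs(float(wts.sum()) - 1.0))

    rr = np.exp(pred) if log_scale else pred
    hot = np.zeros(rr.shape, dtype=bool)
    hot[inside] = rr[inside] > threshold
    return KrigedSurface(
        grid_x=grid_x, grid_y=grid_y, rr=rr, krig_var=kvar, hotspot=hot,
        threshold=threshold, max_weight_sum_error=wsum_err,
    )


def krige_rr(
    rr_summaries: Sequence[SpatialRRSummary],
    model: str = "exponential",
    n_bins: int = 10,
    max_dist_frac: float = 0.5,
    grid_res: int = 100,
    threshold: float = 1.0,
    boundary=None,
) -> tuple[Variogram, KrigedSurface]:
    """Convenience chain: log-RR -> variogram -> WLS fit -> kriged surface."""
    points = [(s.x_km, s.y_km, float(np.log(s.rr_mean))) for s in rr_summaries]
    vg = fit_variogram(
        empirical_variogram(points, n_bins=n_bins, max_dist_frac=max_dist_frac,
                            model=model)
    )
    surface = ordinary_krige(
        points, vg, grid_res=grid_res, threshold=threshold, log_scale=True,
        boundary=boundary,
    )
    return vg, surface


def plot_surface(surface: KrigedSurface, schools=None, path=None, title=None):
    """Blue-to-red heat map of the kriged RR with school locations as dots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    m = ax.pcolormesh(
        surface.grid_x, surface.grid_y, surface.rr, cmap="coolwarm", shading="auto"
    )
    fig.colorbar(m, ax=ax, label="relative risk")
    if schools is not None:
        ax.scatter(
            [s.x_km for s in schools], [s.y_km for s in schools],
            c="black", s=12, zorder=3, label="schools",
        )
        ax.legend(loc="upper right")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
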