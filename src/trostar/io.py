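"""Readers, writers and the record-exclusion filter.

CSV is the interchange format for student and school records, posterior
draws (gzip-compressed CSV) and kriged rasters; GeoJSON for point and
surface geometries; JSON for ground truth, summaries and run manifests.
Exclusions follow the source analysis: records from dropped counties are
removed first, then listwise deletion on the two fields it names — family
standard of living and the analysed outcome.  No imputation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    CODEBOOK,
    SCHOOL_COLUMNS,
    STUDENT_COLUMNS,
    SchoolRecord,
    StudentRecord,
)


def _opt_str(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


def load_students(path) -> list[StudentRecord]:
    """Read students.csv into validated records; errors cite the CSV row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(STUDENT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {sorted(missing_cols)}")
    has_county = "county" in df.columns
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            raw_w = d["samp_weight"]
            try:
                w = float(raw_w)
            except ValueError:
                raise ValueError(f"unparseable samp_weight {raw_w!r}")
            outcome = _opt_str(d["outcome"])
            rec = StudentRecord(
                student_id=d["student_id"],
                school_id=d["school_id"],
                outcome=None if outcome is None else int(float(outcome)),
                sex=d["sex"],
                race3=d["race3"],
                grade=d["grade"],
                family_sol=_opt_str(d["family_sol"]),
                visited_stores=d["visited_stores"],
                recall_marketing=d["recall_marketing"],
                recall_warning=d["recall_warning"],
                samp_weight=w,
                county=_opt_str(d["county"]) if has_county else None,
            )
            rec.validate()
        except ValueError as e:
            raise ValueError(f"{path} row {row_no}: {e}") from None
        out.append(rec)
    return out


def load_schools(path) -> list[SchoolRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(SCHOOL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {sorted(missing_cols)}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            rec = SchoolRecord(
                school_id=str(d["school_id"]),
                x_km=float(d["x_km"]),
                y_km=float(d["y_km"]),
                tro=int(d["tro"]),
                zip_hs_grad_pct=float(d["zip_hs_grad_pct"]),
                zip_med_income=float(d["zip_med_income"]),
                zip_poverty_pct=float(d["zip_poverty_pct"]),
                n_students=int(d["n_students"]),
            )
            rec.validate()
        except (ValueError, TypeError) as e:
            raise ValueError(f"{path} row {row_no}: {e}") from None
        out.append(rec)
    return out


def write_students(students, path) -> None:
    rows = []
    for s in students:
        d = {c: getattr(s, c) for c in STUDENT_COLUMNS}
        if s.county is not None:
            d["county"] = s.county
        d["outcome"] = "" if s.outcome is None else s.outcome
        d["family_sol"] = "" if s.family_sol is None else s.family_sol
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_schools(schools, path) -> None:
    pd.DataFrame(
        [{c: getattr(s, c) for c in SCHOOL_COLUMNS} for s in schools]
    ).to_csv(path, index=False, float_format="%.17g")


def schools_geojson(schools) -> dict:
    """Schools as a GeoJSON FeatureCollection of points (planar km coords)."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [s.x_km, s.y_km]},
                "properties": {
                    c: getattr(s, c) for c in SCHOOL_COLUMNS if c not in ("x_km", "y_km")
                },
            }
            for s in schools
        ],
    }


def write_county(county, outdir) -> dict:
    """Write a synthetic county's full artifact set; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "students": outdir / "students.csv",
        "schools": outdir / "schools.csv",
        "truth": outdir / "truth.json",
        "geojson": outdir / "schools.geojson",
        "edges": outdir / "graph_edges.csv",
    }
    write_students(county.students, paths["students"])
    write_schools(county.schools, paths["schools"])
    truth = county.truth.as_dict()
    truth["missing_log"] = county.missing_log
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["geojson"].write_text(json.dumps(schools_geojson(county.schools)))
    county.graph.to_edge_csv(paths["edges"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------- exclusions


@dataclass
class ExclusionReport:
    """Bookkeeping of the record filter; the counts always balance."""

    n_input: int
    n_excluded_missing: int
    n_excluded_county: int
    n_retained: int
    reasons: dict[str, str]  # student_id -> "county" | "missing_<field>"

    def check(self) -> None:
        assert (
            self.n_input
            == self.n_excluded_missing + self.n_excluded_county + self.n_retained
        )


def apply_exclusions(
    students, outcome: str = "outcome", drop_counties=()
) -> tuple[list[StudentRecord], ExclusionReport]:
    """Drop dropped-county records, then records missing family standard of
    living or the analysed outcome (listwise deletion)."""
    drop = set(drop_counties)
    retained = []
    reasons: dict[str, str] = {}
    n_county = n_missing = 0
    for s in students:
        if s.county is not None and s.county in drop:
            reasons[s.student_id] = "county"
            n_county += 1
            continue
        if s.family_sol is None:
            reasons[s.student_id] = "missing_family_sol"
            n_missing += 1
            continue
        if getattr(s, outcome) is None:
            reasons[s.student_id] = f"missing_{outcome}"
            n_missing += 1
            continue
        retained.append(s)
    report = ExclusionReport(
        n_input=len(students),
        n_excluded_missing=n_missing,
        n_excluded_county=n_county,
        n_retained=len(retained),
        reasons=reasons,
    )
    report.check()
    return retained, report


# ------------------------------------------------------------ fit artifacts


def write_posterior(draws, path) -> None:
    """Persist posterior draws as gzip-compressed CSV (one row per draw)."""
    cols = {"alpha": draws.alpha}
    for k, name in enumerate(draws.beta_names):
        cols[f"beta:{name}"] = draws.beta[:, k]
    for k, name in enumerate(draws.gamma_names):
        cols[f"gamma:{name}"] = draws.gamma[:, k]
    if draws.f is not None:
        for k, sid in enumerate(draws.school_ids):
            cols[f"f:{sid}"] = draws.f[:, k]
        cols["tau2"] = draws.tau2
    pd.DataFrame(cols).to_csv(path, index=False, compression="gzip")


def read_posterior(path):
    """Load posterior draws written by :func:`write_posterior`."""
    from .model import PosteriorDraws

    df = pd.read_csv(path, compression="gzip")
    beta_names = [c[5:] for c in df.columns if c.startswith("beta:")]
    gamma_names = [c[6:] for c in df.columns if c.startswith("gamma:")]
    school_ids = [c[2:] for c in df.columns if c.startswith("f:")]
    has_f = bool(school_ids)
    return PosteriorDraws(
        alpha=df["alpha"].to_numpy(),
        beta=df[[f"beta:{n}" for n in beta_names]].to_numpy(),
        gamma=df[[f"gamma:{n}" for n in gamma_names]].to_numpy(),
        f=df[[f"f:{s}" for s in school_ids]].to_numpy() if has_f else None,
        tau2=df["tau2"].to_numpy() if has_f else None,
        beta_names=beta_names,
        gamma_names=gamma_names,
        school_ids=school_ids,
    )


def summaries_json(summaries) -> list[dict]:
    return [asdict(s) for s in summaries]


def write_rr(rr_summaries, path) -> None:
    pd.DataFrame([asdict(r) for r in rr_summaries]).to_csv(path, index=False)


def read_rr(path):
    from .kriging import SpatialRRSummary

    df = pd.read_csv(path)
    return [SpatialRRSummary(**row._asdict()) for row in df.itertuples(index=False)]


def write_surface_csv(surface, path) -> None:
    """Plain raster export: one row per in-boundary grid cell."""
    gx, gy = np.meshgrid(surface.grid_x, surface.grid_y)
    mask = surface.in_bounds()
    pd.DataFrame(
        {
            "x": gx[mask],
            "y": gy[mask],
            "rr": surface.rr[mask],
            "krig_var": surface.krig_var[mask],
            "hotspot": surface.hotspot[mask].astype(int),
        }
    ).to_csv(path, index=False)


def surface_geojson(surface) -> dict:
    """Kriged surface as GeoJSON square-cell polygon features."""
    dx = float(np.diff(surface.grid_x).mean()) if len(surface.grid_x) > 1 else 1.0
    dy = float(np.diff(surface.grid_y).mean()) if len(surface.grid_y) > 1 else 1.0
    feats = []
    mask = surface.in_bounds()
    for iy, ix in np.argwhere(mask):
        x, y = float(surface.grid_x[ix]), float(surface.grid_y[iy])
        ring = [
            [x - dx / 2, y - dy / 2],
            [x + dx / 2, y - dy / 2],
            [x + dx / 2, y + dy / 2],
            [x - dx / 2, y + dy / 2],
            [x - dx / 2, y - dy / 2],
        ]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "rr": float(surface.rr[iy, ix]),
                    "krig_var": float(surface.krig_var[iy, ix]),
                    "hotspot": bool(surface.hotspot[iy, ix]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
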