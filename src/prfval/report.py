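"""Estimate-vs-truth comparison: error tables, trimmed summaries,
coverage ellipses and HRF-mismatch matrices.

All computations are pure functions of the truth and estimate tables;
re-running on the same inputs is bit-identical for the TSV/JSON outputs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .prf import cartesian_to_polar

__all__ = [
    "compute_errors",
    "summarize",
    "coverage_ellipse",
    "hrf_mismatch_matrix",
    "export_report",
]

_CONDITION_COLS = ("hrf_id", "analysis_hrf", "noise_level", "design")


def _wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def compute_errors(truth: pd.DataFrame, estimates: pd.DataFrame) -> pd.DataFrame:
    """Join truth to estimates on ``voxel_id`` and compute per-voxel errors.

    Errors are in degrees (polar-angle error in radians, wrapped to
    (-pi, pi]); eccentricity error is signed (estimate minus truth).
    Missing or duplicated keys are rejected with the offending ids listed.
    """
    for name, table in (("truth", truth), ("estimates", estimates)):
        dups = table["voxel_id"][table["voxel_id"].duplicated()].tolist()
        if dups:
            raise ValueError(f"duplicate voxel_id in {name} table: {sorted(set(dups))}")
    t_ids, e_ids = set(truth["voxel_id"]), set(estimates["voxel_id"])
    if t_ids != e_ids:
        raise ValueError(
            f"voxel_id mismatch: only-in-truth {sorted(t_ids - e_ids)}, "
            f"only-in-estimates {sorted(e_ids - t_ids)}"
        )
    est = estimates.rename(
        columns={c: f"est_{c}" for c in estimates.columns if c != "voxel_id"}
    )
    df = truth.merge(est, on="voxel_id", how="inner", validate="one_to_one")

    true_sigma = df["sigma_major"] if "sigma_major" in df else df["sigma"]
    df["dx"] = df["est_x0"] - df["x0"]
    df["dy"] = df["est_y0"] - df["y0"]
    df["d_sigma"] = df["est_sigma"] - true_sigma
    t_ecc, t_ang = cartesian_to_polar(df["x0"].to_numpy(), df["y0"].to_numpy())
    e_ecc, e_ang = cartesian_to_polar(df["est_x0"].to_numpy(), df["est_y0"].to_numpy())
    df["ecc_err"] = e_ecc - t_ecc
    df["polar_err"] = _wrap_angle(e_ang - t_ang)
    return df


def coverage_ellipse(points: np.ndarray, mass: float = 0.9) -> dict:
    """Covariance ellipse containing the given probability mass.

    Centered on the sample mean, shaped by the sample covariance, and
    scaled by the chi-square(2 df) quantile at ``mass`` — under bivariate
    normality the ellipse covers that fraction of the points. Returns
    center, semi-axes (major, minor) and major-axis angle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) points")
    cov = np.cov(pts.T)
    rank = np.linalg.matrix_rank(cov, tol=1e-12)
    if rank < 2:
        raise ValueError(f"degenerate point set: covariance rank {rank} < 2 (collinear)")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = math.sqrt(stats.chi2.ppf(mass, df=2))
    return {
        "center": tuple(pts.mean(axis=0)),
        "semi_axes": (scale * math.sqrt(evals[0]), scale * math.sqrt(evals[1])),
        "angle": math.atan2(evecs[1, 0], evecs[0, 0]),
        "mass": mass,
    }


def ellipse_contains(ellipse: dict, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points inside the ellipse (boundary inclusive)."""
    pts = np.asarray(points, dtype=float) - np.asarray(ellipse["center"])
    ca, sa = math.cos(ellipse["angle"]), math.sin(ellipse["angle"])
    u = pts[:, 0] * ca + pts[:, 1] * sa
    v = -pts[:, 0] * sa + pts[:, 1] * ca
    a, b = ellipse["semi_axes"]
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _central_trim(df: pd.DataFrame, by: str, quantile: float) -> pd.DataFrame:
    """Keep the central ceil(quantile * n) rows ranked by column ``by``."""
    n = len(df)
    keep = math.ceil(quantile * n)
    drop = n - keep
    lo = drop // 2
    order = df[by].to_numpy().argsort(kind="stable")
    kept = np.sort(order[lo : lo + keep])
    return df.iloc[kept]


def summarize(errors: pd.DataFrame, trim_quantile: float = 0.9) -> dict:
    """Trimmed summary of one condition's error table.

    Rows are trimmed to the central ``trim_quantile`` mass ranked by the
    pRF size estimate (outlier fits show up as extreme sizes); medians,
    size quantiles and the center-coverage ellipse are computed on the
    trimmed set. With n < 3 the ellipse is omitted and a warning flag set.
    """
    n = len(errors)
    out = {
        "n": n,
        "trim_quantile": trim_quantile,
        "warning": None,
    }
    if n < 3:
        out.update(
            trimmed_n=n, outlier_count=0, warning="n < 3: no trimming or ellipse"
        )
        if n:
            out["median_x"] = float(errors["est_x0"].median())
            out["median_y"] = float(errors["est_y0"].median())
        return out
    trimmed = _central_trim(errors, "est_sigma", trim_quantile)
    out["trimmed_n"] = len(trimmed)
    out["outlier_count"] = n - len(trimmed)
    out["median_x"] = float(trimmed["est_x0"].median())
    out["median_y"] = float(trimmed["est_y0"].median())
    out["median_sigma"] = float(trimmed["est_sigma"].median())
    out["median_d_sigma"] = float(trimmed["d_sigma"].median())
    qs = trimmed["est_sigma"].quantile([0.05, 0.25, 0.5, 0.75, 0.95])
    out["sigma_quantiles"] = {f"q{int(q * 100):02d}": float(v) for q, v in qs.items()}
    centers = trimmed[["est_x0", "est_y0"]].to_numpy()
    try:
        out["center_ellipse"] = coverage_ellipse(centers, mass=0.9)
    except ValueError as exc:
        out["center_ellipse"] = None
        out["warning"] = str(exc)
    return out


def hrf_mismatch_matrix(
    errors: pd.DataFrame,
    synth_order: list[str] | None = None,
    analysis_order: list[str] | None = None,
) -> pd.DataFrame:
    """Median signed pRF-size error per (synthesis HRF, analysis HRF) cell.

    Requires a complete factorial of the two condition labels (``hrf_id``
    for synthesis, ``analysis_hrf`` for the fitter's assumption). With the
    HRFs ordered narrow to wide, cells above the diagonal (synthesis
    narrower than analysis) are negative and below positive; the diagonal
    is near zero.
    """
    for col in ("hrf_id", "analysis_hrf"):
        if col not in errors:
            raise ValueError(f"errors table lacks the {col!r} condition column")
    synth = synth_order or sorted(errors["hrf_id"].unique())
    analysis = analysis_order or sorted(errors["analysis_hrf"].unique())
    missing = [
        (s, a)
        for s in synth
        for a in analysis
        if not ((errors["hrf_id"] == s) & (errors["analysis_hrf"] == a)).any()
    ]
    if missing:
        raise ValueError(f"incomplete HRF factorial, missing cells: {missing}")
    mat = (
        errors.pivot_table(
            index="hrf_id", columns="analysis_hrf", values="d_sigma", aggfunc="median"
        )
        .reindex(index=synth, columns=analysis)
    )
    mat.index.name = "synth_hrf"
    return mat


def export_report(
    summary: dict, errors: pd.DataFrame, out_dir, make_figures: bool = False
) -> list[Path]:
    """Write report.json and errors.tsv (and optional figures); return manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    manifest.append(report_path)
    errors_path = out_dir / "errors.tsv"
    errors.to_csv(errors_path, sep="\t", index=False)
    manifest.append(errors_path)
    if make_figures and {"est_x0", "est_y0"}.issubset(errors.columns):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(errors["est_x0"], errors["est_y0"], s=12, alpha=0.6, label="estimates")
        if {"x0", "y0"}.issubset(errors.columns):
            ax.scatter(
                errors["x0"], errors["y0"], marker="+", color="k", label="truth"
            )
        ax.set_xlabel("x (deg)")
        ax.set_ylabel("y (deg)")
        ax.set_aspect("equal")
        ax.legend()
        for ext in ("svg", "png"):
            p = out_dir / f"centers.{ext}"
            fig.savefig(p)
            manifest.append(p)
        plt.close(fig)
    return manifest
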