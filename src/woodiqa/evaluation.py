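"""Agreement measures between quality scores and opinion scores.

PLCC (Pearson linear correlation coefficient) and RMSE (root mean
squared error) quantify how well a metric's scores track the human mean
opinion scores; higher PLCC and lower RMSE mean better agreement. The
comparison report computes both per distortion stratum (noise-only,
blur-only, mixed, and all distorted images) for any number of candidate
metrics, flagging the best value in each stratum. No logistic remapping
is applied before PLCC; scores are compared as-is.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import JoinError

__all__ = ["compare_metrics", "plcc", "rmse"]


def plcc(x, y) -> float:
    """Pearson product-moment correlation between two score vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 paired scores for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance argument")
    return float(stats.pearsonr(x, y).statistic)


def rmse(x, y) -> float:
    """Root mean squared error between two score vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 1:
        raise ValueError("need at least 1 paired score")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def compare_metrics(
    mos: pd.DataFrame,
    metric_scores: pd.DataFrame,
    manifest,
    include_reference: bool = False,
) -> pd.DataFrame:
    """Per-metric, per-stratum PLCC and RMSE versus MOS.

    Parameters
    ----------
    mos : DataFrame with columns ``image_id, mos`` (extra columns ignored).
    metric_scores : DataFrame with ``image_id`` plus one column per
        candidate metric (externally computed metrics enter as columns).
    manifest : DatasetManifest (or its frame) supplying each image's
        distortion kind for the strata.
    include_reference : include undistorted reference rows in the
        strata-spanning "all" row (default excludes them, and reference
        rows never form their own stratum).

    Returns
    -------
    DataFrame ``metric, stratum, plcc, rmse, n, best_plcc, best_rmse``;
    the best flags mark the winning metric within each stratum.
    """
    frame = getattr(manifest, "frame", manifest)
    metric_cols = [c for c in metric_scores.columns if c != "image_id"]
    if not metric_cols:
        raise ValueError("metric_scores has no metric columns")

    merged = mos[["image_id", "mos"]].merge(metric_scores, on="image_id", how="outer", indicator=True)
    unjoined = merged.loc[merged["_merge"] != "both", "image_id"].astype(str).tolist()
    if unjoined:
        raise JoinError(f"image ids missing from one side: {sorted(unjoined)}", unjoined)
    merged = merged.drop(columns="_merge").merge(
        frame[["image_id", "kind"]], on="image_id", how="inner"
    )
    if len(merged) != len(mos):
        missing = sorted(set(mos["image_id"].astype(str)) - set(frame["image_id"].astype(str)))
        raise JoinError(f"image ids missing from manifest: {missing}", missing)

    strata = {
        "gwn": merged["kind"] == "gwn",
        "mb": merged["kind"] == "mb",
        "mixed": merged["kind"] == "mixed",
        "all": merged["kind"] != "reference"
        if not include_reference
        else merged["kind"].notna(),
    }

    rows = []
    for stratum, mask in strata.items():
        sub = merged.loc[mask]
        if len(sub) == 0:
            continue
        for metric in metric_cols:
            rows.append(
                {
                    "metric": metric,
                    "stratum": stratum,
                    "plcc": plcc(sub["mos"], sub[metric]),
                    "rmse": rmse(sub["mos"], sub[metric]),
                    "n": len(sub),
                }
            )
    report = pd.DataFrame(rows, columns=["metric", "stratum", "plcc", "rmse", "n"])
    report["best_plcc"] = False
    report["best_rmse"] = False
    for stratum, group in report.groupby("stratum"):
        report.loc[group["plcc"].idxmax(), "best_plcc"] = True
        report.loc[group["rmse"].idxmin(), "best_rmse"] = True
    return report
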