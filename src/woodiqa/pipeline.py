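"""Seeded end-to-end workflow: textures -> distortions -> features -> SVR.

``demo_end_to_end`` exercises the whole pipeline on synthetic data:

1. generate ten wood-like reference textures;
2. build the 110-image training layout and the 360-image evaluation
   layout (noise, blur, and noise+blur severities);
3. simulate a ten-rater panel over both layouts and average to MOS;
4. extract the 36 NSS features of every image;
5. run the iterated 80/20 protocol on the training layout and keep the
   median-PLCC model;
6. score the evaluation layout and report PLCC/RMSE per distortion
   stratum plus the monotonicity of the predicted score in each
   severity.

One top-level seed fans out deterministically to per-stage seeds, so a
fixed seed reproduces every artifact byte-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_seed
from .distortions import DatasetManifest, build_eval_set, build_training_set
from .evaluation import compare_metrics
from .nss import extract_features_table
from .regression import ProtocolResult, predict, run_protocol
from .subjective import compute_mos, mos_to_frame
from .synthetic import SyntheticMOSSpec, make_reference_set, make_synthetic_ratings

__all__ = ["DemoSummary", "demo_end_to_end"]

_CSV_FLOAT = "%.10g"  # fixed formatting so reruns are byte-identical


@dataclass
class DemoSummary:
    """Computed artifacts and headline numbers of one demo run."""

    train_size: int
    eval_size: int
    feature_dim: int
    median_plcc: float
    median_rmse: float
    spearman_gwn: float
    spearman_mb: float
    protocol: ProtocolResult
    report: pd.DataFrame
    predictions: pd.DataFrame
    eval_mos: pd.DataFrame

    def headline(self) -> Dict[str, float]:
        row = self.report.loc[
            (self.report["metric"] == "woodiqa") & (self.report["stratum"] == "all")
        ]
        return {
            "train_size": self.train_size,
            "eval_size": self.eval_size,
            "feature_dim": self.feature_dim,
            "median_plcc": self.median_plcc,
            "median_rmse": self.median_rmse,
            "eval_plcc_all": float(row["plcc"].iloc[0]),
            "eval_rmse_all": float(row["rmse"].iloc[0]),
            "spearman_gwn": self.spearman_gwn,
            "spearman_mb": self.spearman_mb,
        }


def _ratings_items(manifest: DatasetManifest):
    return [
        (row["image_id"], manifest.spec_for(row["image_id"]))
        for _, row in manifest.frame.iterrows()
    ]


def _severity_monotonicity(
    predictions: pd.DataFrame, manifest: DatasetManifest, kind: str, severity_col: str
) -> float:
    """Spearman correlation of mean predicted score vs severity level."""
    merged = predictions.merge(manifest.frame, on="image_id")
    sub = merged.loc[merged["kind"] == kind]
    means = sub.groupby(severity_col)["woodiqa"].mean()
    return float(stats.spearmanr(means.index.to_numpy(), means.to_numpy()).statistic)


def demo_end_to_end(
    seed: int,
    size: int = 600,
    n_iter: int = 100,
    rater_sd: float = 0.5,
    out_dir: Optional[str] = None,
    C: float = 512.0,
    g: float = 0.25,
    epsilon: float = 0.1,
) -> DemoSummary:
    """Run the full synthetic pipeline and summarize its performance.

    Parameters
    ----------
    seed : master seed; every stage derives its own stream from it.
    size : side length in pixels of the generated reference textures.
    n_iter : iterations of the random-split training protocol.
    rater_sd : std of the synthetic raters' opinion noise (score units).
    out_dir : if given, write manifests, feature tables, MOS tables, the
        comparison report and a JSON summary there (no images).
    """
    refs = make_reference_set(derive_seed(seed, "textures"), n=10, size=size)

    train = build_training_set(refs, seed=derive_seed(seed, "train"))
    evalset = build_eval_set(refs, seed=derive_seed(seed, "eval"))

    mos_spec_train = SyntheticMOSSpec(rater_sd=rater_sd, seed=derive_seed(seed, "ratings-train"))
    mos_spec_eval = SyntheticMOSSpec(rater_sd=rater_sd, seed=derive_seed(seed, "ratings-eval"))
    train_mos = mos_to_frame(compute_mos(make_synthetic_ratings(_ratings_items(train), mos_spec_train)))
    eval_mos = mos_to_frame(compute_mos(make_synthetic_ratings(_ratings_items(evalset), mos_spec_eval)))

    train_features = extract_features_table(train.images)
    eval_features = extract_features_table(evalset.images)

    protocol = run_protocol(
        train_features,
        train_mos,
        C=C,
        g=g,
        epsilon=epsilon,
        n_iter=n_iter,
        seed=derive_seed(seed, "protocol"),
    )

    predictions = predict(protocol.selected_model, eval_features).rename(
        columns={"score": "woodiqa"}
    )
    report = compare_metrics(eval_mos, predictions, evalset)

    summary = DemoSummary(
        train_size=len(train),
        eval_size=len(evalset),
        feature_dim=train_features.shape[1] - 1,
        median_plcc=protocol.median_plcc,
        median_rmse=protocol.median_rmse,
        spearman_gwn=_severity_monotonicity(predictions, evalset, "gwn", "sigma_gn"),
        spearman_mb=_severity_monotonicity(predictions, evalset, "mb", "sigma_mb"),
        protocol=protocol,
        report=report,
        predictions=predictions,
        eval_mos=eval_mos,
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        train.frame.to_csv(os.path.join(out_dir, "train_manifest.csv"), index=False)
        evalset.frame.to_csv(os.path.join(out_dir, "eval_manifest.csv"), index=False)
        train_features.to_csv(
            os.path.join(out_dir, "train_features.csv"), index=False, float_format=_CSV_FLOAT
        )
        eval_features.to_csv(
            os.path.join(out_dir, "eval_features.csv"), index=False, float_format=_CSV_FLOAT
        )
        train_mos.to_csv(os.path.join(out_dir, "train_mos.csv"), index=False, float_format=_CSV_FLOAT)
        eval_mos.to_csv(os.path.join(out_dir, "eval_mos.csv"), index=False, float_format=_CSV_FLOAT)
        predictions.to_csv(
            os.path.join(out_dir, "eval_predictions.csv"), index=False, float_format=_CSV_FLOAT
        )
        report.to_csv(os.path.join(out_dir, "report.csv"), index=False, float_format=_CSV_FLOAT)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary.headline(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    return summary
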