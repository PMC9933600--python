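"""Leverage-based applicability domain (Williams plot data).

The leverage of sample i is the hat-matrix diagonal computed on the
autoscaled training descriptors,

    h_i = x_i' (X'X)^-1 x_i,

which measures the distance of the sample from the centroid of the
training set in descriptor space.  Predictions for samples with
h > h* = 3p/n extrapolate beyond the calibrated region; samples whose
standardized residual exceeds 3 SD units are response outliers.  The
Williams plot is standardized residual versus leverage with those two
thresholds drawn in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ModelingTable
from .pls import PLSModel
from .preprocess import apply_autoscaler

logger = logging.getLogger(__name__)

RESIDUAL_SD_LIMIT = 3.0


@dataclass
class ApplicabilityReport:
    """Per-sample Williams plot data and domain flags."""

    h_star: float
    table: pd.DataFrame  # structure_id, split, leverage, std_residual, flags
    convention: str      # "p" or "p+1"

    @property
    def n_outliers(self) -> int:
        return int(self.table["outlier"].sum())

    @property
    def n_high_leverage(self) -> int:
        return int(self.table["high_leverage"].sum())

    def to_files(self, directory: str | Path, stem: str = "williams") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / f"{stem}.csv", index=False)
        (directory / f"{stem}_summary.json").write_text(
            json.dumps(
                {
                    "h_star": self.h_star,
                    "convention": self.convention,
                    "n_outliers": self.n_outliers,
                    "n_high_leverage": self.n_high_leverage,
                },
                indent=1,
            )
        )


def critical_leverage(p: int, n: int, convention: str = "p") -> float:
    """Warning leverage h* = 3p/n.

    ``convention`` selects what p counts: the number of model descriptors
    ("p", default) or descriptors plus one for the intercept ("p+1").
    """
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    if convention not in ("p", "p+1"):
        raise ValueError(f"unknown convention {convention!r}")
    eff = p if convention == "p" else p + 1
    return 3.0 * eff / n


def leverages(model: PLSModel, table: ModelingTable, space: str = "descriptors") -> np.ndarray:
    """Hat-matrix diagonals of *table* rows against the model's training space.

    ``space="descriptors"`` (default) uses the autoscaled descriptor
    matrix: h_i = x_i'(X'X)^-1 x_i with X the scaled training matrix.
    ``space="scores"`` uses the model's latent-variable scores instead
    (h_i = t_i'(T'T)^-1 t_i with t_i = R'x_i), the convention of most
    PLS software: a sample can then only be extreme along directions the
    model actually uses.  A validation sample far outside the training
    range of a descriptor that barely loads on the LVs is flagged by the
    first convention but not by the second.
    """
    if model.Xs_train is None:
        raise ValueError("model carries no training matrix; refit or deserialize with Xs_train")
    rows = apply_autoscaler(table, model.scaling)
    if space == "scores":
        R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
        rows = rows @ R
        G = model.x_scores.T @ model.x_scores
    elif space == "descriptors":
        G = model.Xs_train.T @ model.Xs_train
    else:
        raise ValueError(f"unknown leverage space {space!r}")
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        logger.warning("X'X (near-)singular; using pseudo-inverse for leverages")
        Ginv = np.linalg.pinv(G)
    else:
        Ginv = np.linalg.inv(G)
    return np.einsum("ij,jk,ik->i", rows, Ginv, rows)


def williams_data(
    model: PLSModel,
    table: ModelingTable,
    convention: str = "p",
    residual_scale: str = "partition",
    leverage_space: str = "descriptors",
) -> ApplicabilityReport:
    """Williams plot data: leverage and standardized residual per sample.

    Standardized residuals are the raw residuals divided by the RMSE of
    the sample's own partition (RMSEC for training rows, RMSEP for
    validation rows) by default, or by the pooled RMSE with
    ``residual_scale="pooled"``.  ``leverage_space`` is passed through to
    :func:`leverages`.
    """
    h = leverages(model, table, space=leverage_space)
    n_train = int(model.x_scores.shape[0])
    p = len(model.descriptor_names)
    h_star = critical_leverage(p, n_train, convention)
    y = table.y
    yhat = model.predict_table(table)
    resid = y - yhat
    split = table.split_labels
    scale = np.empty(len(y))
    tmask = split == "T"
    rmse_t = float(np.sqrt(np.mean(resid[tmask] ** 2))) if tmask.any() else np.nan
    vmask = ~tmask
    rmse_v = float(np.sqrt(np.mean(resid[vmask] ** 2))) if vmask.any() else rmse_t
    if residual_scale == "pooled":
        scale[:] = float(np.sqrt(np.mean(resid**2)))
    elif residual_scale == "partition":
        scale[tmask] = rmse_t
        scale[vmask] = rmse_v
    else:
        raise ValueError(f"unknown residual_scale {residual_scale!r}")
    std_resid = resid / scale
    df = pd.DataFrame(
        {
            "structure_id": table.structure_ids,
            "split": split,
            "observed": y,
            "predicted": yhat,
            "leverage": h,
            "std_residual": std_resid,
            "high_leverage": h > h_star,
            "outlier": np.abs(std_resid) > RESIDUAL_SD_LIMIT,
        }
    )
    df["in_domain"] = ~(df["high_leverage"] | df["outlier"])
    return ApplicabilityReport(h_star=h_star, table=df, convention=convention)


def plot_williams(report: ApplicabilityReport, path: str | Path) -> None:
    """Render the Williams plot to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.table
    fig, ax = plt.subplots(figsize=(5, 4))
    for split, marker in (("T", "o"), ("V", "s")):
        sub = df[df["split"] == split]
        ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=split)
    ax.axvline(report.h_star, ls="--", c="k", lw=0.8)
    ax.axhline(RESIDUAL_SD_LIMIT, ls=":", c="r", lw=0.8)
    ax.axhline(-RESIDUAL_SD_LIMIT, ls=":", c="r", lw=0.8)
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
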