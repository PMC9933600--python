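"""Autoscaling (column-wise standardization) with training-set parameters.

Scaling parameters (per-descriptor mean and standard deviation) are fit
on the training rows only and applied unchanged to every partition, so
validation samples are expressed in training-set units.  Descriptors
that are constant over the training rows carry no information and are
dropped (with a warning) rather than rejected: inside leave-one-out
folds a corona fingerprint bit present in exactly one training sample
becomes constant when that sample is held out, and the fold must still
be fittable.

The endpoint is mean-centered only (never variance-scaled), so model
errors stay in mV and standardized coefficients read as "mV per
descriptor standard deviation".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import ModelingTable

logger = logging.getLogger(__name__)

#: Default standard-deviation denominator: 0 = population (n), 1 = sample (n-1).
#: The population convention reproduces the reference model's published
#: standardized coefficients; predictions and error statistics are
#: invariant to the choice.
DEFAULT_DDOF = 0


@dataclass
class ScalingParams:
    """Training-set autoscaling state.

    ``kept`` flags columns retained after the zero-variance drop; ``mean``
    and ``sd`` are stored for all columns (sd of a dropped column is 0).
    """

    column_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray
    ddof: int = DEFAULT_DDOF

    @property
    def kept_names(self) -> list[str]:
        return [n for n, k in zip(self.column_names, self.kept) if k]

    @property
    def dropped_names(self) -> list[str]:
        return [n for n, k in zip(self.column_names, self.kept) if not k]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def fit_autoscaler(
    table: ModelingTable, rows: np.ndarray | None = None, ddof: int = DEFAULT_DDOF
) -> ScalingParams:
    """Fit per-descriptor mean/sd on the training rows of *table*.

    ``rows`` is a boolean mask selecting the rows used for fitting
    (default: the T-labeled rows; if none are labeled, all rows).
    Zero-variance columns are flagged for dropping, not an error.
    """
    if rows is None:
        rows = table.train_mask
        if not rows.any():
            rows = np.ones(table.n_samples, dtype=bool)
    X = table.X[rows]
    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    kept = sd > 0
    if not kept.all():
        dropped = [n for n, k in zip(table.descriptor_names, kept) if not k]
        logger.warning("dropping zero-variance descriptor(s): %s", dropped)
    return ScalingParams(
        column_names=list(table.descriptor_names),
        mean=mean,
        sd=sd,
        kept=kept,
        ddof=ddof,
    )


def apply_autoscaler(table: ModelingTable, params: ScalingParams) -> np.ndarray:
    """Scale *table*'s descriptors with training parameters.

    Returns the matrix of retained columns only, transformed to
    ``(x - mean) / sd``.  Dropped columns are removed consistently from
    every partition.
    """
    names = table.descriptor_names
    missing = [n for n in params.column_names if n not in names]
    if missing:
        raise KeyError(f"columns in scaling params missing from table: {missing}")
    order = [names.index(n) for n in params.column_names]
    X = table.X[:, order]
    k = params.kept
    return (X[:, k] - params.mean[k]) / params.sd[k]


def scale_matrix(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Scale a raw matrix whose columns already follow ``params.column_names`` order."""
    k = params.kept
    return (np.asarray(X, dtype=float)[:, k] - params.mean[k]) / params.sd[k]


def invert_autoscaler(X_scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Map scaled values of the retained columns back to raw units."""
    k = params.kept
    return np.asarray(X_scaled, dtype=float) * params.sd[k] + params.mean[k]
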