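"""Goodness-of-fit, leave-one-out cross-validation and external validation.

Statistics follow the standard QSAR battery:

    R^2      = 1 - SS_res / SS_tot            (training fit)
    RMSEC    = sqrt(SS_res / n_train)
    Q^2_cv   = 1 - PRESS / SS_tot             (LOO, training-mean reference)
    RMSECV   = sqrt(PRESS / n_train)
    Q^2_ext  = 1 - SS_V / sum_V (y - mean(y_train))^2    (Q^2 F1)
    RMSEP    = sqrt(SS_V / n_V)

LOO is fully honest: for every fold both the autoscaler and the PLS
model are refit on the remaining rows, and descriptors that become
constant within the fold are dropped for that fold.  On datasets where
a binary fingerprint bit is carried by a single training sample
(e.g. a protein adsorbed on one nanoparticle only), holding that sample
out removes the bit from the fold entirely, so the fold model cannot
predict its effect — this is what makes RMSECV much larger than RMSEP
on such data, and the per-sample LOO table makes the mechanism visible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ModelingTable
from .preprocess import DEFAULT_DDOF
from .pls import PLSModel, _nipals_pls1, fit_pls

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """All validation statistics plus per-sample prediction tables."""

    R2: float
    RMSEC: float
    Q2_cv: float
    RMSECV: float
    Q2_ext: float | None
    RMSEP: float | None
    train: pd.DataFrame        # structure_id, observed, predicted, residual
    loo: pd.DataFrame          # structure_id, observed, predicted, residual, dropped, n_lv
    validation: pd.DataFrame   # structure_id, observed, predicted, residual
    notes: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "R2": self.R2,
            "RMSEC": self.RMSEC,
            "Q2_cv": self.Q2_cv,
            "RMSECV": self.RMSECV,
            "Q2_ext": self.Q2_ext,
            "RMSEP": self.RMSEP,
            "notes": self.notes,
        }

    def to_files(self, directory: str | Path, stem: str = "validation") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{stem}_summary.json").write_text(json.dumps(self.summary(), indent=1))
        for name, df in (("train", self.train), ("loo", self.loo), ("validation", self.validation)):
            df.to_csv(directory / f"{stem}_{name}.csv", index=False)


def fit_statistics(model: PLSModel, table: ModelingTable) -> tuple[float, float]:
    """R^2 and RMSEC of *model* on the training rows of *table*."""
    tr = table.training()
    y = tr.y
    yhat = model.predict_table(tr)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot, float(np.sqrt(ss_res / len(y)))


def loo_cross_validate(
    table: ModelingTable,
    n_lv: int,
    descriptors: list[str] | None = None,
    ddof: int = DEFAULT_DDOF,
    q2_reference: str = "train_mean",
) -> tuple[float, float, pd.DataFrame]:
    """Leave-one-out cross-validation with per-fold rescaling.

    For each training sample the scaler and PLS model are refit from
    scratch on the remaining rows; descriptors with zero variance in the
    fold are dropped and, if the fold rank falls below ``n_lv``, the
    component count is reduced for that fold (logged).  Returns
    (Q^2_cv, RMSECV, per-sample LOO table).  ``q2_reference`` selects the
    reference mean of Q^2_cv: the full-training mean (default, common in
    QSAR software) or the per-fold mean ("fold_mean").
    """
    if descriptors is not None:
        table = table.subset_descriptors(descriptors)
    tr = table.training()
    if tr.n_samples == 0:
        tr = table
    n = tr.n_samples
    if n < 3:
        raise ValueError("LOO needs at least 3 training samples")
    X, y = tr.X, tr.y
    ids = tr.structure_ids
    names = np.array(tr.descriptor_names)
    rows = []
    press = 0.0
    ref_full = y.mean()
    ss_ref = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xf, yf = X[mask], y[mask]
        mean = Xf.mean(axis=0)
        sd = Xf.std(axis=0, ddof=ddof)
        keep = sd > 0
        Xs = (Xf[:, keep] - mean[keep]) / sd[keep]
        y_mean = yf.mean()
        rank = np.linalg.matrix_rank(Xs)
        a = min(n_lv, int(rank))
        if a < 1:
            raise ValueError(f"fold holding out {ids[i]!r} has rank-0 descriptor matrix")
        b = None
        while a >= 1:
            try:
                *_, b = _nipals_pls1(Xs, yf - y_mean, a, rank=int(rank))
                break
            except ValueError:
                a -= 1
        if b is None:
            raise ValueError(f"fold holding out {ids[i]!r} is unfittable")
        if a < n_lv:
            logger.info("fold holding out %s: n_lv reduced to %d", ids[i], a)
        xs_i = (X[i, keep] - mean[keep]) / sd[keep]
        pred = float(xs_i @ b + y_mean)
        resid = y[i] - pred
        press += resid**2
        ref = ref_full if q2_reference == "train_mean" else y_mean
        ss_ref += (y[i] - ref) ** 2
        rows.append(
            {
                "structure_id": ids[i],
                "observed": y[i],
                "predicted": pred,
                "residual": resid,
                "n_lv": a,
                "dropped_in_fold": ";".join(names[~keep]),
            }
        )
    q2 = 1.0 - press / ss_ref
    rmsecv = float(np.sqrt(press / n))
    return q2, rmsecv, pd.DataFrame(rows)


def external_validate(model: PLSModel, table: ModelingTable) -> tuple[float | None, float | None, pd.DataFrame]:
    """Q^2_ext (Q^2 F1, training-mean reference) and RMSEP on the validation rows."""
    va = table.validation()
    if va.n_samples == 0:
        return None, None, pd.DataFrame(
            columns=["structure_id", "observed", "predicted", "residual"]
        )
    y = va.y
    yhat = model.predict_table(va)
    ss = float(np.sum((y - yhat) ** 2))
    ss_ref = float(np.sum((y - model.y_mean) ** 2))
    if ss_ref == 0.0:
        # all validation endpoints sit at the training mean: Q2F1 undefined
        ss_ref = np.nan
    df = pd.DataFrame(
        {
            "structure_id": va.structure_ids,
            "observed": y,
            "predicted": yhat,
            "residual": y - yhat,
        }
    )
    return 1.0 - ss / ss_ref, float(np.sqrt(ss / len(y))), df


def validate_model(
    table: ModelingTable,
    n_lv: int,
    descriptors: list[str] | None = None,
    ddof: int = DEFAULT_DDOF,
) -> tuple[PLSModel, ValidationReport]:
    """Fit on the training rows and run the full validation battery."""
    if descriptors is not None:
        table = table.subset_descriptors(descriptors)
    model = fit_pls(table, n_lv, ddof=ddof)
    r2, rmsec = fit_statistics(model, table)
    q2cv, rmsecv, loo_df = loo_cross_validate(table, n_lv, ddof=ddof)
    q2ext, rmsep, val_df = external_validate(model, table)
    tr = table.training()
    yhat_t = model.predict_table(tr)
    train_df = pd.DataFrame(
        {
            "structure_id": tr.structure_ids,
            "observed": tr.y,
            "predicted": yhat_t,
            "residual": tr.y - yhat_t,
        }
    )
    notes = []
    singleton = loo_df[loo_df["dropped_in_fold"] != ""]
    if not singleton.empty:
        notes.append(
            "LOO folds holding out "
            + ", ".join(singleton["structure_id"])
            + " lose descriptor(s) "
            + ", ".join(sorted(set(";".join(singleton["dropped_in_fold"]).split(";"))))
            + " to the zero-variance drop; these folds dominate RMSECV, which is why "
            "RMSECV can greatly exceed RMSEP on data with singleton fingerprint bits."
        )
    report = ValidationReport(
        R2=r2,
        RMSEC=rmsec,
        Q2_cv=q2cv,
        RMSECV=rmsecv,
        Q2_ext=q2ext,
        RMSEP=rmsep,
        train=train_df,
        loo=loo_df,
        validation=val_df,
        notes=notes,
    )
    return model, report
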