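"""PLS1 regression via NIPALS with latent-vector variance accounting.

Partial least squares projects the autoscaled descriptor matrix X onto a
small number of latent vectors (LVs) — orthogonal score directions t_a
chosen to maximize covariance with the endpoint — and regresses the
centered endpoint on those scores.  For a single response the NIPALS
weights come directly from X'y at each step, so the algorithm is exact
and deterministic: no iteration or random initialization is involved.

Per component a:

    w_a = X_a' y_a / ||X_a' y_a||      (unit weight vector)
    t_a = X_a w_a                      (scores)
    p_a = X_a' t_a / (t_a' t_a)        (x-loadings)
    q_a = y_a' t_a / (t_a' t_a)        (y-loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a   (deflation)

The regression vector on the original scaled X is b = W (P'W)^-1 q.
Explained variance per LV is 100·||t_a p_a'||_F^2 / ||X||_F^2 for the
descriptor block and the per-component drop in residual y sum of squares
over the total centered y sum of squares for the endpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import ModelingTable
from .preprocess import (
    DEFAULT_DDOF,
    ScalingParams,
    apply_autoscaler,
    fit_autoscaler,
    scale_matrix,
)


@dataclass
class PLSModel:
    """Fitted PLS1 state, including the training scaling parameters.

    Coefficients are stored both in scaled space (``b_std``, mV per
    descriptor SD — the "standardized coefficients") and in raw
    descriptor units (``b_raw`` plus ``intercept``).
    """

    n_lv: int
    descriptor_names: list[str]        # retained (post zero-variance drop) columns
    weights: np.ndarray                # W, (p, A)
    x_scores: np.ndarray               # T, (n, A)
    x_loadings: np.ndarray             # P, (p, A)
    y_loadings: np.ndarray             # q, (A,)
    b_std: np.ndarray                  # (p,), scaled-space coefficients
    b_raw: np.ndarray                  # (p,), raw-space coefficients
    intercept: float                   # raw-space intercept, mV
    x_variance_pct: np.ndarray         # (A,), % of ||X||_F^2 per LV
    y_variance_pct: np.ndarray         # (A,), % of centered-y SS per LV
    scaling: ScalingParams
    y_mean: float
    Xs_train: np.ndarray | None = None  # scaled training X, (n, p); needed for leverages

    # -- prediction ------------------------------------------------------

    def predict_scaled(self, X_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(X_scaled, dtype=float) @ self.b_std + self.y_mean

    def predict_raw(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict from raw descriptor rows ordered as ``scaling.column_names``."""
        return self.predict_scaled(scale_matrix(X_raw, self.scaling))

    def predict_table(self, table: ModelingTable) -> np.ndarray:
        return self.predict_scaled(apply_autoscaler(table, self.scaling))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a: np.ndarray) -> list:
            return np.asarray(a, dtype=float).tolist()

        return {
            "n_lv": self.n_lv,
            "descriptor_names": self.descriptor_names,
            "weights": arr(self.weights),
            "x_scores": arr(self.x_scores),
            "x_loadings": arr(self.x_loadings),
            "y_loadings": arr(self.y_loadings),
            "b_std": arr(self.b_std),
            "b_raw": arr(self.b_raw),
            "intercept": self.intercept,
            "x_variance_pct": arr(self.x_variance_pct),
            "y_variance_pct": arr(self.y_variance_pct),
            "y_mean": self.y_mean,
            "Xs_train": None if self.Xs_train is None else arr(self.Xs_train),
            "scaling": {
                "column_names": self.scaling.column_names,
                "mean": arr(self.scaling.mean),
                "sd": arr(self.scaling.sd),
                "kept": np.asarray(self.scaling.kept, dtype=bool).tolist(),
                "ddof": self.scaling.ddof,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        sc = d["scaling"]
        scaling = ScalingParams(
            column_names=list(sc["column_names"]),
            mean=np.array(sc["mean"], dtype=float),
            sd=np.array(sc["sd"], dtype=float),
            kept=np.array(sc["kept"], dtype=bool),
            ddof=int(sc["ddof"]),
        )
        return cls(
            n_lv=int(d["n_lv"]),
            descriptor_names=list(d["descriptor_names"]),
            weights=np.array(d["weights"], dtype=float),
            x_scores=np.array(d["x_scores"], dtype=float),
            x_loadings=np.array(d["x_loadings"], dtype=float),
            y_loadings=np.array(d["y_loadings"], dtype=float),
            b_std=np.array(d["b_std"], dtype=float),
            b_raw=np.array(d["b_raw"], dtype=float),
            intercept=float(d["intercept"]),
            x_variance_pct=np.array(d["x_variance_pct"], dtype=float),
            y_variance_pct=np.array(d["y_variance_pct"], dtype=float),
            scaling=scaling,
            y_mean=float(d["y_mean"]),
            Xs_train=(
                None if d.get("Xs_train") is None else np.array(d["Xs_train"], dtype=float)
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, n_lv: int, rank: int | None = None):
    """Core NIPALS-PLS1 decomposition of scaled X and centered y."""
    n, p = Xs.shape
    if n < 2:
        raise ValueError("PLS needs at least 2 rows")
    if rank is None:
        rank = np.linalg.matrix_rank(Xs)
    if not 1 <= n_lv <= rank:
        raise ValueError(f"n_lv={n_lv} outside [1, rank(X)={rank}]")
    if np.allclose(yc, 0):
        raise ValueError("endpoint is constant (all-zero after centering)")
    Xd, yd = Xs.astype(float).copy(), yc.astype(float).copy()
    W = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"residual X'y vanished at component {a + 1}; reduce n_lv")
        w /= norm
        t = Xd @ w
        tt = t @ t
        p_a = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd -= np.outer(t, p_a)
        yd -= q_a * t  # no-op for predictions in PLS1, kept for variance accounting
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
    b = W @ np.linalg.solve(P.T @ W, q)
    return W, T, P, q, b


def fit_pls(
    table: ModelingTable,
    n_lv: int,
    descriptors: list[str] | None = None,
    ddof: int = DEFAULT_DDOF,
    rows: np.ndarray | None = None,
) -> PLSModel:
    """Autoscale the training rows of *table* and fit an ``n_lv``-component PLS1 model.

    ``descriptors`` restricts the model to a subset of columns (default:
    all).  ``rows`` overrides the training mask.  Descriptors constant
    over the training rows are dropped before fitting.
    """
    if descriptors is not None:
        table = table.subset_descriptors(descriptors)
    if rows is None:
        rows = table.train_mask
        if not rows.any():
            rows = np.ones(table.n_samples, dtype=bool)
    scaling = fit_autoscaler(table, rows=rows, ddof=ddof)
    Xs = apply_autoscaler(table.subset_rows(rows), scaling)
    y = table.y[rows]
    y_mean = float(y.mean())
    yc = y - y_mean
    W, T, P, q, b = _nipals_pls1(Xs, yc, n_lv)

    total_x = np.sum(Xs**2)
    x_var = np.array(
        [100.0 * (T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) / total_x for a in range(n_lv)]
    )
    total_y = np.sum(yc**2)
    y_var = np.empty(n_lv)
    resid = yc.copy()
    for a in range(n_lv):
        before = resid @ resid
        resid = resid - q[a] * T[:, a]
        y_var[a] = 100.0 * (before - resid @ resid) / total_y

    k = scaling.kept
    b_raw = np.zeros(len(scaling.column_names))
    b_raw[k] = b / scaling.sd[k]
    intercept = y_mean - float(b_raw[k] @ scaling.mean[k])

    return PLSModel(
        n_lv=n_lv,
        descriptor_names=scaling.kept_names,
        weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
        b_std=b,
        b_raw=b_raw[k],
        intercept=intercept,
        x_variance_pct=x_var,
        y_variance_pct=y_var,
        scaling=scaling,
        y_mean=y_mean,
        Xs_train=Xs,
    )


def explained_variance(model: PLSModel) -> list[tuple[float, float]]:
    """Per-LV (X%, Y%) explained-variance pairs."""
    return list(zip(model.x_variance_pct.tolist(), model.y_variance_pct.tolist()))


def standardized_coefficients(model: PLSModel) -> dict[str, float]:
    """Named scaled-space coefficients (mV per descriptor SD); positive increases zeta."""
    return dict(zip(model.descriptor_names, model.b_std.tolist()))


def raw_equation(model: PLSModel) -> dict[str, float]:
    """The fitted model in original descriptor units, including the intercept."""
    eq = {"intercept": model.intercept}
    eq.update(zip(model.descriptor_names, model.b_raw.tolist()))
    return eq
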