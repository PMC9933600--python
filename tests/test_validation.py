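"""Validation battery: fit statistics, honest LOO, external validation."""

import numpy as np
import pytest

from nanoqspr import (
    external_validate,
    fit_pls,
    fit_statistics,
    loo_cross_validate,
    validate_model,
)

from test_data_model import make_table


def brute_force_loo(table, n_lv, ddof=0):
    """Independent oracle: rebuild every fold from scratch via the public API."""
    tr = table.training()
    if tr.n_samples == 0:
        tr = table
    n = tr.n_samples
    press = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = tr.subset_rows(mask)
        # relabel everything T so fit_pls trains on the full fold
        fold = make_table(
            fold.X, fold.y, splits=["T"] * fold.n_samples,
            kinds=[c.kind for c in fold.columns], blocks=[c.block for c in fold.columns],
        )
        a = n_lv
        model = None
        while a >= 1:
            try:
                model = fit_pls(fold, a, ddof=ddof)
                break
            except ValueError:
                a -= 1
        probe = make_table(
            tr.X[[i]], tr.y[[i]],
            kinds=[c.kind for c in fold.columns], blocks=[c.block for c in fold.columns],
        )
        press.append((tr.y[i] - model.predict_table(probe)[0]) ** 2)
    return float(np.sqrt(np.mean(press)))


class TestFitStatistics:
    def test_perfect_predictions(self):
        t = make_table([[1.0], [2.0], [3.0], [4.0]], [2, 4, 6, 8], splits=["T"] * 4)
        model = fit_pls(t, 1)
        r2, rmsec = fit_statistics(model, t)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert rmsec == pytest.approx(0.0, abs=1e-10)

    def test_mean_only_predictions_r2_zero(self, rng):
        # a model reduced to the training mean scores R^2 = 0, RMSEC = sd(y)
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        t = make_table(X, y, splits=["T"] * 6)
        model = fit_pls(t, 1)
        model.b_std = np.zeros_like(model.b_std)
        r2, rmsec = fit_statistics(model, t)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert rmsec == pytest.approx(y.std(), abs=1e-12)


class TestLOO:
    def test_exact_linear_relationship_gives_zero_rmsecv(self):
        t = make_table([[1.0], [2.0], [3.0], [4.0]], [10, 20, 30, 40], splits=["T"] * 4)
        q2, rmsecv, df = loo_cross_validate(t, 1)
        assert rmsecv == pytest.approx(0.0, abs=1e-9)
        assert q2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng, table1):
        assert loo_cross_validate(table1, 2)[1] == pytest.approx(
            brute_force_loo(table1, 2), abs=1e-10
        )
        X = rng.normal(size=(12, 4))
        y = X @ np.array([3.0, -1.0, 0.0, 2.0]) + rng.normal(scale=0.5, size=12)
        t = make_table(X, y, splits=["T"] * 12)
        assert loo_cross_validate(t, 2)[1] == pytest.approx(brute_force_loo(t, 2), abs=1e-10)

    def test_singleton_bits_documented_in_loo_table(self, table1):
        _, _, df = loo_cross_validate(table1, 2)
        dropped = dict(zip(df["structure_id"], df["dropped_in_fold"]))
        assert dropped["7"] == "CC1rs"
        assert dropped["5"] == "kininogen-1"
        assert all(v == "" for k, v in dropped.items() if k not in ("5", "7"))

    def test_singleton_folds_drive_rmsecv(self, table1):
        _, rmsecv, df = loo_cross_validate(table1, 2)
        sq = df["residual"] ** 2
        share = sq[df["structure_id"].isin(["5", "7"])].sum() / sq.sum()
        assert share > 0.5

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        t = make_table(X, y, splits=["T"] * 10)
        perm = rng.permutation(10)
        t2 = make_table(X[perm], y[perm], splits=["T"] * 10)
        assert loo_cross_validate(t, 2)[1] == pytest.approx(
            loo_cross_validate(t2, 2)[1], abs=1e-12
        )

    def test_duplicated_sample_loo_approaches_fit(self, rng):
        # with every sample duplicated, each fold still contains a copy of
        # the held-out point, so RMSECV approaches RMSEC
        X = rng.normal(size=(8, 2))
        y = X @ np.array([2.0, -1.0]) + rng.normal(scale=0.3, size=8)
        k = 10
        Xd = np.repeat(X, k, axis=0) + rng.normal(scale=1e-9, size=(8 * k, 2))
        yd = np.repeat(y, k)
        ids_t = make_table(Xd, yd, splits=["T"] * (8 * k))
        model = fit_pls(ids_t, 2)
        _, rmsec = fit_statistics(model, ids_t)
        _, rmsecv, _ = loo_cross_validate(ids_t, 2)
        assert rmsecv == pytest.approx(rmsec, rel=0.05)


class TestExternalValidation:
    def test_q2f1_rmsep_consistency_identity(self, fixture_validation, table1):
        _, report = fixture_validation
        n_v = int(table1.validation_mask.sum())
        y_train_mean = table1.training().y.mean()
        ss_ref = np.sum((table1.validation().y - y_train_mean) ** 2)
        lhs = report.Q2_ext
        rhs = 1 - n_v * report.RMSEP**2 / ss_ref
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_reference_sum_from_printed_endpoints(self, fixture_validation):
        # arithmetic oracle: the 14 training endpoints sum to -110, so the
        # training mean is -55/7; the 6 validation endpoints give the
        # reference sum of squares below
        _, report = fixture_validation
        y_v = [-50, -20, -10, -4, 10, 20]
        mean_t = -110 / 14
        ss_ref = sum((v - mean_t) ** 2 for v in y_v)
        press = sum(report.validation["residual"] ** 2)
        assert report.Q2_ext == pytest.approx(1 - press / ss_ref, abs=1e-10)

    def test_predictions_at_train_mean_give_q2_zero(self):
        t = make_table(
            [[0.0], [1.0], [2.0], [1.0], [3.0]],
            [0, 10, 20, 5, 25],
            splits=["T", "T", "T", "V", "V"],
        )
        model = fit_pls(t, 1)
        # force the model to predict the training mean by zeroing coefficients
        model.b_std = np.zeros_like(model.b_std)
        q2, rmsep, _ = external_validate(model, t)
        assert q2 == pytest.approx(0.0, abs=1e-12)

    def test_no_validation_rows(self, rng):
        t = make_table(rng.normal(size=(5, 2)), rng.normal(size=5), splits=["T"] * 5)
        model = fit_pls(t, 1)
        q2, rmsep, df = external_validate(model, t)
        assert q2 is None and rmsep is None and df.empty


def test_validate_model_report_consistency(fixture_validation):
    model, report = fixture_validation
    assert report.RMSEC < report.RMSEP < report.RMSECV
    assert len(report.train) == 14
    assert len(report.validation) == 6
    assert len(report.loo) == 14
    assert report.notes  # singleton-bit mechanism is documented
    assert "5" in report.notes[0] and "7" in report.notes[0]
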