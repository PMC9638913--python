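"""AUROC, L1 logistic regression, strength optimization, simplification."""

import numpy as np
import pandas as pd
import pytest

from ssmotif.regress import (
    L1_SCALING,
    ModelError,
    MotifModel,
    Standardizer,
    apply_model,
    compute_auroc,
    fit_l1_logreg,
    optimize_l1,
    simplify_model,
)
from ssmotif.scan import FeatureMatrix

from conftest import consensus_pfm


def concordance_auroc(pos, neg):
    """Oracle: exhaustive pairwise concordance counting with half-ties."""
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def prox_l1_logreg(X, y, lam, iters=300_000, lr=0.005):
    """Oracle optimizer: proximal gradient on sum log-loss + lam * ||w||_1."""
    n, p = X.shape
    w = np.zeros(p)
    b = 0.0
    for _ in range(iters):
        z = X @ w + b
        mu = 1.0 / (1.0 + np.exp(-z))
        g_w = X.T @ (mu - y)
        g_b = float(np.sum(mu - y))
        w = w - lr * g_w
        b = b - lr * g_b
        w = np.sign(w) * np.maximum(np.abs(w) - lr * lam, 0.0)  # soft threshold
    return w, b


def feature_matrix(X, y, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=names)
    pfms = [consensus_pfm("sequence", "ACGU", name=n) for n in names]
    return FeatureMatrix(frame, np.asarray(y), pfms)


class TestAuroc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([3, 4], [1, 2], 1.0),
            ([1, 2, 3], [1, 2, 3], 0.5),
            ([3, 1], [2, 0], 0.75),
            ([0, 0], [0, 0], 0.5),
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert compute_auroc(pos, neg) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ModelError):
            compute_auroc([], [1.0])

    def test_concordance_oracle(self, rng):
        """Rank-based AUROC equals exhaustive pairwise concordance counting."""
        for _ in range(30):
            n_pos = int(rng.integers(1, 50))
            n_neg = int(rng.integers(1, 50))
            # integer scores force ties
            pos = rng.integers(0, 10, size=n_pos).astype(float)
            neg = rng.integers(0, 10, size=n_neg).astype(float)
            assert compute_auroc(pos, neg) == pytest.approx(
                concordance_auroc(pos, neg), abs=1e-12
            )


class TestFitL1:
    def test_separating_feature_selected(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 3))
        X[:, 1] = y * 2 - 1 + rng.normal(scale=0.05, size=n)
        X = Standardizer.fit(X).transform(X)
        coef, _ = fit_l1_logreg(X, y, l1_strength=1.0, seed=0)
        assert coef[1] > 0
        assert abs(coef[1]) > 10 * max(abs(coef[0]), abs(coef[2]), 1e-12)

    def test_full_shrinkage_limit(self, rng):
        n = 300
        y = (rng.random(n) < 2 / 3).astype(int)  # unbalanced classes
        X = rng.normal(size=(n, 4))
        coef, intercept = fit_l1_logreg(X, y, l1_strength=1e8, seed=0)
        assert np.allclose(coef, 0.0, atol=1e-6)
        p = y.mean()
        assert intercept == pytest.approx(np.log(p / (1 - p)), abs=0.02)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ModelError):
            fit_l1_logreg(rng.normal(size=(10, 2)), np.ones(10), 1.0)

    def test_tiny_dataset_matches_prox_oracle(self):
        """Six points, two features: agrees with an independent optimizer."""
        X = np.array(
            [[1.0, 0.2], [0.8, -0.1], [0.6, 0.4], [-0.5, 0.1], [-0.9, -0.3], [-0.7, 0.2]]
        )
        y = np.array([1, 1, 1, 0, 0, 0])
        lam = 0.5
        w_ref, b_ref = prox_l1_logreg(X, y, lam)
        coef, intercept = fit_l1_logreg(X, y, lam, seed=0, tol=1e-10, max_iter=200000)
        np.testing.assert_allclose(coef, w_ref, atol=1e-4)
        assert intercept == pytest.approx(b_ref, abs=1e-4)


class TestOptimizeL1:
    def test_singleton_grid(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.repeat([0, 1], 30)
        assert optimize_l1(X, y, grid=[0.37]) == pytest.approx(0.37)

    def test_pure_noise_model_near_chance(self, rng):
        n = 400
        X = rng.normal(size=(n, 10))
        y = np.repeat([0, 1], n // 2)
        lam = optimize_l1(X, y, seed=1)
        std = Standardizer.fit(X)
        coef, intercept = fit_l1_logreg(std.transform(X), y, lam, seed=1)
        X_test = rng.normal(size=(n, 10))
        y_test = np.repeat([0, 1], n // 2)
        scores = std.transform(X_test) @ coef + intercept
        auroc = concordance_auroc(scores[y_test == 1], scores[y_test == 0])
        assert 0.4 <= auroc <= 0.6

    def test_informative_feature_survives(self, rng):
        n = 400
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 8))
        X[:, 3] += y * 1.5
        lam = optimize_l1(X, y, seed=2)
        std = Standardizer.fit(X)
        coef, _ = fit_l1_logreg(std.transform(X), y, lam, seed=2)
        assert coef[3] > 0


class TestSimplify:
    def _planted(self, rng, n=400, p=6):
        y = np.tile([0, 1], n // 2)
        X = rng.normal(size=(n, p))
        X[:, 0] += y * 2.0
        X[:, 1] += y * 0.5
        return X, y

    def test_trace_ratios_and_retention(self, rng):
        X, y = self._planted(rng)
        Xv, yv = self._planted(rng)
        model = simplify_model(feature_matrix(X, y), feature_matrix(Xv, yv), 0.5, seed=0)
        strengths = [t["l1_strength"] for t in model.trace]
        for a, b in zip(strengths, strengths[1:]):
            assert b / a == pytest.approx(L1_SCALING)
        threshold = 0.5 + 0.9 * (model.initial_auroc - 0.5)
        assert model.final_auroc >= threshold
        # rejected step, if any, is the last trace entry
        rejected = [i for i, t in enumerate(model.trace) if not t["accepted"]]
        assert rejected in ([], [len(model.trace) - 1])

    def test_retained_are_nonzero_coefficients(self, rng):
        X, y = self._planted(rng)
        Xv, yv = self._planted(rng)
        model = simplify_model(feature_matrix(X, y), feature_matrix(Xv, yv), 0.5, seed=0)
        assert len(model.retained) == int(np.count_nonzero(model.coefficients))
        assert len(model.retained) >= 1

    def test_uninformative_returns_initial_with_warning(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = np.tile([0, 1], n // 2)
        Xv = rng.normal(size=(n, 3))
        with pytest.warns(UserWarning, match="AUROC"):
            model = simplify_model(
                feature_matrix(X, y), feature_matrix(Xv, y), 1e6, seed=0
            )
        assert len(model.trace) == 1

    def test_roundtrip_json(self, rng, tmp_path):
        X, y = self._planted(rng)
        Xv, yv = self._planted(rng)
        model = simplify_model(feature_matrix(X, y), feature_matrix(Xv, yv), 0.5, seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = MotifModel.load(path)
        np.testing.assert_allclose(loaded.coefficients, model.coefficients)
        assert loaded.final_auroc == model.final_auroc
        assert [p.name for p in loaded.pfms] == [p.name for p in model.pfms]


class TestApplyModel:
    def _model(self, consensus="UGCAUG"):
        pfm = consensus_pfm("sequence", consensus, name="m0")
        return MotifModel(
            pfms=[pfm],
            coefficients=np.array([1.5]),
            intercept=-0.5,
            l1_strength=1.0,
            initial_auroc=0.9,
            final_auroc=0.9,
            standardizer=Standardizer(np.array([0.0]), np.array([10.0])),
            feature_names=["m0"],
        )

    def test_empty_model_scores_sigmoid_intercept(self):
        model = self._model()
        model.coefficients = np.array([0.0])
        records = [("a", "ACGUACGUACGU", "............")]
        probs, errors = apply_model(model, records)
        assert probs[0] == pytest.approx(1 / (1 + np.exp(0.5)))
        assert not errors

    def test_permutation_invariance(self, rng):
        model = self._model()
        letters = np.array(list("ACGU"))
        records = [
            (f"p{i}", "".join(letters[rng.integers(0, 4, size=20)]), "." * 20)
            for i in range(10)
        ]
        probs, _ = apply_model(model, records)
        rev_probs, _ = apply_model(model, records[::-1])
        np.testing.assert_allclose(probs, rev_probs[::-1])

    def test_bad_probe_gets_error_record(self):
        model = self._model()
        records = [
            ("good", "ACGUACGUACGU", "............"),
            ("bad", "ACGU", "((.."),  # unbalanced structure
        ]
        probs, errors = apply_model(model, records)
        assert np.isfinite(probs[0])
        assert np.isnan(probs[1])
        assert errors and errors[0][0] == "bad"

    def test_planted_probes_score_higher(self, rng):
        model = self._model()
        letters = np.array(list("ACGU"))
        bg = ["".join(letters[rng.integers(0, 4, size=30)]) for _ in range(40)]
        planted = [s[:10] + "UGCAUG" + s[16:] for s in bg]
        p_bg, _ = apply_model(model, [(f"b{i}", s, "." * 30) for i, s in enumerate(bg)])
        p_pl, _ = apply_model(model, [(f"p{i}", s, "." * 30) for i, s in enumerate(planted)])
        assert p_pl.mean() > p_bg.mean()
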