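"""Embeddings, profile clustering and the similarity -> cargo standard curve."""

import numpy as np
import pandas as pd
import pytest

from autoprofiler.similarity import (
    SimilarityRecord,
    fit_lda,
    fit_standard_curve,
    hcluster_profiles,
    normalize_cargo,
    predict_cargo,
    profile_similarity,
)


def _profile(values, name="p"):
    idx = pd.MultiIndex.from_tuples([(f"f{i}", 0.5) for i in range(len(values))],
                                    names=["feature", "time"])
    return pd.Series(np.asarray(values, dtype=float), index=idx, name=name)


class TestLDA:
    def test_closed_form_direction(self, rng):
        # identity within-class covariance, means (0,0) vs (1,0):
        # w proportional to S_w^-1 (mu1 - mu0) = (1, 0)
        X = np.vstack([rng.normal((0, 0), 1, (500, 2)), rng.normal((1, 0), 1, (500, 2))])
        y = np.repeat([0, 1], 500)
        res = fit_lda(X, y, d=1)
        w = res.projection[:, 0] / np.linalg.norm(res.projection[:, 0])
        assert abs(w[0]) > 0.99

    def test_identical_classes_no_separation(self, rng):
        X = rng.normal(size=(400, 3))
        y = np.repeat([0, 1], 200)
        res = fit_lda(X, y, d=1)
        sep = fit_lda(np.vstack([X[:200] + (5, 0, 0), X[200:]]), y, d=1)
        assert res.eigenvalues[0] < 0.05 * sep.eigenvalues[0]

    def test_singular_scatter_suggests_shrinkage(self, rng):
        x = rng.normal(size=(40, 1))
        X = np.hstack([x, x])  # perfectly collinear features
        y = np.repeat([0, 1], 20)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            fit_lda(X, y)
        res = fit_lda(X, y, shrinkage=0.1)
        assert res.embedding.shape == (40, 1)


class TestHCluster:
    def test_identical_profiles_merge_at_zero(self):
        Z, _ = hcluster_profiles({"a": _profile([1, 2, 3]), "b": _profile([1, 2, 3])})
        assert Z[0, 2] == 0.0

    def test_hand_upgma_example(self):
        # points on a line at 0, 2, 10: A,B merge at 2; C joins at (10+8)/2
        profs = {"A": _profile([0, 0, 0]), "B": _profile([2, 0, 0]),
                 "C": _profile([10, 0, 0])}
        Z, labels = hcluster_profiles(profs)
        assert Z[0, 2] == pytest.approx(2.0)
        assert Z[1, 2] == pytest.approx(9.0)

    def test_order_invariant_heights(self):
        rng = np.random.default_rng(4)
        profs = {k: _profile(rng.normal(size=6)) for k in "abcde"}
        Z1, _ = hcluster_profiles(profs)
        Z2, _ = hcluster_profiles(dict(reversed(profs.items())))
        assert np.allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]))

    def test_index_mismatch_rejected(self):
        a = _profile([1, 2, 3])
        b = a.copy()
        b.index = pd.MultiIndex.from_tuples([(f"g{i}", 0.5) for i in range(3)])
        with pytest.raises(ValueError):
            hcluster_profiles({"a": a, "b": b})


class TestProfileSimilarity:
    def test_self_similarity_is_one(self, rng):
        p = _profile(rng.normal(size=40))
        assert profile_similarity(p, p).r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        p = _profile(rng.normal(size=40))
        assert profile_similarity(p, -p).r == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        a, b = _profile(rng.normal(size=40)), _profile(rng.normal(size=40))
        assert profile_similarity(a, b).r == pytest.approx(profile_similarity(b, a).r)

    def test_programmed_shared_signal_recovered(self, rng):
        # a = s + lam*e1, b = s + lam*e2 share variance fraction 1/(1+lam^2)
        n, lam = 5000, 0.75
        s = rng.normal(size=n)
        a = _profile(s + lam * rng.normal(size=n))
        b = _profile(s + lam * rng.normal(size=n))
        expected = 1 / (1 + lam**2)
        assert profile_similarity(a, b).r == pytest.approx(expected, abs=0.05)

    def test_degenerate_inputs_rejected(self, rng):
        p = _profile(rng.normal(size=40))
        with pytest.raises(ValueError):
            profile_similarity(p, _profile(np.ones(40)))
        with pytest.raises(ValueError):
            profile_similarity(_profile([1.0]), _profile([1.0]))


class TestStandardCurve:
    def _records(self, x):
        return [SimilarityRecord(f"t{i}", "ref", float(v), 50) for i, v in enumerate(x)]

    def test_collinear_points_perfect_fit(self):
        x = np.array([0.1, 0.4, 0.7, 1.0])
        cargo = {f"t{i}": 2 * v + 1 for i, v in enumerate(x)}
        curve = fit_standard_curve(self._records(x), cargo)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-12)
        pred = predict_cargo(curve, SimilarityRecord("new", "ref", 0.55, 50))
        assert pred.predicted == pytest.approx(2 * 0.55 + 1)

    def test_too_few_points_rejected(self):
        x = [0.1, 0.9]
        cargo = {"t0": 1.0, "t1": 2.0}
        with pytest.raises(ValueError):
            fit_standard_curve(self._records(x), cargo)

    def test_prediction_at_mean_similarity_is_mean_cargo(self, rng):
        x = np.linspace(0, 1, 9)
        y = 2 * x + 1 + rng.normal(0, 0.05, 9)
        cargo = dict(zip([f"t{i}" for i in range(9)], y))
        curve = fit_standard_curve(self._records(x), cargo)
        pred = predict_cargo(curve, SimilarityRecord("new", "ref", float(x.mean()), 50))
        assert pred.predicted == pytest.approx(y.mean())
        assert not pred.extrapolated

    def test_extrapolation_flagged(self, rng):
        x = np.linspace(0, 1, 5)
        cargo = {f"t{i}": float(v) for i, v in enumerate(2 * x)}
        curve = fit_standard_curve(self._records(x), cargo)
        assert predict_cargo(curve, SimilarityRecord("n", "ref", 1.4, 50)).extrapolated

    def test_band_widens_away_from_mean(self, rng):
        x = np.linspace(0, 1, 9)
        y = 2 * x + 1 + rng.normal(0, 0.1, 9)
        curve = fit_standard_curve(self._records(x),
                                   dict(zip([f"t{i}" for i in range(9)], y)))
        _, lo_mid, hi_mid = curve.mean_ci(np.array([float(x.mean())]))
        _, lo_edge, hi_edge = curve.mean_ci(np.array([0.0]))
        assert (hi_edge - lo_edge) > (hi_mid - lo_mid)

    def test_affine_equivariance_in_cargo_units(self, rng):
        x = np.linspace(0, 1, 7)
        y = 1.5 * x + 0.3 + rng.normal(0, 0.05, 7)
        names = [f"t{i}" for i in range(7)]
        c1 = fit_standard_curve(self._records(x), dict(zip(names, y)))
        c2 = fit_standard_curve(self._records(x), dict(zip(names, 10 * y + 4)))
        p1 = predict_cargo(c1, SimilarityRecord("n", "ref", 0.5, 50))
        p2 = predict_cargo(c2, SimilarityRecord("n", "ref", 0.5, 50))
        assert p2.predicted == pytest.approx(10 * p1.predicted + 4)
        assert (p2.upper - p2.lower) == pytest.approx(10 * (p1.upper - p1.lower))

    def test_training_treatment_warns(self, rng):
        x = np.linspace(0, 1, 5)
        cargo = {f"t{i}": float(2 * v + rng.normal(0, 0.01)) for i, v in enumerate(x)}
        curve = fit_standard_curve(self._records(x), cargo)
        with pytest.warns(UserWarning):
            predict_cargo(curve, SimilarityRecord("t0", "ref", 0.0, 50))


def test_normalize_cargo_reference_is_one():
    out = normalize_cargo({"rapa": 4.0, "wort": 1.0}, "rapa")
    assert out["rapa"] == 1.0 and out["wort"] == 0.25
    with pytest.raises(ValueError):
        normalize_cargo({"wort": 1.0}, "rapa")
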