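"""Single-component PLS: closed-form weights vs grid oracle, threshold, scoring."""

import numpy as np
import pandas as pd
import pytest

from plspair import SimConfig, fit, fit_weights, generate_cohort, select_threshold
from plspair.io import NONRESPONDER, RESPONDER
from plspair.pls import PLSModel, ThresholdResult


def labels_pm(y):
    return np.asarray(y, dtype=float)


def make_two_gene(seed, n=40, d1=1.0, d2=-1.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1.0, -1.0], n // 2)
    X = np.column_stack(
        [d1 / 2 * y + rng.normal(size=n), d2 / 2 * y + rng.normal(size=n)]
    )
    return X, y


def grid_oracle_angle(X, y, n_grid=100_000):
    """Brute-force sweep of unit vectors on the circle maximizing cov^2(Xw, y)."""
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    yc = y - y.mean()
    angles = np.linspace(0, np.pi, n_grid, endpoint=False)  # w and -w equivalent
    W = np.column_stack([np.cos(angles), np.sin(angles)])
    cov = (Xs @ W.T).T @ yc / (len(y) - 1)
    return angles[np.argmax(cov**2)]


def angle_distance(a, b):
    """Distance between undirected angles on the half-circle."""
    d = abs(a - b) % np.pi
    return min(d, np.pi - d)


def test_weights_match_grid_search_oracle():
    X, y = make_two_gene(seed=1)
    w = fit_weights(X, y)
    fitted_angle = np.arctan2(w[1], w[0]) % np.pi
    assert angle_distance(fitted_angle, grid_oracle_angle(X, y)) < 1e-3


def test_degenerate_direction_all_signal_in_one_gene():
    rng = np.random.default_rng(2)
    y = np.repeat([1.0, -1.0], 20)
    noise = rng.normal(size=40)
    noise -= noise @ y / (y @ y) * y  # exactly orthogonal to the response
    X = np.column_stack([y, 1e-6 * noise])
    w = fit_weights(X, y)
    assert w[0] == pytest.approx(1.0, abs=1e-9)
    assert abs(w[1]) < 1e-9


def test_unit_norm_and_printed_weight_pairs():
    for seed in range(20):
        X, y = make_two_gene(seed)
        w = fit_weights(X, y)
        assert np.sum(w**2) == pytest.approx(1.0, abs=1e-9)
    # published paired-gene weight values are consistent with a unit-norm
    # single-component reading, to the printed precision
    assert (-0.8251) ** 2 + 0.5650**2 == pytest.approx(1.0, abs=5e-4)
    assert (-0.7780) ** 2 + 0.6282**2 == pytest.approx(1.0, abs=5e-4)


def test_sign_convention_puts_responders_higher():
    for seed in range(10):
        X, y = make_two_gene(seed, d1=-1.5, d2=1.5)
        w = fit_weights(X, y)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        s = Xs @ w
        assert s[y > 0].mean() > s[y < 0].mean()


def test_label_coding_does_not_change_direction():
    X, y = make_two_gene(seed=3)
    w_pm = fit_weights(X, y)
    w_01 = fit_weights(X, (y > 0).astype(float))
    text = np.where(y > 0, RESPONDER, NONRESPONDER)
    w_text = fit_weights(X, text)
    np.testing.assert_allclose(w_pm, w_01, atol=1e-12)
    np.testing.assert_allclose(w_pm, w_text, atol=1e-12)


def test_planted_sign_recovery_across_replicates():
    """Opposite planted effects yield opposite-sign weights (lnc +, mRNA -)."""
    hits = 0
    for seed in range(200):
        X, y = make_two_gene(seed, n=100, d1=1.5, d2=-1.5)
        w = fit_weights(X, y)
        hits += w[0] > 0 > w[1]
    assert hits >= 190


def test_fit_errors():
    X, y = make_two_gene(seed=4)
    Xconst = X.copy()
    Xconst[:, 1] = 3.0
    with pytest.raises(ValueError, match="zero-variance"):
        fit_weights(pd.DataFrame(Xconst, columns=["g1", "g2"]), y)
    with pytest.raises(ValueError, match="each class"):
        fit_weights(X, np.ones_like(y))


def test_threshold_simple_separation():
    scores = np.array([1.0, 2.0, 3.0, -1.0, 0.0])
    labels = np.array([1.0, 1.0, 1.0, -1.0, -1.0])
    res = select_threshold(scores, labels)
    assert res.threshold == pytest.approx(0.5)
    assert res.youden_j == pytest.approx(1.0)
    assert not res.degenerate


def test_threshold_degenerate_identical_scores():
    res = select_threshold(np.full(6, 2.5), [1, 1, 1, -1, -1, -1])
    assert res == ThresholdResult(2.5, 0.0, True)


def exhaustive_threshold(scores, y):
    """Evaluate J at every candidate cutoff by direct counting (exact ties)."""
    from fractions import Fraction

    n_pos, n_neg = int((y > 0).sum()), int((y < 0).sum())
    distinct = np.unique(scores)
    cuts = (distinct[:-1] + distinct[1:]) / 2
    best_t, best_j = None, Fraction(-2)
    for t in cuts:
        j = (
            Fraction(int((scores[y > 0] > t).sum()), n_pos)
            + Fraction(int((scores[y < 0] <= t).sum()), n_neg)
            - 1
        )
        if j > best_j:
            best_t, best_j = t, j
    return best_t, float(best_j)


@pytest.mark.parametrize("seed", range(25))
def test_threshold_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    y = np.repeat([1.0, -1.0], [12, 18])
    scores = rng.normal(loc=(y > 0) * 0.8, scale=1.0)
    if seed % 3 == 0:
        scores = np.round(scores, 1)  # inject ties
    res = select_threshold(scores, y)
    t, j = exhaustive_threshold(scores, y)
    assert res.threshold == pytest.approx(t)
    assert res.youden_j == pytest.approx(j)


def _toy_model(weights, threshold=0.0):
    k = len(weights)
    return PLSModel(
        panel=tuple(f"g{i}" for i in range(k)),
        weights=np.asarray(weights, dtype=float),
        center=np.zeros(k),
        scale=np.ones(k),
        threshold=threshold,
    )


def test_score_is_the_stated_linear_combination():
    m = _toy_model([1.0, 0.0])
    assert m.score(np.array([[0.0, 0.0]]))[0] == 0.0
    assert m.score(np.array([[2.5, 7.0]]))[0] == pytest.approx(2.5)
    m = _toy_model([-0.8251, 0.5650])
    assert m.score(np.array([[1.0, 1.0]]))[0] == pytest.approx(-0.2601)
    with pytest.raises(KeyError, match="missing"):
        m.score(pd.DataFrame({"g0": [1.0]}))


def test_predict_strict_inequality_and_translation_invariance():
    m = _toy_model([1.0, 0.0], threshold=2.5)
    assert m.predict(np.array([[2.5, 0.0]]))[0] == NONRESPONDER
    assert m.predict(np.array([[2.5 + 1e-9, 0.0]]))[0] == RESPONDER

    X, y = make_two_gene(seed=5)
    model = fit(pd.DataFrame(X, columns=["a", "b"]), y)
    shifted = PLSModel(
        panel=model.panel,
        weights=model.weights,
        center=model.center,
        scale=model.scale,
        threshold=model.threshold + 3.0,
    )
    base = model.score(pd.DataFrame(X, columns=["a", "b"]))
    assert np.array_equal(
        base > model.threshold, (base + 3.0) > shifted.threshold
    )


def test_training_accuracy_one_when_separable():
    y = np.repeat([1.0, -1.0], 10)
    rng = np.random.default_rng(6)
    X = np.column_stack([y * 3 + 0.1 * rng.normal(size=20), rng.normal(size=20)])
    Xdf = pd.DataFrame(X, columns=["a", "b"])
    model = fit(Xdf, y)
    pred = model.predict(Xdf)
    assert np.mean((pred == RESPONDER) == (y > 0)) == 1.0


def test_affine_rescaling_of_a_gene_is_absorbed():
    X, y = make_two_gene(seed=7)
    Xdf = pd.DataFrame(X, columns=["a", "b"])
    rescaled = Xdf.assign(a=5.0 * Xdf["a"] - 12.0)
    pred_a = fit(Xdf, y).predict(Xdf)
    pred_b = fit(rescaled, y).predict(rescaled)
    assert np.array_equal(pred_a, pred_b)


def test_model_json_round_trip():
    X, y = make_two_gene(seed=8)
    model = fit(pd.DataFrame(X, columns=["a", "b"]), y, reference_gene="RN18S")
    clone = PLSModel.from_dict(model.to_dict())
    assert clone.panel == model.panel
    np.testing.assert_allclose(clone.weights, model.weights)
    assert clone.threshold == model.threshold
    assert clone.reference_gene == "RN18S"
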