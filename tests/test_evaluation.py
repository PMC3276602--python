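"""Evaluation machinery: LDA curves, RMSE/bias, subset and sensitivity runs."""

import numpy as np
import pandas as pd
import pytest

from aimsel import (
    AncestryEstimate,
    DiscriminantModel,
    FrequencyTable,
    GenotypeMatrix,
    generate_panel_genotypes,
    lda_accuracy_curve,
    markers_needed,
    random_subset_experiment,
    rmse_bias,
    score_table,
    sensitivity_overlap,
)
from aimsel.evaluation import NOT_REACHED
from tests.test_ancestry import table_from


def loocv_oracle(X, y, ridge_scale=1e-6):
    """Brute-force LOOCV: refit from scratch for every fold."""
    correct = 0
    for i in range(len(y)):
        keep = [j for j in range(len(y)) if j != i]
        Xtr, ytr = X[keep], y[keep]
        model = DiscriminantModel.fit(Xtr[ytr == 0], Xtr[ytr == 1], ridge_scale)
        correct += int(model.predict(X[i : i + 1])[0] == y[i])
    return correct / len(y)


def test_lda_fully_differentiated_marker_is_perfect(rng):
    table = table_from([1.0], [0.0])
    G0 = generate_panel_genotypes(table, "pop1", 20, seed=1)
    G1 = generate_panel_genotypes(table, "pop2", 20, seed=2)
    scores = score_table(table)
    curve = lda_accuracy_curve(G0, G1, scores, "delta", [1])
    assert curve[1] == 1.0


def test_lda_uninformative_markers_near_chance():
    table = table_from([0.5] * 10, [0.5] * 10)
    G0 = generate_panel_genotypes(table, "pop1", 20, seed=11)
    G1 = generate_panel_genotypes(table, "pop2", 20, seed=12)
    scores = score_table(table)
    curve = lda_accuracy_curve(G0, G1, scores, "fst", [10])
    assert curve[10] == pytest.approx(0.5, abs=0.2)


def test_loocv_matches_bruteforce_oracle(small_sim):
    _, table, scores, _, _ = small_sim
    G0 = generate_panel_genotypes(table, "pop1", 12, seed=5)
    G1 = generate_panel_genotypes(table, "pop2", 14, seed=6)
    curve = lda_accuracy_curve(G0, G1, scores, "i_n", [3, 8])
    order = scores.df.sort_values("rank_i_n")["marker_id"].tolist()
    for n in (3, 8):
        X = np.vstack(
            [
                G0.subset_markers(order[:n]).g.astype(float),
                G1.subset_markers(order[:n]).g.astype(float),
            ]
        )
        y = np.array([0] * 12 + [1] * 14)
        assert curve[n] == loocv_oracle(X, y)


def test_lda_matches_sklearn_predictions(small_sim):
    """On a well-conditioned problem the ridge is negligible."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    _, table, scores, _, _ = small_sim
    G0 = generate_panel_genotypes(table, "pop1", 25, seed=7)
    G1 = generate_panel_genotypes(table, "pop2", 25, seed=8)
    order = scores.df.sort_values("rank_delta")["marker_id"].tolist()[:5]
    X0 = G0.subset_markers(order).g.astype(float)
    X1 = G1.subset_markers(order).g.astype(float)
    model = DiscriminantModel.fit(X0, X1)
    X = np.vstack([X0, X1])
    y = np.array([0] * 25 + [1] * 25)
    sk = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
    assert np.mean(model.predict(X) == sk.predict(X)) >= 0.95


def test_lda_small_class_raises(toy_table):
    G0 = GenotypeMatrix(["a"], list(toy_table.marker_ids), [[0, 1, 2]])
    G1 = GenotypeMatrix(["b", "c"], list(toy_table.marker_ids), [[0, 1, 2], [2, 1, 0]])
    with pytest.raises(ValueError, match="2 samples"):
        lda_accuracy_curve(G0, G1, score_table(toy_table), "delta", [1])


@pytest.mark.parametrize(
    "curve,thr,expected",
    [
        ({1: 0.80, 2: 0.92, 3: 0.96}, 0.90, 2),
        ({1: 0.80, 2: 0.85, 3: 0.90}, 0.95, NOT_REACHED),
        ({1: 0.91, 2: 0.89, 3: 0.95}, 0.90, 1),  # first crossing counts
    ],
)
def test_markers_needed(curve, thr, expected):
    assert markers_needed(curve, thr) == expected


def make_estimate(ids, q):
    q = np.asarray(q, dtype=float)
    return AncestryEstimate(
        sample_ids=np.asarray(ids, dtype=object),
        q_hat=q,
        loglik=np.zeros(len(q)),
        n_markers=10,
    )


def test_rmse_bias_worked_examples():
    r = rmse_bias(make_estimate(["a", "b"], [0.6, 0.4]), ["a", "b"], [0.5, 0.5])
    assert r["rmse"] == pytest.approx(0.1, abs=1e-12)
    assert r["bias"] == pytest.approx(0.0, abs=1e-12)

    r = rmse_bias(make_estimate(["a", "b"], [0.3, 0.8]), ["a", "b"], [0.3, 0.8])
    assert r["rmse"] == 0.0 and r["bias"] == 0.0

    ids = [f"s{i}" for i in range(100)]
    r = rmse_bias(make_estimate(ids, [0.71] * 100), ids, [0.7] * 100)
    assert r["rmse"] == pytest.approx(0.01, abs=1e-9)
    assert r["bias"] == pytest.approx(0.01, abs=1e-9)


def test_rmse_bias_order_invariant_and_id_checked():
    est = make_estimate(["a", "b"], [0.2, 0.9])
    r1 = rmse_bias(est, ["b", "a"], [0.8, 0.1])  # ids matched, not positional
    r2 = rmse_bias(est, ["a", "b"], [0.1, 0.8])
    assert r1 == r2
    with pytest.raises(ValueError, match="ids"):
        rmse_bias(est, ["a", "x"], [0.1, 0.8])


def _perfect_aim_setup(rng, n_markers=40, n_ind=50):
    """Fixed-difference markers and individuals with known ancestry."""
    table = table_from([1.0] * n_markers, [0.0] * n_markers)
    q = rng.uniform(0.3, 0.9, n_ind)
    g = rng.binomial(2, np.tile(q[:, None], (1, n_markers)))
    G = GenotypeMatrix([f"s{i}" for i in range(n_ind)], list(table.marker_ids), g)
    return table, G, q


def test_subset_experiment_deterministic_and_accurate(rng):
    table, G, q = _perfect_aim_setup(rng)
    scores = score_table(table)
    kwargs = dict(
        fractions=(1.0,), subset_size=20, n_rep=10, seed=7, measures=("delta",)
    )
    s1 = random_subset_experiment(scores, table, G, float(q.mean()), **kwargs)
    s2 = random_subset_experiment(scores, table, G, float(q.mean()), **kwargs)
    pd.testing.assert_frame_equal(s1, s2)
    assert s1["mean_abs_error"].iloc[0] < 0.02  # perfect AIMs, 40 allele draws


def test_subset_experiment_rejects_oversized_subset(rng):
    table, G, q = _perfect_aim_setup(rng, n_markers=10)
    scores = score_table(table)
    with pytest.raises(ValueError, match="exceeds"):
        random_subset_experiment(
            scores, table, G, 0.5, fractions=(0.5,), subset_size=20, n_rep=2,
            measures=("delta",),
        )


def test_sensitivity_identical_m_fully_overlaps(small_sim):
    _, table, _, _, _ = small_sim
    res = sensitivity_overlap(table, "fic", 0.8, 0.8, fraction=0.02)
    assert res["10"] == 0 and res["01"] == 0
    assert res["pct_11"] == 100.0


def test_sensitivity_delta_control_ignores_m(small_sim):
    _, table, _, _, _ = small_sim
    res = sensitivity_overlap(table, "delta", 0.8, 0.3, fraction=0.02)
    assert res["pct_11"] == 100.0
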