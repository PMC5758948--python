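import numpy as np
import pandas as pd
import pytest

from acodopt import ann
from acodopt.ann import (Dataset, LMConvergenceError, TrainHyperparams,
                         TrainedMLP, architecture_search, corrcoef, evaluate,
                         init_network, mse, r2, select_architecture,
                         split_labels, train_lm)
from acodopt.ann import _jacobian, _pack, _residuals
from acodopt.io import packaged_search_table


def _linear_dataset(n=80, seed=0):
    """Noiseless linear target: y = sum(x)/9 and its negation."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, (n, 9))
    y = X.sum(axis=1) / 9.0
    return Dataset(X, np.column_stack([y, -y])).with_split(seed)


# --- splitting ------------------------------------------------------------

def test_split_fractions_100_rows():
    labels = split_labels(100, seed=1)
    counts = pd.Series(labels).value_counts()
    assert counts["train"] == 70 and counts["val"] == 15 and counts["test"] == 15


def test_split_20_rows_floor_then_train_first():
    labels = split_labels(20, seed=1)
    counts = pd.Series(labels).value_counts()
    assert counts["train"] == 14 and counts["val"] == 3 and counts["test"] == 3


def test_split_deterministic_under_seed():
    assert (split_labels(57, 9) == split_labels(57, 9)).all()
    assert (split_labels(57, 9) != split_labels(57, 10)).any()


def test_split_rejects_tiny_datasets():
    with pytest.raises(ValueError):
        split_labels(9, 0)


# --- metrics --------------------------------------------------------------

def test_mse_r2_perfect_prediction():
    obs = [1.0, 2.0, 3.0]
    assert mse(obs, obs) == 0.0
    assert r2(obs, obs) == 1.0


def test_r2_of_mean_predictor_is_zero():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    pred = np.full(4, obs.mean())
    assert r2(pred, obs) == pytest.approx(0.0)


def test_mse_r2_hand_computed_example():
    obs, pred = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
    assert mse(pred, obs) == pytest.approx(1.0 / 3.0)   # SSres=1 over n=3
    assert r2(pred, obs) == pytest.approx(0.5)          # 1 - 1/2


def test_metric_error_conditions():
    with pytest.raises(ValueError):
        mse([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        r2([1.0, 2.0], [3.0, 3.0])     # zero variance in observations
    with pytest.raises(ValueError):
        corrcoef([1.0], [1.0])


# --- network mechanics ----------------------------------------------------

@pytest.mark.parametrize("h", [1, 5, 19, 50])
def test_parameter_count_formula(h):
    net = init_network(h, seed=0)
    assert net.n_params == 9 * h + h + 2 * h + 2
    assert len(_pack(net)) == net.n_params


def test_jacobian_matches_finite_differences():
    """Analytic residual Jacobian agrees with central differences."""
    rng = np.random.default_rng(5)
    Xn = rng.uniform(-1, 1, (7, 9))
    Tn = rng.uniform(-1, 1, (7, 2))
    net = init_network(4, seed=5)
    w = _pack(net)
    R, A = _residuals(w, Xn, Tn, 9, 4, 2)
    J = _jacobian(w, Xn, A, 9, 4, 2)
    eps = 1e-6
    for j in range(0, len(w), 7):       # probe a spread of parameters
        wp, wm = w.copy(), w.copy()
        wp[j] += eps
        wm[j] -= eps
        Rp, _ = _residuals(wp, Xn, Tn, 9, 4, 2)
        Rm, _ = _residuals(wm, Xn, Tn, 9, 4, 2)
        fd = (Rp - Rm).T.ravel() / (2 * eps)
        assert np.allclose(J[:, j], fd, atol=1e-6)


def test_large_damping_step_follows_negative_gradient():
    """As mu grows the LM step turns into a short gradient-descent step."""
    rng = np.random.default_rng(3)
    Xn = rng.uniform(-1, 1, (30, 9))
    Tn = rng.uniform(-1, 1, (30, 2))
    net = init_network(6, seed=3)
    w = _pack(net)
    R, A = _residuals(w, Xn, Tn, 9, 6, 2)
    J = _jacobian(w, Xn, A, 9, 6, 2)
    g = J.T @ R.T.ravel()
    mu = 1e9
    delta = np.linalg.solve(J.T @ J + mu * np.eye(len(w)), -g)
    cos = float(delta @ (-g) / (np.linalg.norm(delta) * np.linalg.norm(g)))
    assert cos > 0.999


def test_undamped_step_solves_linearized_least_squares():
    """With mu -> 0 the step equals the lstsq solution of J delta = -e."""
    rng = np.random.default_rng(7)
    Xn = rng.uniform(-1, 1, (40, 9))
    Tn = rng.uniform(-1, 1, (40, 2))
    net = init_network(3, seed=7)
    w = _pack(net)
    R, A = _residuals(w, Xn, Tn, 9, 3, 2)
    J = _jacobian(w, Xn, A, 9, 3, 2)
    e = R.T.ravel()
    delta = np.linalg.solve(J.T @ J + 1e-12 * np.eye(len(w)), -(J.T @ e))
    oracle = np.linalg.lstsq(J, -e, rcond=None)[0]
    assert np.allclose(delta, oracle, atol=1e-6)


# --- training -------------------------------------------------------------

def test_zero_epochs_returns_initialized_network():
    data = _linear_dataset()
    net = train_lm(data, 5, TrainHyperparams(max_epochs=0), seed=11)
    ref = init_network(5, seed=11)
    assert np.array_equal(net.W1, ref.W1)
    assert np.array_equal(net.b2, ref.b2)
    assert net.stop_epoch == 0
    assert len(net.trace_train) == 1


def test_training_is_bit_identical_under_fixed_seed():
    data = _linear_dataset()
    hp = TrainHyperparams(max_epochs=30)
    a = train_lm(data, 4, hp, seed=2)
    b = train_lm(data, 4, hp, seed=2)
    assert np.array_equal(_pack(a), _pack(b))
    assert a.trace_train == b.trace_train


def test_noiseless_linear_target_converges_fast():
    """LM drives training MSE below 1e-3 within 100 epochs on y = sum(x)/9."""
    data = _linear_dataset()
    net = train_lm(data, 5, TrainHyperparams(max_epochs=100), seed=0)
    m = evaluate(net, data)
    assert m.mse["train"] < 1e-3
    assert len(net.trace_train) - 1 <= 100


def test_training_error_never_worse_than_initialization():
    data = _linear_dataset(seed=4)
    net = train_lm(data, 4, TrainHyperparams(max_epochs=40), seed=4)
    assert net.trace_train[net.stop_epoch] <= net.trace_train[0]


def test_serialization_roundtrip(tmp_path):
    data = _linear_dataset()
    net = train_lm(data, 3, TrainHyperparams(max_epochs=20), seed=1)
    path = tmp_path / "model.json"
    net.to_json(path)
    back = TrainedMLP.from_json(path)
    assert np.allclose(back.predict(data.X), net.predict(data.X))
    assert back.layer_sizes == net.layer_sizes


def test_biogas_more_predictable_than_noisier_methane_content():
    """With heavier observation noise on the methane-content target, its
    fitted R^2 falls below the biogas-yield R^2."""
    import acodopt
    exp = acodopt.generate_experiment(cfg=acodopt.default_config(), seed=0)
    data = Dataset.from_frame(exp.ann_frame).with_split(0)
    net = train_lm(data, 10, TrainHyperparams(max_epochs=200), seed=0)
    m = evaluate(net, data)
    assert (m.r2_per_output["bgp_ml_per_gvs"]
            > m.r2_per_output["bmp_content_pct"])


# --- architecture selection ----------------------------------------------

def test_selection_on_packaged_candidate_table():
    """The published candidate metrics select 19 hidden neurons."""
    h_star, flagged = select_architecture(packaged_search_table())
    assert h_star == 19
    assert {30, 50} <= set(flagged)


def test_overfit_flagging_rule():
    table = pd.DataFrame({
        "hidden_neurons": [50],
        "mse_train": [17.9675],
        "mse_val": [14269.6345],
        "mse_test": [6632.0505],
        "r_all": [0.6443],
    })
    _, flagged = select_architecture(table)
    assert flagged == [50]


def test_single_candidate_is_selected():
    table = packaged_search_table()
    h_star, _ = select_architecture(table[table["hidden_neurons"] == 15])
    assert h_star == 15


def test_architecture_search_trains_and_selects():
    data = _linear_dataset(n=60, seed=6)
    h_star, table = architecture_search(
        data, candidates=(2, 4), seed=6,
        hyper=TrainHyperparams(max_epochs=40),
    )
    assert h_star in (2, 4)
    assert set(table["hidden_neurons"]) == {2, 4}
    assert table[["mse_train", "mse_val", "mse_test"]].notna().all(axis=None)


def test_architecture_search_rejects_empty_candidates():
    with pytest.raises(ValueError):
        architecture_search(_linear_dataset(), candidates=())
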