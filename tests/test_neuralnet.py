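"""Network engine: transfer functions, splitting, training, prediction, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from blastograde import neuralnet as nn
from blastograde.errors import ConfigurationError, InputSchemaError
from blastograde.neuralnet import Genome, _Network, _make_stepper


def _genome(**kw):
    base = dict(n1=10, n2=10, n3=10, tf1="tansig", tf2="tansig", tf3="tansig",
                tf_out="purelin", train_fn="trainrp", n_hidden=1)
    base.update(kw)
    return Genome(**base)


@pytest.mark.parametrize("name,x,expected", [
    ("tribas", 0.0, 1.0), ("tribas", 1.5, 0.0), ("tribas", -0.5, 0.5),
    ("radbas", 0.0, 1.0), ("radbas", 1.0, np.exp(-1.0)),
    ("logsig", 0.0, 0.5), ("hardlim", 0.0, 1.0), ("hardlim", -0.1, 0.0),
    ("satlin", -1.0, 0.0), ("satlin", 0.4, 0.4), ("satlin", 2.0, 1.0),
    ("purelin", 3.5, 3.5),
])
def test_transfer_anchor_values(name, x, expected):
    assert nn.transfer(name, x) == pytest.approx(expected, abs=5e-6)


@given(st.floats(-20, 20))
def test_tansig_is_rescaled_logsig(x):
    assert nn.transfer("tansig", x) == pytest.approx(
        2.0 * nn.transfer("logsig", 2.0 * x) - 1.0, abs=1e-12)


def test_unknown_transfer_rejected():
    with pytest.raises(ConfigurationError):
        nn.transfer("relu", 1.0)


def test_split_sizes_and_determinism():
    s = nn.split(100, seed=0)
    assert (len(s.train), len(s.validation), len(s.test)) == (70, 15, 15)
    all_idx = sorted(s.train + s.validation + s.test)
    assert all_idx == list(range(100))
    assert nn.split(100, seed=0) == s
    assert nn.split(100, seed=1) != s
    with pytest.raises(ConfigurationError):
        nn.split(9, seed=0)


def test_genome_validation_and_inert_genes():
    with pytest.raises(ConfigurationError):
        _genome(n1=5)
    with pytest.raises(ConfigurationError):
        _genome(tf_out="step")
    with pytest.raises(ConfigurationError):
        _genome(n_hidden=4)
    g = _genome(n_hidden=1, n3=99, tf3="radbas")
    assert g.hidden_sizes == (10,)        # n3/tf3 carried but inert
    assert g.to_dict()["n3"] == 99
    assert Genome.from_dict(g.to_dict()) == g


def test_training_on_separable_toy_reaches_high_accuracy(toy_separable):
    model = nn.train(toy_separable.x, toy_separable.y, _genome(),
                     toy_separable.split, seed=0, max_epochs=300)
    tr = np.array(toy_separable.split.train)
    assert model.accuracy(toy_separable.x[tr], toy_separable.y[tr]) >= 0.95
    rec = model.training_record
    assert rec["epochs"] == len(rec["train_mse"]) <= 300
    assert rec["stopped_reason"] in ("max_epochs", "validation", "gradient_floor")


def test_untrained_network_scores_near_chance(toy_separable):
    rng = np.random.default_rng(0)
    y = rng.integers(1, 4, size=60)
    model = nn.train(toy_separable.x, y, _genome(), toy_separable.split,
                     seed=1, max_epochs=0)
    assert model.training_record["epochs"] == 0
    acc = model.accuracy(toy_separable.x, y)
    assert 0.33 - 0.15 <= acc <= 0.33 + 0.15


def test_rp_overshoots_are_reverted_on_quadratic_objective():
    """Rprop's step sizes adapt by gradient sign only, so a transient
    overshoot can raise the mse for an epoch; backtracking must undo it
    within a few epochs and the loss must converge."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(40, 24))
    w = rng.normal(size=(24, 3))
    t = x @ w * 0.1
    g = _genome(tf1="purelin")
    net = _Network(24, g)
    params = net.init_params(np.random.default_rng(3))
    step = _make_stepper("trainrp", net, x, t)
    mses = []
    for _ in range(300):
        params, mse, _ = step(params)
        mses.append(mse)
    for i in range(len(mses) - 4):
        if mses[i + 1] > mses[i] * (1 + 1e-12):
            assert min(mses[i + 1:i + 5]) <= mses[i] * (1 + 1e-9)
    assert mses[-1] < 1e-8


def test_predict_tie_breaks_to_lower_grade():
    g = _genome(tf_out="purelin")
    model = nn.TrainedModel(
        genome=g,
        weights=[np.zeros((10, 4)), np.zeros((3, 10))],
        biases=[np.zeros(10), np.zeros(3)],
        input_min=np.zeros(4), input_max=np.ones(4),
        variable_names=("a", "b", "c", "d"))
    scores, grade = nn.predict(model, np.array([0.3, 0.1, 0.9, 0.5]))
    assert np.array_equal(scores, np.zeros(3))
    assert grade == 1


def test_predict_schema_mismatch_lists_names(toy_separable):
    model = nn.train(pd.DataFrame(toy_separable.x,
                                  columns=[f"f{i}" for i in range(24)]),
                     toy_separable.y, _genome(), toy_separable.split,
                     seed=0, max_epochs=5)
    bad = pd.DataFrame(np.zeros((1, 3)), columns=["f0", "f1", "oops"])
    with pytest.raises(InputSchemaError, match="oops"):
        model.predict(bad)


def test_model_json_roundtrip_is_bit_identical(tmp_path, toy_separable):
    model = nn.train(toy_separable.x, toy_separable.y, _genome(n_hidden=2),
                     toy_separable.split, seed=4, max_epochs=50)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = nn.TrainedModel.load(path)
    s1, g1 = model.predict(toy_separable.x)
    s2, g2 = loaded.predict(toy_separable.x)
    assert np.array_equal(s1, s2)
    assert np.array_equal(g1, g2)
    assert loaded.genome == model.genome
    assert "Feed-forward" in loaded.summary()


def test_training_record_tracks_three_partitions(toy_separable):
    model = nn.train(toy_separable.x, toy_separable.y, _genome(),
                     toy_separable.split, seed=0, max_epochs=40)
    rec = model.training_record
    n = rec["epochs"]
    assert len(rec["validation_mse"]) == len(rec["test_mse"]) == n
    assert all(np.isfinite(rec["train_mse"]))
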