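"""Feed-forward network engine for 3-class blastocyst grading.

Networks have 1-3 hidden layers, 10-120 neurons each, one of seven transfer
functions per layer (logsig, purelin, tansig, hardlim, tribas, radbas,
satlin) and a 3-unit output layer with one-hot grade targets.  The loss is
the mean squared error over all output units and samples, minimized
full-batch by one of five classic training algorithms:

* traingdm  — gradient descent with momentum (0.9, learning rate 0.01)
* traingdx  — the same with multiplicative rate adaptation (x1.05 on
  improvement; step rejected and rate x0.7 when the mse rises by > 4%)
* trainrp   — resilient backpropagation (eta+ 1.2, eta- 0.5, delta0 0.07,
  delta_max 50)
* trainscg  — Moller's scaled conjugate gradient (sigma 5e-5, lambda 5e-7)
* traincgf  — Fletcher-Reeves conjugate gradient with a backtracking
  (Armijo) line search

Data handling mirrors the usual supervised-learning protocol: a seeded
70/15/15 train/validation/test split, inputs min-max scaled to [-1, 1]
using training-partition bounds, early stopping after 6 consecutive
validation-mse increases (best-validation weights restored), a 1000-epoch
cap and a 1e-7 gradient-norm floor.

``hardlim`` has zero derivative everywhere, so hidden layers using it do
not propagate gradient; genomes that select it simply train poorly, which
the architecture search penalises naturally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, InputSchemaError, TrainingDivergedError)

TRANSFER_FUNCTIONS = ("logsig", "purelin", "tansig", "hardlim", "tribas",
                      "radbas", "satlin")
TRAINING_FUNCTIONS = ("trainrp", "trainscg", "traincgf", "traingdx", "traingdm")

NEURON_RANGE = (10, 120)
N_CLASSES = 3
MAX_EPOCHS = 1000
VALIDATION_PATIENCE = 6
GRADIENT_FLOOR = 1e-7


# ---------------------------------------------------------------------------
# transfer functions

def _tf_eval(name: str, x: np.ndarray) -> np.ndarray:
    if name == "logsig":
        with np.errstate(over="ignore"):  # exp overflow saturates to 0/1
            return 1.0 / (1.0 + np.exp(-x))
    if name == "purelin":
        return x
    if name == "tansig":
        return np.tanh(x)  # = 2/(1+exp(-2x)) - 1
    if name == "hardlim":
        return (x >= 0).astype(float)
    if name == "tribas":
        return np.maximum(0.0, 1.0 - np.abs(x))
    if name == "radbas":
        return np.exp(-x * x)
    if name == "satlin":
        return np.clip(x, 0.0, 1.0)
    raise ConfigurationError(f"unknown transfer function: {name}")


def _tf_deriv(name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Derivative d y / d x given pre-activation x and output y."""
    if name == "logsig":
        return y * (1.0 - y)
    if name == "purelin":
        return np.ones_like(x)
    if name == "tansig":
        return 1.0 - y * y
    if name == "hardlim":
        return np.zeros_like(x)  # surrogate gradient 0
    if name == "tribas":
        return np.where(np.abs(x) < 1.0, -np.sign(x), 0.0)
    if name == "radbas":
        return -2.0 * x * y
    if name == "satlin":
        return ((x > 0) & (x < 1)).astype(float)
    raise ConfigurationError(f"unknown transfer function: {name}")


def transfer(name: str, x):
    """Evaluate a named transfer function (scalar or array)."""
    if name not in TRANSFER_FUNCTIONS:
        raise ConfigurationError(f"unknown transfer function: {name}")
    out = _tf_eval(name, np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


# ---------------------------------------------------------------------------
# genome and split

@dataclass(frozen=True)
class Genome:
    """9-gene network-architecture specification.

    Genes beyond ``n_hidden`` (e.g. ``n3`` when only one hidden layer is
    active) are carried but inert, so crossover can still exchange them.
    """

    n1: int
    n2: int
    n3: int
    tf1: str
    tf2: str
    tf3: str
    tf_out: str
    train_fn: str
    n_hidden: int

    def __post_init__(self):
        for n in (self.n1, self.n2, self.n3):
            if not (NEURON_RANGE[0] <= n <= NEURON_RANGE[1]):
                raise ConfigurationError(f"neuron count {n} outside {NEURON_RANGE}")
        for tf in (self.tf1, self.tf2, self.tf3, self.tf_out):
            if tf not in TRANSFER_FUNCTIONS:
                raise ConfigurationError(f"unknown transfer function: {tf}")
        if self.train_fn not in TRAINING_FUNCTIONS:
            raise ConfigurationError(f"unknown training function: {self.train_fn}")
        if self.n_hidden not in (1, 2, 3):
            raise ConfigurationError("n_hidden must be 1, 2 or 3")

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return (self.n1, self.n2, self.n3)[: self.n_hidden]

    @property
    def hidden_transfers(self) -> tuple[str, ...]:
        return (self.tf1, self.tf2, self.tf3)[: self.n_hidden]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        return cls(**d)


@dataclass(frozen=True)
class DataSplit:
    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]


def split(n: int, seed: int) -> DataSplit:
    """Seeded 70/15/15 partition: round-down 15% test and validation, rest train."""
    if n < 10:
        raise ConfigurationError(f"too few samples to split: {n} < 10")
    perm = np.random.default_rng(seed).permutation(n)
    n_test = int(np.floor(0.15 * n))
    n_val = int(np.floor(0.15 * n))
    return DataSplit(test=tuple(int(i) for i in perm[:n_test]),
                     validation=tuple(int(i) for i in perm[n_test:n_test + n_val]),
                     train=tuple(int(i) for i in perm[n_test + n_val:]))


# ---------------------------------------------------------------------------
# network internals: parameters are a flat vector over (W, b) per layer

class _Network:
    def __init__(self, n_inputs: int, genome: Genome):
        self.sizes = [n_inputs, *genome.hidden_sizes, N_CLASSES]
        self.transfers = [*genome.hidden_transfers, genome.tf_out]
        self.shapes = [(self.sizes[l + 1], self.sizes[l])
                       for l in range(len(self.sizes) - 1)]
        self.n_params = sum(o * i + o for o, i in self.shapes)

    def init_params(self, rng: np.random.Generator) -> np.ndarray:
        chunks = []
        for (o, i) in self.shapes:
            limit = 1.0 / np.sqrt(i)
            chunks.append(rng.uniform(-limit, limit, size=o * i))
            chunks.append(rng.uniform(-limit, limit, size=o))
        return np.concatenate(chunks)

    def unflatten(self, params: np.ndarray):
        ws, bs, pos = [], [], 0
        for (o, i) in self.shapes:
            ws.append(params[pos:pos + o * i].reshape(o, i)); pos += o * i
            bs.append(params[pos:pos + o]); pos += o
        return ws, bs

    def forward(self, params: np.ndarray, x: np.ndarray):
        """x: (n, inputs). Returns activations and pre-activations per layer."""
        ws, bs = self.unflatten(params)
        a = x
        zs, acts = [], [a]
        for w, b, tf in zip(ws, bs, self.transfers):
            z = a @ w.T + b
            a = _tf_eval(tf, z)
            zs.append(z)
            acts.append(a)
        return acts, zs

    def loss(self, params: np.ndarray, x: np.ndarray, t: np.ndarray) -> float:
        acts, _ = self.forward(params, x)
        return float(np.mean((acts[-1] - t) ** 2))

    def loss_grad(self, params: np.ndarray, x: np.ndarray, t: np.ndarray):
        """mse and its analytic gradient via backpropagation."""
        ws, bs = self.unflatten(params)
        acts, zs = self.forward(params, x)
        y = acts[-1]
        n_total = y.size
        mse = float(np.mean((y - t) ** 2))
        delta = (2.0 / n_total) * (y - t) * _tf_deriv(self.transfers[-1], zs[-1], y)
        grads_w = [None] * len(ws)
        grads_b = [None] * len(ws)
        for l in range(len(ws) - 1, -1, -1):
            grads_w[l] = delta.T @ acts[l]
            grads_b[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ ws[l]) * _tf_deriv(self.transfers[l - 1],
                                                    zs[l - 1], acts[l])
        flat = np.concatenate([np.concatenate([gw.ravel(), gb])
                               for gw, gb in zip(grads_w, grads_b)])
        return mse, flat


# ---------------------------------------------------------------------------
# the five trainers: each yields one parameter update per epoch

def _make_stepper(train_fn: str, net: _Network, x, t):
    """Returns step(params) -> (new_params, mse_before_step)."""
    state: dict = {}

    if train_fn == "traingdm":
        state["v"] = 0.0

        def step(params):
            mse, g = net.loss_grad(params, x, t)
            state["v"] = 0.9 * np.asarray(state["v"]) - 0.01 * g
            return params + state["v"], mse, g

    elif train_fn == "traingdx":
        state.update(v=0.0, lr=0.01, prev_mse=None)

        def step(params):
            mse, g = net.loss_grad(params, x, t)
            v = 0.9 * np.asarray(state["v"]) - state["lr"] * g
            new = params + v
            new_mse = net.loss(new, x, t)
            if state["prev_mse"] is not None and new_mse > mse * 1.04:
                # reject: shrink the rate, kill momentum, stay put
                state["lr"] = max(state["lr"] * 0.7, 1e-9)
                state["v"] = 0.0
                state["prev_mse"] = mse
                return params, mse, g
            state["lr"] = min(state["lr"] * 1.05, 1.0)
            state["v"] = v
            state["prev_mse"] = mse
            return new, mse, g

    elif train_fn == "trainrp":
        # classic Rprop+ (Riedmiller): per-weight step sizes with
        # backtracking of the previous update on a gradient sign change
        state.update(delta=None, prev_g=0.0, prev_step=0.0)

        def step(params):
            mse, g = net.loss_grad(params, x, t)
            if state["delta"] is None:
                state["delta"] = np.full_like(g, 0.07)
            sign_change = g * np.asarray(state["prev_g"])
            delta = state["delta"]
            delta = np.where(sign_change > 0, np.minimum(delta * 1.2, 50.0), delta)
            delta = np.where(sign_change < 0, np.maximum(delta * 0.5, 1e-9), delta)
            g_eff = np.where(sign_change < 0, 0.0, g)
            upd = np.where(sign_change < 0,
                           -np.asarray(state["prev_step"]),   # revert
                           -np.sign(g_eff) * delta)
            state["delta"] = delta
            state["prev_g"] = g_eff
            state["prev_step"] = np.where(sign_change < 0, 0.0, upd)
            return params + upd, mse, g

    elif train_fn == "trainscg":
        # Moller (1993) scaled conjugate gradient, one iteration per epoch
        state.update(sigma0=5e-5, lam=5e-7, lam_bar=0.0, success=True,
                     p=None, r=None, f=None)

        def step(params):
            if state["p"] is None:
                f, g = net.loss_grad(params, x, t)
                state["f"] = f
                state["r"] = -g
                state["p"] = -g
            f = state["f"]
            p, r = state["p"], state["r"]
            g = -r
            p_norm2 = float(p @ p)
            if p_norm2 < 1e-300:
                return params, f, g
            if state["success"]:
                sigma = state["sigma0"] / np.sqrt(p_norm2)
                _, g_plus = net.loss_grad(params + sigma * p, x, t)
                s = (g_plus - g) / sigma
                state["delta_k"] = float(p @ s)
            delta_k = state["delta_k"] + (state["lam"] - state["lam_bar"]) * p_norm2
            if delta_k <= 0:  # make the Hessian approximation positive definite
                state["lam_bar"] = 2.0 * (state["lam"] - delta_k / p_norm2)
                delta_k = -delta_k + state["lam"] * p_norm2
                state["lam"] = state["lam_bar"]
            mu = float(p @ r)
            alpha = mu / delta_k
            new = params + alpha * p
            f_new = net.loss(new, x, t)
            comp = 2.0 * delta_k * (f - f_new) / (mu * mu) if mu != 0 else -1.0
            if comp >= 0:  # successful step
                _, g_new = net.loss_grad(new, x, t)
                r_new = -g_new
                state["lam_bar"] = 0.0
                state["success"] = True
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                state["p"] = r_new + beta * p
                state["r"] = r_new
                state["f"] = f_new
                if comp >= 0.75:
                    state["lam"] *= 0.25
                out = new
            else:
                state["lam_bar"] = state["lam"]
                state["success"] = False
                out = params
            if comp < 0.25:
                state["lam"] += delta_k * (1.0 - comp) / p_norm2
            state["lam"] = min(state["lam"], 1e10)
            return out, f, g

    elif train_fn == "traincgf":
        # Fletcher-Reeves CG with Armijo backtracking
        state.update(d=None, prev_gg=None, alpha=1.0, since_restart=0)

        def step(params):
            mse, g = net.loss_grad(params, x, t)
            gg = float(g @ g)
            if (state["d"] is None or state["since_restart"] >= net.n_params
                    or float(g @ state["d"]) >= 0):
                d = -g
                state["since_restart"] = 0
            else:
                beta = gg / state["prev_gg"] if state["prev_gg"] else 0.0
                d = -g + beta * state["d"]
                if float(g @ d) >= 0:
                    d = -g
                    state["since_restart"] = 0
            slope = float(g @ d)
            alpha = min(state["alpha"] * 2.0, 10.0)
            for _ in range(25):
                if net.loss(params + alpha * d, x, t) <= mse + 1e-4 * alpha * slope:
                    break
                alpha *= 0.5
            else:
                alpha = 0.0
            state.update(d=d, prev_gg=gg, alpha=max(alpha, 1e-8))
            state["since_restart"] += 1
            return params + alpha * d, mse, g

    else:
        raise ConfigurationError(f"unknown training function: {train_fn}")

    return step


# ---------------------------------------------------------------------------
# results object

@dataclass
class TrainedModel:
    """Fitted network: weights, scaling, provenance and training record."""

    genome: Genome
    weights: list = field(repr=False, default_factory=list)   # per-layer (out, in)
    biases: list = field(repr=False, default_factory=list)
    input_min: np.ndarray = field(repr=False, default=None)
    input_max: np.ndarray = field(repr=False, default=None)
    variable_names: tuple[str, ...] = ()
    training_record: dict = field(default_factory=dict)
    seed: int = 0

    # -- prediction ---------------------------------------------------------
    def _scale(self, x: np.ndarray) -> np.ndarray:
        span = np.maximum(self.input_max - self.input_min, 1e-300)
        return 2.0 * (x - self.input_min) / span - 1.0

    def _forward(self, x: np.ndarray) -> np.ndarray:
        a = self._scale(x)
        transfers = [*self.genome.hidden_transfers, self.genome.tf_out]
        for w, b, tf in zip(self.weights, self.biases, transfers):
            a = _tf_eval(tf, a @ np.asarray(w).T + np.asarray(b))
        return a

    def _check_schema(self, columns) -> None:
        if tuple(columns) == tuple(self.variable_names):
            return
        missing = [n for n in self.variable_names if n not in columns]
        extra = [n for n in columns if n not in self.variable_names]
        if missing or extra:
            raise InputSchemaError(
                f"feature schema mismatch: missing {missing}, unexpected {extra}")

    def predict(self, features) -> tuple[np.ndarray, np.ndarray]:
        """Forward pass; returns (scores (n,3), grades (n,)).

        Accepts a DataFrame/Series with named variables (reordered and
        schema-checked) or a bare array already in model variable order.
        Grade is the argmax of the three output activations, ties breaking
        to the lower grade.
        """
        if isinstance(features, pd.Series):
            features = features.to_frame().T
        if isinstance(features, pd.DataFrame):
            self._check_schema(features.columns)
            x = features[list(self.variable_names)].to_numpy(dtype=float)
        else:
            x = np.atleast_2d(np.asarray(features, dtype=float))
            if x.shape[1] != len(self.variable_names):
                raise InputSchemaError(
                    f"expected {len(self.variable_names)} features, got {x.shape[1]}")
        scores = self._forward(x)
        grades = 1 + np.argmax(scores, axis=1)  # argmax tie -> lower grade
        return scores, grades

    def accuracy(self, features, grades) -> float:
        _, pred = self.predict(features)
        return float(np.mean(pred == np.asarray(grades)))

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        rec = self.training_record
        lines = [
            "Feed-forward blastocyst grading network",
            "=" * 47,
            f"hidden layers: {self.genome.n_hidden} "
            f"{self.genome.hidden_sizes} {self.genome.hidden_transfers}",
            f"output transfer: {self.genome.tf_out}   trainer: {self.genome.train_fn}",
            f"inputs: {len(self.variable_names)} variables, min-max scaled to [-1, 1]",
            f"seed: {self.seed}   epochs run: {rec.get('epochs', 0)}"
            f"   stop: {rec.get('stopped_reason', '?')}",
        ]
        for part in ("train", "validation", "test"):
            hist = rec.get(f"{part}_mse", [])
            if hist:
                lines.append(f"final {part} mse: {hist[-1]:.6f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "genome": self.genome.to_dict(),
            "weights": [np.asarray(w).tolist() for w in self.weights],
            "biases": [np.asarray(b).tolist() for b in self.biases],
            "input_min": np.asarray(self.input_min).tolist(),
            "input_max": np.asarray(self.input_max).tolist(),
            "variable_names": list(self.variable_names),
            "training_record": self.training_record,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genome=Genome.from_dict(payload["genome"]),
            weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
            biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
            input_min=np.asarray(payload["input_min"], dtype=float),
            input_max=np.asarray(payload["input_max"], dtype=float),
            variable_names=tuple(payload["variable_names"]),
            training_record=payload["training_record"],
            seed=int(payload["seed"]),
        )


# ---------------------------------------------------------------------------
# model object

class ANNClassifier:
    """Grading-network model bound to a feature table (statsmodels-style).

    ``fit()`` returns a :class:`TrainedModel` results object.
    """

    def __init__(self, features: pd.DataFrame | np.ndarray, grades, genome: Genome,
                 variable_names=None):
        if isinstance(features, pd.DataFrame):
            self.variable_names = tuple(features.columns)
            self.x = features.to_numpy(dtype=float)
        else:
            self.x = np.asarray(features, dtype=float)
            self.variable_names = tuple(variable_names) if variable_names \
                else tuple(f"x{i}" for i in range(self.x.shape[1]))
        self.grades = np.asarray(grades, dtype=int)
        if not np.isfinite(self.x).all():
            raise ValueError("features must be finite")
        if not np.isin(self.grades, (1, 2, 3)).all():
            raise ValueError("grades must be in {1, 2, 3}")
        if len(self.grades) != self.x.shape[0]:
            raise ValueError("features and grades length mismatch")
        self.genome = genome

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, genome: Genome,
                       grade_column: str = "grade",
                       variable_names=None) -> "ANNClassifier":
        names = list(variable_names) if variable_names is not None else \
            [c for c in table.columns if c not in (grade_column, "file")]
        return cls(table[names], table[grade_column].to_numpy(), genome)

    def fit(self, data_split: DataSplit | None = None, seed: int = 0,
            max_epochs: int = MAX_EPOCHS) -> TrainedModel:
        genome = self.genome
        n = self.x.shape[0]
        if data_split is None:
            data_split = split(n, seed)
        tr = np.asarray(data_split.train, dtype=int)
        va = np.asarray(data_split.validation, dtype=int)
        te = np.asarray(data_split.test, dtype=int)

        xmin = self.x[tr].min(axis=0)
        xmax = self.x[tr].max(axis=0)
        span = np.maximum(xmax - xmin, 1e-300)
        xs = 2.0 * (self.x - xmin) / span - 1.0
        targets = np.eye(N_CLASSES)[self.grades - 1]

        net = _Network(self.x.shape[1], genome)
        rng = np.random.default_rng(seed)
        params = net.init_params(rng)
        stepper = _make_stepper(genome.train_fn, net, xs[tr], targets[tr])

        record = {"train_mse": [], "validation_mse": [], "test_mse": []}
        best_params = params.copy()
        best_val = np.inf
        val_increases = 0
        prev_val = np.inf
        stopped = "max_epochs"
        epochs_run = 0
        for epoch in range(max_epochs):
            params, train_mse, grad = stepper(params)
            if not np.isfinite(train_mse) or not np.isfinite(params).all():
                raise TrainingDivergedError(epoch)
            val_mse = net.loss(params, xs[va], targets[va]) if va.size else np.inf
            test_mse = net.loss(params, xs[te], targets[te]) if te.size else np.nan
            record["train_mse"].append(float(train_mse))
            record["validation_mse"].append(float(val_mse))
            record["test_mse"].append(float(test_mse))
            epochs_run = epoch + 1
            if va.size:
                if val_mse < best_val:
                    best_val = val_mse
                    best_params = params.copy()
                val_increases = val_increases + 1 if val_mse > prev_val else 0
                prev_val = val_mse
                if val_increases >= VALIDATION_PATIENCE:
                    stopped = "validation"
                    params = best_params
                    break
            if float(np.linalg.norm(grad)) < GRADIENT_FLOOR:
                stopped = "gradient_floor"
                break
        else:
            if va.size and best_val < np.inf:
                params = best_params

        if va.size and stopped == "max_epochs":
            pass  # best-validation weights already restored above

        ws, bs = net.unflatten(params)
        record.update(epochs=epochs_run, stopped_reason=stopped,
                      split={"train": tr.tolist(), "validation": va.tolist(),
                             "test": te.tolist()})
        return TrainedModel(genome=genome, weights=[w.copy() for w in ws],
                            biases=[b.copy() for b in bs],
                            input_min=xmin, input_max=xmax,
                            variable_names=self.variable_names,
                            training_record=record, seed=seed)


def train(features, grades, genome: Genome, data_split: DataSplit | None = None,
          seed: int = 0, max_epochs: int = MAX_EPOCHS) -> TrainedModel:
    """Functional wrapper: build an :class:`ANNClassifier` and fit it."""
    return ANNClassifier(features, grades, genome).fit(data_split, seed=seed,
                                                       max_epochs=max_epochs)


def predict(model: TrainedModel, feature_vector):
    """Forward pass for a single vector; returns (scores (3,), grade)."""
    scores, grades = model.predict(feature_vector)
    return scores[0], int(grades[0])
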