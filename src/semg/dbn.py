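"""Restricted Boltzmann machines and a deep belief network classifier.

An RBM is a bipartite energy-based model over binary visible and hidden
units with energy

    E(v, h) = -sum_i a_i v_i - sum_j b_j h_j - sum_ij w_ij v_i h_j

and joint distribution P(v, h) = exp(-E) / Z.  Conditionals factor into
independent sigmoids, which makes block Gibbs sampling and Hinton's
contrastive-divergence (CD-k) gradient approximation cheap.  A deep
belief network stacks greedily pretrained RBMs — each layer trained on
the hidden activation probabilities of the one below — and tops them with
a softmax classifier; the whole network is then fine-tuned by supervised
backpropagation from the pretrained weights.

Real-valued entropy features are min-max scaled to [0, 1] on the training
set and treated as visible activation probabilities, the standard recipe
for feeding continuous inputs to Bernoulli RBMs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "RBMParams",
    "DBNModel",
    "TrainConfig",
    "sigmoid",
    "rbm_energy",
    "rbm_joint_table",
    "rbm_log_likelihood",
    "p_h_given_v",
    "p_v_given_h",
    "cd_update",
    "pretrain",
    "finetune",
    "train_dbn",
    "predict",
    "save_model",
    "load_model",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBMParams:
    """One RBM's parameters: weights ``W`` (n_visible x n_hidden), visible
    offsets ``a``, hidden offsets ``b``."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.W.shape != (self.a.size, self.b.size):
            raise ValueError(
                f"W shape {self.W.shape} inconsistent with offsets "
                f"({self.a.size} visible, {self.b.size} hidden)"
            )
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.a))
                and np.all(np.isfinite(self.b))):
            raise ValueError("RBM parameters contain non-finite values")

    @property
    def n_visible(self) -> int:
        return self.a.size

    @property
    def n_hidden(self) -> int:
        return self.b.size

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass
class TrainConfig:
    """DBN training hyperparameters.

    Layer sizes default to three hidden layers of 300 units, the depth and
    width at which the classifier's accuracy peaks on the gesture task.
    Pretraining is CD-k with plain stochastic gradient steps; fine-tuning
    is mini-batch gradient descent on the softmax cross-entropy with
    classical momentum (weight decay off by default).
    """

    layer_sizes: tuple[int, ...] = (300, 300, 300)
    lr_pretrain: float = 0.05
    lr_finetune: float = 0.1
    epochs_pretrain: int = 30
    epochs_finetune: int = 400
    batch_size: int = 20
    cd_k: int = 1
    seed: int = 0
    momentum: float = 0.9
    weight_decay: float = 0.0
    finetune_scope: Literal["full", "head"] = "full"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.lr_pretrain <= 0 or self.lr_finetune <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs_pretrain < 0 or self.epochs_finetune < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1 or self.cd_k < 1:
            raise ValueError("batch_size and cd_k must be >= 1")


@dataclass
class DBNModel:
    """Pretrained-and-fine-tuned stack plus softmax head and input scaler."""

    rbm_stack: list[RBMParams]
    softmax_W: np.ndarray        # (last hidden, n_classes)
    softmax_b: np.ndarray        # (n_classes,)
    feature_min: np.ndarray
    feature_max: np.ndarray
    classes: np.ndarray          # original class ids, ascending
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = [r.n_hidden for r in self.rbm_stack]
        for lower, upper in zip(self.rbm_stack, self.rbm_stack[1:]):
            if upper.n_visible != lower.n_hidden:
                raise ValueError("inconsistent layer chain in RBM stack")
        if self.rbm_stack and self.softmax_W.shape[0] != sizes[-1]:
            raise ValueError("softmax input size does not match last hidden layer")

    @property
    def n_classes(self) -> int:
        return self.classes.size

    @property
    def n_features(self) -> int:
        return self.rbm_stack[0].n_visible if self.rbm_stack else self.softmax_W.shape[0]


# ---------------------------------------------------------------------------
# Energy model and exact enumeration
# ---------------------------------------------------------------------------

def rbm_energy(v: np.ndarray, h: np.ndarray, theta: RBMParams) -> float:
    """Energy of one (v, h) configuration: the bilinear form
    -a.v - b.h - v'Wh."""
    v = np.asarray(v, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if v.size != theta.n_visible or h.size != theta.n_hidden:
        raise ValueError(
            f"state sizes ({v.size}, {h.size}) do not match RBM "
            f"({theta.n_visible}, {theta.n_hidden})"
        )
    return float(-theta.a @ v - theta.b @ h - v @ theta.W @ h)


def _binary_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, row index = binary value."""
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(float)


def rbm_joint_table(theta: RBMParams) -> np.ndarray:
    """Exact joint distribution P(v, h) by full enumeration.

    Returns a (2^n_visible, 2^n_hidden) table summing to 1; row/column
    indices are the binary values of v and h.  Guarded to at most 16 total
    units.
    """
    nv, nh = theta.n_visible, theta.n_hidden
    if nv + nh > 16:
        raise ValueError(f"enumeration limited to 16 total units, got {nv + nh}")
    V = _binary_states(nv)
    H = _binary_states(nh)
    # -E(v,h) for all pairs at once
    neg_e = (V @ theta.a)[:, None] + (H @ theta.b)[None, :] + V @ theta.W @ H.T
    neg_e -= neg_e.max()  # overflow guard; cancels in the normalization
    table = np.exp(neg_e)
    return table / table.sum()


def rbm_log_likelihood(data: np.ndarray, theta: RBMParams) -> float:
    """Mean exact log-likelihood of binary visible rows under the RBM
    (enumeration over hidden states; small models only)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nv, nh = theta.n_visible, theta.n_hidden
    if nv + nh > 16:
        raise ValueError(f"enumeration limited to 16 total units, got {nv + nh}")
    V = _binary_states(nv)
    H = _binary_states(nh)
    neg_e_all = (V @ theta.a)[:, None] + (H @ theta.b)[None, :] + V @ theta.W @ H.T
    shift = neg_e_all.max()
    log_z = shift + np.log(np.exp(neg_e_all - shift).sum())
    neg_e_data = (data @ theta.a)[:, None] + (H @ theta.b)[None, :] + data @ theta.W @ H.T
    log_p = np.log(np.exp(neg_e_data - shift).sum(axis=1)) + shift - log_z
    return float(log_p.mean())


# ---------------------------------------------------------------------------
# Conditionals and contrastive divergence
# ---------------------------------------------------------------------------

def p_h_given_v(v: np.ndarray, theta: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) = sigmoid(b_j + sum_i w_ij v_i); accepts a single
    vector or a batch of rows."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != theta.n_visible:
        raise ValueError(f"visible size {v.shape[-1]} != {theta.n_visible}")
    return sigmoid(v @ theta.W + theta.b)


def p_v_given_h(h: np.ndarray, theta: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) = sigmoid(a_i + sum_j w_ij h_j)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != theta.n_hidden:
        raise ValueError(f"hidden size {h.shape[-1]} != {theta.n_hidden}")
    return sigmoid(h @ theta.W.T + theta.a)


def cd_update(
    batch: np.ndarray,
    theta: RBMParams,
    lr: float,
    cd_k: int = 1,
    rng: np.random.Generator | None = None,
) -> RBMParams:
    """One contrastive-divergence parameter update from a mini-batch.

    Positive statistics use the data and hidden activation probabilities;
    the reconstruction chain runs ``cd_k`` alternating Gibbs steps with
    hidden states sampled binary and visible units kept as probabilities
    (the usual variance-reduction choice).  Returns updated parameters;
    the input is not modified.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("batch is empty")
    if np.any(batch < 0) or np.any(batch > 1):
        raise ValueError("visible entries must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    n = batch.shape[0]

    h_prob = p_h_given_v(batch, theta)
    pos_w = batch.T @ h_prob
    h_state = (rng.random(h_prob.shape) < h_prob).astype(float)
    v_recon = batch
    for _ in range(cd_k):
        v_recon = p_v_given_h(h_state, theta)
        h_recon = p_h_given_v(v_recon, theta)
        h_state = (rng.random(h_recon.shape) < h_recon).astype(float)
    neg_w = v_recon.T @ h_recon

    return RBMParams(
        W=theta.W + lr * (pos_w - neg_w) / n,
        a=theta.a + lr * (batch - v_recon).mean(axis=0),
        b=theta.b + lr * (h_prob - h_recon).mean(axis=0),
    )


def _init_rbm(n_visible: int, n_hidden: int, rng: np.random.Generator,
              weight_sd: float = 0.2) -> RBMParams:
    # Gaussian weights, zero offsets.  The scale matters for narrow inputs:
    # with only ~12 visible units, very small weights leave every hidden
    # activation pinned near 0.5 regardless of the input and gradients
    # vanish through the sigmoid stack, so a moderate scale is used.
    return RBMParams(
        W=rng.normal(0.0, weight_sd, size=(n_visible, n_hidden)),
        a=np.zeros(n_visible),
        b=np.zeros(n_hidden),
    )


def pretrain(
    features: np.ndarray,
    layer_sizes: Sequence[int],
    cfg: TrainConfig,
) -> list[RBMParams]:
    """Greedy layer-wise CD pretraining.

    Layer k is trained on the hidden activation probabilities propagated
    through the already-trained layers below it; features must already lie
    in [0, 1].
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("pretraining features must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    stack: list[RBMParams] = []
    layer_input = X
    for size in layer_sizes:
        theta = _init_rbm(layer_input.shape[1], size, rng)
        n = layer_input.shape[0]
        for _ in range(cfg.epochs_pretrain):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = layer_input[order[start:start + cfg.batch_size]]
                theta = cd_update(batch, theta, cfg.lr_pretrain, cfg.cd_k, rng)
        stack.append(theta)
        layer_input = p_h_given_v(layer_input, theta)
    return stack


# ---------------------------------------------------------------------------
# Supervised head and fine-tuning
# ---------------------------------------------------------------------------

def _forward(stack: Sequence[RBMParams], X: np.ndarray) -> list[np.ndarray]:
    """Deterministic forward pass; returns activations per layer
    (including the input as element 0)."""
    acts = [X]
    for theta in stack:
        acts.append(sigmoid(acts[-1] @ theta.W + theta.b))
    return acts


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def finetune(
    stack: Sequence[RBMParams],
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    history: list | None = None,
) -> DBNModel:
    """Supervised fine-tuning from the pretrained stack.

    A softmax head is attached to the top hidden layer and the whole
    network (or only the head, with ``finetune_scope='head'``) is trained
    by mini-batch gradient descent on the cross-entropy.  Features must be
    scaled to [0, 1]; labels are arbitrary integer class ids.  The stack
    passed in is copied, not modified.  If ``history`` is given, the
    per-epoch mean cross-entropy is appended to it.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y_raw = np.asarray(labels).ravel()
    classes = np.unique(y_raw)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in y_raw])
    n, _ = X.shape
    k = classes.size

    rng = np.random.default_rng(cfg.seed + 1)
    stack = [theta.copy() for theta in stack]
    top = stack[-1].n_hidden if stack else X.shape[1]
    Wo = rng.normal(0.0, 0.01, size=(top, k))
    bo = np.zeros(k)
    onehot = np.eye(k)[y]

    vel_Wo = np.zeros_like(Wo)
    vel_bo = np.zeros_like(bo)
    vel_W = [np.zeros_like(t.W) for t in stack]
    vel_b = [np.zeros_like(t.b) for t in stack]

    for _ in range(cfg.epochs_finetune):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            acts = _forward(stack, X[sel])
            probs = _softmax(acts[-1] @ Wo + bo)
            m = sel.size
            epoch_loss += -np.sum(np.log(probs[np.arange(m), y[sel]] + 1e-300))

            delta = (probs - onehot[sel]) / m          # d loss / d logits
            grad_Wo = acts[-1].T @ delta + cfg.weight_decay * Wo
            grad_bo = delta.sum(axis=0)
            back = delta @ Wo.T
            vel_Wo = cfg.momentum * vel_Wo - cfg.lr_finetune * grad_Wo
            vel_bo = cfg.momentum * vel_bo - cfg.lr_finetune * grad_bo
            Wo += vel_Wo
            bo += vel_bo
            if cfg.finetune_scope == "full":
                for li in range(len(stack) - 1, -1, -1):
                    act = acts[li + 1]
                    delta_l = back * act * (1.0 - act)
                    grad_W = acts[li].T @ delta_l + cfg.weight_decay * stack[li].W
                    grad_b = delta_l.sum(axis=0)
                    back = delta_l @ stack[li].W.T
                    vel_W[li] = cfg.momentum * vel_W[li] - cfg.lr_finetune * grad_W
                    vel_b[li] = cfg.momentum * vel_b[li] - cfg.lr_finetune * grad_b
                    stack[li].W += vel_W[li]
                    stack[li].b += vel_b[li]
        if history is not None:
            history.append(epoch_loss / n)

    return DBNModel(
        rbm_stack=stack, softmax_W=Wo, softmax_b=bo,
        feature_min=np.zeros(X.shape[1]), feature_max=np.ones(X.shape[1]),
        classes=classes, seed=cfg.seed,
    )


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X.min(axis=0), X.max(axis=0)


def _apply_scaler(X: np.ndarray, fmin: np.ndarray, fmax: np.ndarray) -> np.ndarray:
    span = fmax - fmin
    scaled = np.zeros_like(X, dtype=float)
    ok = span > 0
    scaled[:, ok] = (X[:, ok] - fmin[ok]) / span[ok]
    return np.clip(scaled, 0.0, 1.0)


def train_dbn(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    history: list | None = None,
) -> DBNModel:
    """End-to-end training: scale to [0, 1], greedy CD pretraining of the
    stack, then supervised fine-tuning with the softmax head."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).ravel()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    fmin, fmax = _fit_scaler(X)
    Xs = _apply_scaler(X, fmin, fmax)
    stack = pretrain(Xs, cfg.layer_sizes, cfg)
    model = finetune(stack, Xs, y, cfg, history=history)
    model.feature_min = fmin
    model.feature_max = fmax
    return model


def predict(model: DBNModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class-probability rows and argmax labels (lowest class id wins ties).

    The model's training-set min-max scaler is applied internally, with
    out-of-range values clipped to [0, 1].
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    Xs = _apply_scaler(X, model.feature_min, model.feature_max)
    acts = _forward(model.rbm_stack, Xs)
    probs = _softmax(acts[-1] @ model.softmax_W + model.softmax_b)
    labels = model.classes[np.argmax(probs, axis=1)]
    return probs, labels


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: DBNModel, path) -> None:
    """Save a model to a single ``.npz`` archive; round-trips bit-exactly."""
    arrays = {
        "softmax_W": model.softmax_W,
        "softmax_b": model.softmax_b,
        "feature_min": model.feature_min,
        "feature_max": model.feature_max,
        "classes": model.classes,
        "seed": np.array(model.seed),
        "n_layers": np.array(len(model.rbm_stack)),
    }
    for i, theta in enumerate(model.rbm_stack):
        arrays[f"W_{i}"] = theta.W
        arrays[f"a_{i}"] = theta.a
        arrays[f"b_{i}"] = theta.b
    np.savez(path, **arrays)


def load_model(path) -> DBNModel:
    with np.load(path) as data:
        stack = [
            RBMParams(data[f"W_{i}"], data[f"a_{i}"], data[f"b_{i}"])
            for i in range(int(data["n_layers"]))
        ]
        return DBNModel(
            rbm_stack=stack,
            softmax_W=data["softmax_W"],
            softmax_b=data["softmax_b"],
            feature_min=data["feature_min"],
            feature_max=data["feature_max"],
            classes=data["classes"],
            seed=int(data["seed"]),
        )
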