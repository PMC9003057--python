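"""Feed-forward MLP cross-predictor for generalized synchronization.

Two brain areas are treated as a drive system x(t) and a response system
y(t); if a functional relation y(t) = F(x(t)) exists, a universal
approximator trained to map x(t) to y(t) will predict the response
trajectory well. The predictor here is a fully connected 3-10-10-3
network: 3 linear inputs, two hidden layers of 10 units with a softmax
activation across each layer, and 3 linear outputs. It is trained with
Adam (lr 0.001) for 1000 iterations on min-max normalized trajectories,
with a seeded 50/50 shuffle-split into training and validation halves.

An "iteration" is one pass over the training split (an epoch), taken in
shuffled minibatches of at most ``batch_size`` samples — the semantics
of every mainstream MLP implementation. At lr 0.001 an Adam update
moves each weight by at most ~0.001, so 1000 *single-step* passes
cannot leave the neighbourhood of the initialization; the roughly 10^4
minibatch updates of the default configuration are what make the quoted
iteration budget sufficient. Setting ``batch_size=None`` selects strict
full-batch training (one gradient step per iteration) for comparison.

The implementation is deliberately self-contained numpy: the network is
tiny, training is seeded end to end, and identical (data, config, seed)
reproduce bit-identical outcomes on one platform. Many independent
networks (e.g. the 20 ordered region pairs of one connectivity matrix)
are trained simultaneously by stacking their weights along a leading
axis and advancing them through one loop of batched matmuls; a single
fit is just the stack-of-one case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .regions import RegionTrajectory

__all__ = [
    "TrainConfig",
    "TrainOutcome",
    "MLPPredictor",
    "normalize01",
    "denormalize01",
    "split_shuffle",
    "fit",
    "fit_batch",
    "InsufficientDataError",
    "TrainingDivergenceError",
]

_ACTIVATIONS = ("softmax", "sigmoid", "tanh")


class InsufficientDataError(ValueError):
    """Too few samples to split and train."""


class TrainingDivergenceError(RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite loss at iteration {iteration}")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol of the cross-predictor.

    ``iterations`` counts passes over the training split; each pass runs
    Adam on shuffled minibatches of at most ``batch_size`` samples
    (``batch_size=None`` means one full-batch gradient step per
    iteration). ``hidden_activation`` defaults to softmax across each
    hidden layer's units; sigmoid and tanh are provided as conventional
    alternatives. Adam moment parameters are the standard
    (0.9, 0.999, 1e-8).
    """

    hidden_layers: tuple[int, ...] = (10, 10)
    hidden_activation: str = "softmax"
    learning_rate: float = 0.001
    iterations: int = 1000
    batch_size: int | None = 200
    seed: int = 0
    split_fraction: float = 0.5
    min_samples: int = 50
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 or None for full batch")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(
                f"hidden_activation must be one of {_ACTIVATIONS}, "
                f"got {self.hidden_activation!r}"
            )


def _as_values(traj: RegionTrajectory | np.ndarray) -> np.ndarray:
    if isinstance(traj, RegionTrajectory):
        return traj.values
    arr = np.asarray(traj, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a D x N array or RegionTrajectory")
    return arr


def normalize01(
    traj: RegionTrajectory | np.ndarray,
) -> tuple[RegionTrajectory | np.ndarray, np.ndarray]:
    """Min-max scale each state variable (row) to [0, 1].

    Returns the scaled trajectory and a (D, 2) array of per-row (min, max)
    for inversion. Constant rows have no defined scale and raise.
    """
    values = _as_values(traj)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    if np.any(hi <= lo):
        bad = int(np.argmax((hi <= lo).ravel()))
        raise ValueError(f"row {bad} is constant; (0,1) normalization undefined")
    scaled = (values - lo) / (hi - lo)
    params = np.hstack([lo, hi])
    if isinstance(traj, RegionTrajectory):
        out = RegionTrajectory(
            values=scaled,
            region=traj.region,
            window=traj.window,
            trial_index=traj.trial_index.copy(),
        )
        return out, params
    return scaled, params


def denormalize01(values: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Invert :func:`normalize01` given its (min, max) parameters."""
    lo = params[:, :1]
    hi = params[:, 1:]
    return values * (hi - lo) + lo


def split_shuffle(
    x: RegionTrajectory | np.ndarray,
    y: RegionTrajectory | np.ndarray,
    seed: int,
    fraction: float = 0.5,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Jointly shuffle paired sample columns and split train/validation.

    The pairing (x(t_i), y(t_i)) is preserved: one permutation is applied
    to the columns of both trajectories, then the first ``fraction`` of
    columns becomes the training pair and the rest the validation pair.
    """
    xv = _as_values(x)
    yv = _as_values(y)
    if xv.shape[1] != yv.shape[1]:
        raise ValueError(
            f"drive has {xv.shape[1]} samples but response has {yv.shape[1]}"
        )
    n = xv.shape[1]
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * fraction))
    tr, va = perm[:n_train], perm[n_train:]
    return (xv[:, tr], yv[:, tr]), (xv[:, va], yv[:, va])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MLPPredictor:
    """A fitted feed-forward network mapping 3-vectors to 3-vectors.

    Weights are stored as a list of (W, b) pairs; the hidden activation is
    applied across each hidden layer's units, the output layer is linear.
    """

    def __init__(self, weights: list[tuple[np.ndarray, np.ndarray]], activation: str):
        self.weights = weights
        self.activation = activation

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        sizes = [self.weights[0][0].shape[0]]
        sizes += [w.shape[1] for w, _ in self.weights]
        return tuple(sizes)

    def _hidden(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "softmax":
            return _softmax(z)
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        return np.tanh(z)

    def _forward(self, x_nd: np.ndarray) -> list[np.ndarray]:
        """Return activations per layer for samples-by-features input."""
        acts = [x_nd]
        h = x_nd
        for w, b in self.weights[:-1]:
            h = self._hidden(h @ w + b)
            acts.append(h)
        w, b = self.weights[-1]
        acts.append(h @ w + b)
        return acts

    def predict(self, x: np.ndarray | RegionTrajectory) -> np.ndarray:
        """Predict the response trajectory; input and output are D x N."""
        xv = _as_values(x)
        return self._forward(xv.T)[-1].T

    def save_weights(self, path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(self.weights):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, activation=self.activation, **arrays)

    @classmethod
    def load_weights(cls, path) -> "MLPPredictor":
        data = np.load(path)
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        weights = [(data[f"W{i}"], data[f"b{i}"]) for i in range(n_layers)]
        return cls(weights, str(data["activation"]))


@dataclass
class TrainOutcome:
    """Fitted predictor with its train/validation scores and provenance."""

    predictor: MLPPredictor
    r2_train: float
    r2_validation: float
    config: TrainConfig
    normalization_params: dict[str, np.ndarray] = field(default_factory=dict)
    n_train: int = 0
    n_validation: int = 0

    def to_json(self) -> str:
        payload = {
            "r2_train": self.r2_train,
            "r2_validation": self.r2_validation,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=2)


def _init_weights(
    sizes: tuple[int, ...], rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded Glorot-uniform weights, zero biases."""
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((w, b))
    return weights


def _hidden_grad(activation: str, a: np.ndarray, grad_a: np.ndarray) -> np.ndarray:
    """Gradient through the hidden activation, given activations a."""
    if activation == "softmax":
        # Jacobian of softmax: diag(a) - a a^T, applied row-wise
        inner = (grad_a * a).sum(axis=-1, keepdims=True)
        return a * (grad_a - inner)
    if activation == "sigmoid":
        return grad_a * a * (1.0 - a)
    return grad_a * (1.0 - a * a)


def _stacked_forward(
    x: np.ndarray,
    weights: list[tuple[np.ndarray, np.ndarray]],
    activation: str,
) -> list[np.ndarray]:
    """Forward pass for B stacked networks; x is (B, n, d_in)."""
    acts = [x]
    h = x
    for w, b in weights[:-1]:
        z = h @ w + b
        if activation == "softmax":
            h = _softmax(z)
        elif activation == "sigmoid":
            h = 1.0 / (1.0 + np.exp(-z))
        else:
            h = np.tanh(z)
        acts.append(h)
    w, b = weights[-1]
    acts.append(h @ w + b)
    return acts


def _check_homogeneous(cfgs: list[TrainConfig]) -> TrainConfig:
    ref = cfgs[0]
    keys = (
        "hidden_layers",
        "hidden_activation",
        "learning_rate",
        "iterations",
        "batch_size",
        "split_fraction",
        "adam_beta1",
        "adam_beta2",
        "adam_eps",
    )
    for cfg in cfgs[1:]:
        for key in keys:
            if getattr(cfg, key) != getattr(ref, key):
                raise ValueError(
                    "fit_batch requires identical configs apart from the seed; "
                    f"{key} differs"
                )
    return ref


def fit_batch(
    drives: list[RegionTrajectory | np.ndarray],
    responses: list[RegionTrajectory | np.ndarray],
    cfgs: list[TrainConfig],
) -> list[TrainOutcome]:
    """Train many independent cross-predictors through one stacked loop.

    All pairs must share the sample count and all configs must agree on
    everything but the seed; each network still gets its own seeded
    shuffle-split, initialization and minibatch order, so the outcomes
    match one-at-a-time :func:`fit` calls.
    """
    from .connectivity import r2_score  # local import: connectivity uses fit

    if not (len(drives) == len(responses) == len(cfgs) > 0):
        raise ValueError("drives, responses and cfgs must have equal length")
    cfg = _check_homogeneous(cfgs)

    xs = [_as_values(d) for d in drives]
    ys = [_as_values(r) for r in responses]
    n = xs[0].shape[1]
    for xv, yv in zip(xs, ys):
        if xv.shape[1] != n or yv.shape[1] != n:
            raise ValueError("all pairs must share one sample count")
        if xv.shape[1] < cfg.min_samples:
            raise InsufficientDataError(
                f"{xv.shape[1]} samples < required minimum {cfg.min_samples}"
            )
        for name, v in (("drive", xv), ("response", yv)):
            if v.min() < -1e-6 or v.max() > 1 + 1e-6:
                raise ValueError(
                    f"{name} trajectory is not normalized to (0, 1); "
                    "call normalize01 first"
                )

    n_nets = len(xs)
    d_in, d_out = xs[0].shape[0], ys[0].shape[0]
    sizes = (d_in,) + cfg.hidden_layers + (d_out,)

    # per-net seeded split / init / minibatch-order streams
    xtr_l, ytr_l, xva_l, yva_l, init_l, batch_rngs = [], [], [], [], [], []
    for xv, yv, c in zip(xs, ys, cfgs):
        ss = np.random.SeedSequence([int(c.seed) & 0x7FFFFFFF])
        seed_split, seed_init, seed_batches = ss.spawn(3)
        (xtr, ytr), (xva, yva) = split_shuffle(
            xv, yv, seed=seed_split, fraction=c.split_fraction
        )
        xtr_l.append(xtr.T)
        ytr_l.append(ytr.T)
        xva_l.append(xva.T)
        yva_l.append(yva.T)
        init_l.append(_init_weights(sizes, np.random.default_rng(seed_init)))
        batch_rngs.append(np.random.default_rng(seed_batches))

    xtr = np.stack(xtr_l)  # (B, n_train, d_in)
    ytr = np.stack(ytr_l)
    n_train = xtr.shape[1]
    weights = [
        (
            np.stack([init_l[b][li][0] for b in range(n_nets)]),
            np.stack([init_l[b][li][1] for b in range(n_nets)])[:, None, :],
        )
        for li in range(len(sizes) - 1)
    ]

    batch = n_train if cfg.batch_size is None else min(cfg.batch_size, n_train)
    m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
    lr = cfg.learning_rate
    step = 0

    for it in range(1, cfg.iterations + 1):
        if batch < n_train:
            order = np.stack([rng.permutation(n_train) for rng in batch_rngs])
        for s0 in range(0, n_train, batch):
            if batch < n_train:
                idx = order[:, s0 : s0 + batch, None]
                xb = np.take_along_axis(xtr, idx, axis=1)
                yb = np.take_along_axis(ytr, idx, axis=1)
            else:
                xb, yb = xtr, ytr
            acts = _stacked_forward(xb, weights, cfg.hidden_activation)
            resid = acts[-1] - yb
            loss = np.mean(resid * resid, axis=(1, 2))
            if not np.all(np.isfinite(loss)):
                raise TrainingDivergenceError(it)

            grads = []
            grad_h = resid * (2.0 / (resid.shape[1] * d_out))
            for li in range(len(weights) - 1, -1, -1):
                w, _ = weights[li]
                if li < len(weights) - 1:  # back through the hidden activation
                    grad_h = _hidden_grad(
                        cfg.hidden_activation, acts[li + 1], grad_h
                    )
                gw = np.swapaxes(acts[li], -1, -2) @ grad_h
                gb = grad_h.sum(axis=1, keepdims=True)
                grads.append((gw, gb))
                grad_h = grad_h @ np.swapaxes(w, -1, -2)
            grads.reverse()

            step += 1
            c1 = 1.0 - b1**step
            c2 = 1.0 - b2**step
            new_weights = []
            for li, ((w, b), (gw, gb), (mw, mb), (vw, vb)) in enumerate(
                zip(weights, grads, m, v)
            ):
                mw = b1 * mw + (1 - b1) * gw
                mb = b1 * mb + (1 - b1) * gb
                vw = b2 * vw + (1 - b2) * gw * gw
                vb = b2 * vb + (1 - b2) * gb * gb
                m[li] = (mw, mb)
                v[li] = (vw, vb)
                w = w - lr * (mw / c1) / (np.sqrt(vw / c2) + eps)
                b = b - lr * (mb / c1) / (np.sqrt(vb / c2) + eps)
                new_weights.append((w, b))
            weights = new_weights

    outcomes = []
    for bi in range(n_nets):
        net = [(w[bi], b[bi, 0]) for w, b in weights]
        predictor = MLPPredictor(net, cfg.hidden_activation)
        r2_tr = r2_score(ytr_l[bi].T, predictor.predict(xtr_l[bi].T)).value
        r2_va = r2_score(yva_l[bi].T, predictor.predict(xva_l[bi].T)).value
        outcomes.append(
            TrainOutcome(
                predictor=predictor,
                r2_train=float(r2_tr),
                r2_validation=float(r2_va),
                config=cfgs[bi],
                n_train=n_train,
                n_validation=xva_l[bi].shape[0],
            )
        )
    return outcomes


def fit(
    drive: RegionTrajectory | np.ndarray,
    response: RegionTrajectory | np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> TrainOutcome:
    """Train the cross-predictor drive -> response and score both splits.

    Both trajectories must already be min-max normalized to (0, 1) (see
    :func:`normalize01`). Training minimizes the mean squared error over
    the 3 output components on the training split for ``cfg.iterations``
    seeded minibatch passes; R-squared is then computed on both splits,
    and the held-out validation value is the connectivity estimate.

    Raises
    ------
    InsufficientDataError
        If fewer than ``cfg.min_samples`` paired samples are available.
    TrainingDivergenceError
        If the loss becomes non-finite, reporting the iteration.
    """
    return fit_batch([drive], [response], [cfg])[0]
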