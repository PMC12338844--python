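"""Surrogate networks G1..G4, the SIVM/DIVM losses, and the training loop.

Each surrogate holds two fully connected tanh networks (4 hidden layers of
20 units, Glorot-uniform initialization) mapping (f, s) -> R for SIVM or
(f, s, f', s') -> R for DIVM.  Training minimizes

    L_SIVM = mean_i (f'_i  - G1(f_i, s_i) - G2(f_i, s_i) s'_i)^2
    L_DIVM = mean_i (f''_i - G3(x_i) - G4(x_i) s''_i)^2

with Adam (lr 1e-3).  Inputs are affinely whitened with training-set
statistics and network outputs carry fixed physical scales, so the tanh
stacks operate in their responsive range; the statistics are stored on the
surrogate, making evaluation self-contained.  Every ``val_check_every``
epochs the surrogate is rolled out on the validation series and the best
E_vali snapshot is kept; training stops early when E_vali stagnates.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from runtumble import rollout as _rollout

__all__ = ["NetSpec", "TrainedSurrogate", "make_surrogate", "sivm_loss", "divm_loss", "train"]

_EXCITATION_EPS = 1e-12


@dataclass(frozen=True)
class NetSpec:
    """Architecture and optimization settings."""

    hidden_layers: int = 4
    hidden_width: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 1000
    val_check_every: int = 50
    patience: int = 10
    min_rel_improve: float = 1e-3

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("network dimensions must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class _MLP:
    """Plain NumPy multilayer perceptron with tanh hidden activations."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.dims = list(dims)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, X: np.ndarray):
        """Returns (output (n,), list of layer activations for backprop)."""
        acts = [X]
        h = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.tanh(h)
            acts.append(h)
        return h[:, 0], acts

    def value(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, acts, dout: np.ndarray):
        """Gradients of sum(dout * output) w.r.t. weights and biases."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout[:, None]  # (n, 1) at the linear output
        for i in range(len(self.W) - 1, -1, -1):
            a_in = acts[i]
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - acts[i] ** 2)
        return gW, gb

    def params(self):
        return self.W + self.b

    def state(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def load(self, state):
        self.W = [w.copy() for w in state[0]]
        self.b = [b.copy() for b in state[1]]


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


@dataclass
class TrainedSurrogate:
    """A (possibly untrained) SIVM or DIVM surrogate.

    ``net_a``/``net_b`` are the drift and stimulus-coefficient networks
    (G1/G2 for SIVM, G3/G4 for DIVM).  ``x_mean``/``x_std`` whiten inputs;
    ``scale_a``/``scale_b`` convert network outputs to physical units.
    ``flags`` records identifiability warnings such as 'coefficient_untrained'.
    """

    kind: str
    net_a: _MLP
    net_b: _MLP
    spec: NetSpec
    seed: int
    x_mean: np.ndarray
    x_std: np.ndarray
    scale_a: float = 1.0
    scale_b: float = 1.0
    history: list = field(default_factory=list)
    flags: set = field(default_factory=set)
    best_epoch: int | None = None

    @property
    def input_dim(self) -> int:
        return 2 if self.kind == "SIVM" else 4

    def g_pair(self, X: np.ndarray):
        """Evaluate both networks in physical units at raw inputs X (n, d)."""
        Xw = (np.asarray(X, float) - self.x_mean) / self.x_std
        return self.scale_a * self.net_a.value(Xw), self.scale_b * self.net_b.value(Xw)


def make_surrogate(kind: str, spec: NetSpec | None = None, rng_seed: int = 0) -> TrainedSurrogate:
    """Fresh surrogate with Glorot-uniform weights; deterministic in the seed."""
    if kind not in ("SIVM", "DIVM"):
        raise ValueError("kind must be 'SIVM' or 'DIVM'")
    spec = spec or NetSpec()
    d = 2 if kind == "SIVM" else 4
    dims = [d] + [spec.hidden_width] * spec.hidden_layers + [1]
    rng = np.random.default_rng(rng_seed)
    return TrainedSurrogate(
        kind=kind,
        net_a=_MLP(dims, rng),
        net_b=_MLP(dims, rng),
        spec=spec,
        seed=rng_seed,
        x_mean=np.zeros(d),
        x_std=np.ones(d),
    )


def _residuals(surrogate: TrainedSurrogate, X, c, target):
    a, b = surrogate.g_pair(X)
    return target - a - b * c


def sivm_loss(surrogate: TrainedSurrogate, X, s_prime, f_prime) -> float:
    """Mean squared SIVM residual over the batch."""
    if surrogate.kind != "SIVM":
        raise ValueError("surrogate is not a SIVM")
    if len(np.asarray(X)) == 0:
        raise ValueError("empty batch")
    return float(np.mean(_residuals(surrogate, X, np.asarray(s_prime), np.asarray(f_prime)) ** 2))


def divm_loss(surrogate: TrainedSurrogate, X, s_doubleprime, f_doubleprime) -> float:
    """Mean squared DIVM residual over the batch."""
    if surrogate.kind != "DIVM":
        raise ValueError("surrogate is not a DIVM")
    if len(np.asarray(X)) == 0:
        raise ValueError("empty batch")
    return float(np.mean(_residuals(surrogate, X, np.asarray(s_doubleprime), np.asarray(f_doubleprime)) ** 2))


def train(surrogate: TrainedSurrogate, dataset, spec: NetSpec | None = None) -> TrainedSurrogate:
    """Fit the surrogate on the dataset's training tuples.

    Uses minibatch Adam on the SIVM/DIVM loss; every ``val_check_every``
    epochs E_vali is computed by full rollout on the validation series and
    the best snapshot retained.  If the training stimuli never excite the
    coefficient channel (s' for SIVM, s'' for DIVM, degenerate to machine
    precision), the coefficient network receives no gradient: a
    'coefficient_untrained' flag is set and a warning emitted.
    """
    spec = spec or surrogate.spec
    if surrogate.kind == "SIVM":
        X, c, target = dataset.tuples_sivm("train")
        coeff_name = "G2"
    else:
        X, c, target = dataset.tuples_divm("train")
        coeff_name = "G4"
    if len(X) == 0:
        raise ValueError("no training tuples")
    val_records = dataset.records("val")

    surrogate.x_mean = X.mean(axis=0)
    std = X.std(axis=0)
    surrogate.x_std = np.where(std > _EXCITATION_EPS, std, 1.0)
    t_std = float(np.std(target))
    surrogate.scale_a = t_std if t_std > _EXCITATION_EPS else 1.0
    c_std = float(np.std(c))
    if c_std <= _EXCITATION_EPS:
        surrogate.flags.add("coefficient_untrained")
        warnings.warn(
            f"training stimuli do not excite the {coeff_name} channel; "
            "the coefficient network cannot be effectively trained"
        )
        surrogate.scale_b = surrogate.scale_a
    else:
        surrogate.scale_b = surrogate.scale_a / c_std

    if spec.max_epochs == 0:
        return surrogate

    Xw = (X - surrogate.x_mean) / surrogate.x_std
    n = len(Xw)
    rng = np.random.default_rng(surrogate.seed + 1)
    params = surrogate.net_a.params() + surrogate.net_b.params()
    opt = _Adam(params, spec.learning_rate)
    best = (np.inf, surrogate.net_a.state(), surrogate.net_b.state(), 0)
    stale = 0
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, cb, tb = Xw[idx], c[idx], target[idx]
            out_a, acts_a = surrogate.net_a.forward(xb)
            out_b, acts_b = surrogate.net_b.forward(xb)
            r = tb - surrogate.scale_a * out_a - surrogate.scale_b * out_b * cb
            epoch_loss += float(np.sum(r * r))
            coeff = -2.0 / len(idx)
            gWa, gba = surrogate.net_a.backward(acts_a, coeff * r * surrogate.scale_a)
            gWb, gbb = surrogate.net_b.backward(acts_b, coeff * r * cb * surrogate.scale_b)
            opt.step(params, gWa + gba + gWb + gbb)
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            surrogate.history.append({"epoch": epoch, "train_loss": epoch_loss, "e_vali": np.nan})
            raise RuntimeError(f"training loss diverged at epoch {epoch}")
        if epoch % spec.val_check_every == 0 or epoch == spec.max_epochs:
            if val_records:
                report = _rollout.evaluate(surrogate, _ValView(val_records), split="val")
                ev = report.e_vali
            else:
                ev = epoch_loss
            surrogate.history.append({"epoch": epoch, "train_loss": epoch_loss, "e_vali": ev})
            if ev < best[0] * (1.0 - spec.min_rel_improve):
                best = (ev, surrogate.net_a.state(), surrogate.net_b.state(), epoch)
                stale = 0
            else:
                if ev < best[0]:
                    best = (ev, surrogate.net_a.state(), surrogate.net_b.state(), epoch)
                stale += 1
                if stale >= spec.patience:
                    break
    surrogate.net_a.load(best[1])
    surrogate.net_b.load(best[2])
    surrogate.best_epoch = best[3]
    return surrogate


class _ValView:
    """Minimal dataset view exposing one list of records as a 'val' split."""

    def __init__(self, records):
        self._records = records

    def records(self, split):
        return self._records if split == "val" else []
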