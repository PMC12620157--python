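"""Denoising autoencoder used as the plug-and-play q-space prior.

A compact fully connected net (3 hidden layers, 64-32-64 by default, tanh)
maps a noisy b0-normalized q-space signal vector to its denoised version.
Training minimizes a per-volume weighted MSE in which the highest-b shell
receives an elevated weight (default 1.5), and is fully deterministic
given a seed. Implemented directly in numpy (Adam + backprop); the
environment ships no neural-network framework and the network is small
enough not to need one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol
from .signal_model import CompartmentParams, synthesize_signal, watson_odf

__all__ = [
    "DAEModel",
    "TrainingSet",
    "TrainingError",
    "DEFAULT_PARAM_RANGES",
    "make_training_set",
    "shell_weight_vector",
    "train_dae",
    "denoise",
]


class TrainingError(RuntimeError):
    """Raised when training diverges (NaN/Inf loss)."""


DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "fa": (0.05, 0.70),
    "Da": (0.5, 3.0),
    "De_par": (0.5, 3.0),
    "De_perp_ratio": (0.05, 1.0),   # De_perp = ratio * De_par
    "fw": (0.0, 0.30),
    "kappa": (2.0, 32.0),
}


@dataclass
class TrainingSet:
    clean_signals: np.ndarray   # (n_train, n_q), b0-normalized
    noisy_signals: np.ndarray   # (n_train, n_q)
    shell_ids: np.ndarray       # (n_q,)
    params: np.ndarray | None = None  # (n_train, 6): fa, Da, Depar, Deperp, fw, kappa

    def __post_init__(self) -> None:
        if self.clean_signals.shape != self.noisy_signals.shape:
            raise ValueError("clean/noisy shape mismatch")
        if self.clean_signals.size == 0:
            raise ValueError("empty training set")


@dataclass
class DAEModel:
    """Weights of the fully connected denoiser plus training metadata."""

    weights: list[np.ndarray]       # [W1, b1, W2, b2, W3, b3, W4, b4]
    shell_weights: np.ndarray       # per-volume loss weights
    training_meta: dict = field(default_factory=dict)

    @property
    def n_q(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = X
        for i in range(0, len(self.weights) - 2, 2):
            h = np.tanh(h @ self.weights[i] + self.weights[i + 1])
        return h @ self.weights[-2] + self.weights[-1]


def make_training_set(protocol: AcquisitionProtocol,
                      param_ranges: dict | None = None,
                      n_train: int = 10_000,
                      snr_range: tuple[float, float] = (10.0, 50.0),
                      seed: int = 0,
                      grid_order: int = 500) -> TrainingSet:
    """Simulate signals on the protocol's q-space manifold and add noise.

    Compartment parameters are drawn uniformly in their ranges, ODFs are
    Watson with uniform random axes, and per-sample Gaussian noise at an
    SNR drawn uniformly from ``snr_range`` perturbs the clean signals.
    """
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key}")
    rng = np.random.default_rng(seed)

    def draw(key: str) -> np.ndarray:
        lo, hi = ranges[key]
        return rng.uniform(lo, hi, size=n_train)

    fa, Da = draw("fa"), draw("Da")
    De_par = draw("De_par")
    De_perp = draw("De_perp_ratio") * De_par
    fw, kappa = draw("fw"), draw("kappa")
    mus = rng.standard_normal((n_train, 3))
    mus /= np.linalg.norm(mus, axis=1, keepdims=True)

    clean = np.empty((n_train, protocol.n_volumes))
    for i in range(n_train):
        params = CompartmentParams(fa[i], Da[i], De_par[i], De_perp[i],
                                   fw=fw[i])
        odf = watson_odf(mus[i], kappa[i], grid_order=grid_order)
        clean[i] = synthesize_signal(protocol, params, odf)

    lo, hi = snr_range
    if np.isinf(lo) and np.isinf(hi):
        noisy = clean.copy()
    else:
        snr = rng.uniform(lo, hi, size=(n_train, 1))
        noisy = clean + rng.standard_normal(clean.shape) / snr
    return TrainingSet(clean_signals=clean, noisy_signals=noisy,
                       shell_ids=protocol.shell_ids,
                       params=np.stack([fa, Da, De_par, De_perp, fw, kappa],
                                       axis=1))


def shell_weight_vector(protocol: AcquisitionProtocol,
                        high_b_weight: float = 1.5) -> np.ndarray:
    """Per-volume loss weights: ``high_b_weight`` on the maximal-b shell."""
    bvals = protocol.bvals
    return np.where(bvals == bvals.max(), high_b_weight, 1.0)


def _init_weights(n_q: int, hidden: tuple[int, ...],
                  rng: np.random.Generator) -> list[np.ndarray]:
    sizes = (n_q, *hidden, n_q)
    weights: list[np.ndarray] = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
        weights.append(np.zeros(fan_out))
    return weights


def _weighted_mse(pred: np.ndarray, target: np.ndarray,
                  w: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2 @ w) / w.sum())


def train_dae(training_set: TrainingSet,
              weights: np.ndarray | None = None,
              epochs: int = 300,
              lr: float = 2e-3,
              seed: int = 0,
              hidden: tuple[int, ...] = (64, 32, 64),
              batch_size: int = 128,
              val_frac: float = 0.1,
              patience: int = 40,
              lr_decay: float = 0.999) -> DAEModel:
    """Train the denoiser with Adam on the weighted MSE.

    Early-stops on a held-out split; the best-validation weights are kept.
    Per-shell validation MSEs land in ``model.training_meta``.
    """
    X, Y = training_set.noisy_signals, training_set.clean_signals
    n, n_q = X.shape
    w = np.ones(n_q) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n_q,) or np.any(w <= 0):
        raise ValueError("need one positive weight per volume")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, Yt = X[train_idx], Y[train_idx]
    Xv, Yv = X[val_idx], Y[val_idx]

    params = _init_weights(n_q, hidden, rng)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = [p.copy() for p in params]
    since_best = 0

    n_layers = len(params) // 2
    lr_t = lr
    for epoch in range(epochs):
        lr_t = lr * lr_decay ** epoch
        order = rng.permutation(len(Xt))
        for start in range(0, len(Xt), batch_size):
            idx = order[start:start + batch_size]
            xb, yb = Xt[idx], Yt[idx]
            # forward with cached activations
            acts = [xb]
            h = xb
            for li in range(n_layers - 1):
                h = np.tanh(h @ params[2 * li] + params[2 * li + 1])
                acts.append(h)
            pred = h @ params[-2] + params[-1]
            err = pred - yb
            # d(weighted mse)/d pred
            g = 2.0 * err * w[None, :] / (w.sum() * len(xb))
            grads: list[np.ndarray] = [None] * len(params)
            grads[-2] = acts[-1].T @ g
            grads[-1] = g.sum(axis=0)
            delta = g @ params[-2].T
            for li in range(n_layers - 2, -1, -1):
                delta = delta * (1.0 - acts[li + 1] ** 2)
                grads[2 * li] = acts[li].T @ delta
                grads[2 * li + 1] = delta.sum(axis=0)
                if li > 0:
                    delta = delta @ params[2 * li].T
            step += 1
            for pi in range(len(params)):
                m[pi] = b1 * m[pi] + (1 - b1) * grads[pi]
                v[pi] = b2 * v[pi] + (1 - b2) * grads[pi] ** 2
                mh = m[pi] / (1 - b1 ** step)
                vh = v[pi] / (1 - b2 ** step)
                params[pi] -= lr_t * mh / (np.sqrt(vh) + eps)

        model = DAEModel(weights=params, shell_weights=w)
        val_pred = model.forward(Xv)
        val_loss = _weighted_mse(val_pred, Yv, w)
        if not np.isfinite(val_loss) or val_loss > 1e10:
            raise TrainingError(
                f"training diverged at epoch {epoch}: val loss {val_loss} "
                f"(lr={lr}, hidden={hidden}, seed={seed})")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break

    model = DAEModel(weights=best_params, shell_weights=w)
    val_pred = model.forward(Xv)
    shell_mse = {}
    for sid in np.unique(training_set.shell_ids):
        cols = training_set.shell_ids == sid
        shell_mse[int(sid)] = float(
            np.mean((val_pred[:, cols] - Yv[:, cols]) ** 2))
    model.training_meta = {
        "seed": seed,
        "epochs_run": epoch + 1,
        "val_weighted_mse": best_val,
        "val_shell_mse": shell_mse,
        "hidden": hidden,
    }
    return model


def denoise(model: DAEModel, signals: np.ndarray,
            b0: np.ndarray | float | None = None) -> np.ndarray:
    """Apply the denoiser along the last (q) axis after b0 normalization.

    ``b0`` broadcasts against ``signals[..., 0]``; the output is rescaled
    by the same factor, so the normalization convention is preserved.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != model.n_q:
        raise ValueError(
            f"signal width {signals.shape[-1]} != model width {model.n_q}")
    if b0 is None:
        scale = np.ones(signals.shape[:-1])
    else:
        scale = np.broadcast_to(np.asarray(b0, dtype=float),
                                signals.shape[:-1]).copy()
    safe = np.maximum(scale, 1e-12)
    flat = (signals / safe[..., None]).reshape(-1, model.n_q)
    out = model.forward(flat).reshape(signals.shape)
    return out * safe[..., None]
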