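"""Shallow convolutional velocity classifier.

Two learned stages: a bank of 3D spatiotemporal kernels with half-wave
rectification (the "V1" layer) and a softmax readout over 64 velocity
classes (the "MT" layer, an 8-direction x 8-speed grid).  An average
pooling stage between them (11 x 11 window, stride 1, reducing each
27 x 27 map to 17 x 17) is enabled by default; it fixes the readout at
36,992 x 64 = 2,367,488 weights.  Training is plain mini-batch gradient
descent on the categorical cross entropy, with no momentum or adaptive
scaling.

Everything is implemented directly in numpy: the convolution is an
im2col matrix product, the pooling forward/backward are box sums via
integral images, and since the convolution is the first layer no
gradient with respect to the input is ever needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft

from .types import N_CLASSES, ImageSequence, Velocity, class_velocity
from .corpus import TrainingSet


@dataclass(frozen=True)
class Architecture:
    """Static architecture metadata."""

    n_kernels: int = 128
    kernel_size: int = 6  # cubic: space x space x frames
    input_size: int = 32
    n_frames: int = 6
    pooling: bool = True
    pool_size: int = 11  # stride-1 average pooling window

    @property
    def map_size(self) -> int:
        return self.input_size - self.kernel_size + 1  # valid convolution

    @property
    def pooled_size(self) -> int:
        return self.map_size - self.pool_size + 1 if self.pooling else self.map_size

    @property
    def kernel_volume(self) -> int:
        return self.kernel_size**2 * self.n_frames

    @property
    def n_features(self) -> int:
        return self.n_kernels * self.pooled_size**2


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; the full-scale defaults are below.

    ``learning_rate`` is held constant throughout training.  Desk-scale
    runs (see :func:`scaled_training_config`) use far fewer gradient
    updates and therefore a proportionally larger constant rate.
    """

    learning_rate: float = 1.0e-4
    batch_size: int = 100
    epochs: int = 2500
    seed: int = 0


def scaled_architecture(n_kernels: int = 32, **kw) -> Architecture:
    return Architecture(n_kernels=n_kernels, **kw)


def scaled_training_config(epochs: int = 200, seed: int = 0, learning_rate: float = 0.25) -> TrainingConfig:
    return TrainingConfig(learning_rate=learning_rate, batch_size=100, epochs=epochs, seed=seed)


@dataclass
class NetworkParams:
    """Learnable parameters plus architecture metadata."""

    arch: Architecture
    kernels: np.ndarray  # (kernel_volume, n_kernels) float32
    conv_offsets: np.ndarray  # (n_kernels,)
    readout: np.ndarray  # (n_features, 64)
    readout_offsets: np.ndarray  # (64,)
    log: list = field(default_factory=list)  # (epoch, train_loss, val_accuracy)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            kernels=self.kernels,
            conv_offsets=self.conv_offsets,
            readout=self.readout,
            readout_offsets=self.readout_offsets,
        )
        meta = {"arch": asdict(self.arch), "log": self.log}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        path = Path(path)
        data = np.load(path if path.suffix else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            Architecture(**meta["arch"]),
            data["kernels"],
            data["conv_offsets"],
            data["readout"],
            data["readout_offsets"],
            [tuple(row) for row in meta.get("log", [])],
        )


def init_network(seed: int = 0, arch: Architecture | None = None) -> NetworkParams:
    """Fresh parameters: conv kernels ~ N(0, 0.001^2), everything else 0."""
    arch = arch or Architecture()
    rng = np.random.default_rng(seed)
    kernels = rng.normal(0.0, 0.001, size=(arch.kernel_volume, arch.n_kernels)).astype(np.float32)
    return NetworkParams(
        arch,
        kernels,
        np.zeros(arch.n_kernels, dtype=np.float32),
        np.zeros((arch.n_features, N_CLASSES), dtype=np.float32),
        np.zeros(N_CLASSES, dtype=np.float32),
    )


def count_parameters(arch: Architecture | None = None) -> dict:
    """Printed-size accounting for an architecture."""
    arch = arch or Architecture()
    conv_params = arch.n_kernels * arch.kernel_volume + arch.n_kernels
    conv_connections = arch.n_kernels * arch.map_size**2 * arch.kernel_volume
    units = arch.n_kernels * arch.pooled_size**2
    return {
        "conv_params": conv_params,
        "conv_connections": conv_connections,
        "units": units,
        "readout_weights": units * N_CLASSES,
        "readout_offsets": N_CLASSES,
        "chance_percent": 100.0 / N_CLASSES,
    }


# ---------------------------------------------------------------------------
# forward pass


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[None]
    return X


def im2col(X: np.ndarray, arch: Architecture) -> np.ndarray:
    """(N, H, W, T) -> (N, map^2, kernel_volume) patch matrix.

    Kept as the direct-summation reference for the FFT convolution used
    by the forward/backward passes.
    """
    k, t = arch.kernel_size, arch.n_frames
    win = sliding_window_view(X, (k, k, t), axis=(1, 2, 3))
    n, m = X.shape[0], arch.map_size
    return np.ascontiguousarray(win.reshape(n, m * m, k * k * t))


# The valid 3D convolution is evaluated spectrally: the kernel spans all
# frames, so only spatial correlation remains, done as one rfft2 product
# per (example, kernel) pair with a per-frequency matmul contracting the
# frame axis.  Corpus spectra are precomputed once per training run; the
# conjugations needed for the kernel gradient are folded onto the small
# arrays.


def _corpus_spectra(X: np.ndarray, arch: Architecture) -> np.ndarray:
    """(N, H, W, T) -> per-example spectra (N, F, T), F = S * (S//2+1).

    Example-major storage keeps the per-batch gather a contiguous row
    copy; :func:`_gather_spectra` transposes a batch to the
    frequency-major layout the per-frequency matmuls need.
    """
    Xm = np.ascontiguousarray(np.moveaxis(X, 3, 1))  # (N, T, S, S)
    Xf = sfft.rfft2(Xm)
    n, t = X.shape[0], arch.n_frames
    return np.ascontiguousarray(Xf.reshape(n, t, -1).transpose(0, 2, 1))


def _gather_spectra(spectra: np.ndarray, idx) -> np.ndarray:
    """Select examples and return frequency-major (F, n, T) spectra."""
    sub = spectra[idx] if idx is not None else spectra
    return np.ascontiguousarray(sub.transpose(1, 0, 2))


def _kernel_spectra(kernels: np.ndarray, arch: Architecture) -> np.ndarray:
    """(kernel_volume, K) -> conjugate spectra (F, T, K) for correlation."""
    k, t, K = arch.kernel_size, arch.n_frames, kernels.shape[1]
    W4 = kernels.reshape(k, k, t, K)
    Wf = sfft.rfft2(np.moveaxis(W4, (2, 3), (1, 0)), s=(arch.input_size,) * 2)  # (K,T,S,Sf)
    return np.conj(Wf.reshape(K, t, -1).transpose(2, 1, 0))


def _conv_maps(spec: np.ndarray, wf: np.ndarray, offsets: np.ndarray, arch: Architecture):
    """Rectified conv maps (N, K, m, m) and the ReLU mask, from spectra."""
    S, m = arch.input_size, arch.map_size
    n = spec.shape[1]
    K = wf.shape[2]
    prod = spec @ wf  # (F, N, K)
    prod = np.ascontiguousarray(prod.transpose(1, 2, 0).reshape(n, K, S, S // 2 + 1))
    full = sfft.irfft2(prod, s=(S, S))
    A = full[:, :, :m, :m] + offsets[None, :, None, None]
    mask = A > 0
    np.maximum(A, 0.0, out=A)
    return np.ascontiguousarray(A), mask


def _pool_matrix(arch: Architecture, dtype) -> np.ndarray:
    """Banded (pooled, map) averaging matrix: the separable box window."""
    m, q, p = arch.map_size, arch.pooled_size, arch.pool_size
    B = np.zeros((q, m), dtype=dtype)
    for i in range(q):
        B[i, i : i + p] = 1.0 / p
    return B


def _pool_forward(A: np.ndarray, arch: Architecture) -> np.ndarray:
    """Stride-1 average pooling over the last two axes, as two matmuls."""
    if not arch.pooling:
        return A
    B = _pool_matrix(arch, A.dtype)
    return np.matmul(B, A @ B.T)


def _pool_backward(dP: np.ndarray, arch: Architecture) -> np.ndarray:
    # adjoint of the separable box mean
    if not arch.pooling:
        return dP
    B = _pool_matrix(arch, dP.dtype)
    return np.matmul(B.T, dP @ B)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_batch(
    net: NetworkParams, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward pass on a (N, H, W, T) batch.

    Returns ``(A, P, probs)``: rectified convolutional maps
    (N, map, map, K), pooled features (N, pooled, pooled, K) and softmax
    class probabilities (N, 64).
    """
    arch = net.arch
    X = _as_batch(X)
    if X.shape[1:] != (arch.input_size, arch.input_size, arch.n_frames):
        raise ValueError(f"input shape {X.shape[1:]} does not match architecture")
    spec = _gather_spectra(_corpus_spectra(X, arch), None)
    wf = _kernel_spectra(net.kernels, arch)
    A_km, _ = _conv_maps(spec, wf, net.conv_offsets, arch)  # (N, K, m, m)
    P = _pool_forward(A_km, arch)  # (N, K, p, p)
    feats = P.reshape(X.shape[0], -1)
    probs = _softmax(feats @ net.readout + net.readout_offsets)
    A = np.moveaxis(A_km, 1, 3)  # (N, m, m, K) view
    return A, P, probs


@dataclass
class PopulationResponse:
    """Labelled unit activations of one layer."""

    layer: str  # "V1" or "MT"
    activations: np.ndarray
    labels: list

    def as_dict(self) -> dict:
        return {str(l): float(a) for l, a in zip(self.labels, np.ravel(self.activations))}


def forward(net: NetworkParams, seq: ImageSequence | np.ndarray) -> tuple[PopulationResponse, PopulationResponse]:
    """Single-sequence forward pass returning labelled V1 and MT responses."""
    px = seq.pixels if isinstance(seq, ImageSequence) else np.asarray(seq)
    A, _, probs = forward_batch(net, px[None] if px.ndim == 3 else px)
    v1 = PopulationResponse("V1", A[0], [f"kernel{k}" for k in range(net.arch.n_kernels)])
    mt = PopulationResponse("MT", probs[0], [class_velocity(i) for i in range(N_CLASSES)])
    return v1, mt


def mt_response(net: NetworkParams, X: np.ndarray) -> np.ndarray:
    """(N, 64) softmax responses for a stimulus batch."""
    return forward_batch(net, X)[2]


def v1_response(net: NetworkParams, X: np.ndarray) -> np.ndarray:
    """(N, K) spatially averaged rectified V1 map activations."""
    A, _, _ = forward_batch(net, X)
    return A.mean(axis=(1, 2))


def classify(net: NetworkParams, seq: ImageSequence | np.ndarray) -> int:
    """Predicted class index (argmax; ties resolve to the lowest index)."""
    px = seq.pixels if isinstance(seq, ImageSequence) else np.asarray(seq)
    probs = mt_response(net, px[None] if px.ndim == 3 else px)
    return int(np.argmax(probs[0]))


def accuracy(net: NetworkParams, X: np.ndarray, y: np.ndarray, chunk: int = 256) -> float:
    hits = 0
    for i in range(0, len(y), chunk):
        probs = mt_response(net, X[i : i + chunk])
        hits += int(np.sum(np.argmax(probs, axis=1) == y[i : i + chunk]))
    return hits / len(y)


# ---------------------------------------------------------------------------
# training


def _batch_gradients(net: NetworkParams, spec: np.ndarray, y: np.ndarray):
    """Loss and parameter gradients for one mini batch of input spectra.

    ``spec`` is the frequency-major spectra (F, n, T) of the batch, as
    produced by :func:`_corpus_spectra`.
    """
    arch = net.arch
    n = spec.shape[1]
    S, m, K = arch.input_size, arch.map_size, arch.n_kernels
    wf = _kernel_spectra(net.kernels, arch)
    A, mask = _conv_maps(spec, wf, net.conv_offsets, arch)  # (n, K, m, m)
    P = _pool_forward(A, arch)
    feats = P.reshape(n, -1)
    logits = feats @ net.readout + net.readout_offsets
    probs = _softmax(logits)
    loss = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    dZ = probs
    dZ[np.arange(n), y] -= 1.0
    dZ /= n
    g_readout = feats.T @ dZ
    g_readout_off = dZ.sum(axis=0)
    dP = (dZ @ net.readout.T).reshape(P.shape)
    dA = _pool_backward(dP, arch) * mask  # (n, K, m, m)
    g_conv_off = dA.sum(axis=(0, 2, 3))
    # kernel gradient: correlation of the input with dA, again spectrally
    real_dtype = dA.dtype
    dAp = np.zeros((n, K, S, S), dtype=real_dtype)
    dAp[:, :, :m, :m] = dA
    dAf = sfft.rfft2(dAp).reshape(n, K, -1).transpose(2, 0, 1)  # (F, n, K)
    spec_ct = np.conj(spec.transpose(0, 2, 1))  # (F, T, n): small copy
    dWf = np.conj(spec_ct @ dAf)  # (F, T, K)
    t = arch.n_frames
    dWf = np.ascontiguousarray(dWf.transpose(2, 1, 0).reshape(K, t, S, S // 2 + 1))
    dW_full = sfft.irfft2(dWf, s=(S, S))  # (K, T, S, S)
    k = arch.kernel_size
    g_kernels = np.ascontiguousarray(
        dW_full[:, :, :k, :k].transpose(2, 3, 1, 0).reshape(k * k * t, K)
    )
    return loss, g_kernels, g_conv_off, g_readout, g_readout_off


def train(
    net: NetworkParams,
    ts: TrainingSet,
    cfg: TrainingConfig | None = None,
    callback=None,
) -> NetworkParams:
    """Mini-batch gradient descent on the categorical cross entropy.

    The training split's patch matrix is precomputed once; the corpus is
    reshuffled every epoch under the run seed.  Per-epoch mean training
    loss and validation accuracy are appended to ``net.log``.  Training
    aborts on a non-finite loss.
    """
    cfg = cfg or TrainingConfig()
    rng = np.random.default_rng(cfg.seed)
    arch = net.arch
    X_tr, y_tr = ts.subset(TrainingSet.TRAIN)
    X_val, y_val = ts.subset(TrainingSet.VAL)
    spectra = _corpus_spectra(X_tr.astype(np.float32), arch)
    val_spectra = _corpus_spectra(X_val.astype(np.float32), arch) if len(y_val) else None
    n = len(y_tr)
    lr = np.float32(cfg.learning_rate)
    val_every = max(1, cfg.epochs // 50)

    def _val_accuracy() -> float:
        hits = 0
        for i in range(0, len(y_val), 256):
            sp = _gather_spectra(val_spectra, slice(i, i + 256))
            wf = _kernel_spectra(net.kernels, arch)
            A, _ = _conv_maps(sp, wf, net.conv_offsets, arch)
            feats = _pool_forward(A, arch).reshape(sp.shape[1], -1)
            probs = _softmax(feats @ net.readout + net.readout_offsets)
            hits += int(np.sum(np.argmax(probs, axis=1) == y_val[i : i + 256]))
        return hits / len(y_val)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            spec = _gather_spectra(spectra, idx)
            loss, gk, gco, gr, gro = _batch_gradients(net, spec, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            losses.append(loss)
            net.kernels -= lr * gk.astype(np.float32, copy=False)
            net.conv_offsets -= lr * gco.astype(np.float32, copy=False)
            net.readout -= lr * gr.astype(np.float32, copy=False)
            net.readout_offsets -= lr * gro.astype(np.float32, copy=False)
        if val_spectra is not None and (epoch % val_every == 0 or epoch == cfg.epochs - 1):
            val_acc = _val_accuracy()
        else:
            val_acc = net.log[-1][2] if net.log else float("nan")
        net.log.append((epoch, float(np.mean(losses)), val_acc))
        if callback is not None:
            callback(epoch, net)
    return net


def training_log_frame(net: NetworkParams):
    import pandas as pd

    return pd.DataFrame(net.log, columns=["epoch", "train_loss", "val_accuracy"])


def train_fresh(
    ts: TrainingSet,
    arch: Architecture | None = None,
    cfg: TrainingConfig | None = None,
    init_seed: int | None = None,
) -> NetworkParams:
    """Initialise (seeded) and train a network on ``ts`` in one call."""
    cfg = cfg or TrainingConfig()
    net = init_network(cfg.seed if init_seed is None else init_seed, arch)
    return train(net, ts, cfg)
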