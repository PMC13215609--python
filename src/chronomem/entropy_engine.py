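"""Desk-scale recurrent convolutional network and softmax-entropy traces.

A small untrained conv net with lateral (within-layer) recurrence is run on
an image for a fixed number of timesteps; at each step the softmax readout's
Shannon entropy is recorded, producing an entropy-over-time trace per image.
Weights are random (no training); the entropy decline over timesteps is the
signal of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

#: default channel widths for the 8 layers (narrow on purpose: CPU-friendly)
DEFAULT_CHANNELS = (8, 8, 16, 16, 16, 32, 32, 32)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and initialization of the recurrent network.

    Defaults give an 8-layer net, 8 unrolled timesteps and a 100-way softmax,
    with 2x2 max-pooling after layers 2, 4 and 6 so a 32x32 input ends at a
    4x4 feature map. ``weight_init_scale`` multiplies the 1/sqrt(fan-in)
    Gaussian initialization; ``recurrent_gain`` additionally scales the
    lateral kernels and is tuned so entropy declines on average over
    timesteps rather than saturating.
    """

    n_layers: int = 8
    channels_per_layer: Sequence[int] = DEFAULT_CHANNELS
    kernel_size: int = 3
    n_classes: int = 100
    n_timesteps: int = 8
    input_size: tuple[int, int, int] = (32, 32, 3)
    weight_init_scale: float = 1.6
    recurrent_gain: float = 1.0
    pool_after: Sequence[int] = (2, 4, 6)  # 1-indexed layers followed by 2x2 maxpool
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.n_timesteps < 2:
            raise ConfigError("n_timesteps must be >= 2")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if len(self.channels_per_layer) != self.n_layers:
            raise ConfigError(
                f"channels_per_layer has {len(self.channels_per_layer)} entries "
                f"for n_layers={self.n_layers}"
            )
        if any(c < 1 for c in self.channels_per_layer):
            raise ConfigError("channel counts must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be a positive odd integer")
        if any(d < 1 for d in self.input_size):
            raise ConfigError("input_size dims must be positive")
        if self.weight_init_scale <= 0:
            raise ConfigError("weight_init_scale must be positive")
        object.__setattr__(self, "channels_per_layer", tuple(self.channels_per_layer))
        object.__setattr__(self, "pool_after", tuple(self.pool_after))
        object.__setattr__(self, "input_size", tuple(self.input_size))

    @property
    def max_entropy(self) -> float:
        return float(np.log(self.n_classes))


@dataclass
class EntropyTrace:
    """Per-timestep softmax entropies (nats) for one image."""

    image_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


class RecurrentNet:
    """Untrained conv net with additive lateral recurrence.

    Layer ``l`` at timestep ``t`` computes
    ``h_l(t) = relu(W_ff[l] * x_{l-1}(t) + W_rec[l] * h_l(t-1) + b[l])``:
    the layer's own previous-timestep output is injected back into it through
    a lateral convolution. Stored outputs are zero before the first timestep,
    so t=1 is a plain feedforward pass.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        h, w, c_in = config.input_size
        self.w_ff: list[np.ndarray] = []
        self.w_rec: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        prev_c = c_in
        for li, c_out in enumerate(config.channels_per_layer):
            fan_in = k * k * prev_c
            self.w_ff.append(
                rng.normal(0.0, config.weight_init_scale / np.sqrt(fan_in), size=(k, k, prev_c, c_out))
            )
            fan_rec = k * k * c_out
            self.w_rec.append(
                rng.normal(
                    0.0,
                    config.weight_init_scale * config.recurrent_gain / np.sqrt(fan_rec),
                    size=(k, k, c_out, c_out),
                )
            )
            self.biases.append(np.zeros(c_out))
            prev_c = c_out
        c_last = config.channels_per_layer[-1]
        self.w_out = rng.normal(0.0, config.weight_init_scale / np.sqrt(c_last), size=(config.n_classes, c_last))
        self.b_out = np.zeros(config.n_classes)
        self.state: list[np.ndarray | None] = [None] * config.n_layers

    def reset_state(self) -> None:
        self.state = [None] * self.config.n_layers

    def weight_checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for arr in (*self.w_ff, *self.w_rec, self.w_out):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # -- forward machinery -------------------------------------------------

    def _step(self, image: np.ndarray) -> np.ndarray:
        """One full forward pass; returns the softmax probability vector."""
        cfg = self.config
        x = image
        for li in range(cfg.n_layers):
            z = _conv2d(x, self.w_ff[li]) + self.biases[li]
            if self.state[li] is not None:
                z = z + _conv2d(self.state[li], self.w_rec[li])
            h = np.maximum(z, 0.0)
            self.state[li] = h
            x = _maxpool2(h) if (li + 1) in cfg.pool_after else h
        feat = self.state[-1].mean(axis=(0, 1))
        logits = self.w_out @ feat + self.b_out
        return softmax(logits)


def _conv2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'same' zero-padded 2D convolution; x (H,W,Cin), w (k,k,Cin,Cout)."""
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(0, 1))  # (H, W, Cin, k, k)
    return np.einsum("hwcij,ijco->hwo", win, w, optimize=True)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h - h % 2, w - w % 2
    x = x[:h2, :w2]
    return x.reshape(h2 // 2, 2, w2 // 2, 2, c).max(axis=(1, 3))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def shannon_entropy(p, *, atol: float = 1e-6) -> float:
    """Shannon entropy in nats, with 0*log(0) := 0.

    Raises :class:`DataError` for negative entries or a sum off 1 beyond
    ``atol``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DataError("probability vector has negative entries")
    s = p.sum()
    if abs(s - 1.0) > atol:
        raise DataError(f"probabilities sum to {s!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def build_network(config: NetworkConfig) -> RecurrentNet:
    """Construct a reproducible random-weight network (no training)."""
    return RecurrentNet(config)


def preprocess_image(image, size: tuple[int, int, int]) -> np.ndarray:
    """Resize to ``size`` (H, W, C) and scale pixel values to [0, 1]."""
    h, w, c = size
    if isinstance(image, (str, Path)):
        from PIL import Image

        with Image.open(image) as im:
            im = im.convert("RGB" if c == 3 else "L")
            im = im.resize((w, h))
            arr = np.asarray(im, dtype=float)
    else:
        arr = np.asarray(image, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.shape[:2] != (h, w):
            from PIL import Image

            mode_arr = arr
            if mode_arr.shape[2] == 1:
                mode_arr = mode_arr[:, :, 0]
            im = Image.fromarray(np.clip(mode_arr, 0, 255).astype(np.uint8))
            im = im.resize((w, h))
            arr = np.asarray(im, dtype=float)
            if arr.ndim == 2:
                arr = arr[:, :, None]
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.shape[2] == 1 and c == 3:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape != (h, w, c):
        raise DataError(f"image has shape {arr.shape}, expected {(h, w, c)}")
    return arr


def run_image(net: RecurrentNet, image, image_id: str = "image") -> EntropyTrace:
    """Run one image for ``n_timesteps`` and return its entropy trace.

    The recurrent state is reset before the first timestep, so repeated calls
    on the same image give identical traces.
    """
    cfg = net.config
    x = preprocess_image(image, cfg.input_size)
    net.reset_state()
    values = np.empty(cfg.n_timesteps)
    for t in range(cfg.n_timesteps):
        p = net._step(x)
        values[t] = shannon_entropy(p)
    net.reset_state()
    return EntropyTrace(image_id=image_id, values=values)


def score_image_set(net: RecurrentNet, images: Iterable, fitter=None):
    """Score a batch of images: entropy trace plus power-curve parameters.

    ``images`` yields ``(image_id, image)`` pairs where ``image`` is an array
    or a path. Returns ``(table, errors)``: a DataFrame with one row per
    successfully scored image (columns ``image_id, A, B, C,
    entropy_t1..tN``) and a list of ``(image_id, message)`` for per-image
    failures (the run continues past them).
    """
    import pandas as pd

    from .speed_model import fit_power_curve

    if fitter is None:
        fitter = fit_power_curve
    rows = []
    errors: list[tuple[str, str]] = []
    n_t = net.config.n_timesteps
    n_images = 0
    for image_id, image in images:
        n_images += 1
        try:
            trace = run_image(net, image, image_id=str(image_id))
            fit = fitter(trace)
            row = {"image_id": str(image_id), "A": fit.A, "B": fit.B, "C": fit.C}
            for t in range(n_t):
                row[f"entropy_t{t + 1}"] = trace.values[t]
            rows.append(row)
        except Exception as exc:  # per-image failure is recorded, not fatal
            log.warning("scoring failed for image %r: %s", image_id, exc)
            errors.append((str(image_id), str(exc)))
    if n_images == 0:
        raise DataError("score_image_set requires at least one image")
    cols = ["image_id", "A", "B", "C"] + [f"entropy_t{t + 1}" for t in range(n_t)]
    return pd.DataFrame(rows, columns=cols), errors


def generate_fixture_images(n: int, size: tuple[int, int, int] = (32, 32, 3), seed: int = 0):
    """Synthetic raster images with varied structure for tests and demos.

    Mixes oriented gratings, Gaussian blobs and filtered noise at random
    contrast so scored traces span a range of collapse rates. Returns a list
    of ``(image_id, array)`` pairs with float arrays in [0, 1].
    """
    rng = np.random.default_rng(seed)
    h, w, c = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    out = []
    for i in range(n):
        kind = rng.integers(3)
        contrast = rng.uniform(0.2, 1.0)
        if kind == 0:  # grating
            freq = rng.uniform(0.05, 0.45)
            theta = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            base = 0.5 + 0.5 * np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
        elif kind == 1:  # blob
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            sigma = rng.uniform(2, w / 2)
            base = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        else:  # smoothed noise
            noise = rng.random((h, w))
            kern = np.ones((3, 3)) / 9.0
            base = noise
            for _ in range(rng.integers(0, 4)):
                base = _conv2d(base[:, :, None], kern[:, :, None, None])[:, :, 0]
            base = (base - base.min()) / max(np.ptp(base), 1e-12)
        img = np.empty((h, w, c))
        for ch in range(c):
            gain = rng.uniform(0.5, 1.0)
            img[:, :, ch] = np.clip(0.5 + contrast * gain * (base - 0.5), 0, 1)
        out.append((f"fix{i:04d}", img))
    return out


def write_fixture_images(directory, n: int, size=(32, 32, 3), seed: int = 0) -> list[str]:
    """Write ``n`` fixture images as PNGs into ``directory``; returns paths."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for image_id, arr in generate_fixture_images(n, size=size, seed=seed):
        path = directory / f"{image_id}.png"
        Image.fromarray((arr * 255).astype(np.uint8)).save(path)
        paths.append(str(path))
    return paths
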