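"""9-layer convolutional autoencoder and per-tile feature extraction.

The network compresses a 104 x 120 x 3 tile into a 13 x 15 x 16
bottleneck (three 2x max-poolings: spatial dims / 8) and reconstructs it
with nearest-neighbour up-sampling.  Five encoder layers (2D convolution
+ max-pooling), four decoder layers (up-sampling + convolution), trained
with per-pixel binary cross-entropy between input and reconstruction.
Hidden activations are rectified, so bottleneck maps are non-negative;
the output layer is sigmoid-bounded in (0, 1).

Each of the 16 bottleneck channels is a learned "feature type".  A tile
is summarized by the 16 spatial means of its bottleneck maps
(:func:`summarize_features`); thresholding each map at its own mean
yields 16 binary feature masks (:func:`make_feature_masks`).

The implementation is NumPy plus three numba-compiled stencil kernels
(forward convolution, input gradient as a transposed convolution, weight
gradient), operating channels-first internally so the innermost loops
are unit-stride.  Everything is float32 and seeded; given a seed,
training is reproducible on a fixed build (fastmath compilation fixes
the summation order per binary, not across architectures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from matriscope.tiling import TileSet

_EPS = 1e-7


# ---------------------------------------------------------------------------
# stencil kernels (channels-first; W is (3, 3, cin, cout) throughout)


@njit(cache=True, fastmath=True)
def _k_conv(xp: np.ndarray, W: np.ndarray, b: np.ndarray, relu: bool) -> np.ndarray:
    """Same conv of a padded frame: (n, cin, h+2, w+2) -> (n, cout, h, w).

    One output row for all channels is accumulated while the three input
    rows that feed it are hot in L1, so each input row is read once per
    output row instead of once per output channel.
    """
    n, cin, hp, wp = xp.shape
    cout = W.shape[3]
    h, w = hp - 2, wp - 2
    y = np.empty((n, cout, h, w), dtype=np.float32)
    acc = np.empty((cout, w), dtype=np.float32)
    for nn in range(n):
        for i in range(h):
            for co in range(cout):
                for j in range(w):
                    acc[co, j] = b[co]
            for ci in range(cin):
                for u in range(3):
                    x0 = xp[nn, ci, i + u]
                    # channel pairs share each loaded input row
                    for cp in range(0, cout - 1, 2):
                        a0 = W[u, 0, ci, cp]
                        a1 = W[u, 1, ci, cp]
                        a2 = W[u, 2, ci, cp]
                        b0 = W[u, 0, ci, cp + 1]
                        b1 = W[u, 1, ci, cp + 1]
                        b2 = W[u, 2, ci, cp + 1]
                        r0 = acc[cp]
                        r1 = acc[cp + 1]
                        for j in range(w):
                            xa = x0[j]
                            xb = x0[j + 1]
                            xc = x0[j + 2]
                            r0[j] += a0 * xa + a1 * xb + a2 * xc
                            r1[j] += b0 * xa + b1 * xb + b2 * xc
                    if cout % 2:
                        co = cout - 1
                        w0 = W[u, 0, ci, co]
                        w1 = W[u, 1, ci, co]
                        w2 = W[u, 2, ci, co]
                        r = acc[co]
                        for j in range(w):
                            r[j] += w0 * x0[j] + w1 * x0[j + 1] + w2 * x0[j + 2]
            for co in range(cout):
                if relu:
                    for j in range(w):
                        y[nn, co, i, j] = max(acc[co, j], np.float32(0.0))
                else:
                    for j in range(w):
                        y[nn, co, i, j] = acc[co, j]
    return y


@njit(cache=True, fastmath=True)
def _k_conv_dw(xp: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Weight gradient: dW[u,v,ci,co] = sum xp[n,ci,i+u,j+v] dy[n,co,i,j].

    Row-major traversal keeps each input row in L1 while all output
    channels consume it; dW itself stays cache-resident.
    """
    n, cin, hp, wp = xp.shape
    cout = dy.shape[1]
    h, w = hp - 2, wp - 2
    dW = np.zeros((3, 3, cin, cout), dtype=np.float32)
    for nn in range(n):
        for i in range(h):
            for ci in range(cin):
                for u in range(3):
                    xr = xp[nn, ci, i + u]
                    for co in range(cout):
                        dr = dy[nn, co, i]
                        s0 = np.float32(0.0)
                        s1 = np.float32(0.0)
                        s2 = np.float32(0.0)
                        for j in range(w):
                            d = dr[j]
                            s0 += xr[j] * d
                            s1 += xr[j + 1] * d
                            s2 += xr[j + 2] * d
                        dW[u, 0, ci, co] += s0
                        dW[u, 1, ci, co] += s1
                        dW[u, 2, ci, co] += s2
    return dW


def _pad_frame(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))


@njit(cache=True)
def _k_pool(x: np.ndarray) -> np.ndarray:
    """2x2 max-pool: (n, c, h, w) -> (n, c, h/2, w/2)."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    y = np.empty((n, c, h2, w2), dtype=np.float32)
    for nn in range(n):
        for cc in range(c):
            for i in range(h2):
                r0 = x[nn, cc, 2 * i]
                r1 = x[nn, cc, 2 * i + 1]
                for j in range(w2):
                    y[nn, cc, i, j] = max(
                        max(r0[2 * j], r0[2 * j + 1]),
                        max(r1[2 * j], r1[2 * j + 1]),
                    )
    return y


@njit(cache=True)
def _k_pool_grad(x: np.ndarray, y: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Route pooled gradients back; ties share the gradient evenly."""
    n, c, h, w = x.shape
    dx = np.zeros((n, c, h, w), dtype=np.float32)
    for nn in range(n):
        for cc in range(c):
            for i in range(h // 2):
                for j in range(w // 2):
                    m = y[nn, cc, i, j]
                    cnt = 0
                    for a in range(2):
                        for b in range(2):
                            if x[nn, cc, 2 * i + a, 2 * j + b] == m:
                                cnt += 1
                    g = dy[nn, cc, i, j] / cnt
                    for a in range(2):
                        for b in range(2):
                            if x[nn, cc, 2 * i + a, 2 * j + b] == m:
                                dx[nn, cc, 2 * i + a, 2 * j + b] = g
    return dx


@njit(cache=True)
def _k_upsample(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsample: (n, c, h, w) -> (n, c, 2h, 2w)."""
    n, c, h, w = x.shape
    y = np.empty((n, c, 2 * h, 2 * w), dtype=np.float32)
    for nn in range(n):
        for cc in range(c):
            for i in range(h):
                src = x[nn, cc, i]
                for j in range(w):
                    v = src[j]
                    y[nn, cc, 2 * i, 2 * j] = v
                    y[nn, cc, 2 * i, 2 * j + 1] = v
                    y[nn, cc, 2 * i + 1, 2 * j] = v
                    y[nn, cc, 2 * i + 1, 2 * j + 1] = v
    return y


@njit(cache=True)
def _k_upsample_grad(dy: np.ndarray) -> np.ndarray:
    """Sum gradients of each 2x2 replica block."""
    n, c, h2, w2 = dy.shape
    h, w = h2 // 2, w2 // 2
    dx = np.empty((n, c, h, w), dtype=np.float32)
    for nn in range(n):
        for cc in range(c):
            for i in range(h):
                r0 = dy[nn, cc, 2 * i]
                r1 = dy[nn, cc, 2 * i + 1]
                for j in range(w):
                    dx[nn, cc, i, j] = (
                        r0[2 * j] + r0[2 * j + 1] + r1[2 * j] + r1[2 * j + 1]
                    )
    return dx


@dataclass
class AutoencoderSpec:
    """Architecture and training hyperparameters.

    ``encoder_channels`` are the output channels of the five encoder
    convolutions; the last entry is the number of learned feature types
    (bottleneck channels).  Spatial bottleneck dims must equal input
    dims / 8 (three 2x poolings).
    """

    input_shape: tuple[int, int, int] = (104, 120, 3)
    bottleneck_shape: tuple[int, int, int] = (13, 15, 16)
    encoder_channels: tuple[int, ...] = (8, 16, 32, 32, 16)
    decoder_channels: tuple[int, ...] = (32, 16, 8)
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 3e-3
    weight_decay: float = 1e-4
    seed: int = 0

    n_encoder_layers: int = 5
    n_decoder_layers: int = 4

    @property
    def n_layers(self) -> int:
        return self.n_encoder_layers + self.n_decoder_layers

    def validate(self) -> None:
        h, w, c = self.input_shape
        bh, bw, bc = self.bottleneck_shape
        if h % 8 or w % 8 or (h // 8, w // 8) != (bh, bw):
            raise ValueError(
                f"bottleneck spatial dims must be input dims / 8: "
                f"{h}x{w} -> expected {h // 8}x{w // 8}, got {bh}x{bw}"
            )
        if len(self.encoder_channels) != 5 or self.encoder_channels[-1] != bc:
            raise ValueError(
                "encoder_channels must list 5 layers ending at the "
                f"bottleneck channel count {bc}"
            )
        if len(self.decoder_channels) != 3:
            raise ValueError(
                "decoder_channels must list the 3 hidden decoder widths"
            )


@dataclass
class BottleneckActivation:
    """Rectified bottleneck maps (13 x 15 x 16) for one tile."""

    maps: np.ndarray
    tile_id: str = ""


@dataclass
class FeatureVector:
    """16 values: spatial means of the bottleneck maps of one tile."""

    values: np.ndarray
    tile_id: str = ""
    class_label: str = "unlabeled"


@dataclass
class FeatureMask:
    """16 binary masks at bottleneck resolution, one per feature type.

    Mask ``k`` is true where map ``k`` meets or exceeds ``thresholds[k]``
    (the tile's mean activation of that feature); pixels strictly below
    the threshold are filtered out.
    """

    masks: np.ndarray  # (13, 15, 16) bool
    thresholds: np.ndarray  # (16,)
    tile_id: str = ""

    def upsampled(self, factor: int = 8) -> np.ndarray:
        """Nearest-neighbour upscale to tile resolution, for overlays."""
        return self.masks.repeat(factor, axis=0).repeat(factor, axis=1)


# ---------------------------------------------------------------------------
# layers


class _Conv3x3:
    """Same-padded 3x3 convolution with relu / sigmoid / linear activation.

    Operates channels-first: (n, cin, h, w) -> (n, cout, h, w).
    """

    def __init__(self, cin: int, cout: int, activation: str,
                 rng: np.random.Generator) -> None:
        fan_in = 9 * cin
        if activation == "relu":
            scale = np.sqrt(2.0 / fan_in)  # He init
        else:
            scale = np.sqrt(1.0 / fan_in)  # Glorot-style
        self.W = rng.normal(0.0, scale, size=(3, 3, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.activation = activation
        self._xp: np.ndarray | None = None
        self._act: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp = _pad_frame(x)
        y = _k_conv(xp, self.W, self.b, self.activation == "relu")
        if self.activation == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-y))
        if train:
            self._xp = xp
            self._act = y
        return y

    def backward(self, dy: np.ndarray, preactivation_grad: bool = False
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        xp, act = self._xp, self._act
        assert xp is not None and act is not None
        if not preactivation_grad:
            if self.activation == "relu":
                dy = dy * (act > 0)
            elif self.activation == "sigmoid":
                dy = dy * act * (1.0 - act)
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        db = dy.sum(axis=(0, 2, 3))
        dW = _k_conv_dw(xp, dy)
        # input gradient = transposed convolution with the flipped kernel
        Wt = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2))
        cin = self.W.shape[2]
        zero = np.zeros(cin, dtype=np.float32)
        dx = _k_conv(_pad_frame(dy), Wt, zero, False)
        self._xp = self._act = None
        return dx, [dW, db]


class _MaxPool2:
    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = _k_pool(x)
        if train:
            self._x = x
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dx = _k_pool_grad(self._x, self._y, np.ascontiguousarray(dy))
        self._x = self._y = None
        return dx, []


class _Upsample2:
    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return _k_upsample(x)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        return _k_upsample_grad(np.ascontiguousarray(dy)), []


# ---------------------------------------------------------------------------
# model


class ConvAutoencoder:
    """Trainable 9-layer conv autoencoder (see module docstring)."""

    def __init__(self, spec: AutoencoderSpec) -> None:
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
        c = spec.encoder_channels
        cin = spec.input_shape[2]
        # encoder: 3 conv+pool stages then two stride-1 convolutions
        self.encoder = [
            _Conv3x3(cin, c[0], "relu", rng), _MaxPool2(),
            _Conv3x3(c[0], c[1], "relu", rng), _MaxPool2(),
            _Conv3x3(c[1], c[2], "relu", rng), _MaxPool2(),
            _Conv3x3(c[2], c[3], "relu", rng),
            _Conv3x3(c[3], c[4], "relu", rng),
        ]
        # decoder: three upsample+conv stages and a sigmoid output conv;
        # kept narrower than the encoder so training cost concentrates on
        # the feature-forming layers
        d = spec.decoder_channels
        self.decoder = [
            _Upsample2(), _Conv3x3(c[4], d[0], "relu", rng),
            _Upsample2(), _Conv3x3(d[0], d[1], "relu", rng),
            _Upsample2(), _Conv3x3(d[1], d[2], "relu", rng),
            _Conv3x3(d[2], cin, "sigmoid", rng),
        ]
        self.layers = self.encoder + self.decoder
        self.loss_history: list[float] = []
        self._opt_state: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._opt_t = 0

    # -- inference ---------------------------------------------------------
    # public arrays are channels-last (tiles are H x W x 3 rasters); the
    # layers run channels-first internally

    @staticmethod
    def _to_nchw(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def encode_batch(self, x: np.ndarray) -> np.ndarray:
        """(N, 104, 120, 3) -> (N, 13, 15, 16) bottleneck activations."""
        z = self._to_nchw(x)
        for layer in self.encoder:
            z = layer.forward(z)
        return z.transpose(0, 2, 3, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Full reconstruction pass; output in (0, 1), same shape as x."""
        z = self._to_nchw(x)
        for layer in self.layers:
            z = layer.forward(z)
        return z.transpose(0, 2, 3, 1)

    def reconstruction_loss(self, x: np.ndarray) -> float:
        """Mean per-pixel binary cross-entropy of the reconstruction."""
        y = np.clip(self.forward(x), _EPS, 1 - _EPS)
        x = np.asarray(x, dtype=np.float32)
        return float(-np.mean(x * np.log(y) + (1 - x) * np.log(1 - y)))

    # -- training ----------------------------------------------------------

    def _train_batch(self, x: np.ndarray) -> float:
        """One optimizer step on a channels-first (n, 3, h, w) batch."""
        y = x
        for layer in self.layers:
            y = layer.forward(y, train=True)
        yc = np.clip(y, _EPS, 1 - _EPS)
        loss = float(-np.mean(x * np.log(yc) + (1 - x) * np.log(1 - yc)))
        # combined sigmoid + BCE gradient wrt the output pre-activation
        dz = (y - x) / np.float32(x.size)
        grads: list[np.ndarray] = []
        dy = dz
        for i, layer in enumerate(reversed(self.layers)):
            if i == 0:
                dy, g = layer.backward(dy, preactivation_grad=True)
            else:
                out = layer.backward(dy)
                dy, g = out
            grads = g + grads
        self._adam_step(grads)
        return loss

    def _adam_step(self, grads: list[np.ndarray],
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        params = [p for layer in self.layers for p in layer.params]
        if self._opt_state is None:
            self._opt_state = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
        self._opt_t += 1
        t = self._opt_t
        lr = self.spec.learning_rate
        wd = self.spec.weight_decay
        for p, g, (m, v) in zip(params, grads, self._opt_state):
            if wd and p.ndim > 1:  # decoupled decay on weights, not biases
                p -= lr * wd * p
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            p -= lr * mh / (np.sqrt(vh) + eps)

    def fit(self, x: np.ndarray, epochs: int | None = None) -> list[float]:
        """Train on (N, H, W, 3) tiles; returns per-epoch mean loss."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] == 0:
            raise ValueError("training set must be a non-empty (N, H, W, 3) array")
        x = self._to_nchw(x)
        epochs = self.spec.epochs if epochs is None else epochs
        bs = self.spec.batch_size
        rng = np.random.default_rng(
            np.random.SeedSequence(self.spec.seed, spawn_key=(10,))
        )
        for _ in range(epochs):
            order = rng.permutation(len(x))
            losses, weights = [], []
            for start in range(0, len(x), bs):
                batch = x[order[start : start + bs]]
                loss = self._train_batch(batch)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss ({loss}) at epoch "
                        f"{len(self.loss_history) + 1}; reduce the learning rate"
                    )
                losses.append(loss)
                weights.append(len(batch))
            self.loss_history.append(float(np.average(losses, weights=weights)))
        return self.loss_history

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + spec as JSON metadata."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            if layer.params:
                arrays[f"W{i}"] = layer.params[0]
                arrays[f"b{i}"] = layer.params[1]
        meta = asdict(self.spec)
        np.savez(path, spec_json=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ConvAutoencoder":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["spec_json"]))
            for k in ("input_shape", "bottleneck_shape", "encoder_channels",
                      "decoder_channels"):
                meta[k] = tuple(meta[k])
            model = cls(AutoencoderSpec(**meta))
            for i, layer in enumerate(model.layers):
                if layer.params:
                    layer.W = data[f"W{i}"]
                    layer.b = data[f"b{i}"]
        return model


# ---------------------------------------------------------------------------
# spec-surface operations


def build_autoencoder(spec: AutoencoderSpec | None = None) -> ConvAutoencoder:
    """Construct a seeded, untrained autoencoder from an architecture spec."""
    return ConvAutoencoder(spec or AutoencoderSpec())


def _tile_array(tiles: TileSet | np.ndarray) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(tiles, TileSet):
        if not tiles.tiles:
            raise ValueError("empty tile set")
        return (
            tiles.pixel_array(),
            [t.tile_id for t in tiles.tiles],
            [t.class_label for t in tiles.tiles],
        )
    x = np.asarray(tiles, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    ids = [f"tile_{i}" for i in range(len(x))]
    return x, ids, ["unlabeled"] * len(x)


def train(
    model: ConvAutoencoder,
    tiles: TileSet | np.ndarray,
    epochs: int | None = None,
) -> tuple[ConvAutoencoder, list[float]]:
    """Train the model on a tile set; returns (model, per-epoch loss)."""
    x, _, _ = _tile_array(tiles)
    history = model.fit(x, epochs=epochs)
    return model, history


def encode(
    model: ConvAutoencoder,
    tiles: TileSet | np.ndarray,
    batch_size: int = 256,
) -> list[BottleneckActivation]:
    """Bottleneck activations for each tile, input order preserved."""
    x, ids, _ = _tile_array(tiles)
    if x.shape[1:] != tuple(model.spec.input_shape):
        raise ValueError(
            f"tile shape {x.shape[1:]} does not match model input "
            f"{model.spec.input_shape}"
        )
    out: list[BottleneckActivation] = []
    for start in range(0, len(x), batch_size):
        z = model.encode_batch(x[start : start + batch_size])
        out.extend(
            BottleneckActivation(maps=z[i], tile_id=ids[start + i])
            for i in range(len(z))
        )
    return out


def summarize_features(activation: BottleneckActivation) -> FeatureVector:
    """Average each bottleneck map over its 13 x 15 grid: 16 values."""
    # accumulate in float64 so the mean is exact for constant maps and the
    # >= threshold tie rule in make_feature_masks behaves predictably
    return FeatureVector(
        values=activation.maps.mean(axis=(0, 1), dtype=np.float64),
        tile_id=activation.tile_id,
    )


def feature_matrix(
    activations: list[BottleneckActivation],
    labels: list[str] | np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stack per-tile feature vectors into an (n, 16) matrix."""
    fv = [summarize_features(a) for a in activations]
    if labels is not None:
        for v, lab in zip(fv, labels):
            v.class_label = str(lab)
    return np.stack([v.values for v in fv]), [v.tile_id for v in fv]


def make_feature_masks(
    activation: BottleneckActivation, feature_vector: FeatureVector
) -> FeatureMask:
    """Threshold each map at its tile-average value (ties are kept)."""
    if feature_vector.tile_id != activation.tile_id:
        raise ValueError(
            f"tile_id mismatch: activation {activation.tile_id!r} vs "
            f"feature vector {feature_vector.tile_id!r}"
        )
    thresholds = np.asarray(feature_vector.values)
    return FeatureMask(
        masks=activation.maps >= thresholds[None, None, :],
        thresholds=thresholds,
        tile_id=activation.tile_id,
    )
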