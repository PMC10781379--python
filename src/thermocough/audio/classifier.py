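"""Spectrogram cough classifier and streaming event detection.

The classifier is a compact convolutional network over the prepared
129 x 124 spectrogram input: two convolution stages (16 then 32 filters,
3 x 3, each downsampling the map by 2), one hidden dense stage of 64 units
with dropout, and a softmax output over the five sound classes (a two-class
cough / non-cough variant is supported).  It is implemented directly in
numpy (im2col convolutions, Adam, seeded initialization), which keeps the
whole pipeline dependency-light and bit-reproducible.

Streaming detection slides 1 s windows with 50 % overlap across the input,
skips silence-gated windows, classifies the rest, and merges consecutive
cough windows into single events (debounce gap 0.5 s) — two coughs in quick
succession become one event instead of being lost across window boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestCentroid

from .frontend import (
    MODEL_TIME_BINS,
    N_FREQ_BINS,
    TARGET_RATE,
    AudioClip,
    FrontendConfig,
    compute_spectrogram,
    prepare_model_input,
    silence_gate,
)
from .synth import LABELS, DatasetManifest, clip_features, load_clip

INPUT_SHAPE = (N_FREQ_BINS, MODEL_TIME_BINS)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and initialization of the small CNN."""

    input_shape: tuple[int, int] = INPUT_SHAPE
    conv_filters: tuple[int, int] = (16, 32)
    dense_units: int = 64
    dropout: float = 0.25
    n_classes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 5):
            raise ValueError("n_classes must be 2 or 5")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, minibatches, fixed epoch count)."""

    epochs: int = 12
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class TrainResult:
    """Per-epoch losses plus held-out metrics.

    ``confusion`` rows are true classes, columns predicted; accuracy equals
    its trace divided by its sum.
    """

    epoch_losses: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    test_accuracy: float = float("nan")
    confusion: np.ndarray | None = None
    labels: tuple[str, ...] = LABELS


@dataclass
class StreamEvent:
    """One merged cough detection in a stream."""

    start: float
    end: float
    label: str = "cough"
    confidence: float = 0.0


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

def _conv_out(n: int, k: int = 3, s: int = 2) -> int:
    return (n - k) // s + 1


def _im2col(x: np.ndarray, stride: int = 2) -> np.ndarray:
    """(B, C, H, W) -> (B*Ho*Wo, C*9) patch matrix for a 3x3 kernel."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # (B, C, Ho, Wo, 3, 3)
    b, c, ho, wo = windows.shape[:4]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * 9)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape: tuple, stride: int = 2) -> np.ndarray:
    """Scatter-add patch gradients back onto the input tensor."""
    b, c, h, w = x_shape
    ho, wo = _conv_out(h), _conv_out(w)
    dcols = dcols.reshape(b, ho, wo, c, 3, 3)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dx[:, :, i:i + stride * (ho - 1) + 1:stride,
               j:j + stride * (wo - 1) + 1:stride] += \
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx


class CoughNet:
    """Two-stage CNN with seeded He initialization and an Adam optimizer."""

    def __init__(self, cfg: ModelConfig, labels: tuple[str, ...] | None = None):
        self.cfg = cfg
        if labels is None:
            labels = LABELS if cfg.n_classes == 5 else ("cough", "non_cough")
        if len(labels) != cfg.n_classes:
            raise ValueError("labels must match n_classes")
        self.labels = tuple(labels)
        h, w = cfg.input_shape
        f1, f2 = cfg.conv_filters
        h1, w1 = _conv_out(h), _conv_out(w)
        h2, w2 = _conv_out(h1), _conv_out(w1)
        self._flat = f2 * h2 * w2
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))

        def he(shape, fan_in):
            return rng.normal(0, np.sqrt(2.0 / fan_in), size=shape
                              ).astype(np.float32)

        self.params = {
            "W1": he((9, f1), 9), "b1": np.zeros(f1, np.float32),
            "W2": he((f1 * 9, f2), f1 * 9), "b2": np.zeros(f2, np.float32),
            "W3": he((self._flat, cfg.dense_units), self._flat),
            "b3": np.zeros(cfg.dense_units, np.float32),
            "W4": he((cfg.dense_units, cfg.n_classes), cfg.dense_units),
            "b4": np.zeros(cfg.n_classes, np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward ----------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False,
                 drop_rng: np.random.Generator | None = None):
        """x: (B, H, W) float32 -> logits (B, K), caching intermediates."""
        p = self.params
        b = x.shape[0]
        h, w = self.cfg.input_shape
        f1, f2 = self.cfg.conv_filters
        h1, w1 = _conv_out(h), _conv_out(w)
        h2, w2 = _conv_out(h1), _conv_out(w1)

        x4 = x.reshape(b, 1, h, w)
        cols1 = _im2col(x4)                        # (B*h1*w1, 9)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0)
        a1_map = a1.reshape(b, h1, w1, f1).transpose(0, 3, 1, 2)

        cols2 = _im2col(a1_map)                    # (B*h2*w2, f1*9)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0)
        flat = a2.reshape(b, h2, w2, f2).reshape(b, -1)

        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0)
        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (drop_rng.random(a3.shape) < keep).astype(np.float32) / keep
            a3 = a3 * mask
        else:
            mask = None
        logits = a3 @ p["W4"] + p["b4"]
        cache = (x4, cols1, z1, a1_map, cols2, z2, flat, z3, a3, mask)
        return logits, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a batch of (H, W) inputs."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.cfg.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} != {self.cfg.input_shape}")
        logits, _ = self._forward(x, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- backward ---------------------------------------------------------

    def _backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        x4, cols1, z1, a1_map, cols2, z2, flat, z3, a3, mask = cache
        b = x4.shape[0]
        f1, f2 = self.cfg.conv_filters
        h1, w1 = a1_map.shape[2], a1_map.shape[3]

        grads = {}
        grads["W4"] = a3.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["W4"].T
        if mask is not None:
            da3 = da3 * mask
        dz3 = da3 * (z3 > 0)
        grads["W3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T

        da2 = dflat.reshape(-1, f2)
        dz2 = da2 * (z2 > 0)
        grads["W2"] = cols2.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dcols2 = dz2 @ p["W2"].T
        da1_map = _col2im(dcols2, a1_map.shape)

        da1 = da1_map.transpose(0, 2, 3, 1).reshape(-1, f1)
        dz1 = da1 * (z1 > 0)
        grads["W1"] = cols1.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = self._adam_m[k] / (1 - beta1 ** t)
            v_hat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float,
                    drop_rng: np.random.Generator) -> float:
        """One minibatch step; returns the mean cross-entropy loss."""
        x = np.asarray(x, dtype=np.float32)
        logits, cache = self._forward(x, train=True, drop_rng=drop_rng)
        z = logits - logits.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=1))
        loss = float(np.mean(logsumexp - z[np.arange(len(y)), y]))
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        dlogits = probs
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        self._adam_step(self._backward(cache, dlogits.astype(np.float32)), lr)
        return loss

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        np.savez(path, __format_version__=1,
                 n_classes=self.cfg.n_classes, seed=self.cfg.seed,
                 dense_units=self.cfg.dense_units, dropout=self.cfg.dropout,
                 conv_filters=np.array(self.cfg.conv_filters),
                 labels=np.array(self.labels),
                 **self.params)

    @classmethod
    def load(cls, path) -> "CoughNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig(
                conv_filters=tuple(int(v) for v in data["conv_filters"]),
                dense_units=int(data["dense_units"]),
                dropout=float(data["dropout"]),
                n_classes=int(data["n_classes"]), seed=int(data["seed"]))
            net = cls(cfg, labels=tuple(str(s) for s in data["labels"]))
            for k in net.params:
                net.params[k] = data[k]
        return net


def build_model(cfg: ModelConfig | None = None,
                labels: tuple[str, ...] | None = None) -> CoughNet:
    """Construct the CNN with deterministic seeded initialization."""
    return CoughNet(cfg or ModelConfig(), labels=labels)


# ---------------------------------------------------------------------------
# Dataset preparation, training, evaluation
# ---------------------------------------------------------------------------

class DegenerateLabels(ValueError):
    """Raised when a training split does not cover at least two classes."""


def prepare_split(manifest: DatasetManifest, split: str,
                  labels: tuple[str, ...] = LABELS,
                  duration: float = 1.0,
                  cfg: FrontendConfig | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Materialize a split as (inputs (N, 129, 124) float32, label indices)."""
    rows = manifest.split(split)
    if len(rows) == 0:
        raise ValueError(f"split {split!r} is empty")
    cfg = cfg or FrontendConfig()
    xs, ys = [], []
    for row in rows.itertuples():
        clip = load_clip(row, duration)
        spec = compute_spectrogram(clip, cfg)
        xs.append(prepare_model_input(spec).astype(np.float32))
        ys.append(labels.index(row.label))
    return np.stack(xs), np.array(ys, dtype=np.int64)


def train_model(model: CoughNet, manifest: DatasetManifest,
                train_cfg: TrainConfig | None = None,
                duration: float = 1.0) -> TrainResult:
    """Train on the train split with per-epoch validation feedback, then
    report test-split accuracy and confusion matrix.  Fully seeded."""
    tc = train_cfg or TrainConfig()
    labels = model.labels
    x_train, y_train = prepare_split(manifest, "train", labels, duration)
    x_val, y_val = prepare_split(manifest, "val", labels, duration)
    x_test, y_test = prepare_split(manifest, "test", labels, duration)
    if len(np.unique(y_train)) < 2:
        raise DegenerateLabels("training split covers fewer than two classes")

    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 7]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 11]))
    result = TrainResult(labels=labels)
    n = len(x_train)
    for _ in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            sel = order[start:start + tc.batch_size]
            losses.append(model.train_batch(
                x_train[sel], y_train[sel], tc.learning_rate, drop_rng))
        result.epoch_losses.append(float(np.mean(losses)))
        result.val_accuracies.append(
            float((model.predict(x_val) == y_val).mean()))
    test = evaluate_model(model, x_test, y_test)
    result.test_accuracy = test.test_accuracy
    result.confusion = test.confusion
    return result


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> np.ndarray:
    """Counts matrix, rows = true class, columns = predicted class."""
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return m


def evaluate_model(model: CoughNet, x: np.ndarray, y: np.ndarray
                   ) -> TrainResult:
    """Accuracy and confusion matrix of *model* on (x, y)."""
    pred = model.predict(x)
    m = confusion_matrix(y, pred, model.cfg.n_classes)
    return TrainResult(test_accuracy=float(np.trace(m) / m.sum()),
                       confusion=m, labels=model.labels)


def plot_confusion(result: TrainResult, path) -> None:
    """Render the confusion matrix to a PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(result.confusion, cmap="Blues")
    ax.set_xticks(range(len(result.labels)), result.labels, rotation=45)
    ax.set_yticks(range(len(result.labels)), result.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(result.labels)):
        for j in range(len(result.labels)):
            ax.text(j, i, str(result.confusion[i, j]),
                    ha="center", va="center", fontsize=9)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Analytic baseline
# ---------------------------------------------------------------------------

class BandEnergyBaseline:
    """Nearest-centroid classifier over band-energy + envelope features.

    A deliberately simple analytic reference: any trained network worth
    deploying must beat it on the same held-out data.
    """

    def __init__(self, labels: tuple[str, ...] = LABELS):
        self.labels = labels
        self._clf = NearestCentroid()
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def _featurize(self, clips: list[AudioClip]) -> np.ndarray:
        return np.stack([clip_features(c) for c in clips])

    def fit(self, clips: list[AudioClip], y: np.ndarray) -> "BandEnergyBaseline":
        feats = self._featurize(clips)
        self._mu = feats.mean(axis=0)
        self._sd = feats.std(axis=0) + 1e-9
        self._clf.fit((feats - self._mu) / self._sd, y)
        return self

    def predict(self, clips: list[AudioClip]) -> np.ndarray:
        feats = (self._featurize(clips) - self._mu) / self._sd
        return self._clf.predict(feats)


def baseline_accuracy(manifest: DatasetManifest,
                      labels: tuple[str, ...] = LABELS,
                      duration: float = 1.0) -> float:
    """Fit the baseline on the train split, score it on the test split."""
    def clips_of(split):
        rows = manifest.split(split)
        return ([load_clip(r, duration) for r in rows.itertuples()],
                np.array([labels.index(r.label) for r in rows.itertuples()]))

    train_clips, y_train = clips_of("train")
    test_clips, y_test = clips_of("test")
    model = BandEnergyBaseline(labels).fit(train_clips, y_train)
    return float((model.predict(test_clips) == y_test).mean())


# ---------------------------------------------------------------------------
# Streaming inference
# ---------------------------------------------------------------------------

def classify_stream(stream: np.ndarray, model,
                    window: float = 1.0, hop: float = 0.5,
                    gate_threshold: float | None = None,
                    debounce_gap: float = 0.5,
                    cfg: FrontendConfig | None = None) -> list[StreamEvent]:
    """Detect cough events in a 16 kHz mono stream.

    Windows of ``window`` seconds slide by ``hop``; silence-gated windows
    are skipped; the rest are classified.  Cough windows closer than
    ``debounce_gap`` seconds are merged into one event whose confidence is
    the maximum window cough probability.
    """
    cfg = cfg or FrontendConfig()
    if gate_threshold is None:
        gate_threshold = cfg.silence_rms_threshold
    stream = np.asarray(stream, dtype=np.float64)
    n_win = int(window * TARGET_RATE)
    n_hop = int(hop * TARGET_RATE)
    if len(stream) < n_win:
        import warnings
        warnings.warn("stream shorter than one window; no events")
        return []
    cough_idx = list(model.labels).index("cough")
    detections: list[tuple[float, float, float]] = []
    for start in range(0, len(stream) - n_win + 1, n_hop):
        clip = AudioClip(samples=stream[start:start + n_win])
        if silence_gate(clip, threshold=gate_threshold):
            continue
        x = prepare_model_input(compute_spectrogram(clip, cfg))
        probs = model.predict_proba(x[None] if x.ndim == 2 else x)[0]
        if int(np.argmax(probs)) == cough_idx:
            t0 = start / TARGET_RATE
            detections.append((t0, t0 + window, float(probs[cough_idx])))
    events: list[StreamEvent] = []
    for t0, t1, conf in detections:
        if events and t0 - events[-1].end <= debounce_gap:
            events[-1].end = max(events[-1].end, t1)
            events[-1].confidence = max(events[-1].confidence, conf)
        else:
            events.append(StreamEvent(start=t0, end=t1, confidence=conf))
    return events
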