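"""Binary fovea / no-fovea B-scan classifier.

Architecture (fixed recipe): four convolutional blocks of 3x3 filters
with ReLU, 32 -> 64 -> 128 -> 256, each followed by 2x2 max pooling;
flatten; dense 512 and 256 with ReLU; a single sigmoid output unit.
Training uses batches of 12 for 30 epochs with online photometric
augmentation (random brightness, contrast, saturation and hue), a
stratified train/validation/test split, and retains the checkpoint of
the epoch with the highest validation accuracy.  Grayscale B-scans are
replicated to three channels so the saturation/hue augmentations are
well defined.

The convolutional filter counts and dense widths are part of the recipe
contract; overriding them is possible via :class:`ClassifierSpec` but is
logged as a deviation.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

from . import nn
from .errors import ConfigurationError, DataError, ParameterError
from .scene import OctVolume

logger = logging.getLogger(__name__)

CANONICAL_CONV_FILTERS = (32, 64, 128, 256)
CANONICAL_DENSE_UNITS = (512, 256)


@dataclass(frozen=True)
class AugmentSpec:
    """Photometric augmentation ranges (identity when degenerate).

    ``brightness`` is an additive delta range, ``contrast`` and
    ``saturation`` multiplicative factor ranges, ``hue`` a shift range
    on the 0-1 hue circle.
    """

    brightness: tuple[float, float] = (-0.2, 0.2)
    contrast: tuple[float, float] = (0.8, 1.2)
    saturation: tuple[float, float] = (0.8, 1.2)
    hue: tuple[float, float] = (-0.05, 0.05)

    @staticmethod
    def identity() -> "AugmentSpec":
        return AugmentSpec((0.0, 0.0), (1.0, 1.0), (1.0, 1.0), (0.0, 0.0))


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier recipe: architecture, batching, epochs, augmentation."""

    input_size: tuple[int, int] = (256, 256)
    conv_filters: tuple[int, ...] = CANONICAL_CONV_FILTERS
    kernel: int = 3
    dense_units: tuple[int, ...] = CANONICAL_DENSE_UNITS
    batch_size: int = 12
    epochs: int = 30
    augmentation: AugmentSpec = field(default_factory=AugmentSpec)
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != 3:
            raise ParameterError("kernel: the recipe uses 3x3 filters")
        if self.batch_size < 1 or self.epochs < 1:
            raise ParameterError("batch_size/epochs: must be >= 1")
        if self.conv_filters != CANONICAL_CONV_FILTERS:
            logger.warning("conv_filters %s deviate from the recipe %s",
                           self.conv_filters, CANONICAL_CONV_FILTERS)
        if self.dense_units != CANONICAL_DENSE_UNITS:
            logger.warning("dense_units %s deviate from the recipe %s",
                           self.dense_units, CANONICAL_DENSE_UNITS)
        if (self.batch_size, self.epochs) != (12, 30):
            logger.warning("batch_size/epochs (%d, %d) deviate from the "
                           "recipe (12, 30)", self.batch_size, self.epochs)


@dataclass
class TrainReport:
    """Per-epoch metrics plus the retained best checkpoint."""

    train_loss: list[float]
    train_accuracy: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    best_epoch: int  # 0-based
    best_val_accuracy: float
    checkpoint_path: str | None
    optimizer: str
    learning_rate: float
    seed: int
    test_accuracy: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "train_accuracy",
                             "val_loss", "val_accuracy"])
            for i in range(len(self.train_loss)):
                writer.writerow([i, self.train_loss[i], self.train_accuracy[i],
                                 self.val_loss[i], self.val_accuracy[i]])

    def plot(self, path: str | Path) -> None:
        """Loss and accuracy curves over the epochs (needs matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        epochs = range(len(self.train_loss))
        fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(9, 3.5))
        ax_loss.plot(epochs, self.train_loss, label="train")
        ax_loss.plot(epochs, self.val_loss, label="validation")
        ax_loss.set_xlabel("epoch")
        ax_loss.set_ylabel("binary cross-entropy")
        ax_loss.legend()
        ax_acc.plot(epochs, self.train_accuracy, label="train")
        ax_acc.plot(epochs, self.val_accuracy, label="validation")
        ax_acc.axvline(self.best_epoch, ls="--", c="gray", lw=0.8)
        ax_acc.set_xlabel("epoch")
        ax_acc.set_ylabel("accuracy")
        ax_acc.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_model(spec: ClassifierSpec) -> nn.Sequential:
    """Build the convolutional classifier for ``spec``.

    Raises :class:`ConfigurationError` when ``input_size`` cannot
    survive one 2x2 pooling stage per convolutional block.
    """
    rows, cols = spec.input_size
    n_pools = len(spec.conv_filters)
    div = 2 ** n_pools
    if rows % div or cols % div or rows < div * 2 or cols < div * 2:
        raise ConfigurationError(
            f"input_size {spec.input_size} collapses under {n_pools} "
            f"pooling stages (needs multiples of {div}, at least {2 * div})")

    rng = np.random.default_rng(spec.seed)
    layers: list[nn.Layer] = []
    channels = 3
    for filters in spec.conv_filters:
        layers += [nn.Conv2D(channels, filters, rng), nn.ReLU(), nn.MaxPool2()]
        channels = filters
    layers.append(nn.Flatten())
    features = (rows // div) * (cols // div) * channels
    for units in spec.dense_units:
        layers += [nn.Dense(features, units, rng), nn.ReLU()]
        features = units
    layers.append(nn.Dense(features, 1, rng))
    return nn.Sequential(layers)


def describe_architecture(model: nn.Sequential) -> list[tuple[str, int | None]]:
    """Layer (kind, width) sequence, for regression audits of the recipe."""
    return model.architecture()


def prepare_image(image: np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    """Resize to the model input and replicate grayscale to 3 channels."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.dstack([img] * 3)
    if img.shape[:2] != tuple(input_size):
        img = resize(img, input_size, anti_aliasing=True,
                     preserve_range=True).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def augment(image: np.ndarray, aug: AugmentSpec,
            rng: np.random.Generator | int) -> np.ndarray:
    """Apply random photometric adjustments (label preserving).

    Deterministic for a fixed seed/generator state; degenerate ranges
    are skipped entirely, so an all-identity spec returns the input
    bit-exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    img = np.asarray(image, dtype=np.float32)

    def draw(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    delta = draw(*aug.brightness)
    c_factor = draw(*aug.contrast)
    s_factor = draw(*aug.saturation)
    h_shift = draw(*aug.hue)

    if s_factor != 1.0 or h_shift != 0.0:
        hsv = rgb2hsv(img.astype(float))
        hsv[..., 0] = (hsv[..., 0] + h_shift) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * s_factor, 0.0, 1.0)
        img = hsv2rgb(hsv).astype(np.float32)
    if c_factor != 1.0:
        img = (img - img.mean()) * c_factor + img.mean()
    if delta != 0.0:
        img = img + delta
    if (delta, c_factor, s_factor, h_shift) == (0.0, 1.0, 1.0, 0.0):
        return img
    return np.clip(img, 0.0, 1.0)


def load_image_directory(data_dir: str | Path,
                         input_size: tuple[int, int],
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Load a directory-per-class dataset ("fovea" / "no fovea").

    Labels follow the folder structure: a class directory whose name
    starts with "fovea" is the positive class.  PNG and TIFF accepted.
    """
    import imageio.v3 as iio

    root = Path(data_dir)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) != 2:
        raise DataError(f"{root}: expected exactly two class directories")
    images, labels = [], []
    for d in class_dirs:
        label = 1.0 if d.name.lower().replace("_", " ").startswith("fovea") else 0.0
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in {".png", ".tif", ".tiff"}:
                continue
            img = iio.imread(f).astype(np.float32)
            if img.max() > 1.0:
                img = img / 255.0
            images.append(prepare_image(img, input_size))
            labels.append(label)
    if not images:
        raise DataError(f"{root}: no images found")
    return np.stack(images), np.asarray(labels, dtype=np.float32)


def _stratified_split(labels: np.ndarray, fractions: tuple[float, float, float],
                      rng: np.random.Generator):
    """Stratified train/val/test index split (70/15/15 by default)."""
    train, val, test = [], [], []
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_train = max(1, min(n_train, n - 2)) if n >= 3 else max(1, n - 1)
        n_val = max(1, min(n_val, n - n_train - 1)) if n - n_train >= 2 else 0
        train.extend(idx[:n_train])
        val.extend(idx[n_train:n_train + n_val])
        test.extend(idx[n_train + n_val:])
    return (np.sort(np.asarray(train)), np.sort(np.asarray(val)),
            np.sort(np.asarray(test)))


def _accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean((probs >= 0.5) == (labels >= 0.5))) if len(labels) else 0.0


def train(images: np.ndarray, labels: np.ndarray, spec: ClassifierSpec,
          checkpoint_path: str | Path | None = None,
          split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
          ) -> tuple[nn.Sequential, TrainReport]:
    """Train the classifier for exactly ``spec.epochs`` epochs.

    ``images`` are float arrays in [0, 1] (grayscale or RGB; resized and
    channel-replicated as needed).  The best-validation-accuracy
    checkpoint is restored into the returned model (and written to
    ``checkpoint_path`` when given).
    """
    labels = np.asarray(labels, dtype=np.float32)
    if len(images) == 0:
        raise DataError("empty dataset")
    if len(images) != len(labels):
        raise DataError("images and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise DataError("dataset must contain both classes")

    x = np.stack([prepare_image(img, spec.input_size) for img in images])
    ss = np.random.SeedSequence(spec.seed)
    rng_split, rng_train, rng_aug = (np.random.default_rng(s)
                                     for s in ss.spawn(3))
    tr, va, te = _stratified_split(labels, split_fractions, rng_split)
    model = build_model(spec)
    optimizer = nn.Adam(model.all_params(), lr=spec.learning_rate)

    report = TrainReport([], [], [], [], best_epoch=0, best_val_accuracy=-1.0,
                         checkpoint_path=None, optimizer="adam",
                         learning_rate=spec.learning_rate, seed=spec.seed)
    best_weights = model.get_weights()
    for epoch in range(spec.epochs):
        order = tr.copy()
        rng_train.shuffle(order)
        losses, accs = [], []
        for start in range(0, len(order), spec.batch_size):
            batch = order[start:start + spec.batch_size]
            xb = np.stack([augment(x[i], spec.augmentation, rng_aug)
                           for i in batch])
            loss, probs = model.train_step(xb, labels[batch], optimizer)
            losses.append(loss)
            accs.append(_accuracy(probs, labels[batch]))
        val_probs = model.predict(x[va], spec.batch_size)
        val_acc = _accuracy(val_probs, labels[va])
        report.train_loss.append(float(np.mean(losses)))
        report.train_accuracy.append(float(np.mean(accs)))
        report.val_loss.append(nn.bce_loss(val_probs, labels[va])
                               if len(va) else float("nan"))
        report.val_accuracy.append(val_acc)
        if val_acc > report.best_val_accuracy:  # first best epoch retained
            report.best_val_accuracy = val_acc
            report.best_epoch = epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    if len(te):
        report.test_accuracy = _accuracy(model.predict(x[te], spec.batch_size),
                                         labels[te])
    if checkpoint_path is not None:
        model.save(checkpoint_path, meta={"spec": _spec_meta(spec),
                                          "best_epoch": report.best_epoch})
        report.checkpoint_path = str(checkpoint_path)
    return model, report


def _spec_meta(spec: ClassifierSpec) -> dict:
    meta = asdict(spec)
    meta["augmentation"] = asdict(spec.augmentation)
    return meta


def load_model(checkpoint_path: str | Path) -> tuple[nn.Sequential, ClassifierSpec]:
    """Restore a trained model and its spec from a checkpoint file."""
    data = np.load(checkpoint_path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))["spec"]
    meta["input_size"] = tuple(meta["input_size"])
    meta["conv_filters"] = tuple(meta["conv_filters"])
    meta["dense_units"] = tuple(meta["dense_units"])
    meta["augmentation"] = AugmentSpec(
        **{k: tuple(v) for k, v in meta["augmentation"].items()})
    spec = ClassifierSpec(**meta)
    model = build_model(spec)
    model.load(checkpoint_path)
    return model, spec


def classify_stack(volume: OctVolume, model: nn.Sequential,
                   threshold: float = 0.5,
                   input_size: tuple[int, int] | None = None,
                   ) -> tuple[list[bool], np.ndarray]:
    """Classify every B-scan of a volume in acquisition order.

    Returns per-scan booleans (probability >= ``threshold``) plus the
    raw probabilities for audit logging.  ``threshold`` must lie in the
    open interval (0, 1).  Images whose shape differs from the training
    input are resized (logged).
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold: must be in the open interval (0, 1)")
    if input_size is None:
        # infer spatial size from the first dense layer and conv channels
        input_size = _infer_input_size(model)
    prepared = []
    for b in volume.bscans:
        if b.shape[:2] != tuple(input_size):
            logger.info("resizing B-scan %s to %s", b.shape[:2], input_size)
        prepared.append(prepare_image(b, input_size))
    probs = model.predict(np.stack(prepared), batch_size=12)
    return [bool(p >= threshold) for p in probs], probs


def _infer_input_size(model: nn.Sequential) -> tuple[int, int]:
    convs = [l for l in model.layers if isinstance(l, nn.Conv2D)]
    dense = next(l for l in model.layers if isinstance(l, nn.Dense))
    n_pools = sum(1 for l in model.layers if isinstance(l, nn.MaxPool2))
    pixels = dense.w.shape[0] // convs[-1].filters
    side = int(round(np.sqrt(pixels))) * 2 ** n_pools
    return (side, side)
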