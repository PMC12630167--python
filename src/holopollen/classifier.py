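"""Two-branch abstaining pollen classifier.

:class:`PollenClassifier` is the model object (architecture + training
configuration); its :meth:`~PollenClassifier.fit` returns a
:class:`ClassifierFit` results object carrying the trained network, the
training report and prediction/summary/export methods.

The network fuses a small VGG-style convolutional branch over the two
stacked hologram planes with a deliberately narrow dense branch over the
13 fluorescence channels plus a presence flag.  To stay robust to
missing fluorescence, a fraction ``fluor_mask_prob`` (default 20%) of
the fluorescence signals is discarded at random during every training
epoch; absent fluorescence is always encoded as a zero vector with
presence flag 0, so the trained model accepts events with or without
the fluorescence modality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import NUM_FLUOR_CHANNELS, EventRecord
from .errors import (
    ConfigurationError,
    DataError,
    InvalidParameterError,
    UNCLASSIFIED,
)
from .nn import Adam, TwoBranchNet, cross_entropy, softmax
from .utils import config_hash, derive_seed


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    ``conv_blocks`` lists (channel count, conv layers) per VGG-style
    block; each block ends in 2x2 max pooling, so ``image_side`` must be
    divisible by ``2 ** len(conv_blocks)``.  ``fluor_hidden_units`` is
    kept small on purpose: few neurons avoid over-complex fluorescence
    features.  ``droplet_class``, when set, must appear in
    ``class_names`` (operational models must know water droplets).
    """

    class_names: Tuple[str, ...]
    image_side: int = 200
    conv_blocks: Tuple[Tuple[int, int], ...] = ((16, 2), (32, 2), (64, 2))
    fluor_hidden_units: int = 8
    fluor_mask_prob: float = 0.2
    epochs: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 32
    rng_seed: int = 0
    image_features: int = 32
    droplet_class: Optional[str] = "droplet"

    def __post_init__(self):
        self.class_names = tuple(self.class_names)
        if len(self.class_names) < 1:
            raise ConfigurationError("class_names must be non-empty")
        if len(set(self.class_names)) != len(self.class_names):
            raise ConfigurationError("class_names must be unique")
        if not 0.0 <= self.fluor_mask_prob <= 1.0:
            raise InvalidParameterError("fluor_mask_prob must be in [0, 1]")
        if self.fluor_hidden_units < 1:
            raise ConfigurationError("fluor_hidden_units must be >= 1")
        if len(self.conv_blocks) < 1:
            raise ConfigurationError("at least one conv block is required")
        if self.droplet_class is not None and (
            self.droplet_class not in self.class_names
        ):
            raise ConfigurationError(
                f"droplet class {self.droplet_class!r} not in class_names; "
                "set droplet_class=None for non-operational experiments"
            )

    def hash(self) -> str:
        return config_hash(dataclasses.asdict(self))


@dataclass
class Prediction:
    """Per-event class probabilities and threshold-dependent label."""

    event_id: str
    probs: np.ndarray
    class_names: Tuple[str, ...]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (len(self.class_names),):
            raise DataError("probs length must match class_names")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise DataError("probs must be a probability vector (sum 1)")
        self.probs = p

    @property
    def confidence(self) -> float:
        return float(self.probs.max())

    def label_at(self, c: float) -> str:
        return apply_confidence_threshold(self, c)


def apply_confidence_threshold(prediction: Prediction, c: float) -> str:
    """Class label at confidence threshold ``c``, or abstention.

    Returns the argmax class iff confidence >= c and the argmax is
    unique; a tied maximum abstains (conservative rule).
    """
    if not 0.0 <= c <= 1.0:
        raise InvalidParameterError(f"threshold must be in [0, 1], got {c}")
    conf = prediction.confidence
    if conf < c:
        return UNCLASSIFIED
    if int((prediction.probs == prediction.probs.max()).sum()) > 1:
        return UNCLASSIFIED
    return prediction.class_names[int(prediction.probs.argmax())]


def mask_fluorescence_batch(
    events: Sequence[EventRecord], p: float, rng_seed: int
) -> List[EventRecord]:
    """Independently discard each event's fluorescence with probability p.

    Events that already lack fluorescence stay absent; decisions are
    reproducible from the seed.
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"mask probability must be in [0,1], got {p}")
    rng = np.random.default_rng(rng_seed)
    drop = rng.uniform(size=len(events)) < p
    out = []
    for ev, d in zip(events, drop):
        if d and ev.fluorescence is not None:
            out.append(dataclasses.replace(ev, fluorescence=None))
        else:
            out.append(ev)
    return out


def encode_events(
    events: Sequence[EventRecord], image_side: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Encode events as (images (N,2,S,S), fluorescence (N,14)) arrays.

    The 14th fluorescence entry is the presence flag; absent
    fluorescence becomes a zero vector with flag 0 — the canonical
    missing-modality encoding shared by training, prediction and the
    exported graph.
    """
    n = len(events)
    images = np.zeros((n, 2, image_side, image_side), dtype=np.float32)
    fluor = np.zeros((n, NUM_FLUOR_CHANNELS + 1), dtype=np.float32)
    for i, ev in enumerate(events):
        if ev.image_side != image_side:
            raise ConfigurationError(
                f"event {ev.event_id} has {ev.image_side} px holograms; "
                f"model expects {image_side} px"
            )
        images[i, 0] = ev.holograms[0]
        images[i, 1] = ev.holograms[1]
        if ev.fluorescence is not None:
            fluor[i, :NUM_FLUOR_CHANNELS] = ev.fluorescence
            fluor[i, NUM_FLUOR_CHANNELS] = 1.0
    return images, fluor


@dataclass
class TrainReport:
    """Per-epoch training trace."""

    loss: List[float]
    held_out_accuracy: List[float]
    config_hash: str
    seed: int

    def __post_init__(self):
        if len(self.loss) != len(self.held_out_accuracy):
            raise DataError("loss and accuracy traces must have equal length")


class PollenClassifier:
    """Two-branch hologram + fluorescence classifier (untrained model).

    The network is initialised from ``config.rng_seed`` at construction
    (no pre-trained weights), so two builds with the same seed produce
    identical outputs.  Call :meth:`fit` to train.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.net = TwoBranchNet(
            image_side=config.image_side,
            conv_blocks=config.conv_blocks,
            fluor_hidden_units=config.fluor_hidden_units,
            n_classes=len(config.class_names),
            rng_seed=config.rng_seed,
            image_features=config.image_features,
        )

    # -- prediction ---------------------------------------------------
    def predict_logits(
        self, images: np.ndarray, fluor: np.ndarray, batch: int = 256
    ) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch):
            out.append(self.net.forward(images[i:i + batch], fluor[i:i + batch]))
        return np.concatenate(out) if out else np.empty((0, len(self.config.class_names)))

    def predict(self, events: Sequence[EventRecord]) -> List[Prediction]:
        images, fluor = encode_events(events, self.config.image_side)
        probs = softmax(self.predict_logits(images, fluor)) if len(events) else []
        return [
            Prediction(ev.event_id, p, self.config.class_names)
            for ev, p in zip(events, probs)
        ]

    # -- training -----------------------------------------------------
    def fit(
        self,
        train_events: Sequence[EventRecord],
        val_events: Optional[Sequence[EventRecord]] = None,
    ) -> "ClassifierFit":
        """Train by cross-entropy with per-epoch fluorescence masking.

        Every training event must be labelled with a class from
        ``config.class_names`` (prefilter acceptance is the caller's
        pipeline responsibility).  Deterministic given the config seed.
        """
        cfg = self.config
        index = {name: i for i, name in enumerate(cfg.class_names)}
        y = np.empty(len(train_events), dtype=np.int64)
        for i, ev in enumerate(train_events):
            if ev.true_label is None:
                raise DataError(f"training event {ev.event_id} is unlabelled")
            if ev.true_label not in index:
                raise DataError(
                    f"training event {ev.event_id} has label "
                    f"{ev.true_label!r} outside class_names"
                )
            y[i] = index[ev.true_label]
        images, fluor = encode_events(train_events, cfg.image_side)
        has_fluor = fluor[:, -1] > 0
        val = None
        if val_events is not None:
            vy = np.array([index[ev.true_label] for ev in val_events])
            val = (*encode_events(val_events, cfg.image_side), vy)

        rng = np.random.default_rng(derive_seed(cfg.rng_seed, "train"))
        opt = Adam(self.net.params(), lr=cfg.learning_rate)
        losses, accs = [], []
        n = len(train_events)
        for epoch in range(cfg.epochs):
            # fluorescence masking is re-drawn each epoch
            drop = rng.uniform(size=n) < cfg.fluor_mask_prob
            fl = fluor.copy()
            fl[drop & has_fluor] = 0.0
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                self.net.zero_grad()
                logits = self.net.forward(images[sel], fl[sel])
                loss, dlogits = cross_entropy(logits, y[sel])
                self.net.backward(dlogits)
                opt.step()
                epoch_loss += float(loss) * len(sel)
            losses.append(epoch_loss / max(n, 1))
            if val is not None:
                vl = self.predict_logits(val[0], val[1])
                accs.append(float((vl.argmax(axis=1) == val[2]).mean()))
            else:
                accs.append(float("nan"))
        report = TrainReport(
            loss=losses, held_out_accuracy=accs,
            config_hash=cfg.hash(), seed=cfg.rng_seed,
        )
        return ClassifierFit(model=self, report=report)


@dataclass
class ClassifierFit:
    """Results of :meth:`PollenClassifier.fit`."""

    model: PollenClassifier
    report: TrainReport

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def predict(self, events: Sequence[EventRecord]) -> List[Prediction]:
        return self.model.predict(events)

    def accuracy(self, events: Sequence[EventRecord]) -> float:
        preds = self.predict(events)
        hits = [
            p.class_names[int(p.probs.argmax())] == ev.true_label
            for p, ev in zip(preds, events)
        ]
        return float(np.mean(hits)) if hits else float("nan")

    def export(self, path) -> None:
        from .onnx_io import export_model

        export_model(self.model, path)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Two-branch pollen classifier fit",
            "=" * 40,
            f"classes:            {', '.join(cfg.class_names)}",
            f"image side:         {cfg.image_side} px",
            f"conv blocks:        {cfg.conv_blocks}",
            f"fluor hidden units: {cfg.fluor_hidden_units}",
            f"fluor mask prob:    {cfg.fluor_mask_prob}",
            f"epochs:             {cfg.epochs}",
            f"seed / config hash: {cfg.rng_seed} / {self.report.config_hash}",
            "-" * 40,
            "epoch  train_loss  held_out_acc",
        ]
        for i, (l, a) in enumerate(
            zip(self.report.loss, self.report.held_out_accuracy), start=1
        ):
            lines.append(f"{i:5d}  {l:10.4f}  {a:12.4f}")
        return "\n".join(lines)


def build_model(config: ModelConfig) -> PollenClassifier:
    """Construct an untrained classifier from a configuration."""
    return PollenClassifier(config)


def train_model(
    model: PollenClassifier,
    train_events: Sequence[EventRecord],
    val_events: Optional[Sequence[EventRecord]] = None,
) -> ClassifierFit:
    """Functional façade over :meth:`PollenClassifier.fit`."""
    return model.fit(train_events, val_events)
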