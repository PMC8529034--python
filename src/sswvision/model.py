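"""CNN that predicts 88-dim phonological probability vectors from texture images.

The network maps an RGB texture crop to one raw 88-dimensional output whose
slices are normalized per group (softmax over the vowel/consonant slots,
sigmoid over special phonemes, repetition and the hash bits).  Training
minimizes the composite cross-entropy — the sum of a log-softmax loss for
v1, c1, v2, c2 and a log-sigmoid loss for s1, s2, r, h — by minibatch SGD
with momentum, with the convolutional stack frozen by default so that only
the fully connected head is fitted.

Two backbones are available: a VGG16-style stack (13 conv + 3 FC layers,
dropout on the first two FC layers) and a small two-conv test backbone that
trains in seconds on a CPU.  Following the statsmodels convention, data and
configuration are held by :class:`TexturePhonologyModel`, whose ``fit``
returns a :class:`TrainingResults` carrying per-fold models, learning curves
and a ``summary()`` table; the module-level ``build_model`` / ``train`` /
``predict`` / ``composite_loss`` functions are thin wrappers over these
objects.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict, field, replace

import numpy as np
import pandas as pd
from PIL import Image

from . import _nn, phonology
from .phonology import (DIM, SOFTMAX_GROUPS, SIGMOID_GROUPS,
                        GroupProbabilities)

__all__ = [
    "ModelConfig", "PhonoCNN", "TexturePhonologyModel", "TrainingResults",
    "FoldResult", "UnknownBackbone", "InsufficientData",
    "build_model", "composite_loss", "composite_loss_grad", "train", "predict",
    "save_model", "load_model",
]

# fixed preprocessing constants (images scaled to [0,1] then standardized)
_MEAN = 0.45
_STD = 0.225


class UnknownBackbone(ValueError):
    pass


class InsufficientData(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration.

    The defaults are the full-scale regime: VGG16-style backbone, dropout
    0.5 on the first two FC layers, minibatches of 40, momentum 0.5,
    learning rate 2.5e-6, 100 epochs, convolutional layers frozen.
    ``small_test`` gives the small backbone a step size suited to its scale.
    """

    backbone: str = "vgg16"
    freeze_conv: bool = True
    dropout_rate: float = 0.5
    batch_size: int = 40
    momentum: float = 0.5
    learning_rate: float = 2.5e-6
    epochs: int = 100
    seed: int = 0

    @classmethod
    def small_test(cls, **overrides) -> "ModelConfig":
        base = dict(backbone="small", epochs=10, learning_rate=0.01)
        base.update(overrides)
        return cls(**base)

    @property
    def input_size(self) -> int:
        # the small profile keeps 64 px so high-frequency texture survives
        return {"vgg16": 224, "small": 64}[self.backbone]


_VGG_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
             512, 512, 512, "M", 512, 512, 512, "M"]


class PhonoCNN:
    """A convolutional feature stack plus a fully connected head.

    ``conv`` ends in a Flatten; ``head`` is three Dense layers with dropout
    on the first two and a raw 88-dim output.
    """

    def __init__(self, config: ModelConfig):
        if config.backbone not in ("vgg16", "small"):
            raise UnknownBackbone(f"unknown backbone {config.backbone!r}")
        self.config = config
        rng = np.random.default_rng(config.seed)
        conv_layers = []
        size = config.input_size
        ch = 3
        if config.backbone == "vgg16":
            for item in _VGG_PLAN:
                if item == "M":
                    conv_layers.append(_nn.MaxPool2D())
                    size //= 2
                else:
                    conv_layers.append(_nn.Conv2D(ch, item, rng=rng))
                    conv_layers.append(_nn.ReLU())
                    ch = item
            fc_sizes = (4096, 4096)
        else:
            for out_ch in (8, 16):
                conv_layers.append(_nn.Conv2D(ch, out_ch, rng=rng))
                conv_layers.append(_nn.ReLU())
                conv_layers.append(_nn.MaxPool2D())
                ch = out_ch
                size //= 2
            fc_sizes = (256, 128)
        conv_layers.append(_nn.Flatten())
        self.conv = _nn.Sequential(conv_layers)
        self.feature_dim = size * size * ch
        head_layers = []
        n_in = self.feature_dim
        for n_out in fc_sizes:
            head_layers += [_nn.Dense(n_in, n_out, rng=rng), _nn.ReLU(),
                            _nn.Dropout(config.dropout_rate)]
            n_in = n_out
        head_layers.append(_nn.Dense(n_in, DIM, rng=rng))
        self.head = _nn.Sequential(head_layers)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        # per-dimension feature standardization, set from the training fold
        self.feature_mean = None
        self.feature_std = None

    # -- introspection -----------------------------------------------------
    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, _nn.Conv2D) for l in self.conv.layers)

    @property
    def n_fc_layers(self) -> int:
        return sum(isinstance(l, _nn.Dense) for l in self.head.layers)

    @property
    def output_dim(self) -> int:
        return self.head.layers[-1].W.shape[1]

    def conv_params(self):
        return [arr for _, _, arr in self.conv.param_list()]

    # -- forward -----------------------------------------------------------
    def preprocess(self, images) -> np.ndarray:
        """Resize (bilinear) to the backbone input and standardize channels."""
        single = not isinstance(images, (list, tuple)) and np.ndim(images) == 3
        if single:
            images = [images]
        size = self.config.input_size
        out = np.empty((len(images), size, size, 3))
        for i, img in enumerate(images):
            if not isinstance(img, Image.Image):
                arr = np.asarray(img)
                if arr.dtype != np.uint8:
                    arr = np.clip(arr * 255.0 if arr.max() <= 1.0 else arr, 0, 255)
                    arr = arr.astype(np.uint8)
                img = Image.fromarray(arr)
            img = img.convert("RGB").resize((size, size), Image.BILINEAR)
            out[i] = np.asarray(img, dtype=float) / 255.0
        return (out - _MEAN) / _STD

    def features(self, images) -> np.ndarray:
        feats = self.conv.forward(self.preprocess(images))
        if self.feature_mean is not None:
            feats = (feats - self.feature_mean) / self.feature_std
        return feats

    def forward(self, images, train=False) -> np.ndarray:
        return self.head_forward(self.features(images), train=train)

    def head_forward(self, feats, train=False) -> np.ndarray:
        return self.head.forward(feats, train=train, rng=self._dropout_rng)

    def predict(self, images):
        """Raw outputs and per-sample :class:`GroupProbabilities`."""
        raw = self.forward(images, train=False)
        probs = [GroupProbabilities.from_raw(row) for row in raw]
        return raw, probs

    # -- checkpointing -----------------------------------------------------
    def head_snapshot(self):
        return [(name, arr.copy()) for _, name, arr in self.head.param_list()]

    def load_head_snapshot(self, snapshot):
        for (layer, name, arr), (sname, sarr) in zip(self.head.param_list(), snapshot):
            assert name == sname
            arr[...] = sarr


def build_model(config: ModelConfig = None) -> PhonoCNN:
    """Construct the network described by ``config`` (default configuration
    if omitted)."""
    return PhonoCNN(config or ModelConfig())


# ---------------------------------------------------------------------------
# Composite loss


def composite_loss(output, target) -> float:
    """Mean over samples of the summed per-group cross-entropies.

    ``output`` is raw (pre-normalization); ``target`` is the 88-bit encoding.
    Accepts single vectors or batches.  Equals
    ``phonology.score_candidate`` on a single pair.
    """
    X = np.atleast_2d(np.asarray(output, dtype=float))
    T = np.atleast_2d(np.asarray(target, dtype=float))
    total = np.zeros(X.shape[0])
    for g in SOFTMAX_GROUPS:
        m = X[:, g].max(axis=1, keepdims=True)
        log_z = m[:, 0] + np.log(np.exp(X[:, g] - m).sum(axis=1))
        total += log_z - (X[:, g] * T[:, g]).sum(axis=1)
    for g in SIGMOID_GROUPS:
        # -t log sigma(x) - (1-t) log(1 - sigma(x)), stable form
        x, t = X[:, g], T[:, g]
        total += (np.logaddexp(0.0, -x) * t + np.logaddexp(0.0, x) * (1 - t)).sum(axis=1)
    return float(total.mean())


def composite_loss_grad(output, target) -> np.ndarray:
    """Gradient of :func:`composite_loss` w.r.t. the raw output batch."""
    X = np.atleast_2d(np.asarray(output, dtype=float))
    T = np.atleast_2d(np.asarray(target, dtype=float))
    grad = np.empty_like(X)
    for g in SOFTMAX_GROUPS:
        e = np.exp(X[:, g] - X[:, g].max(axis=1, keepdims=True))
        grad[:, g] = e / e.sum(axis=1, keepdims=True) - T[:, g]
    for g in SIGMOID_GROUPS:
        grad[:, g] = 1.0 / (1.0 + np.exp(-X[:, g])) - T[:, g]
    return grad / X.shape[0]


# ---------------------------------------------------------------------------
# Training


def _as_triples(pairs):
    """Normalize pairs to (image_id, image, target)."""
    out = []
    for i, p in enumerate(pairs):
        if len(p) == 3:
            out.append((p[0], p[1], np.asarray(p[2], dtype=float)))
        else:
            out.append((i, p[0], np.asarray(p[1], dtype=float)))
    return out


@dataclass
class FoldResult:
    fold: int
    model: PhonoCNN
    curve: pd.DataFrame
    test_ids: list
    checkpoints: list = field(default_factory=list)


class TrainingResults:
    """Fit results: one trained model and learning curve per fold."""

    def __init__(self, config: ModelConfig, folds):
        self.config = config
        self.folds = folds

    @property
    def model(self) -> PhonoCNN:
        """The first fold's trained model (the only one when folds=1)."""
        return self.folds[0].model

    @property
    def curves(self) -> pd.DataFrame:
        frames = []
        for fr in self.folds:
            df = fr.curve.copy()
            df.insert(0, "fold", fr.fold)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        buf = io.StringIO()
        cfg = self.config
        buf.write("Texture -> sound-symbolic word model\n")
        buf.write("=" * 52 + "\n")
        buf.write(f"backbone        {cfg.backbone:>12}    frozen conv  {cfg.freeze_conv}\n")
        buf.write(f"epochs          {cfg.epochs:>12}    batch size   {cfg.batch_size}\n")
        buf.write(f"learning rate   {cfg.learning_rate:>12g}    momentum     {cfg.momentum}\n")
        buf.write(f"dropout         {cfg.dropout_rate:>12}    seed         {cfg.seed}\n")
        buf.write(f"folds           {len(self.folds):>12}\n")
        buf.write("-" * 52 + "\n")
        buf.write("fold  final train loss  final test loss   acc1   acc2\n")
        for fr in self.folds:
            last = fr.curve.iloc[-1]
            a1 = f"{last['acc1']:.3f}" if np.isfinite(last.get("acc1", np.nan)) else "   --"
            a2 = f"{last['acc2']:.3f}" if np.isfinite(last.get("acc2", np.nan)) else "   --"
            tl = last["test_loss"]
            tl = f"{tl:16.4f}" if np.isfinite(tl) else " " * 14 + "--"
            buf.write(f"{fr.fold:>4}  {last['train_loss']:17.4f} {tl}  {a1}  {a2}\n")
        return buf.getvalue()


class TexturePhonologyModel:
    """Image/SSW-target pairs plus a configuration, ready to fit.

    ``pairs`` is a list of ``(image_id, image, target_88bits)`` (one entry
    per annotated SSW token, so an image appears once per token) or plain
    ``(image, target)`` tuples.  Fold assignment groups by image id so the
    same image never spans train and test.
    """

    def __init__(self, pairs, config: ModelConfig = None):
        self.pairs = _as_triples(pairs)
        if not self.pairs:
            raise InsufficientData("no training pairs")
        self.config = config or ModelConfig()
        ids, images = [], {}
        for img_id, img, _ in self.pairs:
            if img_id not in images:
                images[img_id] = img
                ids.append(img_id)
        self.image_ids = ids
        self.images = images

    @classmethod
    def from_corpus(cls, images: dict, annotations, config: ModelConfig = None,
                    skip_unparseable: bool = False):
        """Build from an image map and annotation records via dataset.make_pairs."""
        from . import dataset
        return cls(dataset.make_pairs(images, annotations,
                                      skip_unparseable=skip_unparseable), config)

    # -- fold assignment ---------------------------------------------------
    def fold_assignment(self, folds: int):
        if len(self.image_ids) < folds:
            raise InsufficientData(
                f"{len(self.image_ids)} images cannot be split into {folds} folds")
        rng = np.random.default_rng(self.config.seed)
        ids = list(self.image_ids)
        rng.shuffle(ids)
        if folds == 1:
            return [set()]
        return [set(chunk) for chunk in np.array_split(ids, folds)]

    # -- fitting -----------------------------------------------------------
    def fit(self, folds: int = 1, lexicon=None, counts=None, answered=None,
            keep_checkpoints: bool = False, epochs: int = None,
            fit_folds=None) -> TrainingResults:
        """Train one model per cross-validation fold.

        If ``lexicon`` (list of SSWForm) and ``answered`` (image id -> set of
        canonical word strings) are given, per-epoch rank-1/rank-2 candidate
        accuracies on the held-out images are added to the curves.
        ``fit_folds`` restricts training to a subset of fold indices while
        keeping the full fold assignment (useful for spot checks).
        """
        cfg = self.config if epochs is None else replace(self.config, epochs=epochs)
        test_sets = self.fold_assignment(folds)
        if fit_folds is not None:
            test_sets = [test_sets[i] for i in fit_folds]
        targets_matrix = None
        if lexicon is not None:
            lexicon = list(lexicon)
            targets_matrix = np.stack([phonology.encode_ssw(f) for f in lexicon]).astype(float)
        results = []
        for fold, test_ids in enumerate(test_sets):
            fold_cfg = replace(cfg, seed=cfg.seed + 1000 * fold)
            results.append(self._fit_fold(fold, fold_cfg, test_ids, lexicon,
                                          targets_matrix, counts, answered,
                                          keep_checkpoints))
        return TrainingResults(cfg, results)

    def _fit_fold(self, fold, cfg, test_ids, lexicon, targets_matrix, counts,
                  answered, keep_checkpoints):
        model = PhonoCNN(cfg)
        rng = np.random.default_rng(cfg.seed + 7)

        frozen = cfg.freeze_conv
        if frozen:
            # conv stack is fixed: extract features once per unique image and
            # standardize them with training-fold statistics
            id_index = {img_id: i for i, img_id in enumerate(self.image_ids)}
            feats = model.features([self.images[i] for i in self.image_ids])
            train_rows = [id_index[i] for i in self.image_ids if i not in test_ids]
            model.feature_mean = feats[train_rows].mean(axis=0)
            # floor keeps near-constant ReLU dims from exploding off-fold
            model.feature_std = np.maximum(feats[train_rows].std(axis=0), 1e-2)
            feats = (feats - model.feature_mean) / model.feature_std
        train_idx = [i for i, (img_id, _, _) in enumerate(self.pairs)
                     if img_id not in test_ids]
        test_idx = [i for i, (img_id, _, _) in enumerate(self.pairs)
                    if img_id in test_ids]
        if not train_idx:
            raise InsufficientData("a fold has no training pairs")
        T = np.stack([self.pairs[i][2] for i in range(len(self.pairs))])

        def batch_inputs(idx):
            if frozen:
                return feats[[id_index[self.pairs[i][0]] for i in idx]]
            return model.preprocess([self.pairs[i][1] for i in idx])

        def mean_loss(idx):
            if not idx:
                return float("nan")
            total, n = 0.0, 0
            for s in range(0, len(idx), 256):
                chunk = idx[s:s + 256]
                x = batch_inputs(chunk)
                out = model.head_forward(x, train=False) if frozen else \
                    model.head_forward(model.conv.forward(x), train=False)
                total += composite_loss(out, T[chunk]) * len(chunk)
                n += len(chunk)
            return total / n

        eval_test_ids = sorted(test_ids, key=str)
        records, checkpoints = [], []
        params = model.head.param_list()
        if not frozen:
            params = model.conv.param_list() + params
        opt = _nn.SGD(params, cfg.learning_rate, cfg.momentum)
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(train_idx)
            for s in range(0, len(order), cfg.batch_size):
                chunk = list(order[s:s + cfg.batch_size])
                x = batch_inputs(chunk)
                if frozen:
                    out = model.head_forward(x, train=True)
                    grad = composite_loss_grad(out, T[chunk])
                    model.head.backward(grad)
                else:
                    h = model.conv.forward(x, train=True)
                    out = model.head_forward(h, train=True)
                    grad = composite_loss_grad(out, T[chunk])
                    model.conv.backward(model.head.backward(grad))
                opt.step()
            rec = {"epoch": epoch,
                   "train_loss": mean_loss(train_idx),
                   "test_loss": mean_loss(test_idx),
                   "acc1": float("nan"), "acc2": float("nan")}
            if targets_matrix is not None and answered is not None and eval_test_ids:
                from . import evaluation
                raw = self._raw_for_ids(model, eval_test_ids, feats if frozen else None,
                                        id_index if frozen else None)
                ranked = evaluation.rank_images(raw, eval_test_ids, lexicon,
                                                targets=targets_matrix, k=2,
                                                counts=counts)
                rec["acc1"] = evaluation.candidate_accuracy(ranked, answered, 1)
                rec["acc2"] = evaluation.candidate_accuracy(ranked, answered, 2)
            records.append(rec)
            if keep_checkpoints:
                checkpoints.append(model.head_snapshot())
        curve = pd.DataFrame.from_records(records)
        return FoldResult(fold, model, curve, eval_test_ids, checkpoints)

    def _raw_for_ids(self, model, img_ids, feats=None, id_index=None):
        if feats is not None:
            x = feats[[id_index[i] for i in img_ids]]
            return model.head_forward(x, train=False)
        return model.forward([self.images[i] for i in img_ids], train=False)


def train(pairs, config: ModelConfig = None, folds: int = 10,
          **fit_kwargs) -> TrainingResults:
    """Fit one model per fold; see :meth:`TexturePhonologyModel.fit`."""
    return TexturePhonologyModel(pairs, config).fit(folds=folds, **fit_kwargs)


def predict(model: PhonoCNN, image):
    """Raw 88-dim output and normalized group probabilities for one image."""
    raw, probs = model.predict([image] if np.ndim(image) == 3 else image)
    return raw[0], probs[0]


# ---------------------------------------------------------------------------
# Checkpoint I/O


def save_model(model: PhonoCNN, path) -> None:
    """Save config and all weights to an .npz checkpoint."""
    arrays = {"config_json": np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)}
    for prefix, seq in (("conv", model.conv), ("head", model.head)):
        for i, (layer, name, arr) in enumerate(seq.param_list()):
            arrays[f"{prefix}_{i}_{name}"] = arr
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_std"] = model.feature_std
    np.savez(path, **arrays)


def load_model(path) -> PhonoCNN:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = PhonoCNN(cfg)
        for prefix, seq in (("conv", model.conv), ("head", model.head)):
            for i, (layer, name, arr) in enumerate(seq.param_list()):
                arr[...] = data[f"{prefix}_{i}_{name}"]
        if "feature_mean" in data:
            model.feature_mean = data["feature_mean"]
            model.feature_std = data["feature_std"]
    return model
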