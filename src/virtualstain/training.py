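"""Stain-specific tile classifier training and cross-validated evaluation.

One binary classifier per IHC stain family is trained on weakly labeled
H&E tiles (binary cross-entropy, mini-batch optimization, early stopping on
validation loss with best-checkpoint restore) and scored by AUROC and AUPRC
on the patient-held-out test split of each fold.  AUROC uses the pairwise
rank statistic with midrank (0.5) credit for ties; AUPRC is step-function
integration of the precision-recall curve.  AUPRC is also reported as a
fold over the prevalence baseline, since a no-skill classifier attains
AUPRC equal to the positive-class prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .dataset import DatasetManifest, LabeledPair, NormStats, compute_norm_stats, gather_tiles, normalize
from .nn import Adam, SGD, SmallConvNet, bce_grad, bce_with_logits, sigmoid

__all__ = [
    "TrainConfig",
    "TileClassifier",
    "Metrics",
    "train",
    "evaluate",
    "cross_validate",
    "auroc_score",
    "auprc_score",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults mirror the study protocol (SGD, learning rate 1e-4, batch 240,
    early-stopping patience 8); ``grid`` optionally holds
    (optimizer, learning-rate) pairs to search by mean validation loss.
    The ``small_convnet`` backbone is the supported desk-scale default; a
    large pretrained backbone would need a DL framework and is out of scope
    here, so requesting one raises.
    """

    backbone: str = "small_convnet"
    optimizer: str = "sgd"
    learning_rate: float = 1e-4
    batch_size: int = 240
    patience_epochs: int = 8
    max_epochs: int = 100
    seed: int = 0
    grid: tuple[tuple[str, float], ...] | None = None
    channels: tuple[int, ...] = (8, 16, 32, 32)
    input_downsample: int = 4

    def __post_init__(self):
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.backbone != "small_convnet":
            raise ValueError(
                f"backbone {self.backbone!r} is not available in this build; use 'small_convnet'"
            )
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


@dataclass
class Metrics:
    auroc: float
    auprc: float
    prevalence: float
    auprc_fold_over_baseline: float
    n_tiles: int


class TileClassifier:
    """A trained tile model plus the normalization statistics it expects.

    Exposes per-tile melanocyte probability and, through ``net``, all
    convolutional activations/gradients needed by the saliency stage.
    """

    def __init__(self, net: SmallConvNet, norm_stats: NormStats, config: TrainConfig, history: dict | None = None):
        self.net = net
        self.norm_stats = norm_stats
        self.config = config
        self.history = history or {}

    # ------------------------------------------------------------------
    def normalize_tiles(self, tiles: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> normalized float32 (N, 3, H, W)."""
        x = normalize(tiles, self.norm_stats)
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def probability(self, tiles: np.ndarray, batch_size: int = 240) -> np.ndarray:
        """Melanocyte probability in [0, 1] per uint8 RGB tile."""
        if tiles.ndim == 3:
            tiles = tiles[None]
        out = np.empty(len(tiles), dtype=np.float64)
        for i in range(0, len(tiles), batch_size):
            x = self.normalize_tiles(tiles[i : i + batch_size])
            out[i : i + batch_size] = sigmoid(self.net.forward(x))
        return out

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {f"p{i}": a for i, a in enumerate(self.net.get_state())}
        np.savez(path.with_suffix(".npz"), **state)
        meta = {
            "channels": list(self.net.channels),
            "downsample": self.net.downsample,
            "pool": self.net.pool,
            "norm_mean": list(self.norm_stats.mean),
            "norm_sd": list(self.norm_stats.sd),
            "config": {
                "backbone": self.config.backbone,
                "optimizer": self.config.optimizer,
                "learning_rate": self.config.learning_rate,
                "batch_size": self.config.batch_size,
                "patience_epochs": self.config.patience_epochs,
                "max_epochs": self.config.max_epochs,
                "seed": self.config.seed,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TileClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = SmallConvNet(
            channels=tuple(meta["channels"]), downsample=meta["downsample"], pool=meta.get("pool", "stride")
        )
        with np.load(path.with_suffix(".npz")) as z:
            net.set_state([z[f"p{i}"] for i in range(len(z.files))])
        stats = NormStats(tuple(meta["norm_mean"]), tuple(meta["norm_sd"]))
        cfg = TrainConfig(**meta["config"])
        return cls(net, stats, cfg)


def _make_optimizer(net: SmallConvNet, cfg: TrainConfig):
    return SGD(net, cfg.learning_rate) if cfg.optimizer == "sgd" else Adam(net, cfg.learning_rate)


def train(
    train_tiles: np.ndarray,
    train_labels: np.ndarray,
    val_tiles: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig | None = None,
    norm_stats: NormStats | None = None,
) -> TileClassifier:
    """Train a tile classifier with early stopping.

    Normalization statistics come from the training split only.  Training
    stops when the validation loss has not improved for
    ``cfg.patience_epochs`` consecutive epochs (or at ``max_epochs``) and
    the best-validation-loss weights are restored.  Deterministic per seed.
    """
    cfg = cfg or TrainConfig()
    y_tr = np.asarray(train_labels, dtype=np.float64)
    y_va = np.asarray(val_labels, dtype=np.float64)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split must contain both classes")
    stats = norm_stats or compute_norm_stats(train_tiles)
    net = SmallConvNet(channels=cfg.channels, downsample=cfg.input_downsample, seed=cfg.seed)
    clf = TileClassifier(net, stats, cfg)
    opt = _make_optimizer(net, cfg)
    rng = np.random.default_rng(cfg.seed)

    # reduce once: the entry pooling is parameter-free
    x_tr = net.reduce_input(clf.normalize_tiles(train_tiles))
    x_va = net.reduce_input(clf.normalize_tiles(val_tiles))

    def val_loss() -> float:
        losses = []
        weights = []
        for i in range(0, len(x_va), cfg.batch_size):
            z = net.forward(x_va[i : i + cfg.batch_size], pre_reduced=True)
            losses.append(bce_with_logits(z, y_va[i : i + cfg.batch_size]))
            weights.append(len(z))
        return float(np.average(losses, weights=weights))

    best = np.inf
    best_state = net.get_state()
    since_best = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        ep_losses, ep_w = [], []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            z = net.forward(x_tr[idx], pre_reduced=True)
            ep_losses.append(bce_with_logits(z, y_tr[idx]))
            ep_w.append(len(idx))
            net.zero_grad()
            net.backward(bce_grad(z, y_tr[idx]), need_input_grad=False)
            opt.step()
        vl = val_loss()
        history["train_loss"].append(float(np.average(ep_losses, weights=ep_w)))
        history["val_loss"].append(vl)
        if vl < best - 1e-9:
            best = vl
            best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience_epochs:
                break
    net.set_state(best_state)
    clf.history = history
    return clf


def auroc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive outranks a random negative, ties 0.5."""
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: test set contains a single class")
    ranks = rankdata(s)  # midranks
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average precision: step integration of the precision-recall curve."""
    y = np.asarray(labels).astype(np.float64)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = y.sum()
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("AUPRC undefined: test set contains a single class")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    # evaluate at the last index of each tied-score block
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[last]
    n_at = last + 1.0
    precision = tp / n_at
    recall = tp / n_pos
    prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev) * precision))


def evaluate(model: TileClassifier, tiles: np.ndarray, labels: np.ndarray) -> Metrics:
    """AUROC/AUPRC of a trained model on labeled test tiles."""
    scores = model.probability(tiles)
    return evaluate_scores(labels, scores)


def evaluate_scores(labels: np.ndarray, scores: np.ndarray) -> Metrics:
    y = np.asarray(labels)
    prevalence = float(np.mean(y))
    auroc = auroc_score(y, scores)
    auprc = auprc_score(y, scores)
    return Metrics(auroc, auprc, prevalence, auprc / prevalence, len(y))


@dataclass
class CVResult:
    per_fold: list[Metrics]
    models: list[TileClassifier]
    mean_auroc: float
    sd_auroc: float
    mean_auprc: float
    sd_auprc: float
    chosen_config: TrainConfig


def cross_validate(
    manifest: DatasetManifest,
    pairs: list[LabeledPair],
    negatives: list[np.ndarray] | None,
    cfg: TrainConfig | None = None,
) -> CVResult:
    """Train one model per fold and aggregate test metrics (mean, population sd).

    When ``cfg.grid`` is set, each (optimizer, learning-rate) combination is
    trained on every fold and the one with the lowest mean best-validation
    loss is selected before test evaluation.
    """
    cfg = cfg or TrainConfig()
    n_folds = manifest.n_folds
    data = []
    for f in range(n_folds):
        data.append(
            {
                split: gather_tiles(manifest, pairs, negatives, f, split)
                for split in ("train", "val", "test")
            }
        )

    candidates = [replace(cfg, optimizer=o, learning_rate=lr, grid=None) for (o, lr) in cfg.grid] if cfg.grid else [replace(cfg, grid=None)]
    best_models: list[TileClassifier] | None = None
    best_cfg = candidates[0]
    best_val = np.inf
    for cand in candidates:
        models = []
        val_losses = []
        for f in range(n_folds):
            (x_tr, y_tr), (x_va, y_va) = data[f]["train"], data[f]["val"]
            m = train(x_tr, y_tr, x_va, y_va, cand)
            models.append(m)
            val_losses.append(min(m.history["val_loss"]))
        mean_val = float(np.mean(val_losses))
        if mean_val < best_val:
            best_val, best_models, best_cfg = mean_val, models, cand

    per_fold = []
    for f, m in enumerate(best_models):
        x_te, y_te = data[f]["test"]
        per_fold.append(evaluate(m, x_te, y_te))
    aurocs = np.array([m.auroc for m in per_fold])
    auprcs = np.array([m.auprc for m in per_fold])
    return CVResult(
        per_fold=per_fold,
        models=best_models,
        mean_auroc=float(aurocs.mean()),
        sd_auroc=float(aurocs.std()),
        mean_auprc=float(auprcs.mean()),
        sd_auprc=float(auprcs.std()),
        chosen_config=best_cfg,
    )
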