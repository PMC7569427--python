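"""Training, inference and experiment orchestration.

Training follows the reference recipe: Adam (lr 0.001, beta1 0.9,
beta2 0.999, eps 1e-8), batch size 32, He-normal initialization of the
conv kernels, a seeded 90/10 train/validation split of the patch set,
and the combined cross-entropy + Dice objective. Inference tiles an
image with the sliding-window grid, runs the model per patch, and
averages overlapping vessel-probability windows back into a full map.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import metrics as metrics_mod
from .model import (
    LasppSpec,
    NetworkConfig,
    SegmentationModel,
    build_variant,
)
from .nn import Conv2d, Param, he_normal
from .objective import LossConfig, segmentation_loss, segmentation_loss_logits
from .preprocess import PreprocessConfig, extract_patches, preprocess_pipeline, reconstruct_map
from .synthfundus import SynthConfig, generate_dataset


@dataclass
class TrainConfig:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    epochs: int = 100
    val_fraction: float = 0.1
    init: str = "he_normal"
    seed: int = 0
    loss: LossConfig = field(default_factory=lambda: LossConfig(reduction="mean"))
    restore_best: bool = False
    verbose: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    n_train: int = 0
    n_val: int = 0
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    checkpoint_path: str | None = None

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "train_loss", "val_loss", "val_acc", "seconds"])
            for i, (tr, vl, va, sec) in enumerate(zip(
                    self.train_loss, self.val_loss, self.val_acc,
                    self.epoch_seconds), start=1):
                wr.writerow([i, tr, vl, va, sec])


def iter_convs(obj) -> list[Conv2d]:
    """All Conv2d layers reachable from a model/block, in registry order."""
    found: list[Conv2d] = []
    seen: set[int] = set()

    def walk(o) -> None:
        if id(o) in seen:
            return
        seen.add(id(o))
        if isinstance(o, Conv2d):
            found.append(o)
            return
        if isinstance(o, (list, tuple)):
            for item in o:
                walk(item)
            return
        if hasattr(o, "__dict__"):
            for val in vars(o).values():
                walk(val)

    walk(obj)
    return found


def init_weights(model: SegmentationModel, scheme: str = "he_normal",
                 seed: int = 0) -> SegmentationModel:
    """He-normal re-initialization of every conv kernel (biases to zero).

    Kernels are drawn from N(0, 2/fan_in); under weight normalization the
    draw becomes the direction tensor with g set to its norm, so the
    effective kernel equals the draw at initialization.
    """
    if scheme != "he_normal":
        raise ValueError(f"unknown init scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    for conv in iter_convs(model):
        shape = (conv.cout, conv.cin, conv.k, conv.k)
        conv.set_weight(he_normal(rng, shape))
        if conv.b is not None:
            conv.b.val = np.zeros_like(conv.b.val)
    return model


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999,
                 epsilon: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, epsilon
        self.t = 0
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _snapshot(model: SegmentationModel):
    return ([p.val.copy() for p in model.params()],
            [(l.running_mean.copy(), l.running_var.copy())
             for _, l in model._bn_layers()])


def _restore(model: SegmentationModel, snap) -> None:
    vals, bnstats = snap
    for p, v in zip(model.params(), vals):
        p.val = v.copy()
    for (_, l), (mean, var) in zip(model._bn_layers(), bnstats):
        l.running_mean, l.running_var = mean.copy(), var.copy()


def train(model: SegmentationModel, patches: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig | None = None,
          checkpoint_path: str | None = None) -> TrainHistory:
    """Optimize the model on a patch set with a seeded 90/10 split.

    ``patches``: (N, S, S) or (N, S, S, 1) preprocessed images in [0, 1];
    ``labels``: (N, S, S) binary masks. Returns the per-epoch history;
    the best-validation parameters are checkpointed (to
    ``checkpoint_path`` when given, and restored into the model when
    cfg.restore_best is set).
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(patches, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(labels)
    if len(x) != len(y):
        raise ValueError("patches and labels must be aligned")
    if len(x) < cfg.batch_size and len(x) < 2:
        raise ValueError("need at least 2 patches")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(x))
    n_val = max(1, int(round(cfg.val_fraction * len(x))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("empty training split")

    opt = Adam(model.params(), cfg.lr, cfg.beta1, cfg.beta2, cfg.epsilon)
    hist = TrainHistory(n_train=len(train_idx), n_val=len(val_idx))
    best = None
    for epoch in range(cfg.epochs):
        t0 = time.time()
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            probs = model.forward(x[idx], train=True)
            loss, dlogits = segmentation_loss_logits(probs, y[idx], cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch + 1}")
            model.backward(dlogits, from_logits=True)
            opt.step()
            losses.append(loss)
        # validation in eval mode
        vloss, vcorrect, vtotal = 0.0, 0, 0
        for i in range(0, len(val_idx), cfg.batch_size):
            idx = val_idx[i:i + cfg.batch_size]
            probs = model.forward(x[idx], train=False)
            loss, _ = segmentation_loss(probs, y[idx], cfg.loss)
            vloss += loss * len(idx)
            vcorrect += int(((probs[..., 1] >= 0.5) == (y[idx] > 0)).sum())
            vtotal += int(np.prod(y[idx].shape))
        vloss /= len(val_idx)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(vloss))
        hist.val_acc.append(vcorrect / vtotal)
        hist.epoch_seconds.append(time.time() - t0)
        if vloss < hist.best_val_loss:
            hist.best_val_loss = float(vloss)
            hist.best_epoch = epoch + 1
            best = _snapshot(model)
        if cfg.verbose:
            print(f"epoch {epoch + 1:3d} train {hist.train_loss[-1]:.4f} "
                  f"val {vloss:.4f} acc {hist.val_acc[-1]:.4f}")
    if best is not None and checkpoint_path is not None:
        final = _snapshot(model)
        _restore(model, best)
        model.save(checkpoint_path)
        hist.checkpoint_path = str(checkpoint_path)
        if not cfg.restore_best:
            _restore(model, final)
    elif best is not None and cfg.restore_best:
        _restore(model, best)
    return hist


def predict_image(model: SegmentationModel, image: np.ndarray,
                  patch_size: int = 48, stride: int = 5,
                  fov: np.ndarray | None = None,
                  batch_size: int = 32) -> np.ndarray:
    """Sliding-window vessel-probability map for a preprocessed image.

    With ``fov``, probabilities outside the field of view are zeroed
    (those pixels are trivially background)."""
    grid = extract_patches(image, size=patch_size, stride=stride, mode="grid")
    probs = model.predict_proba(grid.patches[..., None].astype(np.float32),
                                batch_size=batch_size)
    grid.patches = probs[..., 1]
    pmap = reconstruct_map(grid)
    if fov is not None:
        pmap = pmap * (np.asarray(fov) > 0)
    return pmap


# ---------------------------------------------------------------------------
# experiment orchestration


def desk_config(seed: int = 0) -> dict:
    """Default desk-scale experiment: a slimmed WA-Net (widths 8/16/32,
    LASPP 64) trained on 2,000 synthetic patches for 15 epochs."""
    return {
        "seed": seed,
        "synth": {},
        "synth_test": None,  # defaults to the training synth config
        "network": {"encoder_widths": [8, 16, 32], "laspp_channels": 64,
                    "variant": "wa_net"},
        "train": {"epochs": 15, "batch_size": 32},
        "n_train_images": 6,
        "n_test_images": 2,
        "n_train_patches": 2000,
        "patch_size": 48,
        "test_stride": 8,
        "threshold": 0.5,
    }


def _network_config(spec: dict, patch_size: int) -> NetworkConfig:
    laspp = LasppSpec(
        channels=spec.get("laspp_channels", 128),
        dilations=tuple(spec.get("laspp_dilations", (1, 2, 4, 8))),
    )
    return NetworkConfig(
        encoder_widths=tuple(spec.get("encoder_widths", (16, 32, 64))),
        laspp=laspp,
        patch_size=patch_size,
        variant=spec.get("variant", "wa_net"),
    )


def _prepare_patches(images, cfg: dict, seed: int):
    """Preprocess images and sample seeded random training patches."""
    pp = PreprocessConfig()
    size = cfg["patch_size"]
    n_per = int(np.ceil(cfg["n_train_patches"] / len(images)))
    xs, ys = [], []
    for i, (img, mask, fov) in enumerate(images):
        proc = preprocess_pipeline(img, pp)
        gx, gy = extract_patches(proc, mask, size=size, mode="random",
                                 n=n_per, seed=seed + 17 * i, fov=fov)
        xs.append(gx.patches)
        ys.append(gy.patches)
    x = np.concatenate(xs)[: cfg["n_train_patches"]]
    y = np.concatenate(ys)[: cfg["n_train_patches"]]
    return x, y


def run_experiment(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Synthesize -> preprocess -> train -> predict -> evaluate.

    ``config`` is a dict (see :func:`desk_config`) or a path to a
    JSON/YAML file of the same shape. Returns a report with the training
    history and held-out metrics (per image and pooled over FOV pixels);
    with ``outdir`` the checkpoint, probability maps, history and
    metrics are also written to disk.
    """
    if not isinstance(config, dict):
        text = Path(config).read_text()
        if str(config).endswith((".yml", ".yaml")):
            import yaml
            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    cfg = {**desk_config(), **config}
    seed = int(cfg["seed"])

    synth = SynthConfig(**cfg["synth"])
    synth_test = (SynthConfig(**cfg["synth_test"])
                  if cfg.get("synth_test") else synth)
    train_set = generate_dataset(cfg["n_train_images"], synth, seed=seed)
    test_set = generate_dataset(cfg["n_test_images"], synth_test,
                                seed=seed + 1000)

    x, y = _prepare_patches(train_set, cfg, seed)
    net_cfg = _network_config(cfg["network"], cfg["patch_size"])
    model = build_variant(net_cfg.variant, net_cfg, seed=seed)
    init_weights(model, seed=seed)
    tcfg = TrainConfig(**{"seed": seed, **cfg["train"]})

    out = Path(outdir) if outdir is not None else None
    ckpt = None
    if out is not None:
        (out / "checkpoint").mkdir(parents=True, exist_ok=True)
        (out / "maps").mkdir(exist_ok=True)
        ckpt = str(out / "checkpoint" / "model.npz")
    history = train(model, x, y, tcfg, checkpoint_path=ckpt)

    pp = PreprocessConfig()
    per_image = []
    all_p, all_t = [], []
    for i, (img, mask, fov) in enumerate(test_set):
        proc = preprocess_pipeline(img, pp)
        pmap = predict_image(model, proc, cfg["patch_size"], cfg["test_stride"])
        rep = metrics_mod.evaluate(pmap, mask, cfg["threshold"], fov=fov)
        per_image.append(rep)
        all_p.append(pmap[fov.astype(bool)])
        all_t.append(np.asarray(mask)[fov.astype(bool)])
        if out is not None:
            from .io import save_prob_map
            save_prob_map(out / "maps" / f"test_{i:02d}.png", pmap)
    pooled_p = np.concatenate(all_p)
    pooled_t = np.concatenate(all_t)
    roc, auc = metrics_mod.roc_auc(pooled_p, pooled_t)
    pooled = metrics_mod.summarize(
        metrics_mod.confusion(pooled_p, pooled_t, cfg["threshold"]),
        cfg["threshold"])
    pooled.auc = auc

    report = {
        "config": {k: v for k, v in cfg.items() if k != "synth_test" or v},
        "history": {"train_loss": history.train_loss,
                    "val_loss": history.val_loss,
                    "val_acc": history.val_acc,
                    "best_epoch": history.best_epoch},
        "per_image": [r.to_dict() | {"roc_points": None} for r in per_image],
        "pooled": pooled.to_dict() | {"roc_points": None},
        "auc": auc,
        "n_parameters": model.n_parameters(),
    }
    if out is not None:
        (out / "metrics.json").write_text(json.dumps(report, indent=1))
        history.to_csv(out / "history.csv")
        with open(out / "roc.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["fpr", "tpr"])
            wr.writerows(np.asarray(roc).tolist())
    return report
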