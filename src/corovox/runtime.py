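"""Training, inference and ablation drivers.

Training optimises the deep-supervision Dice loss with Adam under the
piecewise learning-rate / alpha schedules, on synthetic phantom cases (or any
provided volume/mask pairs).  Everything — case generation, the train/val/test
split, weight initialisation and batch shuffling — is driven by one integer
seed, so a run is reproducible on a single device.

The full-scale recipe (180 epochs, 16x512x512 blocks) is GPU work; the
first-class *desk preset* trains the same architecture at reduced size
(small phantoms, 8 base channels, a proportionally compressed schedule with
desk-appropriate learning rates) so the full pipeline runs on one CPU core
in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._autograd import Tensor
from .imaging_io import (
    CTVolume,
    LabelMask,
    extract_blocks,
    plan_blocks,
    stitch_blocks,
    window_and_normalize,
)
from .network import DRLCTUNet, NetworkConfig, build, count_params, make_variant
from .nn import Adam
from .objectives import (
    ScheduleConfig,
    alpha_at_epoch,
    deep_supervision_loss,
    dice_loss,
    lr_at_epoch,
)
from .phantom_gen import PhantomSpec, case_specs, generate_case
from .seg_metrics import confusion, evaluate_case

__all__ = ["TrainConfig", "RunLog", "TrainResult", "desk_train_config", "train",
           "predict", "run_ablation", "save_checkpoint", "load_checkpoint"]

DESK_LR_VALUES = (3e-3, 1e-3, 3e-4)


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_train: int = 48
    n_val: int = 8
    n_test: int = 25
    seed: int = 0
    block_depth: int = 16
    stride: int = 8

    def __post_init__(self):
        if min(self.n_train, self.n_val, self.n_test) < 1:
            raise ValueError("each split needs at least one case")


@dataclass
class RunLog:
    """One record per completed epoch plus the final test evaluation."""

    records: list[dict] = field(default_factory=list)
    test_reports: list[dict] = field(default_factory=list)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


@dataclass
class TrainResult:
    net: DRLCTUNet
    log: RunLog
    best_val_dsc: float
    best_state: dict


def desk_train_config(
    seed: int = 0,
    epochs: int = 14,
    base_channels: int = 8,
    shape: tuple[int, int, int] = (16, 32, 32),
    n_train: int = 16,
    n_val: int = 4,
    n_test: int = 6,
    deep_supervision: bool = True,
) -> TrainConfig:
    """CPU-scale preset: small phantoms, narrow network, compressed schedule."""
    phantom = PhantomSpec(
        shape=shape,
        n_trees=1,
        max_bifurcations=2,
        root_radius=1.9,
        segment_length=(6.0, 10.0),
    )
    sched = ScheduleConfig(batch_size=2).scaled(epochs, lr_values=DESK_LR_VALUES)
    net_cfg = NetworkConfig(
        base_channels=base_channels, deep_supervision=deep_supervision
    )
    return TrainConfig(
        network=net_cfg, schedule=sched, phantom=phantom,
        n_train=n_train, n_val=n_val, n_test=n_test, seed=seed,
    )


def make_dataset(cfg: TrainConfig):
    """Generate the seeded phantom cases and split them train/val/test."""
    n = cfg.n_train + cfg.n_val + cfg.n_test
    specs = case_specs(cfg.phantom, n, seed=cfg.seed)
    cases = [generate_case(s) for s in specs]
    train = cases[: cfg.n_train]
    val = cases[cfg.n_train : cfg.n_train + cfg.n_val]
    test = cases[cfg.n_train + cfg.n_val :]
    return train, val, test


def _case_blocks(vol: CTVolume, mask: LabelMask, block_depth: int, stride: int):
    norm = window_and_normalize(vol)
    plan = plan_blocks(norm.voxels.shape[0], block_depth, stride)
    xblocks = extract_blocks(norm.voxels, plan)
    yblocks = extract_blocks(mask.voxels, plan)
    return [(x[None], y) for x, y in zip(xblocks, yblocks)]


def _val_dsc(net: DRLCTUNet, cases, block_depth: int, stride: int) -> float:
    scores = []
    for vol, mask in cases:
        pred = predict(net, vol, block_depth=block_depth, stride=stride)
        c = confusion(pred, mask)
        denom = 2 * c.tp + c.fn + c.fp
        scores.append(2 * c.tp / denom if denom else 1.0)
    return float(np.mean(scores))


def train(cfg: TrainConfig, verbose: bool = False,
          max_epochs: int | None = None) -> TrainResult:
    """Optimise the configured network on seeded phantom data.

    ``max_epochs`` optionally stops the run early while keeping the
    configured schedule (useful for probing the early training phase).
    """
    train_cases, val_cases, _ = make_dataset(cfg)
    samples = []
    for vol, mask in train_cases:
        samples.extend(_case_blocks(vol, mask, cfg.block_depth, cfg.stride))

    net = build(cfg.network, seed=cfg.seed)
    opt = Adam(net.parameters(), weight_decay=cfg.schedule.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    log = RunLog()
    best_dsc = -1.0
    best_state: dict = {}
    bs = cfg.schedule.batch_size
    ds = cfg.network.deep_supervision

    n_epochs = cfg.schedule.epochs if max_epochs is None else min(
        max_epochs, cfg.schedule.epochs
    )
    for epoch in range(n_epochs):
        lr = lr_at_epoch(epoch, cfg.schedule)
        alpha = alpha_at_epoch(epoch, cfg.schedule)
        opt.lr = lr
        order = rng.permutation(len(samples))
        net.train()
        epoch_losses = []
        for lo in range(0, len(order), bs):
            batch = [samples[i] for i in order[lo : lo + bs]]
            x = Tensor(np.stack([b[0] for b in batch]).astype(net.dtype))
            y = np.stack([b[1] for b in batch]).astype(net.dtype)
            out = net(x)
            l1 = dice_loss(out.main[:, 1], y)
            if ds:
                l2, l3, l4 = (dice_loss(a[:, 1], y) for a in out.aux)
                loss = deep_supervision_loss(l1, l2, l3, l4, alpha)
            else:
                loss = l1
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_dsc = _val_dsc(net, val_cases, cfg.block_depth, cfg.stride)
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_dsc": val_dsc,
            "lr": lr,
            "alpha": alpha,
        }
        log.records.append(record)
        if verbose:  # pragma: no cover
            print(json.dumps(record))
        if val_dsc > best_dsc:
            best_dsc = val_dsc
            best_state = {k: v.copy() for k, v in net.state_dict().items()}

    if best_state:
        net.load_state_dict(best_state)
    return TrainResult(net=net, log=log, best_val_dsc=best_dsc, best_state=best_state)


def predict(
    net: DRLCTUNet,
    vol: CTVolume,
    block_depth: int = 16,
    stride: int = 8,
) -> LabelMask:
    """Window, block, forward, stitch and argmax a full volume."""
    net.eval()
    norm = window_and_normalize(vol)
    plan = plan_blocks(norm.voxels.shape[0], block_depth, stride)
    outputs = []
    for xb in extract_blocks(norm.voxels, plan):
        out = net(Tensor(xb[None, None].astype(net.dtype)))
        outputs.append(out.main.data[0])
    probs = stitch_blocks(plan, outputs)
    pred = (probs[1] > probs[0]).astype(np.uint8)  # exact ties -> background
    return LabelMask(pred, spacing=vol.spacing)


def evaluate_on_cases(net: DRLCTUNet, cases, block_depth: int = 16,
                      stride: int = 8) -> pd.DataFrame:
    rows = []
    for i, (vol, mask) in enumerate(cases):
        pred = predict(net, vol, block_depth=block_depth, stride=stride)
        rep = evaluate_case(pred, mask)
        rows.append(
            {"case": i, "dsc": rep.dsc, "recall": rep.recall,
             "precision": rep.precision, "assd": rep.assd, "hd": rep.hd}
        )
    return pd.DataFrame(rows)


def run_ablation(variants: list[str], cfg: TrainConfig) -> pd.DataFrame:
    """Train each ablation variant on identical data/seed; tabulate results."""
    rows = []
    for name in variants:
        vcfg = replace(
            cfg,
            network=make_variant(
                name,
                base_channels=cfg.network.base_channels,
                deep_supervision=cfg.network.deep_supervision,
                norm=cfg.network.norm,
            ),
        )
        result = train(vcfg)
        _, _, test_cases = make_dataset(vcfg)
        table = evaluate_on_cases(result.net, test_cases, cfg.block_depth, cfg.stride)
        means = table[["dsc", "recall", "precision", "assd", "hd"]].mean()
        rows.append(
            {"variant": name, "params": count_params(result.net), **means.to_dict()}
        )
    return pd.DataFrame(
        rows, columns=["variant", "params", "dsc", "recall", "precision", "assd", "hd"]
    )


def save_checkpoint(net: DRLCTUNet, path: str | Path) -> None:
    """Serialise weights, buffers and the architecture config to one .npz."""
    from dataclasses import asdict

    state = net.state_dict()
    meta = json.dumps(asdict(net.config))
    np.savez(path, __config__=np.array(meta), **state)


def load_checkpoint(path: str | Path) -> DRLCTUNet:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__config__"]))
    net = build(NetworkConfig(**meta))
    net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net
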