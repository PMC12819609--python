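"""Training protocol: multi-seed runner, combined loss, plateau scheduling,
checkpointing, evaluation and the ablation harness."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .assembly import AFCNet, ModelConfig, build_model
from .data import augment, load_pairs
from .exceptions import NumericError
from .metrics import (
    METRIC_NAMES,
    MetricReport,
    SeedSummary,
    combined_loss,
    compute_metrics,
    confusion,
    seed_aggregate,
    welch_t_test,
)
from .nd import Adam, ReduceLROnPlateau, Tensor, count_params
from .synthdata import ManifestRow

DEFAULT_SEEDS = (42, 8, 36, 120)


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-4
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    scheduler_min_lr: float = 1e-6
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    val_fraction: float = 0.1
    use_augmentation: bool = True
    max_steps: int | None = None  # early cut-off for smoke-scale runs

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not self.seeds:
            raise ValueError("at least one seed is required")
        self.seeds = tuple(int(s) for s in self.seeds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seeds"] = list(self.seeds)
        return d


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(model: AFCNet, path: str | Path) -> None:
    state = model.state_dict()
    state["__config__"] = np.array(json.dumps(model.config.to_dict()))
    np.savez(str(path), **state)


def load_checkpoint(path: str | Path) -> AFCNet:
    with np.load(str(path), allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(config, seed=0)
    model.load_state_dict(state)
    model.eval()
    return model


# ----------------------------------------------------------------- evaluation

def evaluate_arrays(
    model: AFCNet, images: np.ndarray, masks: np.ndarray
) -> tuple[MetricReport, list[MetricReport]]:
    """Per-image confusion metrics at model resolution, then their mean."""
    model.eval()
    per_image: list[MetricReport] = []
    for i in range(len(images)):
        out = model(Tensor(images[i : i + 1]))
        per_image.append(compute_metrics(confusion(out.binary_mask[0, 0], masks[i])))
    mean = MetricReport(
        **{
            name: float(np.mean([getattr(r, name) for r in per_image]))
            for name in METRIC_NAMES
        }
    )
    return mean, per_image


def evaluate(checkpoint: str | Path, rows: list[ManifestRow]) -> tuple[MetricReport, list[MetricReport]]:
    model = load_checkpoint(checkpoint)
    images, masks = load_pairs(rows, input_size=model.config.input_size)
    return evaluate_arrays(model, images, masks)


# ------------------------------------------------------------------- training

def _val_loss_and_dice(model: AFCNet, images: np.ndarray, masks: np.ndarray) -> tuple[float, float]:
    model.eval()
    losses, dices = [], []
    for i in range(len(images)):
        prob = model.forward_probability(Tensor(images[i : i + 1]))
        losses.append(combined_loss(prob, masks[i : i + 1, None].astype(float)).item())
        pred = (prob.data[0, 0] >= model.config.threshold).astype(np.uint8)
        dices.append(compute_metrics(confusion(pred, masks[i])).dice)
    return float(np.mean(losses)), float(np.mean(dices))


def train_single_seed(
    model_config: ModelConfig,
    train_config: TrainConfig,
    images: np.ndarray,
    masks: np.ndarray,
    seed: int,
    init_state: dict | None = None,
) -> tuple[AFCNet, list[dict], dict]:
    """Train one model under one seed; returns (model, epoch log, best state).

    `init_state` resumes from a previously saved state dict.
    """
    rng = np.random.default_rng(seed)
    model = build_model(model_config, seed=seed)
    if init_state is not None:
        model.load_state_dict({k: v for k, v in init_state.items() if k != "__config__"})
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    sched = ReduceLROnPlateau(
        opt,
        factor=train_config.scheduler_factor,
        patience=train_config.scheduler_patience,
        min_lr=train_config.scheduler_min_lr,
    )

    n = len(images)
    n_val = max(1, int(round(train_config.val_fraction * n))) if n > 1 else 0
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        tr_idx = order
    tr_images, tr_masks = images[tr_idx], masks[tr_idx]
    val_images, val_masks = images[val_idx], masks[val_idx]

    log: list[dict] = []
    best_dice = -1.0
    best_state = model.state_dict()
    step = 0
    done = False
    for epoch in range(train_config.epochs):
        model.train()
        perm = rng.permutation(len(tr_images))
        epoch_losses = []
        for start in range(0, len(perm), train_config.batch_size):
            idx = perm[start : start + train_config.batch_size]
            batch_imgs, batch_masks = [], []
            for i in idx:
                img = tr_images[i].transpose(1, 2, 0)
                msk = tr_masks[i]
                if train_config.use_augmentation:
                    img, msk = augment(img, msk, rng)
                batch_imgs.append(img.transpose(2, 0, 1))
                batch_masks.append(msk)
            x = Tensor(np.stack(batch_imgs))
            gt = np.stack(batch_masks)[:, None].astype(float)
            prob = model.forward_probability(x)
            loss = combined_loss(prob, gt)
            if not np.isfinite(loss.item()):
                raise NumericError(f"non-finite training loss at step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
            if train_config.max_steps is not None and step >= train_config.max_steps:
                done = True
                break
        if len(val_images):
            val_loss, val_dice = _val_loss_and_dice(model, val_images, val_masks)
        else:
            val_loss, val_dice = float(np.mean(epoch_losses)), float("nan")
        sched.step(val_loss)
        log.append(
            {
                "epoch": epoch,
                "step": step,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_dice": val_dice,
                "lr": opt.lr,
            }
        )
        if not len(val_images) or val_dice >= best_dice:
            best_dice = val_dice if len(val_images) else 0.0
            best_state = model.state_dict()
        if done:
            break
    model.load_state_dict(best_state)
    model.eval()
    return model, log, best_state


def train_seeds(
    model_config: ModelConfig,
    train_config: TrainConfig,
    rows_or_arrays,
    out_dir: str | Path | None = None,
    eval_arrays: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Run the full multi-seed protocol.

    `rows_or_arrays` is either a manifest (list of ManifestRow) or a
    preloaded (images, masks) pair.  If `eval_arrays` is given, each seed's
    best checkpoint is evaluated on it and per-metric seed summaries are
    reported; otherwise the best validation dice is summarized.
    """
    if isinstance(rows_or_arrays, tuple):
        images, masks = rows_or_arrays
    else:
        images, masks = load_pairs(rows_or_arrays, input_size=model_config.input_size)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    per_seed_metrics: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    logs: dict[int, list[dict]] = {}
    for seed in train_config.seeds:
        model, log, _ = train_single_seed(model_config, train_config, images, masks, seed)
        logs[seed] = log
        if out_dir is not None:
            save_checkpoint(model, out_dir / f"seed{seed}.npz")
            with open(out_dir / f"seed{seed}_log.jsonl", "w") as fh:
                for rec in log:
                    fh.write(json.dumps(rec, sort_keys=True) + "\n")
        if eval_arrays is not None:
            mean, _ = evaluate_arrays(model, *eval_arrays)
            for name in METRIC_NAMES:
                per_seed_metrics[name].append(getattr(mean, name))
        else:
            per_seed_metrics["dice"].append(log[-1]["val_dice"])

    report: dict = {
        "model_config": model_config.to_dict(),
        "train_config": train_config.to_dict(),
        "seeds": list(train_config.seeds),
        "param_count": count_params(build_model(model_config, seed=0)),
        "metrics": {},
    }
    for name, vals in per_seed_metrics.items():
        if len(vals) >= 2:
            report["metrics"][name] = seed_aggregate(vals).as_dict()
        elif vals:
            report["metrics"][name] = {"per_seed": vals, "mean": vals[0], "spread": 0.0}
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ------------------------------------------------------------------- ablation

ABLATION_VARIANTS = (
    ("baseline", dict(use_mdca=False, use_maff=False, use_ufr=False)),
    ("+MAFF", dict(use_mdca=False, use_maff=True, use_ufr=False)),
    ("+MAFF+MDCA", dict(use_mdca=True, use_maff=True, use_ufr=False)),
    ("+MAFF+MDCA+UFR", dict(use_mdca=True, use_maff=True, use_ufr=True)),
)


def ablate(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_arrays: tuple[np.ndarray, np.ndarray],
    test_arrays: tuple[np.ndarray, np.ndarray],
    out_dir: str | Path | None = None,
) -> dict:
    """Train/evaluate the four module variants under identical seeds and data.

    Emits a variant x metric table (mean +/- spread), per-variant parameter
    counts, and pairwise Welch t-test p-values per metric.
    """
    rows = []
    per_variant_values: dict[str, dict[str, list[float]]] = {}
    for name, flags in ABLATION_VARIANTS:
        cfg = replace(model_config, **flags)
        rep = train_seeds(cfg, train_config, train_arrays, out_dir=None, eval_arrays=test_arrays)
        rows.append(
            {
                "variant": name,
                "param_count": rep["param_count"],
                "metrics": rep["metrics"],
            }
        )
        per_variant_values[name] = {
            m: rep["metrics"][m]["per_seed"] for m in METRIC_NAMES if m in rep["metrics"]
        }

    pvalues: dict[str, dict[str, float]] = {m: {} for m in METRIC_NAMES}
    names = [n for n, _ in ABLATION_VARIANTS]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            for m in METRIC_NAMES:
                va = per_variant_values[a].get(m)
                vb = per_variant_values[b].get(m)
                if va and vb and len(va) >= 2 and len(vb) >= 2:
                    pvalues[m][f"{a} vs {b}"] = welch_t_test(va, vb)

    report = {
        "variants": rows,
        "pvalues": pvalues,
        "seeds": list(train_config.seeds),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "ablation.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out_dir / "ablation.tsv", "w") as fh:
            fh.write("variant\tparams\t" + "\t".join(METRIC_NAMES) + "\n")
            for row in rows:
                cells = [
                    f"{row['metrics'][m]['mean']:.4f}+/-{row['metrics'][m]['spread']:.4f}"
                    if m in row["metrics"]
                    else "-"
                    for m in METRIC_NAMES
                ]
                fh.write(f"{row['variant']}\t{row['param_count']}\t" + "\t".join(cells) + "\n")
    return report
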