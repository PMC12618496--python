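"""Two-stage optimization: imaging-encoder pretraining, then frozen-encoder
fusion training with augmentation and validation C-index early stopping."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .metrics import c_index
from .nn.layers import Adam
from .nn.model import (
    FusionConfig,
    SurvivalTransformer,
    ViTSurvival,
    nll_loss,
)
from .weibull import WeibullParams, median_time

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 1000
    patience: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    augment: bool = False
    flip_prob: float = 0.5
    rotate_deg: float = 10.0
    translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


def audit_no_leakage(dev_ids, val_ids) -> None:
    """Strict cohort isolation: any shared subject id aborts."""
    overlap = set(dev_ids) & set(val_ids)
    if overlap:
        raise RuntimeError(
            f"data leakage: subjects present in both splits: {sorted(overlap)[:5]}"
        )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(volume: np.ndarray, seed: int, index: int = 0,
            config: TrainConfig | None = None,
            mask: np.ndarray | None = None):
    """Per-sample deterministic augmentation of a (C, X, Y, Z) volume:
    axis flips (p=0.5 each), in-plane rotation, translation, isotropic
    scaling, and gamma contrast.  The mask (if given) is transformed
    congruently with nearest-neighbour interpolation."""
    cfg = config or TrainConfig(augment=True)
    rng = np.random.default_rng([seed, index])
    out = np.asarray(volume, dtype=np.float64).copy()
    m = None if mask is None else np.asarray(mask).copy()

    flips = [rng.random() < cfg.flip_prob for _ in range(3)]
    for ax, flip in enumerate(flips):
        if flip:
            out = np.flip(out, axis=ax + 1)
            if m is not None:
                m = np.flip(m, axis=ax)

    theta = np.deg2rad(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
    scale = rng.uniform(*cfg.scale_range)
    shape = np.array(out.shape[1:], dtype=float)
    shift = rng.uniform(-cfg.translate_frac, cfg.translate_frac, size=3) * shape
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]) / scale
    center = (shape - 1) / 2.0
    offset = center - rot @ (center + shift)
    if abs(theta) > 1e-12 or abs(scale - 1) > 1e-12 or np.any(np.abs(shift) > 1e-12):
        out = np.stack(
            [ndimage.affine_transform(ch, rot, offset=offset, order=1,
                                      mode="constant") for ch in out]
        )
        if m is not None:
            m = ndimage.affine_transform(m.astype(float), rot, offset=offset,
                                         order=0, mode="constant").astype(mask.dtype)

    gamma = rng.uniform(*cfg.gamma_range)
    if abs(gamma - 1) > 1e-12:
        lo = out.min(axis=(1, 2, 3), keepdims=True)
        hi = out.max(axis=(1, 2, 3), keepdims=True)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        out = ((out - lo) / span) ** gamma * span + lo

    out = np.ascontiguousarray(out)
    if mask is None:
        return out
    return out, np.ascontiguousarray(m)


def _identity_augment(volume, *_args, **_kw):
    return volume


# ---------------------------------------------------------------------------
# Shared loop helpers
# ---------------------------------------------------------------------------

def _risk_from_output(out) -> np.ndarray:
    return -median_time(out.params)


def _eval_c_index(model, volumes, prompts, times, events, batch_size=64,
                  image_present=None) -> float:
    risks = []
    for start in range(0, len(times), batch_size):
        sl = slice(start, start + batch_size)
        vb = None if volumes is None else volumes[sl]
        kw = {}
        if image_present is not None:
            kw["image_present"] = image_present[sl]
        out = model.forward(vb, list(prompts[sl]) if prompts is not None else None,
                            **kw)
        risks.append(_risk_from_output(out))
    return c_index(np.concatenate(risks), times, events)


def _train_loop(model, optimizer, forward_batch, val_score, config: TrainConfig,
                n_subjects: int):
    """Generic loop with validation-score early stopping.  Returns
    (best_state, history) where history rows are
    (epoch, train_nll, val_c_index)."""
    rng = np.random.default_rng(config.seed)
    history = []
    best = (-np.inf, None, -1)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_subjects)
        losses = []
        for start in range(0, n_subjects, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = forward_batch(idx, epoch)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch indices {idx[:8]}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_c = val_score()
        history.append((epoch, float(np.mean(losses)), val_c))
        if val_c > best[0]:
            best = (val_c, {k: v.copy() for k, v in model.state_dict().items()},
                    epoch)
        elif epoch - best[2] >= config.patience:
            log.info("early stop at epoch %d (best %d)", epoch, best[2])
            break
    model.load_state_dict(best[1])
    return best, history


# ---------------------------------------------------------------------------
# Stage 1: imaging-encoder pretraining
# ---------------------------------------------------------------------------

def pretrain_image_encoder(
    dev_volumes: np.ndarray,
    dev_times,
    dev_events,
    fusion_config: FusionConfig,
    config: TrainConfig,
    dev_ids=None,
    holdout_ids=None,
    val_fraction: float = 0.2,
    objective: str = "survival_nll",
):
    """Train an imaging-only patch transformer (throwaway AFT head) on the
    development cohort; returns (encoder state dict, history, model).

    ``holdout_ids`` (validation/external subjects) must be disjoint from
    ``dev_ids`` — any overlap aborts.
    """
    if dev_ids is not None and holdout_ids is not None:
        audit_no_leakage(dev_ids, holdout_ids)
    if objective not in ("survival_nll", "reconstruction"):
        raise ValueError(f"unknown pretraining objective {objective!r}")

    dev_volumes = np.asarray(dev_volumes, dtype=np.float64)
    dev_times = np.asarray(dev_times, float)
    dev_events = np.asarray(dev_events, int)
    n = len(dev_volumes)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(2, int(round(val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    model = ViTSurvival(fusion_config)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)

    def forward_batch(idx, epoch):
        batch_idx = tr_idx[idx]
        vols = dev_volumes[batch_idx]
        if config.augment:
            vols = np.stack([
                augment(v, config.seed, int(epoch * n + i), config)
                for i, v in zip(batch_idx, vols)
            ])
        out = model.forward(vols)
        if objective == "survival_nll":
            return nll_loss(out.log_lambda_t, out.log_rho_t,
                            dev_times[batch_idx], dev_events[batch_idx])
        # masked-patch reconstruction is intentionally simple: predict the
        # per-patch mean intensity from the class-token-free features
        target = vols.reshape(len(batch_idx), -1).mean(axis=1)
        pred = out.log_lambda_t
        diff = pred - np.log(np.maximum(target - target.min() + 1.0, 1e-6))
        return (diff * diff).mean()

    def val_score():
        out = model.forward(dev_volumes[val_idx])
        return c_index(_risk_from_output(out), dev_times[val_idx],
                       dev_events[val_idx])

    (best_c, _, _), history = _train_loop(
        model, optimizer, forward_batch, val_score, config, len(tr_idx)
    )
    encoder_state = {}
    model.encoder._collect_state("", encoder_state)
    return encoder_state, history, model


# ---------------------------------------------------------------------------
# Stage 2: frozen-encoder fusion training
# ---------------------------------------------------------------------------

def train_fusion(
    dev_records,
    dev_volumes,
    dev_prompts,
    val_records,
    val_volumes,
    val_prompts,
    fusion_config: FusionConfig,
    config: TrainConfig,
    encoder_state: dict | None = None,
    use_image: bool = True,
    image_present_dev: np.ndarray | None = None,
    image_present_val: np.ndarray | None = None,
):
    """Optimize adaptors + queries + fusion layers + AFT head by censored
    NLL with frozen encoders; early stopping on validation C-index.

    Returns (model, history dicts).
    """
    audit_no_leakage([r.subject_id for r in dev_records],
                     [r.subject_id for r in val_records])
    model = SurvivalTransformer(fusion_config, use_image=use_image)
    frozen_before = None
    if use_image and encoder_state is not None:
        model.encoder.load_state_dict(encoder_state)
        for p in model.encoder.parameters():
            p.requires_grad = False
        frozen_before = model.encoder.state_dict()

    trainable = [p for p in model.parameters() if p.requires_grad]
    optimizer = Adam(trainable, lr=config.learning_rate)

    dev_times = np.array([r.os_months for r in dev_records])
    dev_events = np.array([r.event for r in dev_records])
    val_times = np.array([r.os_months for r in val_records])
    val_events = np.array([r.event for r in val_records])
    dev_prompts = np.asarray(dev_prompts, dtype=object)
    val_prompts = np.asarray(val_prompts, dtype=object)
    dev_volumes = None if dev_volumes is None else np.asarray(dev_volumes, float)
    val_volumes = None if val_volumes is None else np.asarray(val_volumes, float)
    n = len(dev_records)

    # the encoder is frozen: without augmentation its per-subject features
    # are constant across epochs, so compute them once
    cache_features = (use_image and not config.augment
                      and encoder_state is not None and dev_volumes is not None)
    dev_feats = val_feats = None
    if cache_features:
        dev_feats = model.image_features(dev_volumes)
        if val_volumes is not None:
            val_feats = model.image_features(val_volumes)

    def forward_batch(idx, epoch):
        ipd = None if image_present_dev is None else image_present_dev[idx]
        if dev_feats is not None:
            out = model.forward(None, list(dev_prompts[idx]), image_present=ipd,
                                image_features=dev_feats[idx])
        else:
            vols = None if dev_volumes is None else dev_volumes[idx]
            if vols is not None and config.augment:
                vols = np.stack([
                    augment(v, config.seed + 1, int(epoch * n + i), config)
                    for i, v in zip(idx, vols)
                ])
            out = model.forward(vols, list(dev_prompts[idx]), image_present=ipd)
        return nll_loss(out.log_lambda_t, out.log_rho_t,
                        dev_times[idx], dev_events[idx])

    def val_score():
        risks = []
        for start in range(0, len(val_times), 128):
            sl = slice(start, start + 128)
            kw = {}
            if image_present_val is not None:
                kw["image_present"] = image_present_val[sl]
            if val_feats is not None:
                out = model.forward(None, list(val_prompts[sl]),
                                    image_features=val_feats[sl], **kw)
            else:
                vb = None if val_volumes is None else val_volumes[sl]
                out = model.forward(vb, list(val_prompts[sl]), **kw)
            risks.append(_risk_from_output(out))
        return c_index(np.concatenate(risks), val_times, val_events)

    (best_c, _, best_epoch), history = _train_loop(
        model, optimizer, forward_batch, val_score, config, n
    )

    if frozen_before is not None:
        after = model.encoder.state_dict()
        for k in frozen_before:
            if not np.array_equal(frozen_before[k], after[k]):
                raise AssertionError(f"frozen encoder weight drifted: {k}")

    hist = [
        {"epoch": e, "train_nll": l, "val_c_index": c} for e, l, c in history
    ]
    return model, {"history": hist, "best_epoch": best_epoch,
                   "best_val_c_index": best_c}


def write_run_dir(out_dir, fusion_config, train_config, history, seed) -> None:
    """Persist config snapshot, epoch log (CSV), and seeds for a run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps({
        "fusion_config": asdict(fusion_config),
        "train_config": asdict(train_config),
        "seed": seed,
    }, indent=2))
    import pandas as pd

    pd.DataFrame(history["history"]).to_csv(out / "epochs.csv", index=False)
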