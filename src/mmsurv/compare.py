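"""Head-to-head comparison: fusion model vs {cnn, vit, nimt} architectures
and vs {mode, mice} imputation, on one cohort with a shared dev/val split.

Emits a metric matrix (C-index, IAUC, IBS) with percentile-bootstrap CIs and
paired-bootstrap p-values against the fusion model.
"""
from __future__ import annotations

import numpy as np

from .impute import mice_impute, mode_impute
from .metrics import bootstrap_ci, bootstrap_compare, c_index, iauc, ibs
from .nn.layers import Adam
from .nn.model import FusionConfig, build_baseline, nll_loss
from .tabular import discretize, to_prompts
from .training import TrainConfig, _train_loop, pretrain_image_encoder, train_fusion
from .weibull import WeibullParams, median_time, survival


def _predictions(model, volumes, prompts, grid):
    risks, surv = [], []
    n = len(prompts) if prompts is not None else len(volumes)
    for start in range(0, n, 64):
        sl = slice(start, start + 64)
        vols = None if volumes is None else volumes[sl]
        pr = list(prompts[sl]) if prompts is not None else None
        out = model.forward(vols, pr)
        risks.append(-median_time(out.params))
        p = out.params
        surv.append(np.stack(
            [survival(WeibullParams(p.log_lambda[i], p.log_rho[i]), grid)
             for i in range(len(p.log_lambda))]
        ))
    return np.concatenate(risks), np.concatenate(surv, axis=0)


def _train_image_only(kind, volumes, times, events, fusion_config, config):
    model = build_baseline(kind, fusion_config)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    n = len(volumes)
    rng = np.random.default_rng(config.seed + 7)
    n_val = max(2, n // 5)
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    def forward_batch(idx, epoch):
        bi = tr_idx[idx]
        out = model.forward(volumes[bi])
        return nll_loss(out.log_lambda_t, out.log_rho_t, times[bi], events[bi])

    def val_score():
        out = model.forward(volumes[val_idx])
        return c_index(-median_time(out.params), times[val_idx], events[val_idx])

    _train_loop(model, optimizer, forward_batch, val_score, config, len(tr_idx))
    return model


def _metric_block(risk, surv, times, events, grid, n_boot, seed):
    return {
        "c_index": bootstrap_ci(c_index, (risk, times, events),
                                n_boot=n_boot, seed=seed).to_dict(),
        "iauc": bootstrap_ci(lambda s, t, e: iauc(s, t, e, grid),
                             (surv, times, events),
                             n_boot=n_boot, seed=seed, name="iauc").to_dict(),
        "ibs": bootstrap_ci(lambda s, t, e: ibs(s, t, e, grid),
                            (surv, times, events),
                            n_boot=n_boot, seed=seed, name="ibs").to_dict(),
    }


def run_comparison(records, prompts, volumes, epochs: int = 40,
                   n_boot: int = 199, seed: int = 0,
                   val_fraction: float = 0.25,
                   include: tuple = ("cnn", "vit", "nimt", "mode", "mice")):
    rng = np.random.default_rng(seed)
    n = len(records)
    perm = rng.permutation(n)
    n_val = max(4, int(round(val_fraction * n)))
    val_idx, dev_idx = perm[:n_val], perm[n_val:]
    prompts = np.asarray(prompts, dtype=object)
    volumes = None if volumes is None else np.asarray(volumes, float)

    dev = [records[i] for i in dev_idx]
    val = [records[i] for i in val_idx]
    dev_p, val_p = prompts[dev_idx], prompts[val_idx]
    dev_v = None if volumes is None else volumes[dev_idx]
    val_v = None if volumes is None else volumes[val_idx]
    dev_t = np.array([r.os_months for r in dev])
    dev_e = np.array([r.event for r in dev])
    val_t = np.array([r.os_months for r in val])
    val_e = np.array([r.event for r in val])

    # keep only horizons with at least one evaluable case and one control
    grid = np.arange(6.0, 37.0)
    grid = grid[[((val_t <= t) & (val_e == 1)).sum() >= 3
                 and (val_t > t).sum() >= 3 for t in grid]]
    if len(grid) < 2:
        raise ValueError("validation follow-up too short for a time grid")

    shape = volumes.shape[2:] if volumes is not None else (24, 24, 8)
    fc = FusionConfig(volume_shape=shape, seed=seed)
    tc = TrainConfig(max_epochs=epochs, patience=max(1, epochs - 1),
                     learning_rate=3e-3, seed=seed)

    enc_state = None
    if volumes is not None:
        enc_state, _, _ = pretrain_image_encoder(
            dev_v, dev_t, dev_e, fc,
            TrainConfig(max_epochs=max(2, epochs // 2),
                        patience=max(1, epochs // 2 - 1),
                        learning_rate=3e-3, seed=seed),
        )

    table: dict[str, dict] = {}
    risks: dict[str, np.ndarray] = {}
    survs: dict[str, np.ndarray] = {}

    def add(name, model, vols, prm):
        risk, surv = _predictions(model, vols, prm, grid)
        risks[name], survs[name] = risk, surv
        table[name] = _metric_block(risk, surv, val_t, val_e, grid, n_boot, seed)

    fusion, _ = train_fusion(dev, dev_v, dev_p, val, val_v, val_p, fc, tc,
                             encoder_state=enc_state,
                             use_image=volumes is not None)
    add("fusion", fusion, val_v, val_p)

    if volumes is not None and "cnn" in include:
        cnn_tc = TrainConfig(max_epochs=max(2, epochs // 2),
                             patience=max(1, epochs // 2 - 1),
                             learning_rate=3e-3, batch_size=16, seed=seed)
        add("cnn", _train_image_only("cnn", dev_v, dev_t, dev_e, fc, cnn_tc),
            val_v, None)
    if volumes is not None and "vit" in include:
        add("vit", _train_image_only("vit_image_only", dev_v, dev_t, dev_e,
                                     fc, tc), val_v, None)
    if "nimt" in include:
        nimt, _ = train_fusion(dev, None, dev_p, val, None, val_p, fc, tc,
                               use_image=False)
        add("nimt", nimt, None, val_p)

    # imputation comparators: fill the tables, re-serialize prompts (all
    # presence masks true), retrain the same fusion architecture
    for name, imputer in (("mode", mode_impute), ("mice", mice_impute)):
        if name not in include:
            continue
        imp_dev = [discretize(r) for r in imputer(dev)]
        imp_val = [discretize(r) for r in imputer(val)]
        imp_dev_p = np.array([to_prompts(r) for r in imp_dev], dtype=object)
        imp_val_p = np.array([to_prompts(r) for r in imp_val], dtype=object)
        m, _ = train_fusion(imp_dev, dev_v, imp_dev_p, imp_val, val_v,
                            imp_val_p, fc, tc, encoder_state=enc_state,
                            use_image=volumes is not None)
        add(name, m, val_v, imp_val_p)

    comparisons = {}
    for name in table:
        if name == "fusion":
            continue
        comparisons[name] = {
            "c_index_p": bootstrap_compare(
                c_index, (risks["fusion"], val_t, val_e),
                (risks[name], val_t, val_e), paired=True,
                n_boot=n_boot, seed=seed),
            "iauc_p": bootstrap_compare(
                lambda s, t, e: iauc(s, t, e, grid),
                (survs["fusion"], val_t, val_e),
                (survs[name], val_t, val_e), paired=True,
                n_boot=n_boot, seed=seed),
            "ibs_p": bootstrap_compare(
                lambda s, t, e: ibs(s, t, e, grid),
                (survs["fusion"], val_t, val_e),
                (survs[name], val_t, val_e), paired=True,
                n_boot=n_boot, seed=seed),
        }
    return {"metrics": table, "paired_p_vs_fusion": comparisons,
            "grid": grid.tolist(), "n_val": int(n_val)}
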