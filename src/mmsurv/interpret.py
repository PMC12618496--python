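"""Interpretability operators: Eigen-CAM volumes, gradient-based tabular
relevance, exact Shapley attribution, and CAM-vs-mask localization metrics.

All operators are pure functions of (weights, input): no randomness.
Sign convention: positive scores raise the predicted risk (shorter
predicted survival); negative scores are protective.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy import ndimage

from .nn.autodiff import Tensor
from .tabular import PromptSet

__all__ = [
    "RelevanceReport",
    "eigen_cam",
    "eigen_cam_from_features",
    "tabular_relevance",
    "shapley_tabular",
    "localization_metrics",
]


@dataclass
class RelevanceReport:
    variables: list[str]
    gradient_scores: dict[str, float]
    shapley_values: dict[str, float]
    shapley_base_value: float
    cam_volume: np.ndarray | None = None


def _risk_tensor(ll: Tensor, lr: Tensor) -> Tensor:
    """Differentiable scalar risk = -median survival time
    = -exp(log_lambda + exp(-log_rho) * log log 2)."""
    return -(ll + (-lr).exp() * float(np.log(np.log(2.0)))).exp()


# ---------------------------------------------------------------------------
# Eigen-CAM
# ---------------------------------------------------------------------------

def eigen_cam_from_features(features: np.ndarray, grid, out_shape) -> np.ndarray:
    """First principal component of the (tokens x dim) feature matrix,
    reshaped to the patch grid, trilinearly upsampled, sign-aligned, and
    min-max normalized to [0, 1].

    PCA is computed on token-centered features.  The component sign is
    aligned so the skewed tail (the minority of salient tokens) is positive;
    for symmetric score distributions it falls back to positive mean.
    Mean-alignment alone inverts the map whenever the salient region covers
    a minority of tokens.
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 2:
        raise ValueError("expected a (tokens, dim) feature matrix")
    if not np.any(f):
        raise ValueError("degenerate (rank-0) feature maps")
    fc = f - f.mean(axis=0, keepdims=True)
    if not np.any(fc):
        raise ValueError("degenerate (rank-0) feature maps")
    u, s, vt = np.linalg.svd(fc, full_matrices=False)
    cam = fc @ vt[0]  # projection on the first principal direction
    skew = np.mean((cam - cam.mean()) ** 3)
    if abs(skew) > 1e-12:
        if skew < 0:
            cam = -cam
    elif cam.mean() < 0:
        cam = -cam
    cam = cam.reshape(grid)
    factors = tuple(o / g for o, g in zip(out_shape, grid))
    cam = ndimage.zoom(cam, factors, order=1, mode="nearest")
    cam = cam - cam.min()
    peak = cam.max()
    if peak == 0:
        raise ValueError("degenerate (constant) activation map")
    return cam / peak


def eigen_cam(model, volume: np.ndarray) -> np.ndarray:
    """Eigen-CAM on the model's image-encoder features for one volume."""
    if not hasattr(model, "encoder"):
        raise ValueError("model exposes no image encoder")
    vol = np.asarray(volume, dtype=np.float64)[None]
    feats = model.encoder(vol).data[0]
    grid = model.encoder.embed.grid
    return eigen_cam_from_features(feats, grid, vol.shape[2:])


# ---------------------------------------------------------------------------
# Gradient x input tabular relevance
# ---------------------------------------------------------------------------

def _token_variables(prompt_set: PromptSet) -> list[str]:
    """Variable names in fusion token order (clinical block, then treatment)."""
    clin = [v for v, _, m in prompt_set.entries if m == "clinical_genetic"]
    trt = [v for v, _, m in prompt_set.entries if m == "treatment"]
    return clin + trt


def tabular_relevance(model, volume, prompt_set: PromptSet) -> dict[str, float]:
    """Gradient of the scalar risk wrt each variable's token embedding,
    contracted with the embedding (gradient x input).  Missing variables
    score exactly 0."""
    obs = [v for v, p, _ in prompt_set.entries if p is not None]
    if not obs and volume is None:
        raise ValueError("record has no observed variable")
    vols = None if volume is None else np.asarray(volume, np.float64)[None]
    out = model.forward(vols, [prompt_set], tabular_grad=True)
    risk = _risk_tensor(out.log_lambda_t, out.log_rho_t).sum()
    risk.backward()
    grad = out.tabular_tokens.grad
    emb = out.tabular_tokens.data
    scores = (grad * emb).sum(axis=-1)[0] if grad is not None else np.zeros(
        emb.shape[1]
    )
    return dict(zip(_token_variables(prompt_set), scores.tolist()))


# ---------------------------------------------------------------------------
# Exact Shapley attribution
# ---------------------------------------------------------------------------

def shapley_tabular(model, volume, prompt_set: PromptSet,
                    max_exact: int = 16):
    """Exact Shapley values of the scalar risk over observed tabular
    variables, where "absent" means presence_mask=False (the model's native
    missingness).  Returns (values dict, base value).

    Enumerates all 2^k coalitions in one batched forward; requires an
    observed image so the empty coalition is well-posed.
    """
    token_vars = _token_variables(prompt_set)
    by_var = {v: i for i, v in enumerate(token_vars)}
    prompts_by_var = {v: p for v, p, _ in prompt_set.entries}
    players = [v for v in token_vars if prompts_by_var[v] is not None]
    k = len(players)
    if k > max_exact:
        raise ValueError(
            f"{k} observed variables exceed the exact enumeration bound "
            f"({max_exact}); use a sampling estimator"
        )
    if volume is None:
        raise ValueError(
            "exact Shapley needs an observed image for the empty coalition"
        )
    n_tok = len(token_vars)
    n_coal = 1 << k
    masks = np.zeros((n_coal, n_tok), dtype=bool)
    for s in range(n_coal):
        for j, v in enumerate(players):
            if s >> j & 1:
                masks[s, by_var[v]] = True

    vol = np.asarray(volume, np.float64)[None]
    feats = model.image_features(vol) if hasattr(model, "image_features") else None
    values = np.empty(n_coal)
    batch = 256
    for start in range(0, n_coal, batch):
        sl = slice(start, min(start + batch, n_coal))
        b = sl.stop - sl.start
        if feats is not None:
            out = model.forward(
                None, [prompt_set] * b, tabular_mask_override=masks[sl],
                image_features=np.repeat(feats, b, axis=0),
            )
        else:
            out = model.forward(np.repeat(vol, b, axis=0), [prompt_set] * b,
                                tabular_mask_override=masks[sl])
        values[sl] = -np.asarray(
            np.exp(out.params.log_lambda)
            * np.log(2.0) ** np.exp(-out.params.log_rho)
        )

    weights = [factorial(s) * factorial(k - s - 1) / factorial(k)
               for s in range(k)]
    phi = np.zeros(k)
    for s in range(n_coal):
        size = bin(s).count("1")
        for j in range(k):
            if s >> j & 1:
                continue
            phi[j] += weights[size] * (values[s | (1 << j)] - values[s])
    base = float(values[0])
    return dict(zip(players, phi.tolist())), base


# ---------------------------------------------------------------------------
# Localization metrics
# ---------------------------------------------------------------------------

def localization_metrics(cam_volume: np.ndarray, tumor_mask: np.ndarray,
                         threshold: float = 0.5):
    """Pixel-level AUC of the CAM against the binary mask, sensitivity at
    the given CAM threshold, and a hit flag (CAM argmax inside the 1-voxel
    dilated mask)."""
    cam = np.asarray(cam_volume, float).ravel()
    mask = np.asarray(tumor_mask).astype(bool)
    if cam.size != mask.size:
        raise ValueError("CAM and mask must share the grid")
    if not mask.any():
        raise ValueError("empty tumor mask")
    y = mask.ravel()
    # rank-based AUC (Mann-Whitney)
    order = np.argsort(cam, kind="stable")
    ranks = np.empty_like(cam)
    ranks[order] = np.arange(1, cam.size + 1)
    # midranks for ties
    uniq, inv, counts = np.unique(cam, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    mid = cum - (counts - 1) / 2.0
    ranks = mid[inv]
    n_pos = y.sum()
    n_neg = y.size - n_pos
    if n_neg == 0:
        raise ValueError("mask covers the entire grid")
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    sensitivity = float(np.mean(cam[y] >= threshold))
    dilated = ndimage.binary_dilation(mask, iterations=1)
    argmax = np.unravel_index(int(np.argmax(cam_volume)), mask.shape)
    hit_flag = bool(dilated[argmax])
    return float(auc), sensitivity, hit_flag


def full_report(model, volume, prompt_set: PromptSet,
                tumor_mask: np.ndarray | None = None) -> RelevanceReport:
    grad_scores = tabular_relevance(model, volume, prompt_set)
    shap, base = shapley_tabular(model, volume, prompt_set)
    cam = None
    if volume is not None and hasattr(model, "encoder"):
        cam = eigen_cam(model, volume)
    return RelevanceReport(
        variables=_token_variables(prompt_set),
        gradient_scores=grad_scores,
        shapley_values=shap,
        shapley_base_value=base,
        cam_volume=cam,
    )
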