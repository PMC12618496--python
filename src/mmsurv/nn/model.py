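"""The multimodal survival architecture and its comparators.

Three streams (image patches, clinical/genetic prompts, treatment prompts)
are encoded, passed through two-layer modality adaptors, and fused by two
learnable survival-query tokens via masked cross-attention; the queries are
decoded into per-subject Weibull (log lambda, log rho).  Missing variables
and absent modalities are represented by presence masks — masked keys get
-inf attention logits, so outputs are bitwise independent of placeholder
values.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..tabular import PromptSet, template_table_hash
from ..weibull import LOG_LAMBDA_RANGE, LOG_RHO_RANGE, WeibullParams
from .autodiff import Tensor, concat
from .conv import Conv3d
from .layers import (
    Adaptor,
    CrossAttentionLayer,
    Linear,
    Module,
    TransformerEncoderLayer,
    softclip,
)

__all__ = [
    "FusionConfig",
    "ModalityTokens",
    "ModelOutput",
    "SurvivalTransformer",
    "PatchEmbed",
    "AFTHead",
    "encode_text",
    "build_baseline",
    "nll_loss",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

MODALITIES = ("image", "clinical_genetic", "treatment")


@dataclass(frozen=True)
class FusionConfig:
    embed_dim: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    n_fusion_layers: int = 2
    patch_size: tuple[int, int, int] = (8, 8, 4)
    volume_shape: tuple[int, int, int] = (24, 24, 8)
    n_channels: int = 4
    adaptor_hidden: int = 128
    text_backend: str = "hashed_stub"
    log_lambda_range: tuple[float, float] = LOG_LAMBDA_RANGE
    log_rho_range: tuple[float, float] = LOG_RHO_RANGE
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        for ax, (s, p) in enumerate(zip(self.volume_shape, self.patch_size)):
            if s % p:
                raise ValueError(
                    f"volume axis {ax} (size {s}) not divisible by patch size {p}"
                )
        if self.text_backend not in ("pretrained_lm", "hashed_stub"):
            raise ValueError(f"unknown text backend {self.text_backend!r}")


@dataclass
class ModalityTokens:
    """An embedding sequence plus a per-token presence mask."""

    embeddings: np.ndarray        # (B, T, d)
    presence_mask: np.ndarray     # (B, T) bool, True = observed
    modality: str

    def __post_init__(self):
        if self.embeddings.shape[:2] != self.presence_mask.shape:
            raise ValueError("mask shape must match token sequence")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class ModelOutput:
    params: WeibullParams
    log_lambda_t: Tensor
    log_rho_t: Tensor
    attention_records: list[np.ndarray]      # per fusion layer: (B, h, 2, T)
    encoder_features: np.ndarray | None      # (B, T_img, d) for CAM
    token_ranges: dict[str, tuple[int, int]]
    tabular_tokens: Tensor | None = None     # leaf tensor (for relevance)


# ---------------------------------------------------------------------------
# Text encoding
# ---------------------------------------------------------------------------

_STUB_CACHE: dict[tuple[str, int, int], np.ndarray] = {}


def _stub_vector(prompt: str, dim: int, seed: int) -> np.ndarray:
    key = (prompt, dim, seed)
    cached = _STUB_CACHE.get(key)
    if cached is None:
        digest = hashlib.sha256(f"{seed}:{prompt}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        v = rng.normal(size=dim)
        cached = _STUB_CACHE[key] = v / np.linalg.norm(v)
    return cached


def encode_text(
    prompt_sets: list[PromptSet],
    backend: str = "hashed_stub",
    dim: int = 64,
    seed: int = 0,
    modality: str | None = None,
) -> ModalityTokens:
    """One pooled token per variable; MISSING variables yield a zero vector
    with presence_mask False.

    ``hashed_stub`` maps each distinct prompt to a fixed pseudo-random unit
    vector; ``pretrained_lm`` requires an installed sentence-transformer
    stack and is optional.
    """
    if backend == "pretrained_lm":
        try:
            from sentence_transformers import SentenceTransformer  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "text_backend='pretrained_lm' requires the sentence-transformers "
                "package; use 'hashed_stub' for a dependency-free encoder"
            ) from exc
        raise RuntimeError("pretrained_lm backend not configured in this build")
    if backend != "hashed_stub":
        raise ValueError(f"unknown text backend {backend!r}")

    if modality is not None:
        prompt_sets = [
            PromptSet(tuple(e for e in ps.entries if e[2] == modality))
            for ps in prompt_sets
        ]
    n_var = len(prompt_sets[0].entries)
    B = len(prompt_sets)
    emb = np.zeros((B, n_var, dim))
    mask = np.zeros((B, n_var), dtype=bool)
    for b, ps in enumerate(prompt_sets):
        if len(ps.entries) != n_var:
            raise ValueError("prompt sets must share the variable list")
        for t, (_, prompt, _) in enumerate(ps.entries):
            if prompt is None:
                continue
            emb[b, t] = _stub_vector(prompt, dim, seed)
            mask[b, t] = True
    tag = modality if modality is not None else "clinical_genetic"
    return ModalityTokens(emb, mask, tag)


# ---------------------------------------------------------------------------
# Image stream
# ---------------------------------------------------------------------------

class PatchEmbed(Module):
    """Non-overlapping 3D patches -> learned linear projection + learned
    positional encoding."""

    def __init__(self, rng, config: FusionConfig):
        shape, patch = config.volume_shape, config.patch_size
        self.grid = tuple(s // p for s, p in zip(shape, patch))
        self.n_tokens = int(np.prod(self.grid))
        in_dim = config.n_channels * int(np.prod(patch))
        self.proj = Linear(rng, in_dim, config.embed_dim)
        self.pos = Tensor(
            rng.normal(0, 0.02, size=(self.n_tokens, config.embed_dim)),
            requires_grad=True,
        )
        self.patch = patch
        self.n_channels = config.n_channels

    def __call__(self, volumes: np.ndarray) -> Tensor:
        B, C, X, Y, Z = volumes.shape
        px, py, pz = self.patch
        gx, gy, gz = X // px, Y // py, Z // pz
        if (gx, gy, gz) != self.grid:
            raise ValueError(
                f"volume shape {(X, Y, Z)} incompatible with configured grid"
            )
        v = volumes.reshape(B, C, gx, px, gy, py, gz, pz)
        v = v.transpose(0, 2, 4, 6, 1, 3, 5, 7).reshape(B, self.n_tokens, -1)
        return self.proj(Tensor(v)) + self.pos


class ImageEncoder(Module):
    def __init__(self, rng, config: FusionConfig):
        self.embed = PatchEmbed(rng, config)
        self.layers = [
            TransformerEncoderLayer(rng, config.embed_dim, config.n_heads,
                                    2 * config.embed_dim)
            for _ in range(config.n_encoder_layers)
        ]

    def __call__(self, volumes: np.ndarray) -> Tensor:
        x = self.embed(volumes)
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# AFT head
# ---------------------------------------------------------------------------

class AFTHead(Module):
    """Linear maps query 1 -> log lambda, query 2 -> log rho, smoothly
    clamped to the configured ranges.  Zero-initialized with bias
    (log 24, 0): at init every subject gets lambda = 24 months, rho = 1."""

    def __init__(self, rng, dim: int, config: FusionConfig):
        self.head_lambda = Linear(rng, dim, 1, zero_init=True)
        self.head_rho = Linear(rng, dim, 1, zero_init=True)
        self.head_lambda.bias.data[:] = np.log(24.0)
        self.head_rho.bias.data[:] = 0.0
        self.ll_range = config.log_lambda_range
        self.lr_range = config.log_rho_range

    def __call__(self, q_lambda: Tensor, q_rho: Tensor):
        ll = softclip(self.head_lambda(q_lambda).reshape(-1), *self.ll_range)
        lr = softclip(self.head_rho(q_rho).reshape(-1), *self.lr_range)
        return ll, lr


# ---------------------------------------------------------------------------
# The fusion model
# ---------------------------------------------------------------------------

class SurvivalTransformer(Module):
    """Masked cross-attention fusion of image/clinical/treatment streams
    into two survival-query tokens decoded by the AFT head.

    With ``use_image=False`` this is the non-imaging ablation (NIMT): the
    forward pass never reads the supplied volumes.
    """

    def __init__(self, config: FusionConfig, use_image: bool = True):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.use_image = use_image
        d = config.embed_dim
        if use_image:
            self.encoder = ImageEncoder(rng, config)
            self.vision_adaptor = Adaptor(rng, d, config.adaptor_hidden)
        self.clinical_adaptor = Adaptor(rng, d, config.adaptor_hidden)
        self.treatment_adaptor = Adaptor(rng, d, config.adaptor_hidden)
        self.queries = Tensor(rng.normal(0, 0.5, size=(2, d)), requires_grad=True)
        self.fusion_layers = [
            CrossAttentionLayer(rng, d, config.n_heads, 2 * d)
            for _ in range(config.n_fusion_layers)
        ]
        self.aft_head = AFTHead(rng, d, config)

    # -- encoders ------------------------------------------------------------
    def encode_image(self, volumes: np.ndarray | None, batch_size: int,
                     image_features: np.ndarray | None = None):
        d = self.config.embed_dim
        if not self.use_image:
            return None, None, None
        n_tok = self.encoder.embed.n_tokens
        if image_features is not None:
            feats = Tensor(np.asarray(image_features, dtype=np.float64))
            mask = np.ones((batch_size, n_tok), dtype=bool)
            return feats, mask, feats.data.copy()
        if volumes is None:
            emb = Tensor(np.zeros((batch_size, n_tok, d)))
            mask = np.zeros((batch_size, n_tok), dtype=bool)
            return emb, mask, None
        feats = self.encoder(np.asarray(volumes, dtype=np.float64))
        mask = np.ones((batch_size, n_tok), dtype=bool)
        return feats, mask, feats.data.copy()

    def image_features(self, volumes: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Run only the (typically frozen) image encoder, returning detached
        per-patch features for reuse across training steps."""
        chunks = []
        for start in range(0, len(volumes), batch_size):
            chunks.append(
                self.encoder(np.asarray(volumes[start:start + batch_size],
                                        dtype=np.float64)).data
            )
        return np.concatenate(chunks, axis=0)

    def encode_tabular(self, prompt_sets: list[PromptSet], modality: str):
        return encode_text(
            prompt_sets,
            backend=self.config.text_backend,
            dim=self.config.embed_dim,
            seed=self.config.seed,
            modality=modality,
        )

    # -- forward -------------------------------------------------------------
    def forward(
        self,
        volumes: np.ndarray | None,
        prompt_sets: list[PromptSet],
        tabular_mask_override: np.ndarray | None = None,
        tabular_grad: bool = False,
        image_present: np.ndarray | None = None,
        image_features: np.ndarray | None = None,
    ) -> ModelOutput:
        B = len(prompt_sets)
        img_feats, img_mask, enc_feats = self.encode_image(volumes, B,
                                                           image_features)
        if img_mask is not None and image_present is not None:
            img_mask = img_mask & np.asarray(image_present, bool)[:, None]

        clin = self.encode_tabular(prompt_sets, "clinical_genetic")
        trt = self.encode_tabular(prompt_sets, "treatment")
        tab_emb = np.concatenate([clin.embeddings, trt.embeddings], axis=1)
        tab_mask = np.concatenate([clin.presence_mask, trt.presence_mask], axis=1)
        if tabular_mask_override is not None:
            tab_mask = tab_mask & np.asarray(tabular_mask_override, bool)
        n_clin = clin.embeddings.shape[1]

        tab_tokens = Tensor(tab_emb, requires_grad=tabular_grad)
        clin_tok = tab_tokens[:, :n_clin, :]
        trt_tok = tab_tokens[:, n_clin:, :]

        banks, masks, ranges = [], [], {}
        pos = 0
        if self.use_image:
            adapted = self.vision_adaptor(img_feats)
            banks.append(adapted)
            masks.append(img_mask)
            ranges["image"] = (pos, pos + img_mask.shape[1])
            pos += img_mask.shape[1]
        banks.append(self.clinical_adaptor(clin_tok))
        masks.append(tab_mask[:, :n_clin])
        ranges["clinical_genetic"] = (pos, pos + n_clin)
        pos += n_clin
        banks.append(self.treatment_adaptor(trt_tok))
        masks.append(tab_mask[:, n_clin:])
        ranges["treatment"] = (pos, pos + tab_mask.shape[1] - n_clin)

        tokens = concat(banks, axis=1)
        key_mask = np.concatenate(masks, axis=1)
        if not key_mask.any(axis=1).all():
            raise ValueError("no observed modality for at least one subject")

        q = self.queries.reshape(1, 2, self.config.embed_dim) * Tensor(
            np.ones((B, 1, 1))
        )
        attn_records = []
        for layer in self.fusion_layers:
            q, w = layer(q, tokens, key_mask)
            attn_records.append(w)

        ll, lr = self.aft_head(q[:, 0, :], q[:, 1, :])
        params = WeibullParams(ll.data.copy(), lr.data.copy())
        return ModelOutput(
            params=params,
            log_lambda_t=ll,
            log_rho_t=lr,
            attention_records=attn_records,
            encoder_features=enc_feats,
            token_ranges=ranges,
            tabular_tokens=tab_tokens if tabular_grad else None,
        )

    __call__ = forward


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

class ViTSurvival(Module):
    """Image-only patch transformer with a class token feeding the AFT head."""

    def __init__(self, config: FusionConfig):
        rng = np.random.default_rng(config.seed + 1)
        self.config = config
        self.encoder = ImageEncoder(rng, config)
        self.cls = Tensor(rng.normal(0, 0.5, size=(1, 1, config.embed_dim)),
                          requires_grad=True)
        self.cls_layers = [
            TransformerEncoderLayer(rng, config.embed_dim, config.n_heads,
                                    2 * config.embed_dim)
        ]
        self.aft_head = AFTHead(rng, config.embed_dim, config)

    def forward(self, volumes: np.ndarray, prompt_sets=None, **_) -> ModelOutput:
        volumes = np.asarray(volumes, dtype=np.float64)
        B = volumes.shape[0]
        feats = self.encoder(volumes)
        cls = self.cls * Tensor(np.ones((B, 1, 1)))
        x = concat([cls, feats], axis=1)
        for layer in self.cls_layers:
            x = layer(x)
        pooled = x[:, 0, :]
        ll, lr = self.aft_head(pooled, pooled)
        return ModelOutput(
            params=WeibullParams(ll.data.copy(), lr.data.copy()),
            log_lambda_t=ll,
            log_rho_t=lr,
            attention_records=[],
            encoder_features=feats.data.copy(),
            token_ranges={"image": (1, 1 + feats.shape[1])},
        )

    __call__ = forward


class CNNSurvival(Module):
    """Small grouped-convolution residual 3D network (ResNeXt-flavoured)
    with global average pooling into the shared AFT head."""

    def __init__(self, config: FusionConfig, width: int = 16, groups: int = 4):
        rng = np.random.default_rng(config.seed + 2)
        self.config = config
        self.stem = Conv3d(rng, config.n_channels, width, kernel=3, stride=2)
        self.block1a = Conv3d(rng, width, width, kernel=3, stride=1, groups=groups)
        self.block1b = Conv3d(rng, width, width, kernel=3, stride=1, groups=groups)
        self.down = Conv3d(rng, width, 2 * width, kernel=3, stride=2)
        self.block2a = Conv3d(rng, 2 * width, 2 * width, kernel=3, stride=1,
                              groups=groups)
        self.block2b = Conv3d(rng, 2 * width, 2 * width, kernel=3, stride=1,
                              groups=groups)
        self.proj = Linear(rng, 2 * width, config.embed_dim)
        self.aft_head = AFTHead(rng, config.embed_dim, config)

    def forward(self, volumes: np.ndarray, prompt_sets=None, **_) -> ModelOutput:
        x = Tensor(np.asarray(volumes, dtype=np.float64))
        x = self.stem(x).relu()
        x = x + self.block1b(self.block1a(x).relu())
        x = self.down(x.relu()).relu()
        x = x + self.block2b(self.block2a(x).relu())
        B = x.shape[0]
        pooled = x.reshape(B, x.shape[1], -1).mean(axis=2)
        feat = self.proj(pooled).relu()
        ll, lr = self.aft_head(feat, feat)
        return ModelOutput(
            params=WeibullParams(ll.data.copy(), lr.data.copy()),
            log_lambda_t=ll,
            log_rho_t=lr,
            attention_records=[],
            encoder_features=None,
            token_ranges={},
        )

    __call__ = forward


def build_baseline(kind: str, config: FusionConfig) -> Module:
    """kind in {cnn, vit_image_only, nimt}; all share the AFT contract."""
    if kind == "cnn":
        return CNNSurvival(config)
    if kind == "vit_image_only":
        return ViTSurvival(config)
    if kind == "nimt":
        return SurvivalTransformer(config, use_image=False)
    raise ValueError(f"unknown baseline kind {kind!r}")


# ---------------------------------------------------------------------------
# Loss, parameter counting, checkpoints
# ---------------------------------------------------------------------------

def nll_loss(log_lambda: Tensor, log_rho: Tensor, times, events) -> Tensor:
    """Mean censored Weibull NLL as a differentiable graph node."""
    times = np.asarray(times, dtype=float)
    ev = np.asarray(events, dtype=float)
    logt = Tensor(np.log(times))
    rho = log_rho.exp()
    u = logt - log_lambda
    z = (rho * u).exp()
    log_f = log_rho - log_lambda + (rho - 1.0) * u - z
    terms = Tensor(ev) * (-log_f) + Tensor(1.0 - ev) * z
    return terms.mean()


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: Module, path, extra: dict | None = None) -> None:
    meta = {
        "config": asdict(model.config),
        "template_hash": template_table_hash(),
        "class": type(model).__name__,
        "use_image": getattr(model, "use_image", True),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint; refuses to load if the prompt
    template table has changed since the model was trained."""
    archive = np.load(path)
    meta = json.loads(bytes(archive["__meta__"]).decode())
    if meta["template_hash"] != template_table_hash():
        raise RuntimeError(
            "checkpoint was trained under a different prompt template table"
        )
    cfg_dict = meta["config"]
    for key in ("patch_size", "volume_shape", "log_lambda_range", "log_rho_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = FusionConfig(**cfg_dict)
    cls = meta["class"]
    if cls == "SurvivalTransformer":
        model = SurvivalTransformer(config, use_image=meta["use_image"])
    elif cls == "ViTSurvival":
        model = ViTSurvival(config)
    elif cls == "CNNSurvival":
        model = CNNSurvival(config)
    else:
        raise ValueError(f"unknown checkpoint class {cls!r}")
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    return model, meta.get("extra", {})
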