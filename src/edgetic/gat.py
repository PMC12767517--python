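"""Graph-attention model for interaction-perturbation prediction.

Architecture: node features (per-residue embeddings plus two structural
channels) pass through two multi-head graph-attention layers with self-loops;
the post-attention representation of the mutation-site node is concatenated
with a feed-forward encoding of the mutation difference vector, and a small
head maps the concatenation to a single interaction-loss probability through
a logistic output. The two structural channels — a chain-role bit and the
normalized contact degree — make interface membership and burial visible to
the attention layers, which are otherwise degree-blind under softmax
normalization.

Training is two-stage: the model is first pretrained on monomeric stability
labels (preserving vs disrupting, from |ΔΔG| thresholds) and then fine-tuned
end to end on labeled variant-partner triplets, both with class-weighted
binary cross-entropy. Everything is implemented in numpy with hand-derived
gradients (verified against finite differences in the test suite) and Adam;
runs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .errors import (
    CompatibilityError,
    ConfigError,
    DataError,
    DegenerateClassError,
    RoleError,
)
from .features import Normalizer
from .structure import INTERACTOR, ContactGraph

_CHECKPOINT_MAGIC = b"EDGT"
_CHECKPOINT_VERSION = 1

STAGE_INITIALIZED = "initialized"
STAGE_PRETRAINED = "pretrained"
STAGE_FINETUNED = "finetuned"


@dataclass
class ModelConfig:
    embed_dim: int = 32          # D of the per-residue embeddings
    hidden_dim: int = 64         # total width of each GAT layer (heads concatenated)
    n_layers: int = 2
    heads: int = 4
    dropout: float = 0.2
    leaky_slope: float = 0.2     # LeakyReLU slope inside attention scores
    lr: float = 1e-3             # pretraining learning rate
    finetune_lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    weight_decay: float = 1e-3       # decoupled (AdamW-style) regularization
    feature_noise: float = 1.0       # train-time Gaussian noise on embedding channels
    class_weight: str = "balanced"   # "balanced" | "none"
    val_fraction: float = 0.1
    patience: int = 10
    structural_channels: bool = True  # append chain-role bit + degree channel
    seed: int = 0

    def validate(self) -> None:
        if min(self.embed_dim, self.hidden_dim, self.n_layers, self.heads,
               self.epochs, self.batch_size) < 1:
            raise ConfigError("all size parameters must be positive")
        if self.hidden_dim % self.heads != 0:
            raise ConfigError("hidden_dim must be divisible by heads")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")

    @property
    def input_dim(self) -> int:
        return self.embed_dim + (2 if self.structural_channels else 0)


@dataclass
class TrainingExample:
    """One (graph, mutation) sample ready for the model."""

    graph: ContactGraph
    node_features: np.ndarray    # N × D embedding rows
    raw_encoding: np.ndarray     # D, un-normalized mutation difference vector
    mutation_node: int
    label: int | None = None
    record: object = None        # backing VariantPartnerPair / StabilityRecord


@dataclass
class TrainReport:
    losses: list            # (train_loss, monitor_loss) per epoch
    final_epoch: int
    best_epoch: int
    class_weights: dict
    seed: int


def compute_class_weights(labels) -> dict[int, float]:
    """Inverse-frequency weights normalized to mean 1: w_c = n / (2 n_c)."""
    labels = list(labels)
    n = len(labels)
    counts = {c: labels.count(c) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise DegenerateClassError("both classes must be present for weighting")
    return {c: n / (2.0 * counts[c]) for c in (0, 1)}


# ---------------------------------------------------------------------------
# numerics

def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: float) -> float:
    x = float(np.clip(x, -30.0, 30.0))
    return 1.0 / (1.0 + np.exp(-x))


def _init_params(config: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    h, hid = config.heads, config.hidden_dim
    fh = hid // h
    params: dict[str, np.ndarray] = {}

    def glorot(*shape):
        fan_in, fan_out = shape[-2], shape[-1]
        scale = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-scale, scale, size=shape)

    d_in = config.input_dim
    for layer in range(config.n_layers):
        params[f"gat{layer}_W"] = glorot(h, d_in, fh)
        params[f"gat{layer}_asrc"] = glorot(h, 1, fh)[:, 0, :]
        params[f"gat{layer}_adst"] = glorot(h, 1, fh)[:, 0, :]
        params[f"gat{layer}_b"] = np.zeros(hid)
        d_in = hid
    d = config.embed_dim
    params["mp_W1"] = glorot(d, hid)
    params["mp_b1"] = np.zeros(hid)
    params["mp_W2"] = glorot(hid, hid)
    params["mp_b2"] = np.zeros(hid)
    params["head_W1"] = glorot(2 * hid, hid)
    params["head_b1"] = np.zeros(hid)
    params["head_W2"] = glorot(hid, 1)
    params["head_b2"] = np.zeros(1)
    return params


def _gat_forward(params, name, x, mask, slope):
    w = params[f"{name}_W"]
    z = np.einsum("nf,hfk->hnk", x, w)
    s = np.einsum("hnk,hk->hn", z, params[f"{name}_asrc"])
    t = np.einsum("hnk,hk->hn", z, params[f"{name}_adst"])
    pre = s[:, :, None] + t[:, None, :]
    act = _leaky(pre, slope)
    logits = np.where(mask[None, :, :], act, -np.inf)
    logits = logits - logits.max(axis=2, keepdims=True)
    expv = np.exp(logits) * mask[None, :, :]
    attn = expv / expv.sum(axis=2, keepdims=True)
    agg = np.einsum("hij,hjk->hik", attn, z)
    n = x.shape[0]
    out = agg.transpose(1, 0, 2).reshape(n, -1) + params[f"{name}_b"]
    return out, (x, z, attn, pre)


def _gat_backward(params, name, d_out, cache, slope, grads):
    x, z, attn, pre = cache
    w = params[f"{name}_W"]
    heads, _, fh = w.shape
    n = x.shape[0]
    grads[f"{name}_b"] += d_out.sum(axis=0)
    d_agg = d_out.reshape(n, heads, fh).transpose(1, 0, 2)
    d_attn = np.einsum("hik,hjk->hij", d_agg, z)
    d_z = np.einsum("hij,hik->hjk", attn, d_agg)
    # softmax (rows) backward; attn is exactly 0 outside the mask
    d_e = attn * (d_attn - (d_attn * attn).sum(axis=2, keepdims=True))
    d_pre = d_e * np.where(pre > 0, 1.0, slope)
    d_s = d_pre.sum(axis=2)
    d_t = d_pre.sum(axis=1)
    asrc, adst = params[f"{name}_asrc"], params[f"{name}_adst"]
    d_z += d_s[:, :, None] * asrc[:, None, :] + d_t[:, :, None] * adst[:, None, :]
    grads[f"{name}_asrc"] += np.einsum("hn,hnk->hk", d_s, z)
    grads[f"{name}_adst"] += np.einsum("hn,hnk->hk", d_t, z)
    grads[f"{name}_W"] += np.einsum("nf,hnk->hfk", x, d_z)
    return np.einsum("hnk,hfk->nf", d_z, w)


def _forward(params, config, x_in, mask, mut_idx, enc, dropout_rng=None):
    """Full forward pass; returns the logit and a cache for backprop."""
    cache: dict = {"layers": [], "dropout": []}
    h = x_in
    for layer in range(config.n_layers):
        h, layer_cache = _gat_forward(params, f"gat{layer}", h, mask,
                                      config.leaky_slope)
        elu_in = None
        if layer < config.n_layers - 1:
            elu_in = h
            h = _elu(h)
        drop_mask = None
        if dropout_rng is not None and config.dropout > 0:
            drop_mask = (dropout_rng.random(h.shape) >= config.dropout) / (
                1 - config.dropout
            )
            h = h * drop_mask
        cache["layers"].append(layer_cache)
        cache["dropout"].append(drop_mask)
        cache.setdefault("elu", []).append(elu_in)
    z = h[mut_idx]

    m1_in = enc @ params["mp_W1"] + params["mp_b1"]
    m1 = _relu(m1_in)
    m2_in = m1 @ params["mp_W2"] + params["mp_b2"]
    m2 = _relu(m2_in)

    c = np.concatenate([z, m2])
    u_in = c @ params["head_W1"] + params["head_b1"]
    u = _relu(u_in)
    logit = float((u @ params["head_W2"] + params["head_b2"])[0])
    cache.update(
        h=h, z=z, enc=enc, m1_in=m1_in, m1=m1, m2_in=m2_in, m2=m2,
        c=c, u_in=u_in, u=u, mut_idx=mut_idx,
    )
    return logit, cache


def _backward(params, config, cache, d_logit, grads):
    u, c = cache["u"], cache["c"]
    grads["head_W2"] += np.outer(u, [d_logit])
    grads["head_b2"] += np.array([d_logit])
    d_u = d_logit * params["head_W2"][:, 0]
    d_u_in = d_u * (cache["u_in"] > 0)
    grads["head_W1"] += np.outer(c, d_u_in)
    grads["head_b1"] += d_u_in
    d_c = params["head_W1"] @ d_u_in
    hid = config.hidden_dim
    d_z, d_m2 = d_c[:hid], d_c[hid:]

    d_m2_in = d_m2 * (cache["m2_in"] > 0)
    grads["mp_W2"] += np.outer(cache["m1"], d_m2_in)
    grads["mp_b2"] += d_m2_in
    d_m1 = params["mp_W2"] @ d_m2_in
    d_m1_in = d_m1 * (cache["m1_in"] > 0)
    grads["mp_W1"] += np.outer(cache["enc"], d_m1_in)
    grads["mp_b1"] += d_m1_in

    n = cache["h"].shape[0]
    d_h = np.zeros_like(cache["h"])
    d_h[cache["mut_idx"]] = d_z
    for layer in range(config.n_layers - 1, -1, -1):
        drop_mask = cache["dropout"][layer]
        if drop_mask is not None:
            d_h = d_h * drop_mask
        elu_in = cache["elu"][layer]
        if elu_in is not None:
            d_h = d_h * np.where(elu_in > 0, 1.0, np.exp(np.minimum(elu_in, 0.0)))
        d_h = _gat_backward(params, f"gat{layer}", d_h,
                            cache["layers"][layer], config.leaky_slope, grads)
    return d_h


class PerturbationModel:
    """GAT + mutation-processor + prediction-head classifier."""

    def __init__(self, config: ModelConfig, params=None,
                 normalizer: Normalizer | None = None,
                 stage: str = STAGE_INITIALIZED):
        config.validate()
        self.config = config
        self.params = params if params is not None else _init_params(config)
        self.normalizer = normalizer
        self.stage = stage

    # -- input preparation --------------------------------------------------

    def _prepare_graph(self, example: TrainingExample):
        graph = example.graph
        x = np.asarray(example.node_features, dtype=float)
        if x.shape[1] != self.config.embed_dim:
            raise ConfigError(
                f"node features have dim {x.shape[1]}, "
                f"model expects {self.config.embed_dim}"
            )
        if graph.chain_role[example.mutation_node] != INTERACTOR:
            raise RoleError(
                "mutation node lies on the partner chain; flip roles first"
            )
        if self.config.structural_channels:
            role = np.array(
                [1.0 if r == INTERACTOR else 0.0 for r in graph.chain_role]
            )
            deg = graph.degrees().astype(float)
            # z-score within the graph: burial/interface contrast stays visible
            # at any graph size, unlike a raw degree fraction
            spread = deg.std()
            deg = (deg - deg.mean()) / spread if spread > 0 else deg * 0.0
            x = np.column_stack([x, role, deg])
        mask = graph.adjacency()
        np.fill_diagonal(mask, True)  # self-loops for attention
        return x, mask

    def _encoding(self, example: TrainingExample) -> np.ndarray:
        if self.normalizer is not None and self.normalizer.fitted:
            return self.normalizer.transform(example.raw_encoding).vector
        return np.asarray(example.raw_encoding, dtype=float)

    # -- inference ----------------------------------------------------------

    def forward(self, example: TrainingExample) -> float:
        """Predicted probability of interaction loss, strictly in (0, 1)."""
        x, mask = self._prepare_graph(example)
        logit, _ = _forward(self.params, self.config, x, mask,
                            example.mutation_node, self._encoding(example))
        return _sigmoid(logit)

    predict_proba = forward

    def predict_many(self, examples) -> np.ndarray:
        return np.array([self.forward(ex) for ex in examples])

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        names = sorted(self.params)
        header = {
            "version": _CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "stage": self.stage,
            "normalizer": (
                self.normalizer.to_dict()
                if self.normalizer is not None and self.normalizer.fitted
                else None
            ),
            "arrays": [
                {"name": n, "shape": list(self.params[n].shape)} for n in names
            ],
        }
        blob = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(_CHECKPOINT_MAGIC)
            fh.write(_CHECKPOINT_VERSION.to_bytes(2, "little"))
            fh.write(len(blob).to_bytes(8, "little"))
            fh.write(blob)
            for name in names:
                fh.write(np.ascontiguousarray(self.params[name], dtype=np.float64).tobytes())

    @classmethod
    def load(cls, path, expect_dim: int | None = None) -> "PerturbationModel":
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != _CHECKPOINT_MAGIC:
                raise CompatibilityError(f"{path} is not a model checkpoint")
            version = int.from_bytes(fh.read(2), "little")
            if version != _CHECKPOINT_VERSION:
                raise CompatibilityError(
                    f"checkpoint version {version} != {_CHECKPOINT_VERSION}"
                )
            header = json.loads(fh.read(int.from_bytes(fh.read(8), "little")))
            config = ModelConfig(**header["config"])
            if expect_dim is not None and config.embed_dim != expect_dim:
                raise CompatibilityError(
                    f"checkpoint embedding dim {config.embed_dim} != expected {expect_dim}"
                )
            params = {}
            for entry in header["arrays"]:
                shape = tuple(entry["shape"])
                count = int(np.prod(shape)) if shape else 1
                data = np.frombuffer(fh.read(8 * count), dtype=np.float64)
                params[entry["name"]] = data.reshape(shape).copy()
        normalizer = (
            Normalizer.from_dict(header["normalizer"])
            if header["normalizer"] is not None
            else None
        )
        return cls(config, params=params, normalizer=normalizer,
                   stage=header["stage"])


# ---------------------------------------------------------------------------
# training

def _weighted_bce_loss_grad(logit: float, label: int, weight: float):
    # stable softplus-based BCE on the logit
    loss = weight * (np.logaddexp(0.0, logit) - label * logit)
    d_logit = weight * (_sigmoid(logit) - label)
    return float(loss), float(d_logit)


class _Adam:
    """Adam with decoupled weight decay (AdamW)."""

    def __init__(self, params, lr, weight_decay=0.0):
        self.lr = lr
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = beta1 * self.m[k] + (1 - beta1) * g
            self.v[k] = beta2 * self.v[k] + (1 - beta2) * g * g
            mhat = self.m[k] / (1 - beta1 ** self.t)
            vhat = self.v[k] / (1 - beta2 ** self.t)
            params[k] -= self.lr * (
                mhat / (np.sqrt(vhat) + eps) + self.weight_decay * params[k]
            )


def _mean_loss(model, prepared, indices, weights):
    total = 0.0
    for i in indices:
        x, mask, mut, enc, label = prepared[i]
        logit, _ = _forward(model.params, model.config, x, mask, mut, enc)
        loss, _ = _weighted_bce_loss_grad(logit, label, weights[label])
        total += loss
    return total / max(1, len(indices))


def _fit(model: PerturbationModel, examples, lr: float, seed: int) -> TrainReport:
    config = model.config
    labeled = [ex for ex in examples if ex.label is not None]
    if not labeled:
        raise DataError("no labeled examples to train on")
    labels = [ex.label for ex in labeled]
    if config.class_weight == "balanced":
        weights = compute_class_weights(labels)
    else:
        weights = {0: 1.0, 1: 1.0}

    model.normalizer = Normalizer().fit([ex.raw_encoding for ex in labeled])
    prepared = []
    for ex in labeled:
        x, mask = model._prepare_graph(ex)
        prepared.append((x, mask, ex.mutation_node,
                         model.normalizer.transform(ex.raw_encoding).vector,
                         int(ex.label)))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(prepared))
    n_val = int(round(config.val_fraction * len(prepared))) if len(prepared) >= 10 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]

    opt = _Adam(model.params, lr, weight_decay=config.weight_decay)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    best_loss, best_epoch, best_params = np.inf, 0, None
    losses = []
    epochs_run = 0
    for epoch in range(config.epochs):
        epochs_run = epoch + 1
        perm = rng.permutation(train_idx)
        epoch_loss, count = 0.0, 0
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            for i in batch:
                x, mask, mut, enc, label = prepared[i]
                if config.feature_noise > 0:
                    # perturb only the embedding channels; structural channels
                    # (role bit, degree) stay clean so the graph context keeps
                    # its meaning while variant-specific noise is washed out
                    d = config.embed_dim
                    x = x.copy()
                    x[:, :d] += drop_rng.normal(0, config.feature_noise,
                                                size=(x.shape[0], d))
                    enc = enc + drop_rng.normal(0, config.feature_noise,
                                                size=enc.shape)
                logit, cache = _forward(model.params, config, x, mask, mut,
                                        enc, dropout_rng=drop_rng)
                loss, d_logit = _weighted_bce_loss_grad(logit, label, weights[label])
                _backward(model.params, config, cache, d_logit / len(batch), grads)
                epoch_loss += loss
                count += 1
            opt.step(model.params, grads)
        train_loss = epoch_loss / max(1, count)
        monitor = (
            _mean_loss(model, prepared, val_idx, weights)
            if n_val > 0
            else _mean_loss(model, prepared, train_idx, weights)
        )
        if not np.isfinite(monitor):
            warnings.warn("non-finite loss; stopping early", stacklevel=2)
            break
        losses.append((train_loss, monitor))
        if monitor < best_loss - 1e-9:
            best_loss, best_epoch = monitor, epoch + 1
            best_params = copy.deepcopy(model.params)
        elif epoch + 1 - best_epoch >= config.patience:
            break
    if best_params is not None:
        model.params = best_params
    return TrainReport(
        losses=losses,
        final_epoch=epochs_run,
        best_epoch=best_epoch,
        class_weights=weights,
        seed=seed,
    )


def pretrain_stability(config: ModelConfig, examples,
                       seed: int | None = None):
    """Stage 1: train on monomer graphs with stability-disruption labels."""
    seed = config.seed if seed is None else seed
    model = PerturbationModel(
        ModelConfig(**{**asdict(config), "seed": seed}), stage=STAGE_PRETRAINED
    )
    report = _fit(model, examples, lr=config.lr, seed=seed)
    return model, report


def finetune(pretrained: PerturbationModel | None, config: ModelConfig,
             examples, seed: int | None = None, from_scratch: bool = False):
    """Stage 2: fine-tune every parameter on variant-partner triplets.

    With ``from_scratch=True`` the model is initialized fresh (no stability
    pretraining), which serves as the transfer-learning ablation.
    """
    seed = config.seed if seed is None else seed
    cfg = ModelConfig(**{**asdict(config), "seed": seed})
    if from_scratch:
        model = PerturbationModel(cfg)
    else:
        if pretrained is None or pretrained.stage not in (
            STAGE_PRETRAINED, STAGE_FINETUNED
        ):
            raise ConfigError(
                "finetune requires a pretrained model (or from_scratch=True)"
            )
        if pretrained.config.input_dim != cfg.input_dim:
            raise CompatibilityError("pretrained model dimensionality differs")
        model = PerturbationModel(cfg, params=copy.deepcopy(pretrained.params))
    report = _fit(model, examples, lr=config.finetune_lr, seed=seed)
    model.stage = STAGE_FINETUNED
    return model, report


def predict_ensemble(models, example: TrainingExample) -> float:
    """Arithmetic mean of member probabilities."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    dims = {m.config.embed_dim for m in models}
    if len(dims) > 1:
        raise CompatibilityError("ensemble members disagree on embedding dim")
    return float(np.mean([m.forward(example) for m in models]))


def save_model(model: PerturbationModel, path) -> None:
    model.save(path)


def load_model(path, expect_dim: int | None = None) -> PerturbationModel:
    return PerturbationModel.load(path, expect_dim=expect_dim)
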