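"""Components of the variational REBA-regression network.

Two VAE branches share one decoder after alignment:

* **Skel-to-REBA** — a multi-stream MLP encoder (one branch per body-part
  stream) feeds a Transformer encoder whose blocks progressively reduce the
  token dimensionality; its output parameterizes the diagonal-Gaussian
  skeletal latent (dim 128 full scale). A sampled latent is decoded by
  ``D_skel`` into the 6 REBA score components.
* **REBA-to-REBA** — an autoencoder over the 6-dim ground-truth score
  vector with its own latent (dim 64 full scale); it acts as a teacher.
* **Alignment maps** — ``M_skel`` and ``M_reba`` project both latent
  distributions into a common 128-dim space decoded by the (frozen)
  pretrained ``D_skel``, distilling score structure into the skeletal
  latent.

All distributions are parameterized as (mu, log sigma^2) for numerical
stability; sampling uses the reparameterization z = mu + sigma * eps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .layers import MLP, Linear, Module, TransformerLayer

__all__ = [
    "NetworkConfig",
    "LatentDistribution",
    "MultiStreamEncoder",
    "TransformerEncoder",
    "ScoreDecoder",
    "RebaEncoder",
    "AlignmentMap",
    "ModelBundle",
    "sample_latent",
    "kl_to_standard_normal",
    "DESK_PRESET",
    "FULL_PRESET",
]

N_SCORE_COMPONENTS = 6


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Full-scale defaults follow the reference architecture (per-stream
    encoder up to 2048, three transformer blocks of four layers and four
    heads with a 2048->512->128 reduction schedule, latents 128/64,
    six-layer decoders). The ``desk`` preset shrinks every width so a full
    two-phase training run fits on a laptop CPU in minutes.
    """

    stream_dims: dict = field(
        default_factory=lambda: {"trunk": 486, "arms": 648, "legs": 648})
    stream_hidden_dims: tuple = (512, 1024, 1536, 2048)
    transformer_blocks: int = 3
    layers_per_block: int = 4
    heads: int = 4
    token_dims: tuple = (2048, 512, 128)
    skel_latent_dim: int = 128
    reba_latent_dim: int = 64
    decoder_layers: int = 6
    decoder_hidden: int = 256
    reba_hidden: int = 64
    align_hidden: int = 256
    activation: str = "relu"
    seed: int = 0

    def validate(self) -> "NetworkConfig":
        dims = (list(self.stream_hidden_dims) + list(self.token_dims)
                + [self.skel_latent_dim, self.reba_latent_dim,
                   self.decoder_hidden, self.reba_hidden, self.align_hidden])
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if len(self.token_dims) != self.transformer_blocks:
            raise ValueError("token_dims must list one dim per block")
        if any(a <= b for a, b in zip(self.token_dims, self.token_dims[1:])):
            raise ValueError("token_dims schedule must be strictly decreasing")
        for d in self.token_dims:
            if d % self.heads:
                raise ValueError(
                    f"heads={self.heads} must divide token dim {d}")
        if self.stream_hidden_dims[-1] != self.token_dims[0]:
            raise ValueError(
                "stream encoder output dim must equal the first token dim")
        return self


FULL_PRESET = NetworkConfig()
DESK_PRESET = NetworkConfig(
    stream_hidden_dims=(256, 256, 256, 256),
    token_dims=(256, 128, 64),
    skel_latent_dim=32,
    reba_latent_dim=16,
    decoder_hidden=64,
    reba_hidden=32,
    align_hidden=64,
)


def get_preset(name: str) -> NetworkConfig:
    presets = {"full": FULL_PRESET, "desk": DESK_PRESET}
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {presets}")
    cfg = presets[name]
    return NetworkConfig(**asdict(cfg)).validate()


@dataclass
class LatentDistribution:
    """Diagonal Gaussian N(mu, diag(exp(log_var)))."""

    mu: Tensor
    log_var: Tensor

    def __post_init__(self):
        if not isinstance(self.mu, Tensor):
            self.mu = Tensor(self.mu)
        if not isinstance(self.log_var, Tensor):
            self.log_var = Tensor(self.log_var)
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have equal shapes")
        if not (np.all(np.isfinite(self.mu.data))
                and np.all(np.isfinite(self.log_var.data))):
            raise ValueError("latent distribution parameters must be finite")

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var.data)

    @property
    def dim(self) -> int:
        return self.mu.shape[-1]


def sample_latent(dist: LatentDistribution, rng: np.random.Generator,
                  deterministic: bool = False) -> Tensor:
    """Reparameterized draw z = mu + sigma * eps (differentiable w.r.t.
    the distribution parameters). ``deterministic=True`` collapses the
    Gaussian to its mean."""
    if deterministic:
        return dist.mu
    eps = rng.standard_normal(dist.mu.shape)
    return dist.mu + (dist.log_var * 0.5).exp() * Tensor(eps)


def kl_to_standard_normal(dist: LatentDistribution) -> Tensor:
    """Closed-form KL( N(mu, sigma^2) || N(0, I) ) =
    1/2 sum_j (sigma_j^2 + mu_j^2 - ln sigma_j^2 - 1),
    summed over the latent dimension and averaged over any batch axes."""
    var = dist.log_var.exp()
    per_dim = var + dist.mu * dist.mu - dist.log_var - 1.0
    per_sample = per_dim.sum(axis=-1) * 0.5
    return per_sample.mean() if per_sample.ndim else per_sample


class MultiStreamEncoder(Module):
    """E_MS: one four-layer MLP per body-part stream, upsampling each
    stream to the common embedding width."""

    STREAMS = ("trunk", "arms", "legs")

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.nets = [
            MLP([cfg.stream_dims[s]] + list(cfg.stream_hidden_dims), rng)
            for s in self.STREAMS
        ]

    def __call__(self, streams: dict) -> list[Tensor]:
        out = []
        for name, net in zip(self.STREAMS, self.nets):
            x = streams[name]
            if not isinstance(x, Tensor):
                x = Tensor(x)
            expected = self.cfg.stream_dims[name]
            if x.shape[-1] != expected:
                raise ValueError(
                    f"stream '{name}' has dim {x.shape[-1]}, "
                    f"expected {expected}")
            out.append(net(x))
        return out


class TransformerEncoder(Module):
    """E_T: the three stream embeddings as tokens (learned positional
    encodings), three self-attention blocks with a linear dimensionality
    reduction after each non-final block, mean-pool over tokens, then two
    linear heads emitting (mu, log_var) of the skeletal latent."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        d0 = cfg.token_dims[0]
        self.pos = Tensor(rng.normal(0.0, 0.02, size=(3, d0)),
                          requires_grad=True)
        self.blocks = []
        self.reducers = []
        for bi, d in enumerate(cfg.token_dims):
            self.blocks.append([
                TransformerLayer(d, cfg.heads, rng)
                for _ in range(cfg.layers_per_block)
            ])
            if bi < cfg.transformer_blocks - 1:
                self.reducers.append(
                    Linear(d, cfg.token_dims[bi + 1], rng))
        d_last = cfg.token_dims[-1]
        self.mu_head = Linear(d_last, cfg.skel_latent_dim, rng)
        self.lv_head = Linear(d_last, cfg.skel_latent_dim, rng,
                              scale=1e-2)
        self.lv_head.bias.data[:] = -4.0  # start near-deterministic

    def parameters(self) -> list[Tensor]:
        params = [self.pos]
        for block in self.blocks:
            for layer in block:
                params.extend(layer.parameters())
        for r in self.reducers:
            params.extend(r.parameters())
        params.extend(self.mu_head.parameters())
        params.extend(self.lv_head.parameters())
        return params

    def __call__(self, embeddings: list[Tensor]) -> LatentDistribution:
        if len(embeddings) != 3:
            raise ValueError("expected exactly 3 stream tokens")
        # stack tokens: (batch, 3, d0)
        toks = [e.reshape(e.shape[0], 1, e.shape[-1])
                if e.ndim == 2 else e.reshape(1, 1, e.shape[-1])
                for e in embeddings]
        x = concat(toks, axis=1) + self.pos
        for bi, block in enumerate(self.blocks):
            for layer in block:
                x = layer(x)
            if bi < len(self.reducers):
                x = self.reducers[bi](x)
        pooled = x.mean(axis=1)
        return LatentDistribution(self.mu_head(pooled), self.lv_head(pooled))


class ScoreDecoder(Module):
    """D_skel / D_reba: six fully connected layers latent -> 6 scores."""

    def __init__(self, latent_dim: int, hidden: int, n_layers: int,
                 rng: np.random.Generator):
        dims = [latent_dim] + [hidden] * (n_layers - 1) + [N_SCORE_COMPONENTS]
        self.net = MLP(dims, rng)
        self.latent_dim = latent_dim

    def __call__(self, z: Tensor) -> Tensor:
        if z.shape[-1] != self.latent_dim:
            raise ValueError(
                f"latent dim {z.shape[-1]} != expected {self.latent_dim}")
        return self.net(z)


class RebaEncoder(Module):
    """E_reba: six fully connected layers (5 hidden + two statistic heads)
    encoding the 6-dim score vector into its latent distribution."""

    def __init__(self, latent_dim: int, hidden: int, rng: np.random.Generator):
        self.body = MLP([N_SCORE_COMPONENTS] + [hidden] * 4, rng,
                        final_activation=True)
        self.mu_head = Linear(hidden, latent_dim, rng)
        self.lv_head = Linear(hidden, latent_dim, rng, scale=1e-2)
        self.lv_head.bias.data[:] = -4.0

    def __call__(self, x: Tensor) -> LatentDistribution:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[-1] != N_SCORE_COMPONENTS:
            raise ValueError(
                f"score vector dim {x.shape[-1]} != {N_SCORE_COMPONENTS}")
        h = self.body(x)
        return LatentDistribution(self.mu_head(h), self.lv_head(h))


class AlignmentMap(Module):
    """M_skel / M_reba: two-layer feed-forward map on the concatenated
    [mu || log_var] statistics, emitting a new (mu, log_var) pair in the
    shared (skeletal) latent dimension so D_skel can decode either path."""

    def __init__(self, d_in: int, d_out: int, hidden: int,
                 rng: np.random.Generator):
        self.hidden_layer = Linear(2 * d_in, hidden, rng)
        self.mu_head = Linear(hidden, d_out, rng)
        self.lv_head = Linear(hidden, d_out, rng, scale=1e-2)
        self.lv_head.bias.data[:] = -4.0
        self.d_in = d_in

    def __call__(self, dist: LatentDistribution) -> LatentDistribution:
        if dist.dim != self.d_in:
            raise ValueError(
                f"alignment input dim {dist.dim} != expected {self.d_in}")
        h = self.hidden_layer(concat([dist.mu, dist.log_var], axis=-1)).relu()
        return LatentDistribution(self.mu_head(h), self.lv_head(h))


class ModelBundle(Module):
    """All network components plus config and training-phase tag."""

    PHASES = ("init", "phase1", "aligned")

    def __init__(self, cfg: NetworkConfig, seed: int | None = None):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        self.e_ms = MultiStreamEncoder(cfg, rng)
        self.e_t = TransformerEncoder(cfg, rng)
        self.d_skel = ScoreDecoder(cfg.skel_latent_dim, cfg.decoder_hidden,
                                   cfg.decoder_layers, rng)
        self.e_reba = RebaEncoder(cfg.reba_latent_dim, cfg.reba_hidden, rng)
        self.d_reba = ScoreDecoder(cfg.reba_latent_dim, cfg.reba_hidden,
                                   cfg.decoder_layers, rng)
        self.m_skel = AlignmentMap(cfg.skel_latent_dim, cfg.skel_latent_dim,
                                   cfg.align_hidden, rng)
        self.m_reba = AlignmentMap(cfg.reba_latent_dim, cfg.skel_latent_dim,
                                   cfg.align_hidden, rng)
        self.phase = "init"
        self.stream_norm: dict | None = None

    # -- forward paths ------------------------------------------------------

    def fit_normalization(self, streams: dict) -> None:
        """Store per-dimension mean/std of the training features; applied
        on every subsequent encode. Standardizing the heterogeneous feature
        scales (coordinates vs line distances) speeds up convergence."""
        self.stream_norm = {}
        for name in MultiStreamEncoder.STREAMS:
            arr = np.asarray(streams[name], dtype=np.float64)
            mean = arr.mean(axis=0)
            std = arr.std(axis=0)
            std[std < 1e-8] = 1.0
            self.stream_norm[name] = (mean, std)

    def _normalize(self, streams: dict) -> dict:
        if self.stream_norm is None:
            return streams
        out = {}
        for name, x in streams.items():
            mean, std = self.stream_norm[name]
            data = x.data if isinstance(x, Tensor) else np.asarray(x)
            out[name] = Tensor((data - mean) / std)
        return out

    def encode_skel(self, streams: dict) -> LatentDistribution:
        return self.e_t(self.e_ms(self._normalize(streams)))

    def predict_scores(self, streams: dict, use_alignment: bool | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Deterministic inference: encode, (align), take the latent mean
        and decode. Pass ``rng`` to sample the latent instead."""
        if use_alignment is None:
            use_alignment = self.phase == "aligned"
        if use_alignment and self.phase != "aligned":
            raise RuntimeError("bundle has no trained alignment maps")
        with no_grad():
            dist = self.encode_skel(streams)
            if use_alignment:
                dist = self.m_skel(dist)
            z = (dist.mu if rng is None
                 else sample_latent(dist, rng))
            return self.d_skel(z).data

    # -- persistence ---------------------------------------------------------

    _COMPONENTS = ("e_ms", "e_t", "d_skel", "e_reba", "d_reba",
                   "m_skel", "m_reba")

    def parameters(self) -> list[Tensor]:
        params = []
        for name in self._COMPONENTS:
            params.extend(getattr(self, name).parameters())
        return params

    def save(self, path) -> None:
        path = Path(path)
        arrays = {}
        for name in self._COMPONENTS:
            for i, a in enumerate(getattr(self, name).state_arrays()):
                arrays[f"{name}__{i}"] = a
        if self.stream_norm is not None:
            for name, (mean, std) in self.stream_norm.items():
                arrays[f"norm__{name}__mean"] = mean
                arrays[f"norm__{name}__std"] = std
        cfg_json = json.dumps({"config": asdict(self.cfg),
                               "phase": self.phase, "schema": 1,
                               "normalized": self.stream_norm is not None})
        with open(path, "wb") as fh:  # keep the exact path (no .npz append)
            np.savez(fh, __meta__=np.frombuffer(cfg_json.encode(),
                                                dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            cfg_dict["stream_hidden_dims"] = tuple(
                cfg_dict["stream_hidden_dims"])
            cfg_dict["token_dims"] = tuple(cfg_dict["token_dims"])
            bundle = cls(NetworkConfig(**cfg_dict))
            for name in cls._COMPONENTS:
                comp = getattr(bundle, name)
                n = len(comp.state_arrays())
                comp.load_state_arrays(
                    [data[f"{name}__{i}"] for i in range(n)])
            bundle.phase = meta["phase"]
            if meta.get("normalized"):
                bundle.stream_norm = {
                    s: (data[f"norm__{s}__mean"], data[f"norm__{s}__std"])
                    for s in MultiStreamEncoder.STREAMS}
        return bundle
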