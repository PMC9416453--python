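"""Two-phase optimization of the variational REBA regressor.

Phase 1 trains the two VAE branches independently: the Skel-to-REBA branch
regresses the (smoothed) 6-component score vector from the stream features,
and the REBA-to-REBA branch autoencodes the score vector itself. Each is
optimized with a beta-weighted KL term to N(0, I) plus the mean squared
error over the K = 6 score components.

Phase 2 trains the alignment maps (and fine-tunes both encoders) so that
both projected latent distributions decode through the *frozen* pretrained
Skel-to-REBA decoder: L = L_align_skel + gamma * L_align_reba, each term
again beta * KL + MSE.

Inference takes the latent mean (no sampling) for determinism; evaluation
reports per-component MSE / MAE / RMSE, optionally as mean +/- std over
4 sequence-level folds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .features import STREAM_DIMS, StreamFeatures, sequence_stream_features
from .nn.autodiff import Tensor, no_grad
from .nn.layers import Adam
from .nn.models import (LatentDistribution, ModelBundle, NetworkConfig,
                        get_preset, kl_to_standard_normal, sample_latent)
from .reba import SCORE_COMPONENTS, RebaScoreVector
from .skeleton import SkeletonFrame, SkeletonSequence

__all__ = [
    "TrainConfig",
    "LabeledDataset",
    "EvalReport",
    "TrainingDiverged",
    "loss_skel_vae",
    "loss_reba_vae",
    "loss_align",
    "train_phase1",
    "train_phase2",
    "predict",
    "evaluate",
]

K_TARGET = 6


class TrainingDiverged(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    beta (KL weight 1e-4), gamma (teacher-branch weight 1e-2), learning
    rate 1e-4 and batch size 128 are the reference defaults; "until
    convergence" is operationalized as early stopping on a held-out
    validation split.
    """

    beta: float = 1e-4
    gamma: float = 1e-2
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.15
    seed: int = 0
    freeze_decoder_phase2: bool = True
    #: aligning fine-tunes pretrained encoders; a smaller step protects them
    phase2_lr_factor: float = 0.2

    def __post_init__(self):
        if min(self.beta, self.gamma) <= 0 or self.learning_rate < 0:
            raise ValueError("beta and gamma must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LabeledDataset:
    """Per-frame stream features, (smoothed) score targets and the sequence
    id of every frame (folds split on sequence, never on frame, to prevent
    temporal leakage)."""

    streams: dict
    targets: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.float64)
        self.groups = np.asarray(self.groups)
        n = len(self.targets)
        if self.targets.ndim != 2 or self.targets.shape[1] != K_TARGET:
            raise ValueError("targets must have shape (n, 6)")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("targets must be finite")
        for name in ("trunk", "arms", "legs"):
            arr = np.asarray(self.streams[name], dtype=np.float64)
            if arr.shape != (n, STREAM_DIMS[name]):
                raise ValueError(
                    f"stream '{name}' must have shape "
                    f"({n}, {STREAM_DIMS[name]}), got {arr.shape}")
            self.streams[name] = arr
        if self.groups.shape != (n,):
            raise ValueError("groups must have one id per frame")

    def __len__(self) -> int:
        return len(self.targets)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            {k: v[idx] for k, v in self.streams.items()},
            self.targets[idx], self.groups[idx])

    def split_by_groups(self, held_groups: Sequence) -> tuple[
            "LabeledDataset", "LabeledDataset"]:
        mask = np.isin(self.groups, list(held_groups))
        if mask.all() or not mask.any():
            raise ValueError("held-out groups must be a proper subset")
        return self.subset(~mask), self.subset(mask)


# ---------------------------------------------------------------------------
# losses

def _mse(pred: Tensor, target: Tensor) -> Tensor:
    diff = pred - target
    per_sample = (diff * diff).sum(axis=-1) * (1.0 / K_TARGET)
    return per_sample.mean() if per_sample.ndim else per_sample


def loss_skel_vae(pred: Tensor, target, dist: LatentDistribution,
                  beta: float) -> Tensor:
    """beta * KL(q_skel || N(0,I)) + (1/K) sum (y - yhat)^2."""
    target = target if isinstance(target, Tensor) else Tensor(target)
    return kl_to_standard_normal(dist) * beta + _mse(pred, target)


def loss_reba_vae(xhat: Tensor, x, dist: LatentDistribution,
                  beta: float) -> Tensor:
    """Same structure as the skeletal VAE loss, on the teacher branch."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    return kl_to_standard_normal(dist) * beta + _mse(xhat, x)


def loss_align(streams: dict, targets, bundle: ModelBundle, beta: float,
               gamma: float, rng: np.random.Generator) -> Tensor:
    """L_align_skel + gamma * L_align_reba, both decoded by D_skel."""
    if bundle.phase == "init":
        raise RuntimeError(
            "alignment loss requires a phase-1-trained bundle")
    y = targets if isinstance(targets, Tensor) else Tensor(targets)
    skel_aligned = bundle.m_skel(bundle.encode_skel(streams))
    y_hat = bundle.d_skel(sample_latent(skel_aligned, rng))
    term_skel = kl_to_standard_normal(skel_aligned) * beta + _mse(y_hat, y)

    reba_aligned = bundle.m_reba(bundle.e_reba(y))
    x_hat = bundle.d_skel(sample_latent(reba_aligned, rng))
    term_reba = kl_to_standard_normal(reba_aligned) * beta + _mse(x_hat, y)
    return term_skel + term_reba * gamma


# ---------------------------------------------------------------------------
# optimization loops

def _val_split(data: LabeledDataset, cfg: TrainConfig
               ) -> tuple[LabeledDataset, LabeledDataset]:
    """Hold out whole sequences when possible, otherwise a frame fraction."""
    rng = np.random.default_rng(cfg.seed)
    uniq = np.unique(data.groups)
    if len(uniq) >= 4:
        n_hold = max(1, int(round(cfg.val_fraction * len(uniq))))
        held = rng.permutation(uniq)[:n_hold]
        return data.split_by_groups(held)
    idx = rng.permutation(len(data))
    n_val = max(1, int(cfg.val_fraction * len(data)))
    return data.subset(idx[n_val:]), data.subset(idx[:n_val])


def _check_finite(loss: float, context: str):
    if not np.isfinite(loss):
        raise TrainingDiverged(
            f"{context}: loss became non-finite ({loss}); lower the "
            "learning rate or inspect the input scale")


def _early_stop_loop(step_fn, val_fn, snapshot_fn, restore_fn,
                     cfg: TrainConfig, context: str) -> list[float]:
    best, best_state, bad, history = np.inf, None, 0, []
    for epoch in range(cfg.max_epochs):
        try:
            train_loss = step_fn(epoch)
            _check_finite(train_loss, context)
            val_loss = val_fn()
            _check_finite(val_loss, context)
        except ValueError as e:  # non-finite activations surface here
            if "finite" in str(e):
                raise TrainingDiverged(f"{context}: {e}") from e
            raise
        history.append(val_loss)
        if val_loss < best - 1e-12:
            best, best_state, bad = val_loss, snapshot_fn(), 0
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    if best_state is not None:
        restore_fn(best_state)
    return history


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_phase1(data: LabeledDataset, cfg: TrainConfig,
                 net_cfg: NetworkConfig | str = "desk") -> ModelBundle:
    """Train the two VAE branches independently (stage one).

    Returns a bundle tagged ``phase1``. Reproducible bit-for-bit for a
    fixed (seed, config, data) triple.
    """
    if isinstance(net_cfg, str):
        net_cfg = get_preset(net_cfg)
    if len(data) == 0:
        raise ValueError("empty dataset")
    bundle = ModelBundle(net_cfg, seed=cfg.seed)
    train, val = _val_split(data, cfg)
    bundle.fit_normalization(train.streams)
    # start both decoders at the train-target mean so optimization spends
    # its budget on structure rather than on shifting the output scale
    target_mean = train.targets.mean(axis=0)
    for dec in (bundle.d_skel, bundle.d_reba):
        dec.net.layers[-1].bias.data = target_mean.astype(
            dec.net.layers[-1].bias.data.dtype)
    rng = np.random.default_rng(cfg.seed + 1)

    # --- skeletal branch: features -> scores
    skel_modules = [bundle.e_ms, bundle.e_t, bundle.d_skel]
    skel_params = [p for m in skel_modules for p in m.parameters()]
    opt = Adam(skel_params, lr=cfg.learning_rate)

    def skel_epoch(_):
        losses = []
        for idx in _batches(len(train), cfg.batch_size, rng):
            streams = {k: v[idx] for k, v in train.streams.items()}
            dist = bundle.encode_skel(streams)
            pred = bundle.d_skel(sample_latent(dist, rng))
            loss = loss_skel_vae(pred, train.targets[idx], dist, cfg.beta)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def skel_val():
        with no_grad():
            dist = bundle.encode_skel(val.streams)
            pred = bundle.d_skel(dist.mu)
            return float(loss_skel_vae(pred, val.targets, dist,
                                       cfg.beta).data)

    def snap():
        return [[a.copy() for a in m.state_arrays()] for m in skel_modules]

    def rest(state):
        for m, arrays in zip(skel_modules, state):
            m.load_state_arrays(arrays)

    _early_stop_loop(skel_epoch, skel_val, snap, rest, cfg,
                     "phase 1 (Skel-to-REBA)")

    # --- teacher branch: scores -> scores
    reba_modules = [bundle.e_reba, bundle.d_reba]
    reba_params = [p for m in reba_modules for p in m.parameters()]
    opt_r = Adam(reba_params, lr=cfg.learning_rate * 10)

    def reba_epoch(_):
        losses = []
        for idx in _batches(len(train), cfg.batch_size, rng):
            x = train.targets[idx]
            dist = bundle.e_reba(x)
            xhat = bundle.d_reba(sample_latent(dist, rng))
            loss = loss_reba_vae(xhat, x, dist, cfg.beta)
            opt_r.zero_grad()
            loss.backward()
            opt_r.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def reba_val():
        with no_grad():
            dist = bundle.e_reba(val.targets)
            xhat = bundle.d_reba(dist.mu)
            return float(loss_reba_vae(xhat, val.targets, dist,
                                       cfg.beta).data)

    def snap_r():
        return [[a.copy() for a in m.state_arrays()] for m in reba_modules]

    def rest_r(state):
        for m, arrays in zip(reba_modules, state):
            m.load_state_arrays(arrays)

    # the 6-dim teacher branch is orders of magnitude cheaper per epoch
    # than the skeletal branch; give it a correspondingly larger budget
    reba_cfg = replace(cfg, max_epochs=cfg.max_epochs * 5,
                       patience=cfg.patience * 3)
    _early_stop_loop(reba_epoch, reba_val, snap_r, rest_r, reba_cfg,
                     "phase 1 (REBA-to-REBA)")

    bundle.phase = "phase1"
    return bundle


def train_phase2(data: LabeledDataset, bundle: ModelBundle,
                 cfg: TrainConfig) -> ModelBundle:
    """Variational aligning stage: train M_skel / M_reba and fine-tune both
    encoders under the joint alignment loss; D_skel stays frozen by
    default. Returns the bundle tagged ``aligned``."""
    if bundle.phase == "init":
        raise RuntimeError("train_phase2 requires a phase-1-trained bundle")
    train, val = _val_split(data, cfg)
    rng = np.random.default_rng(cfg.seed + 2)

    modules = [bundle.m_skel, bundle.m_reba, bundle.e_ms, bundle.e_t,
               bundle.e_reba]
    if not cfg.freeze_decoder_phase2:
        modules.append(bundle.d_skel)
    params = [p for m in modules for p in m.parameters()]
    opt = Adam(params, lr=cfg.learning_rate * cfg.phase2_lr_factor)

    def epoch_fn(_):
        losses = []
        for idx in _batches(len(train), cfg.batch_size, rng):
            streams = {k: v[idx] for k, v in train.streams.items()}
            loss = loss_align(streams, train.targets[idx], bundle,
                              cfg.beta, cfg.gamma, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def val_fn():
        with no_grad():
            dist = bundle.m_skel(bundle.encode_skel(val.streams))
            pred = bundle.d_skel(dist.mu)
            return float(loss_skel_vae(pred, val.targets, dist,
                                       cfg.beta).data)

    def snap():
        return [[a.copy() for a in m.state_arrays()] for m in modules]

    def rest(state):
        for m, arrays in zip(modules, state):
            m.load_state_arrays(arrays)

    _early_stop_loop(epoch_fn, val_fn, snap, rest, cfg, "phase 2 (align)")
    bundle.phase = "aligned"
    return bundle


# ---------------------------------------------------------------------------
# inference and evaluation

def predict(inputs, bundle: ModelBundle, use_alignment: bool | None = None,
            sample_rng: np.random.Generator | None = None):
    """Regress 6-component score vectors.

    ``inputs`` may be a SkeletonSequence, a single SkeletonFrame, a
    StreamFeatures instance, or a dict of stream arrays. Inference is
    deterministic (latent mean) unless ``sample_rng`` is given.
    """
    from .features import stream_features_for_frame

    single = False
    if isinstance(inputs, SkeletonSequence):
        streams = sequence_stream_features(inputs)
    elif isinstance(inputs, SkeletonFrame):
        sf = stream_features_for_frame(inputs)
        streams = {k: getattr(sf, k)[None, :] for k in
                   ("trunk", "arms", "legs")}
        single = True
    elif isinstance(inputs, StreamFeatures):
        streams = {k: getattr(inputs, k)[None, :] for k in
                   ("trunk", "arms", "legs")}
        single = True
    elif isinstance(inputs, dict):
        streams = {k: np.atleast_2d(np.asarray(v, dtype=np.float64))
                   for k, v in inputs.items()}
    else:
        raise TypeError(f"cannot predict from {type(inputs).__name__}")
    scores = bundle.predict_scores(streams, use_alignment=use_alignment,
                                   rng=sample_rng)
    vectors = [RebaScoreVector.from_array(row) for row in scores]
    return vectors[0] if single else vectors


@dataclass
class EvalReport:
    """Per-component regression metrics; ``folds`` holds per-fold values
    when k-fold grouping was requested (then the scalar fields are
    across-fold means and ``std`` the across-fold deviations)."""

    mse: dict
    mae: dict
    rmse: dict
    std: dict | None = None
    folds: list | None = None


def _metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    err = pred - truth
    mse = (err ** 2).mean(axis=0)
    return {"mse": mse, "mae": np.abs(err).mean(axis=0),
            "rmse": np.sqrt(mse)}


def _as_array(scores) -> np.ndarray:
    if isinstance(scores, np.ndarray):
        return np.asarray(scores, dtype=np.float64)
    return np.stack([s.as_array() if isinstance(s, RebaScoreVector)
                     else np.asarray(s, dtype=np.float64) for s in scores])


def evaluate(pred, truth, groups: np.ndarray | None = None,
             n_folds: int = 4) -> EvalReport:
    """MSE / MAE / RMSE per score component.

    With ``groups``, sequences are dealt round-robin into ``n_folds`` folds
    and metrics are reported as mean +/- std across folds.
    """
    p, t = _as_array(pred), _as_array(truth)
    if p.shape != t.shape or p.ndim != 2 or p.shape[1] != K_TARGET:
        raise ValueError(
            f"prediction/truth shape mismatch: {p.shape} vs {t.shape}")
    if len(p) == 0:
        raise ValueError("cannot evaluate empty inputs")

    def pack(m):
        return {name: {k: float(m[k][i]) for k in ("mse", "mae", "rmse")}
                for i, name in enumerate(SCORE_COMPONENTS)}

    if groups is None:
        m = _metrics(p, t)
        return EvalReport(
            mse={n: v["mse"] for n, v in pack(m).items()},
            mae={n: v["mae"] for n, v in pack(m).items()},
            rmse={n: v["rmse"] for n, v in pack(m).items()})

    groups = np.asarray(groups)
    uniq = np.unique(groups)
    fold_of = {g: i % n_folds for i, g in enumerate(uniq)}
    fold_metrics = []
    for f in range(n_folds):
        mask = np.array([fold_of[g] == f for g in groups])
        if mask.any():
            fold_metrics.append(_metrics(p[mask], t[mask]))
    stack = {k: np.stack([fm[k] for fm in fold_metrics])
             for k in ("mse", "mae", "rmse")}
    mean = {k: v.mean(axis=0) for k, v in stack.items()}
    names = SCORE_COMPONENTS
    return EvalReport(
        mse={n: float(mean["mse"][i]) for i, n in enumerate(names)},
        mae={n: float(mean["mae"][i]) for i, n in enumerate(names)},
        rmse={n: float(mean["rmse"][i]) for i, n in enumerate(names)},
        std={k: {n: float(stack[k].std(axis=0)[i])
                 for i, n in enumerate(names)} for k in stack},
        folds=[{k: fm[k].tolist() for k in fm} for fm in fold_metrics])
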