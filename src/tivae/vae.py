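"""Variational autoencoder embedding of stacked expression rows.

A single-hidden-layer VAE: an affine + rectified-linear encoder stage feeds
two affine heads producing the latent mean mu and log-variance; the decoder
is one affine map with sigmoid activation back to the [0, 1]-scaled gene
space. The latent width defaults to the number of tissues so each unit can
specialize on one tissue. Cases and controls are embedded by separate
models, and the whole procedure is repeated with shifted seeds to assess
repeatability; downstream gene ranking reads the decoder weight matrix
(latent units x genes).

Loss = per-gene binary cross-entropy summed over genes (the natural negative
log-likelihood for [0, 1]-scaled data under a sigmoid decoder) plus
``warmup_kappa`` times the KL divergence of the latent Gaussian from the
standard-normal prior. The reparameterization trick (z = mu + sigma * eps)
is used during training only; :func:`encode` returns the deterministic mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .preprocessing import StackedDataset, split_stratified

__all__ = [
    "VAEConfig",
    "VAEModel",
    "TrainingHistory",
    "kl_divergence",
    "vae_loss_and_grads",
    "train_vae",
    "encode",
    "run_repeated_vaes",
]


class VAETrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class VAEConfig:
    """Training hyperparameters; defaults follow the full-scale protocol."""

    latent_dim: int = 42
    learning_rate: float = 0.001
    epochs: int = 75
    batch_size: int = 500
    warmup_kappa: float = 1.0
    n_repeats: int = 75
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("latent_dim", "epochs", "batch_size", "n_repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch loss decomposition on train and (optional) held-out rows."""

    epochs: list[int] = field(default_factory=list)
    train_total: list[float] = field(default_factory=list)
    train_reconstruction: list[float] = field(default_factory=list)
    train_kl: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)
    val_reconstruction: list[float] = field(default_factory=list)
    val_kl: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        data = {
            "epoch": self.epochs,
            "train_total": self.train_total,
            "train_reconstruction": self.train_reconstruction,
            "train_kl": self.train_kl,
        }
        if self.val_total:
            data.update(
                val_total=self.val_total,
                val_reconstruction=self.val_reconstruction,
                val_kl=self.val_kl,
            )
        return pd.DataFrame(data)


class VAEModel:
    """Trained VAE: batch-normalized rectified mu/log-variance heads, sigmoid decoder.

    The latent layer is the single hidden layer: each head is an affine map
    from the gene space followed by batch normalization and a rectified
    linear unit, so latent activations are non-negative — which breaks the
    rotational symmetry of the latent space and lets individual units
    specialize (the property the tissue-matching stage relies on).
    ``decoder_weights`` (latent_dim x n_genes) is the matrix downstream gene
    prioritization ranks; ``gene_universe`` fixes the column contract for
    :func:`encode`.
    """

    def __init__(self, n_genes: int, latent_dim: int, rng: np.random.Generator,
                 gene_universe: list[str] | None = None):
        self.latent_dim = latent_dim
        self.n_genes = n_genes
        self.gene_universe = list(gene_universe) if gene_universe is not None else None
        self.mu_dense = nn.Dense(n_genes, latent_dim, rng)
        self.mu_bn = nn.BatchNorm(latent_dim)
        self.logvar_dense = nn.Dense(n_genes, latent_dim, rng)
        self.logvar_bn = nn.BatchNorm(latent_dim)
        self.decoder = nn.Dense(latent_dim, n_genes, rng)
        self.repeat: int | None = None
        self.class_tag: str | None = None

    @property
    def decoder_weights(self) -> np.ndarray:
        return self.decoder.W.value

    @property
    def decoder_bias(self) -> np.ndarray:
        return self.decoder.b.value

    def params(self) -> list[nn.Param]:
        return (
            self.mu_dense.params()
            + self.mu_bn.params()
            + self.logvar_dense.params()
            + self.logvar_bn.params()
            + self.decoder.params()
        )

    # -- forward pieces -----------------------------------------------------
    def encode_mu_logvar(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        mu_pre = self.mu_bn.forward(self.mu_dense.forward(x), train=train)
        self._mu_mask = mu_pre > 0
        lv_pre = self.logvar_bn.forward(self.logvar_dense.forward(x), train=train)
        self._lv_mask = lv_pre > 0
        return mu_pre * self._mu_mask, lv_pre * self._lv_mask

    def backward_heads(self, dmu: np.ndarray, dlogvar: np.ndarray) -> None:
        self.mu_dense.backward(self.mu_bn.backward(dmu * self._mu_mask))
        self.logvar_dense.backward(self.logvar_bn.backward(dlogvar * self._lv_mask))

    def decode(self, z: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.decoder.forward(z))

    def losses(self, x: np.ndarray, kappa: float) -> tuple[float, float, float]:
        """Deterministic (z = mu, running batch-norm stats) loss decomposition."""
        mu, logvar = self.encode_mu_logvar(x, train=False)
        xhat = self.decode(mu)
        rec = float(_bce_sum(x, xhat).mean())
        kl = float(_kl_rows(mu, logvar).mean())
        return rec + kappa * kl, rec, kl


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(N(mu, exp(logvar)) || N(0, I)) in closed form for one latent vector.

    Equals ``-0.5 * sum(1 + logvar - mu^2 - exp(logvar))``; non-negative, zero
    exactly when the posterior matches the standard-normal prior.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar must have equal shapes")
    if not (np.isfinite(mu).all() and np.isfinite(logvar).all()):
        raise ValueError("non-finite values in mu/logvar")
    return float(-0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar)))


def _kl_rows(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    return -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)


def _bce_sum(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    eps = 1e-12
    return -np.sum(x * np.log(xhat + eps) + (1.0 - x) * np.log(1.0 - xhat + eps), axis=1)


def vae_loss_and_grads(
    model: VAEModel, x: np.ndarray, eps: np.ndarray, kappa: float
) -> float:
    """One training-mode forward/backward pass; accumulates parameter gradients.

    The reparameterized sample is z = mu + exp(logvar / 2) * eps with the
    noise ``eps`` supplied by the caller, which keeps the pass a
    deterministic function of (parameters, x, eps) — the property the
    finite-difference gradient checks rely on. Returns the batch loss
    (mean row-wise binary cross-entropy summed over genes + kappa * KL).
    """
    B = x.shape[0]
    mu, logvar = model.encode_mu_logvar(x, train=True)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    logits = model.decoder.forward(z)
    xhat = nn.sigmoid(logits)

    loss = float(_bce_sum(x, xhat).mean() + kappa * _kl_rows(mu, logvar).mean())

    dlogits = (xhat - x) / B  # fused sigmoid + BCE gradient
    dz = model.decoder.backward(dlogits)
    dmu = dz + kappa * mu / B
    dlogvar = dz * eps * 0.5 * sigma + kappa * 0.5 * (np.exp(logvar) - 1.0) / B
    model.backward_heads(dmu, dlogvar)
    return loss


def train_vae(
    train: np.ndarray | StackedDataset,
    config: VAEConfig,
    val: np.ndarray | None = None,
    gene_universe: list[str] | None = None,
) -> tuple[VAEModel, TrainingHistory]:
    """Train one VAE on [0, 1]-scaled rows with Adam.

    Gradients are exact manual backpropagation through the reparameterized
    sample; the final partial batch is trained on (batch size is clamped to
    the row count for small inputs). Raises on a non-finite loss, naming the
    epoch. Deterministic given ``config.seed``.
    """
    if isinstance(train, StackedDataset):
        gene_universe = train.gene_universe
        train = train.matrix
    x_all = np.asarray(train, dtype=np.float64)
    if x_all.ndim != 2 or x_all.shape[0] == 0:
        raise ValueError("training input must be a non-empty 2-D array")
    if x_all.min() < 0.0 or x_all.max() > 1.0:
        raise ValueError("training values must lie in [0, 1]; scale first")

    rng = np.random.default_rng(config.seed)
    model = VAEModel(x_all.shape[1], config.latent_dim, rng, gene_universe)
    optimizer = nn.Adam(model.params(), learning_rate=config.learning_rate)
    batch_size = min(config.batch_size, x_all.shape[0])
    kappa = config.warmup_kappa
    history = TrainingHistory()

    for epoch in range(config.epochs):
        order = rng.permutation(x_all.shape[0])
        for start in range(0, x_all.shape[0], batch_size):
            x = x_all[order[start : start + batch_size]]
            B = x.shape[0]

            eps = rng.standard_normal((x.shape[0], config.latent_dim))
            optimizer.zero_grad()
            loss = vae_loss_and_grads(model, x, eps, kappa)
            if not np.isfinite(loss):
                raise VAETrainingError(f"non-finite loss at epoch {epoch + 1}")
            optimizer.step()

        total, rec, kl = model.losses(x_all, kappa)
        history.epochs.append(epoch + 1)
        history.train_total.append(total)
        history.train_reconstruction.append(rec)
        history.train_kl.append(kl)
        if val is not None:
            v_total, v_rec, v_kl = model.losses(np.asarray(val, dtype=np.float64), kappa)
            history.val_total.append(v_total)
            history.val_reconstruction.append(v_rec)
            history.val_kl.append(v_kl)

    return model, history


def encode(model: VAEModel, rows: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Latent activations (the deterministic mu head) for scaled rows."""
    if isinstance(rows, pd.DataFrame):
        if model.gene_universe is not None:
            missing = [g for g in model.gene_universe if g not in rows.columns]
            if missing:
                raise ValueError(
                    f"{len(missing)} genes of the training universe are missing, "
                    f"e.g. {missing[:5]}"
                )
            rows = rows[model.gene_universe]
        rows = rows.to_numpy()
    rows = np.asarray(rows, dtype=np.float64)
    if rows.shape[1] != model.n_genes:
        raise ValueError(
            f"expected {model.n_genes} gene columns, got {rows.shape[1]}"
        )
    mu, _ = model.encode_mu_logvar(rows)
    return mu


def run_repeated_vaes(
    cases: StackedDataset,
    controls: StackedDataset,
    config: VAEConfig,
) -> tuple[list[VAEModel], list[VAEModel]]:
    """Train ``n_repeats`` VAEs per class on fresh tissue-stratified 80/20 splits.

    Repeat ``r`` uses seed ``config.seed + r`` for both the split and the
    training; models carry their repeat index and class tag. Case and control
    rows are embedded by entirely separate models.
    """
    if cases.n_rows == 0 or controls.n_rows == 0:
        raise ValueError("both class partitions must be non-empty")
    collections: tuple[list[VAEModel], list[VAEModel]] = ([], [])
    for tag, data, store in (("case", cases, collections[0]), ("control", controls, collections[1])):
        for r in range(config.n_repeats):
            repeat_seed = config.seed + r
            split = split_stratified(data, config.train_fraction, key="tissue", seed=repeat_seed)
            repeat_cfg = VAEConfig(
                latent_dim=config.latent_dim,
                learning_rate=config.learning_rate,
                epochs=config.epochs,
                batch_size=config.batch_size,
                warmup_kappa=config.warmup_kappa,
                n_repeats=config.n_repeats,
                train_fraction=config.train_fraction,
                seed=repeat_seed,
            )
            model, _ = train_vae(
                data.matrix[split.train_rows],
                repeat_cfg,
                val=data.matrix[split.test_rows],
                gene_universe=data.gene_universe,
            )
            model.repeat = r
            model.class_tag = tag
            store.append(model)
    return collections
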