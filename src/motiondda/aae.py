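"""Adversarial autoencoder with a 2-D latent space and a polar-rose prior.

The model couples a dense autoencoder (64-value flattened motion -> 2-D
latent point -> reconstruction) with a discriminator that learns to tell
encoder outputs from draws of a six-component Gaussian mixture arranged like
a polar rose.  Each epoch alternates three minibatch steps:

1. reconstruction — minimise the mean squared error L_AE over encoder and
   decoder;
2. discriminator — minimise the cross-entropy L_D separating prior samples
   (target 1) from encoder outputs (target 0), encoder frozen;
3. generator — update the encoder alone to minimise L_G, the cross-entropy
   with encoder outputs relabelled as 1 (the non-saturating convention), so
   the aggregated latent distribution is pushed toward the prior.

In unsupervised mode (UAAE) the prior component is drawn uniformly; in
semi-supervised mode (SSAAE) the one-hot motion label is concatenated to the
discriminator input and prior samples come from the label's own component, so
label information shapes the latent layout without ever reaching the encoder.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from motiondda.latent_eval import LatentEmbedding, mean_cluster_kl
from motiondda.nn import MLP, Adam, _sigmoid
from motiondda.shapes import LABELS, MotionMatrix

# hyperparameter vocabulary for the architecture search
HIDDEN_LAYER_CHOICES = (2, 3)
WIDTH_CHOICES = (4, 8, 16, 32, 64, 128, 256, 512)
AE_ACTIVATIONS = ("sigmoid", "tanh", "relu")
DISC_ACTIVATIONS = ("sigmoid", "relu")
LEARNING_RATE_CHOICES = (0.01, 0.005, 0.001, 0.0005, 0.0001)
DROPOUT_CHOICES = (0.0, 0.1, 0.2, 0.3, 0.4)

_BCE_EPS = 1e-7


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: pd.DataFrame):
        super().__init__(message)
        self.history = history


@dataclass
class PriorMixture:
    """Six 2-D Gaussian components on a circle — the latent regularisation target.

    Component i sits at angle 2*pi*i/6 on a circle of radius ``radius``; its
    covariance is anisotropic with the long axis pointing radially
    (``sigma_radial`` outward, ``sigma_tangential`` across), which gives the
    petal-like polar-rose layout.
    """

    n_components: int = 6
    radius: float = 4.0
    sigma_radial: float = 1.0
    sigma_tangential: float = 0.5

    def _angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_components) / self.n_components

    def means(self) -> np.ndarray:
        a = self._angles()
        return self.radius * np.column_stack([np.cos(a), np.sin(a)])

    def covariances(self) -> np.ndarray:
        covs = np.empty((self.n_components, 2, 2))
        base = np.diag([self.sigma_radial**2, self.sigma_tangential**2])
        for i, a in enumerate(self._angles()):
            rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            covs[i] = rot @ base @ rot.T
        return covs


def sample_prior(
    mixture: PriorMixture,
    n: int,
    labels_or_none: np.ndarray | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n latent points from the prior.

    Without labels the component is chosen uniformly per point; with labels
    each point is drawn from the component matching its label index.  Returns
    the points and the component indices used.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if labels_or_none is None:
        comp = rng.integers(0, mixture.n_components, size=n)
    else:
        comp = np.asarray(labels_or_none, dtype=int)
        if len(comp) != n:
            raise ValueError("labels length must equal n")
        if comp.min() < 0 or comp.max() >= mixture.n_components:
            raise ValueError(
                f"label index out of range [0, {mixture.n_components}): "
                f"{comp.min()}..{comp.max()}"
            )
    means = mixture.means()
    covs = mixture.covariances()
    # factor each covariance once; handles the degenerate zero-covariance case
    factors = []
    for c in covs:
        w, v = np.linalg.eigh(c)
        factors.append(v @ np.diag(np.sqrt(np.clip(w, 0.0, None))))
    z = rng.standard_normal((n, 2))
    pts = np.empty((n, 2))
    for k in range(mixture.n_components):
        mask = comp == k
        pts[mask] = means[k] + z[mask] @ factors[k].T
    return pts, comp


def reconstruction_loss(X: np.ndarray, X_prime: np.ndarray) -> float:
    """Mean squared error over all coordinate entries."""
    X = np.asarray(X, dtype=float)
    X_prime = np.asarray(X_prime, dtype=float)
    if X.shape != X_prime.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_prime.shape}")
    return float(np.mean((X_prime - X) ** 2))


def binary_cross_entropy(targets: np.ndarray, predictions: np.ndarray) -> float:
    """Mean binary cross-entropy; predictions are clamped to [eps, 1-eps]."""
    y = np.asarray(targets, dtype=float)
    p = np.clip(np.asarray(predictions, dtype=float), _BCE_EPS, 1.0 - _BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class AAEConfig:
    """Architecture and training configuration.

    ``hidden_widths`` applies to the encoder; the decoder mirrors it in
    reverse and the discriminator reuses the same stack.  ``mode`` selects
    unsupervised or semi-supervised adversarial training.
    """

    hidden_widths: tuple[int, ...] = (64, 64)
    ae_activation: str = "relu"
    disc_activation: str = "relu"
    learning_rate: float = 0.001
    dropout: float = 0.0
    batch_size: int = 64
    latent_dim: int = 2
    mode: str = "unsupervised"
    max_epochs: int = 300
    patience: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if len(self.hidden_widths) not in HIDDEN_LAYER_CHOICES:
            raise ValueError(f"hidden layer count must be in {HIDDEN_LAYER_CHOICES}")
        for w in self.hidden_widths:
            if w not in WIDTH_CHOICES:
                raise ValueError(f"width {w} not in vocabulary {WIDTH_CHOICES}")
        if self.ae_activation not in AE_ACTIVATIONS:
            raise ValueError(f"ae_activation must be one of {AE_ACTIVATIONS}")
        if self.disc_activation not in DISC_ACTIVATIONS:
            raise ValueError(f"disc_activation must be one of {DISC_ACTIVATIONS}")
        if self.mode not in ("unsupervised", "semi_supervised"):
            raise ValueError("mode must be 'unsupervised' or 'semi_supervised'")
        if self.latent_dim != 2:
            raise ValueError("latent_dim is fixed to 2 in this pipeline")


@dataclass
class TrainedAAE:
    """Trained encoder (plus decoder/discriminator) and its training history."""

    encoder: MLP
    decoder: MLP
    discriminator: MLP
    config: AAEConfig
    mixture: PriorMixture
    history: pd.DataFrame
    best_epoch: int = -1

    def encode(self, motions) -> np.ndarray:
        return encode(self, motions)

    def save(self, path: str | Path) -> None:
        """Single-file npz checkpoint with a JSON history sidecar."""
        path = Path(path)
        arrays = {}
        for name, net in (("enc", self.encoder), ("dec", self.decoder),
                          ("disc", self.discriminator)):
            for i, p in enumerate(net.params):
                arrays[f"{name}_{i}"] = p
        meta = {
            "config": asdict(self.config),
            "mixture": asdict(self.mixture),
            "best_epoch": self.best_epoch,
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        self.history.to_json(path.with_suffix(".history.json"), orient="records")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedAAE":
        path = Path(path)
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        config = AAEConfig(**{**meta["config"],
                              "hidden_widths": tuple(meta["config"]["hidden_widths"])})
        mixture = PriorMixture(**meta["mixture"])
        enc, dec, disc = _build_networks(config, np.random.default_rng(0))
        model = cls(enc, dec, disc, config, mixture,
                    pd.read_json(path.with_suffix(".history.json"), orient="records")
                    if path.with_suffix(".history.json").exists() else pd.DataFrame(),
                    best_epoch=meta["best_epoch"])
        for name, net in (("enc", enc), ("dec", dec), ("disc", disc)):
            net.set_state([data[f"{name}_{i}"] for i in range(len(net.params))])
        return model


def _build_networks(config: AAEConfig, rng: np.random.Generator) -> tuple[MLP, MLP, MLP]:
    n_in = 2 * 32
    widths = list(config.hidden_widths)
    disc_in = config.latent_dim + (len(LABELS) if config.mode == "semi_supervised" else 0)
    enc = MLP([n_in, *widths, config.latent_dim], config.ae_activation, config.dropout, rng)
    dec = MLP([config.latent_dim, *widths[::-1], n_in], config.ae_activation,
              config.dropout, rng)
    disc = MLP([disc_in, *widths, 1], config.disc_activation, config.dropout, rng)
    return enc, dec, disc


def _as_matrix(motions) -> np.ndarray:
    """Accept (n,64) arrays, (n,32,2) arrays, or sequences of motions."""
    if isinstance(motions, np.ndarray):
        if motions.ndim == 3:
            return motions.reshape(motions.shape[0], -1)
        return np.atleast_2d(motions)
    rows = []
    for m in motions:
        if isinstance(m, MotionMatrix):
            rows.append(m.flattened())
        elif hasattr(m, "motion"):  # AnnotatedMotion
            rows.append(m.motion.flattened())
        else:
            rows.append(np.asarray(m, dtype=float).reshape(-1))
    return np.stack(rows)


def _onehot(labels: np.ndarray) -> np.ndarray:
    out = np.zeros((len(labels), len(LABELS)))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _disc_input(z: np.ndarray, y: np.ndarray, semi: bool) -> np.ndarray:
    return np.concatenate([z, _onehot(y)], axis=1) if semi else z


def _recon_step(enc: MLP, dec: MLP, opt_ae: Adam, Xb: np.ndarray,
                rng: np.random.Generator) -> float:
    """Reconstruction step: encoder + decoder minimise the MSE L_AE."""
    z = enc.forward(Xb, train=True, rng=rng)
    Xr = dec.forward(z, train=True, rng=rng)
    l_ae = reconstruction_loss(Xb, Xr)
    grad = 2.0 * (Xr - Xb) / Xr.size
    enc.backward(dec.backward(grad))
    opt_ae.step(enc.grads + dec.grads)
    return l_ae


def _disc_step(enc: MLP, disc: MLP, opt_d: Adam, Xb: np.ndarray, yb: np.ndarray,
               mixture: PriorMixture, semi: bool, rng: np.random.Generator) -> float:
    """Discriminator step: prior samples (target 1) vs encoder outputs
    (target 0); the encoder is frozen and evaluated without dropout."""
    nb = len(Xb)
    zq = enc.forward(Xb, train=False)
    zp, _ = sample_prior(mixture, nb, yb if semi else None, rng)
    d_in = np.concatenate([_disc_input(zp, yb, semi), _disc_input(zq, yb, semi)])
    targets = np.concatenate([np.ones(nb), np.zeros(nb)])[:, None]
    probs = _sigmoid(disc.forward(d_in, train=True, rng=rng))
    l_d = binary_cross_entropy(targets, probs)
    disc.backward((probs - targets) / len(targets))
    opt_d.step(disc.grads)
    return l_d


def _gen_step(enc: MLP, disc: MLP, opt_g: Adam, Xb: np.ndarray, yb: np.ndarray,
              semi: bool, latent_dim: int, rng: np.random.Generator) -> float:
    """Generator step: encoder outputs relabelled 1 (non-saturating
    convention); gradients flow through the frozen discriminator, whose
    parameters are never stepped."""
    nb = len(Xb)
    zq = enc.forward(Xb, train=True, rng=rng)
    probs = _sigmoid(disc.forward(_disc_input(zq, yb, semi), train=False))
    l_g = binary_cross_entropy(np.ones((nb, 1)), probs)
    grad_in = disc.backward((probs - 1.0) / nb)
    enc.backward(grad_in[:, :latent_dim])
    opt_g.step(enc.grads)
    return l_g


def train_aae(
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: AAEConfig,
    mixture: PriorMixture | None = None,
) -> TrainedAAE:
    """Train an adversarial autoencoder on flattened motion matrices.

    Parameters
    ----------
    train_data, val_data
        Pairs (X, y): inputs of shape (n, 64) and integer label indices.
        Labels are required even in unsupervised mode (they drive the
        semi-supervised discriminator and the validation metric only; the
        encoder never sees them).
    config
        Architecture/training configuration; all randomness derives from
        ``config.rng_seed``.
    mixture
        The latent prior; defaults to the standard polar rose.

    Early stopping monitors the mean cluster KL on the validation embedding
    in semi-supervised mode (where cluster-to-component assignment is fixed
    by the labels) and the validation reconstruction error in unsupervised
    mode; the returned model carries the parameters of the best epoch.
    """
    mixture = mixture or PriorMixture()
    X_train, y_train = _as_matrix(train_data[0]), np.asarray(train_data[1], dtype=int)
    X_val, y_val = _as_matrix(val_data[0]), np.asarray(val_data[1], dtype=int)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.rng_seed)
    enc, dec, disc = _build_networks(config, rng)
    opt_ae = Adam(enc.params + dec.params, config.learning_rate)
    opt_d = Adam(disc.params, config.learning_rate)
    opt_g = Adam(enc.params, config.learning_rate)
    semi = config.mode == "semi_supervised"
    history_rows = []
    best_metric = np.inf
    best_state = None
    best_epoch = -1
    n = len(X_train)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        ep_ae, ep_d, ep_g, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            Xb, yb = X_train[idx], y_train[idx]
            l_ae = _recon_step(enc, dec, opt_ae, Xb, rng)
            l_d = _disc_step(enc, disc, opt_d, Xb, yb, mixture, semi, rng)
            l_g = _gen_step(enc, disc, opt_g, Xb, yb, semi, config.latent_dim, rng)
            ep_ae += l_ae
            ep_d += l_d
            ep_g += l_g
            n_batches += 1

        z_val = enc.forward(X_val, train=False)
        if semi:
            val_metric = mean_cluster_kl(LatentEmbedding(z_val, y_val), mixture)
        else:
            val_metric = reconstruction_loss(X_val, dec.forward(z_val, train=False))
        row = {
            "epoch": epoch,
            "L_AE": ep_ae / n_batches,
            "L_D": ep_d / n_batches,
            "L_G": ep_g / n_batches,
            "val_metric": val_metric,
        }
        history_rows.append(row)
        if not all(np.isfinite(v) for v in row.values()):
            raise TrainingDiverged(
                f"non-finite loss at epoch {epoch}", pd.DataFrame(history_rows)
            )
        if val_metric < best_metric - 1e-12:
            best_metric = val_metric
            best_state = (enc.get_state(), dec.get_state(), disc.get_state())
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break

    if best_state is not None:
        enc.set_state(best_state[0])
        dec.set_state(best_state[1])
        disc.set_state(best_state[2])
    return TrainedAAE(enc, dec, disc, config, mixture,
                      pd.DataFrame(history_rows), best_epoch=best_epoch)


def encode(model: TrainedAAE, motions) -> np.ndarray:
    """Deterministic 2-D embedding of motions (dropout disabled)."""
    X = _as_matrix(motions)
    return model.encoder.forward(X, train=False)


def embed_dataset(model: TrainedAAE, dataset) -> LatentEmbedding:
    """Embed an :class:`~motiondda.augment.ArtificialDataset` with annotations."""
    X, y = dataset.arrays()
    pts = encode(model, X)
    sched = np.array([it.schedule_index for it in dataset.items])
    noise = np.array([it.noise_index for it in dataset.items])
    return LatentEmbedding(pts, y, schedule_index=sched, noise_index=noise)
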