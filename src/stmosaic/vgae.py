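"""Masked variational graph autoencoder.

Encoder: two dense layers produce a feature embedding Z_f; a shared graph
convolution followed by two parallel graph convolutions produce the
posterior mean and log-variance; the reparameterized sample Z_g is added
to Z_f to give the final embedding Z.  Decoders: inner-product adjacency
reconstruction and a single linear graph convolution back to the reduced
expression space.  Losses: adjacency MSE, Gaussian KL to the standard
normal, and a scaled cosine error on masked rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._autograd import Parameter, Tensor, exp, relu, sigmoid, spmm
from ._nn import Adam, BatchNorm1d, Linear, Module, glorot

__all__ = [
    "MaskedVGAE",
    "LatentEmbedding",
    "reparameterize",
    "decode_adjacency",
    "loss_graph",
    "loss_kl",
    "loss_sce",
    "loss_vgae",
]


@dataclass
class LatentEmbedding:
    """All per-spot latent matrices from one encoder pass (numpy copies)."""

    Z_f: np.ndarray
    mu: np.ndarray
    logvar: np.ndarray
    Z_g: np.ndarray
    Z: np.ndarray

    def __post_init__(self):
        shapes = {m.shape for m in (self.Z_f, self.mu, self.logvar, self.Z_g, self.Z)}
        if len(shapes) != 1:
            raise ValueError(f"latent matrices disagree in shape: {shapes}")


def reparameterize(
    mu: Tensor | np.ndarray,
    logvar: Tensor | np.ndarray,
    eps: np.ndarray,
    mode: str = "standard",
) -> Tensor | np.ndarray:
    """Draw Z_g from the posterior.

    ``standard``: mu + exp(logvar/2) * eps (the usual trick, default).
    ``literal``: mu + logvar * eps (as-printed variant, kept for
    faithfulness experiments; collapses to mu when logvar == 0).
    """
    if mode not in ("standard", "literal"):
        raise ValueError(f"unknown reparameterization mode {mode!r}")
    if isinstance(mu, Tensor):
        if mode == "standard":
            return mu + exp(logvar * 0.5) * Tensor(eps)
        return mu + logvar * Tensor(eps)
    if mode == "standard":
        return mu + np.exp(0.5 * logvar) * eps
    return mu + logvar * eps


class MaskedVGAE(Module):
    """dims: input m -> FC (64) -> FC (d_f=16) = Z_f; GCN 16->64->16 for mu/logvar."""

    def __init__(
        self,
        in_dim: int,
        fc_hidden: int = 64,
        latent_dim: int = 16,
        gcn_hidden: int = 64,
        seed: int = 0,
        logvar_activation: bool = True,
        reparam_mode: str = "standard",
    ):
        super().__init__()
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0xA11])))
        self.in_dim = in_dim
        self.latent_dim = latent_dim
        self.logvar_activation = logvar_activation
        self.reparam_mode = reparam_mode

        self.fc1 = Linear(in_dim, fc_hidden, rng)
        self.fc2 = Linear(fc_hidden, latent_dim, rng)
        self.W0 = Parameter(glorot(rng, latent_dim, gcn_hidden))
        self.bn0 = BatchNorm1d(gcn_hidden)
        self.W_mu = Parameter(glorot(rng, gcn_hidden, latent_dim))
        self.bn_mu = BatchNorm1d(latent_dim)
        self.W_sigma = Parameter(glorot(rng, gcn_hidden, latent_dim))
        self.bn_sigma = BatchNorm1d(latent_dim)
        self.decoder_W = Parameter(glorot(rng, latent_dim, in_dim))
        self.decoder_b = Parameter(np.zeros(in_dim))
        self.mask_vector = Parameter(np.zeros((1, in_dim)))

    # -- forward pieces -------------------------------------------------------
    def encode(
        self, X_mask: Tensor | np.ndarray, A_hat: sp.spmatrix, eps: np.ndarray | None = None
    ) -> dict[str, Tensor]:
        X_mask = X_mask if isinstance(X_mask, Tensor) else Tensor(X_mask)
        if X_mask.shape[1] != self.in_dim:
            raise ValueError(
                f"input has {X_mask.shape[1]} features but encoder expects {self.in_dim}"
            )
        if A_hat.shape[0] != X_mask.shape[0]:
            raise ValueError(
                f"A_hat is {A_hat.shape} but X has {X_mask.shape[0]} rows"
            )
        Z_f = self.fc2(relu(self.fc1(X_mask)))
        H = relu(self.bn0(spmm(A_hat, Z_f @ self.W0)))
        mu = relu(self.bn_mu(spmm(A_hat, H @ self.W_mu)))
        logvar_pre = self.bn_sigma(spmm(A_hat, H @ self.W_sigma))
        logvar = relu(logvar_pre) if self.logvar_activation else logvar_pre
        if eps is None:
            eps = np.zeros(mu.shape)
        Z_g = reparameterize(mu, logvar, eps, mode=self.reparam_mode)
        Z = Z_f + Z_g
        return {"Z_f": Z_f, "mu": mu, "logvar": logvar, "Z_g": Z_g, "Z": Z}

    def encode_numpy(
        self, X_mask: np.ndarray, A_hat: sp.spmatrix, eps: np.ndarray | None = None
    ) -> LatentEmbedding:
        out = self.encode(X_mask, A_hat, eps=eps)
        return LatentEmbedding(**{k: v.data.copy() for k, v in out.items()})

    def decode_expression(self, Z: Tensor, A_hat: sp.spmatrix) -> Tensor:
        """Single linear graph convolution back to the reduced expression space."""
        return spmm(A_hat, Z) @ self.decoder_W + self.decoder_b


def decode_adjacency(Z: Tensor | np.ndarray) -> Tensor | np.ndarray:
    """Inner-product decoder: sigmoid(Z Z^T), symmetric with entries in (0,1)."""
    if isinstance(Z, Tensor):
        return sigmoid(Z @ Z.T)
    return 1.0 / (1.0 + np.exp(-(Z @ Z.T)))


# -- losses (tensor-aware; return Tensor if any input is a Tensor) ------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _maybe_scalar(x: Tensor, want_tensor: bool):
    return x if want_tensor else float(x.data)


def loss_graph(A, A_tilde):
    """Mean squared difference over all n^2 adjacency entries."""
    want = isinstance(A, Tensor) or isinstance(A_tilde, Tensor)
    A, A_tilde = _as_tensor(A), _as_tensor(A_tilde)
    if A.shape != A_tilde.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {A_tilde.shape}")
    return _maybe_scalar(((A - A_tilde) ** 2).mean(), want)


def loss_kl(mu, logvar):
    """Analytic Gaussian KL to N(0, I), averaged over spots."""
    want = isinstance(mu, Tensor) or isinstance(logvar, Tensor)
    mu, logvar = _as_tensor(mu), _as_tensor(logvar)
    per_spot = (-0.5) * (1.0 + logvar - mu**2 - exp(logvar)).sum(axis=1)
    return _maybe_scalar(per_spot.mean(), want)


def loss_sce(X_true, X_tilde, V_m, gamma: float = 2.0):
    """Scaled cosine error on masked rows.

    (1/|V_m|) sum_{i in V_m} (1 - cos(x_i, x~_i))^gamma, where x_i is the
    original (pre-mask) feature row and x~_i the reconstruction.  Rows of
    zero norm contribute cos = 0 (maximal direction-free penalty of 1^gamma).
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    V_m = np.asarray(V_m, dtype=int)
    if V_m.size == 0:
        raise ValueError("masked set is empty; SCE loss undefined")
    want = isinstance(X_true, Tensor) or isinstance(X_tilde, Tensor)
    X_true, X_tilde = _as_tensor(X_true), _as_tensor(X_tilde)
    a = X_true[V_m]
    b = X_tilde[V_m]
    eps = 1e-12
    na = ((a**2).sum(axis=1) + eps) ** 0.5
    nb = ((b**2).sum(axis=1) + eps) ** 0.5
    cos = (a * b).sum(axis=1) / (na * nb)
    return _maybe_scalar(((1.0 - cos) ** gamma).mean(), want)


def loss_vgae(lg, lkl, lsce):
    """Unweighted sum of the three VGAE components."""
    return lg + lkl + lsce


def make_optimizer(model: MaskedVGAE, lr: float = 5e-4, weight_decay: float = 1e-4) -> Adam:
    return Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
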