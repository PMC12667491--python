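"""Two-stage training schedule.

Stage 1 (pretraining) minimizes the VGAE loss alone.  Stage 2
(fine-tuning) adds the deep-embedded-clustering KL term (target refreshed
every ``dec_refresh`` epochs) and the cross-slice triplet term (anchors
refreshed every ``anchor_refresh`` epochs), weighted by lambda1..3.

All randomness (mask sampling, reparameterization noise, k-means,
negative sampling) derives from one root seed through named
``numpy.random.SeedSequence`` spawns, so runs are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Parameter, Tensor
from ._nn import Adam
from . import dec as dec_mod
from . import triplet as tri_mod
from .data_io import JointDataset
from .masking import MaskSpec, apply_mask_tensor, sample_mask
from .spatial_graph import normalize_adjacency
from .vgae import LatentEmbedding, MaskedVGAE, loss_graph, loss_kl, loss_sce

__all__ = ["TrainingConfig", "Trainer", "pretrain", "finetune", "overall_loss"]


@dataclass
class TrainingConfig:
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    lr: float = 5e-4
    weight_decay: float = 1e-4
    epochs_pretrain: int = 500
    epochs_finetune: int = 1000
    dec_refresh: int = 20
    anchor_refresh: int = 500
    seed: int = 0
    gamma: float = 2.0
    mask_rate: float = 0.2
    resample_mask_each_epoch: bool = False
    n_centroids: int = 20
    alpha: int = 2
    tau: float = 1.0
    nn_size: int = 50
    fc_hidden: int = 64
    latent_dim: int = 16
    gcn_hidden: int = 64
    logvar_activation: bool = True
    reparam_mode: str = "standard"

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.dec_refresh < 1 or self.anchor_refresh < 1:
            raise ValueError("refresh intervals must be >= 1")


def overall_loss(lv: float, ld: float, lt: float, config: TrainingConfig) -> float:
    return config.lambda1 * lv + config.lambda2 * ld + config.lambda3 * lt


class Trainer:
    """Holds the model, optimizer and random streams across both stages."""

    def __init__(self, dataset: JointDataset, config: TrainingConfig):
        if dataset.A is None:
            raise ValueError("dataset has no adjacency graph; build it first")
        dataset.validate()
        self.dataset = dataset
        self.config = config
        root = np.random.SeedSequence(config.seed)
        (ss_model, ss_mask, ss_eps, ss_kmeans, ss_neg) = root.spawn(5)
        self._model_seed = int(ss_model.generate_state(1)[0] % (2**31))
        self._mask_seed = int(ss_mask.generate_state(1)[0] % (2**31))
        self._kmeans_seed = int(ss_kmeans.generate_state(1)[0] % (2**31))
        self._neg_seed_root = int(ss_neg.generate_state(1)[0] % (2**31))
        self._eps_rng = np.random.Generator(np.random.PCG64(ss_eps))

        self.A_hat = normalize_adjacency(dataset.A, add_self_loops=True)
        self.A_dense = np.asarray(dataset.A.todense(), dtype=float)
        self.model = MaskedVGAE(
            in_dim=dataset.m,
            fc_hidden=config.fc_hidden,
            latent_dim=config.latent_dim,
            gcn_hidden=config.gcn_hidden,
            seed=self._model_seed,
            logvar_activation=config.logvar_activation,
            reparam_mode=config.reparam_mode,
        )
        self.optimizer = Adam(
            self.model.parameters(), lr=config.lr, weight_decay=config.weight_decay
        )
        self.mask_spec: MaskSpec = sample_mask(dataset.n, config.mask_rate, self._mask_seed)
        self.centroids: Parameter | None = None
        self.history: list[dict] = []
        self._epoch = 0
        self._refresh_count = 0

    # -- shared single step ---------------------------------------------------
    def _vgae_forward(self) -> tuple[Tensor, dict, dict]:
        cfg = self.config
        if cfg.resample_mask_each_epoch:
            self.mask_spec = sample_mask(
                self.dataset.n, cfg.mask_rate, self._mask_seed + self._epoch + 1
            )
        X = self.dataset.X
        X_mask_t = apply_mask_tensor(X, self.mask_spec, self.model.mask_vector)
        eps = self._eps_rng.standard_normal((self.dataset.n, cfg.latent_dim))
        latent = self.model.encode(X_mask_t, self.A_hat, eps=eps)
        from .vgae import decode_adjacency

        A_tilde = decode_adjacency(latent["Z"])
        X_tilde = self.model.decode_expression(latent["Z"], self.A_hat)
        lg = loss_graph(Tensor(self.A_dense), A_tilde)
        lkl = loss_kl(latent["mu"], latent["logvar"])
        if self.mask_spec.V_m.size > 0:
            lsce = loss_sce(Tensor(X), X_tilde, self.mask_spec.V_m, gamma=cfg.gamma)
        else:
            lsce = Tensor(0.0)
        lv = lg + lkl + lsce
        parts = {
            "graph": float(lg.data),
            "kl": float(lkl.data),
            "sce": float(lsce.data),
        }
        return lv, parts, latent

    def _step(self, total: Tensor, parts: dict):
        if not np.isfinite(total.data):
            raise RuntimeError(
                f"non-finite loss at epoch {self._epoch}: components {parts}"
            )
        self.optimizer.zero_grad()
        total.backward()
        self.optimizer.step()
        self.history.append({"epoch": self._epoch, "total": float(total.data), **parts})
        self._epoch += 1

    # -- stages ---------------------------------------------------------------
    def pretrain(self, epochs: int | None = None) -> LatentEmbedding:
        epochs = self.config.epochs_pretrain if epochs is None else epochs
        self.model.train()
        for _ in range(epochs):
            lv, parts, _ = self._vgae_forward()
            self._step(self.config.lambda1 * lv, parts)
        return self.extract_embedding()

    def finetune(self, epochs: int | None = None) -> LatentEmbedding:
        cfg = self.config
        epochs = cfg.epochs_finetune if epochs is None else epochs
        use_dec = cfg.lambda2 > 0
        use_tri = cfg.lambda3 > 0
        P: np.ndarray | None = None
        ts: tri_mod.TripletSet | None = None

        if use_dec:
            Z0 = self.extract_embedding().Z
            cents = dec_mod.init_centroids(Z0, cfg.n_centroids, self._kmeans_seed)
            self.centroids = Parameter(cents)
            self.optimizer.params.append(self.centroids)
            self.optimizer.m.append(np.zeros_like(cents))
            self.optimizer.v.append(np.zeros_like(cents))

        self.model.train()
        for e in range(epochs):
            if use_dec and e % cfg.dec_refresh == 0:
                Q_now = dec_mod.soft_assign(self.extract_embedding().Z, self.centroids.data)
                P = dec_mod.target_distribution(Q_now)
                self.model.train()
            if use_tri and e % cfg.anchor_refresh == 0:
                Z_now = self.extract_embedding().Z
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ts = tri_mod.build_triplet_set(
                        Z_now,
                        self.dataset.slice_of,
                        self.dataset.A,
                        alpha=cfg.alpha,
                        tau=cfg.tau,
                        nn_size=cfg.nn_size,
                        seed=self._neg_seed_root + self._refresh_count,
                    )
                self._refresh_count += 1
                if ts.n_triplets == 0:
                    warnings.warn("no MNN anchors found; triplet term contributes 0")
                self.model.train()

            lv, parts, latent = self._vgae_forward()
            total = cfg.lambda1 * lv
            if use_dec:
                Q_t = dec_mod.soft_assign(latent["Z"], self.centroids)
                ld = dec_mod.loss_dec(P, Q_t)
                parts["dec"] = float(ld.data)
                total = total + cfg.lambda2 * ld
            if use_tri and ts is not None and ts.n_triplets > 0:
                lt = tri_mod.triplet_loss_from_set(latent["Z"], ts)
                parts["triplet"] = float(lt.data)
                total = total + cfg.lambda3 * lt
            self._step(total, parts)
        return self.extract_embedding()

    # -- extraction -----------------------------------------------------------
    def extract_embedding(self) -> LatentEmbedding:
        """Deterministic embedding: eval-mode batch norm, eps = 0, no masking."""
        self.model.eval()
        emb = self.model.encode_numpy(self.dataset.X, self.A_hat, eps=None)
        self.model.train()
        return emb

    def export_history_tsv(self, path):
        keys = ["epoch", "total", "graph", "kl", "sce", "dec", "triplet"]
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in self.history:
                fh.write("\t".join(str(row.get(k, "")) for k in keys) + "\n")


def pretrain(dataset: JointDataset, config: TrainingConfig) -> tuple[Trainer, LatentEmbedding]:
    trainer = Trainer(dataset, config)
    emb = trainer.pretrain()
    return trainer, emb


def finetune(
    dataset: JointDataset, pretrained: Trainer | None, config: TrainingConfig
) -> tuple[Trainer, LatentEmbedding]:
    trainer = pretrained if pretrained is not None else Trainer(dataset, config)
    emb = trainer.finetune()
    return trainer, emb
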