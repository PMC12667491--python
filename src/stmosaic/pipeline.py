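"""End-to-end orchestration shared by the CLI and the acceptance harness."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster_metrics import MetricsReport, cluster_embedding, evaluate_embedding
from .data_io import JointDataset, SliceData, build_joint_matrix
from .spatial_graph import block_diagonal_join, build_knn_graph
from .trainer import Trainer, TrainingConfig
from .vgae import LatentEmbedding

__all__ = ["PipelineResult", "attach_graph", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: JointDataset
    trainer: Trainer
    pretrain_embedding: LatentEmbedding
    final_embedding: LatentEmbedding
    labels: np.ndarray
    report: MetricsReport
    params: dict = field(default_factory=dict)


def attach_graph(
    dataset: JointDataset,
    slices: list[SliceData],
    k: int = 8,
    metric: str = "euclidean",
) -> JointDataset:
    graphs = [build_knn_graph(s.coords, k=k, metric=metric) for s in slices]
    dataset.A = block_diagonal_join(graphs).A
    dataset.validate()
    return dataset


def run_pipeline(
    slices: list[SliceData],
    n_domains: int,
    training: TrainingConfig | None = None,
    k: int = 8,
    graph_metric: str = "euclidean",
    min_spots: int = 50,
    min_total: int = 10,
    n_hvg: int = 2000,
    n_components: int = 200,
    true_labels: np.ndarray | None = None,
    perplexity: float = 30.0,
) -> PipelineResult:
    """preprocess -> graph -> mask/pretrain -> finetune -> cluster -> evaluate."""
    training = training or TrainingConfig()
    dataset = build_joint_matrix(
        slices,
        min_spots=min_spots,
        min_total=min_total,
        n_hvg=n_hvg,
        n_components=n_components,
        seed=training.seed,
    )
    attach_graph(dataset, slices, k=k, metric=graph_metric)

    trainer = Trainer(dataset, training)
    pre_emb = trainer.pretrain()
    final_emb = trainer.finetune()

    labels = cluster_embedding(final_emb.Z, n_domains=n_domains, seed=training.seed)
    report = evaluate_embedding(
        final_emb.Z,
        labels,
        true_labels=true_labels,
        slice_labels=dataset.slice_of,
        perplexity=perplexity,
    )
    return PipelineResult(
        dataset=dataset,
        trainer=trainer,
        pretrain_embedding=pre_emb,
        final_embedding=final_emb,
        labels=labels,
        report=report,
        params={
            "n_domains": n_domains,
            "k": k,
            "graph_metric": graph_metric,
            "n_hvg": n_hvg,
            "n_components": n_components,
            "seed": training.seed,
        },
    )
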