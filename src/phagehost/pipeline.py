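"""End-to-end orchestration: corpus -> genes -> clusters -> features ->
trees -> held-out evaluation.

Every stage is also usable on its own; this module wires them together
with a single RunConfig so the command-line interface, the test suite
and the reproduction script all execute the identical path.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

import pandas as pd

from . import clustering, corpus, evaluation, features, genecalling, hosttrees
from .clustering import ClusterDB
from .io_formats import GenomeRecord, HostLabelTable, ModelBundle

log = logging.getLogger("phagehost")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default.

    The config travels verbatim inside every model and report written by
    the pipeline, so a run can always be reproduced from its artifacts.
    """

    min_aa: int = 30
    identity_threshold: float = 0.95
    k: int = 4
    min_shared: int = 2
    gap_open: float = 11.0
    gap_extend: float = 1.0
    norm_threshold: float = 0.4
    inflation: float = 2.0
    expansion: int = 2
    prune_below: float = 1e-5
    mcl_tol: float = 1e-6
    mcl_max_iter: int = 200
    min_prevalence: float = 0.01
    max_presence: float = 0.99
    min_impurity_split: float = 0.03
    balanced: bool = True
    decision_threshold: float = 0.5
    assign_threshold: float = 0.4
    split_fraction: float = 0.8
    stratify: bool = False
    top_n_genera: int = 50
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class TrainedModel:
    """The frozen training artifacts plus provenance useful for analysis."""

    bundle: ModelBundle
    train_matrix: pd.DataFrame
    train_calls: dict[str, genecalling.GeneCall]
    train_proteins: dict[str, str]
    partition: list[set[str]]  # full MCL partition (all train proteins)
    dup_map: dict[str, str]
    genera: list[str]


@dataclass
class PipelineResult:
    config: RunConfig
    split: corpus.CorpusSplit
    model: TrainedModel
    test_matrix: pd.DataFrame
    test_calls: dict[str, dict[str, genecalling.GeneCall]]
    predictions: dict[str, set[str]]
    report: evaluation.EvalReport


def call_training_genes(
    genomes: list[GenomeRecord], train_ids: list[str], min_aa: int
) -> tuple[dict[str, genecalling.GeneCall], dict[str, str], dict[str, str]]:
    """ORF-call the training genomes; returns (calls, proteins, protein->phage)."""
    by_id = {g.id: g for g in genomes}
    calls: dict[str, genecalling.GeneCall] = {}
    for pid in sorted(train_ids):
        calls.update(genecalling.call_genes(by_id[pid], min_aa=min_aa))
    proteins = {cid: c.aa_seq for cid, c in calls.items()}
    protein_to_phage = {cid: c.genome_id for cid, c in calls.items()}
    return calls, proteins, protein_to_phage


def cluster_proteins(
    proteins: dict[str, str],
    protein_to_phage: dict[str, str],
    n_training_phages: int,
    cfg: RunConfig,
    annotations: Mapping[str, str] | None = None,
) -> tuple[ClusterDB, list[set[str]], dict[str, str]]:
    """Dedup -> candidate pairs -> alignment graph -> MCL -> prevalence filter.

    Returns the kept ClusterDB, the full expanded partition (before the
    prevalence filter) and the dedup map.
    """
    reps, dup_map = clustering.dedup_proteins(proteins, cfg.identity_threshold)
    log.info("dedup: %d proteins -> %d representatives", len(proteins), len(reps))
    pairs = clustering.candidate_pairs(reps, k=cfg.k, min_shared=cfg.min_shared)
    log.info("candidate pairs: %d", len(pairs))
    graph = clustering.build_graph(
        pairs, reps, cfg.norm_threshold, cfg.gap_open, cfg.gap_extend
    )
    partition = clustering.mcl(
        graph,
        inflation=cfg.inflation,
        expansion=cfg.expansion,
        prune_below=cfg.prune_below,
        tol=cfg.mcl_tol,
        max_iter=cfg.mcl_max_iter,
    )
    full_partition = clustering.expand_clusters(partition, dup_map)
    log.info("MCL: %d clusters over %d proteins", len(full_partition), len(proteins))
    db = clustering.filter_clusters(
        full_partition,
        protein_to_phage,
        n_training_phages,
        sequences=proteins,
        min_prevalence=cfg.min_prevalence,
        annotations=annotations,
        config={
            "identity_threshold": cfg.identity_threshold,
            "k": cfg.k,
            "min_shared": cfg.min_shared,
            "gap_open": cfg.gap_open,
            "gap_extend": cfg.gap_extend,
            "norm_threshold": cfg.norm_threshold,
            "inflation": cfg.inflation,
            "expansion": cfg.expansion,
            "prune_below": cfg.prune_below,
            "min_prevalence": cfg.min_prevalence,
        },
    )
    log.info("prevalence filter: %d clusters kept", len(db))
    return db, full_partition, dup_map


def train_model(
    genomes: list[GenomeRecord],
    labels: HostLabelTable,
    train_ids: list[str],
    cfg: RunConfig,
    annotations: Mapping[str, str] | None = None,
) -> TrainedModel:
    calls, proteins, protein_to_phage = call_training_genes(genomes, train_ids, cfg.min_aa)
    db, partition, dup_map = cluster_proteins(
        proteins, protein_to_phage, len(train_ids), cfg, annotations
    )
    matrix = features.build_feature_matrix(
        db.protein_to_cluster, protein_to_phage, db, phage_ids=list(train_ids)
    )
    reduced, kept = features.variance_threshold_filter(matrix, cfg.max_presence)
    log.info("variance filter: %d of %d columns kept", len(kept), matrix.shape[1])
    genera = sorted({g for pid in train_ids for g in labels.genera_of(pid)})
    suite = hosttrees.train_suite(
        reduced,
        labels,
        genera,
        min_impurity_split=cfg.min_impurity_split,
        balanced=cfg.balanced,
    )
    bundle = ModelBundle(
        suite=suite, cluster_db=db, kept_columns=kept, config=cfg.to_dict()
    )
    return TrainedModel(
        bundle=bundle,
        train_matrix=reduced,
        train_calls=calls,
        train_proteins=proteins,
        partition=partition,
        dup_map=dup_map,
        genera=genera,
    )


def vectorize_test_genomes(
    genomes: list[GenomeRecord],
    test_ids: list[str],
    bundle: ModelBundle,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, genecalling.GeneCall]]]:
    by_id = {g.id: g for g in genomes}
    per_genome: dict[str, dict[str, str]] = {}
    all_calls: dict[str, dict[str, genecalling.GeneCall]] = {}
    for pid in sorted(test_ids):
        calls = genecalling.call_genes(by_id[pid], min_aa=cfg.min_aa)
        all_calls[pid] = calls
        per_genome[pid] = {cid: c.aa_seq for cid, c in calls.items()}
    matrix = features.vectorize_genomes(
        per_genome,
        bundle.cluster_db,
        bundle.kept_columns,
        assign_threshold=cfg.assign_threshold,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
    )
    return matrix, all_calls


def run_pipeline(
    genomes: list[GenomeRecord],
    labels: HostLabelTable,
    cfg: RunConfig,
) -> PipelineResult:
    """Execute the full training + held-out evaluation pipeline."""
    selected = corpus.select_top_genera(labels, cfg.top_n_genera)
    labels = labels.restricted_to(selected)
    keep_ids = set(labels.phage_ids())
    genomes = [g for g in genomes if g.id in keep_ids]
    split = corpus.split_corpus(
        keep_ids,
        fraction=cfg.split_fraction,
        seed=cfg.seed,
        labels=labels,
        stratify_by_genus=cfg.stratify,
    )
    model = train_model(genomes, labels, split.train_ids, cfg)
    test_matrix, test_calls = vectorize_test_genomes(
        genomes, split.test_ids, model.bundle, cfg
    )
    predictions = hosttrees.predict_matrix(
        test_matrix, model.bundle.suite, cfg.decision_threshold
    )
    report = evaluation.evaluate_suite(
        model.bundle.suite, test_matrix, labels, cfg.decision_threshold
    )
    return PipelineResult(
        config=cfg,
        split=split,
        model=model,
        test_matrix=test_matrix,
        test_calls=test_calls,
        predictions=predictions,
        report=report,
    )


def cluster_family_labels(
    cluster_db: ClusterDB,
    gene_families: Mapping[str, str],
) -> dict[int, str | None]:
    """Label each kept cluster with the modal planted family among its
    truth-attributed members (None when no member is attributed)."""
    out: dict[int, str | None] = {}
    for c in cluster_db.clusters:
        fams = [gene_families[m] for m in c.member_ids if m in gene_families]
        out[c.cluster_id] = max(sorted(set(fams)), key=fams.count) if fams else None
    return out
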