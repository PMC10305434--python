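"""Integer cluster-count vectors for phages.

A phage i is represented by the vector a_{i,j} = number of its genes
assigned to gene cluster j.  A presence-based variance filter drops
columns that are nearly always present or nearly always absent, and
novel genomes are vectorized against a frozen cluster database by
aligning their proteins to cluster representatives.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import ClusterDB, norm_score, self_score, sw_score


def build_feature_matrix(
    protein_to_cluster: Mapping[str, int],
    protein_to_phage: Mapping[str, str],
    cluster_db: ClusterDB,
    phage_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Count matrix a_{i,j}: rows = phages, columns = cluster ids.

    Phages listed in ``phage_ids`` with no clustered genes keep an
    all-zero row.
    """
    if len(cluster_db) == 0:
        raise ValueError("empty cluster database")
    valid = set(cluster_db.cluster_ids)
    rows = set(phage_ids or [])
    rows.update(protein_to_phage[p] for p in protein_to_cluster)
    index = sorted(rows)
    columns = cluster_db.cluster_ids
    mat = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for pid, cid in protein_to_cluster.items():
        if cid not in valid:
            raise ValueError(f"protein {pid!r} mapped to unknown cluster {cid}")
        mat.loc[protein_to_phage[pid], cid] += 1
    mat.index.name = "phage_id"
    return mat


def variance_threshold_filter(
    matrix: pd.DataFrame,
    max_presence: float = 0.99,
) -> tuple[pd.DataFrame, list[int]]:
    """Drop near-constant presence/absence columns.

    A column is binarized (count >= 1) for the test only and dropped iff
    its presence fraction or its absence fraction exceeds max_presence
    (strictly).  Survivors keep their integer counts and cluster ids.
    """
    if matrix.empty:
        raise ValueError("empty feature matrix")
    presence = (matrix >= 1).mean(axis=0)
    keep = [c for c in matrix.columns if presence[c] <= max_presence and (1 - presence[c]) <= max_presence]
    if not keep:
        raise ValueError("variance threshold removed every column")
    return matrix[keep], list(keep)


def vectorize_novel(
    proteins: Mapping[str, str],
    cluster_db: ClusterDB,
    kept_columns: list[int],
    assign_threshold: float = 0.4,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    member_seqs: Mapping[str, str] | None = None,
) -> pd.Series:
    """Vectorize one genome's proteins against a frozen cluster database.

    Each protein is aligned to every cluster representative; clusters
    with normalized score >= assign_threshold are candidates and the
    protein counts once toward the best-scoring one (ties -> smallest
    cluster id).  When ``member_seqs`` is given, proteins with no
    representative match fall back to a full member search.  Counts are
    reported over the kept (post-variance-filter) columns only.
    """
    counts = pd.Series(0, index=list(kept_columns), dtype=int)
    if not proteins:
        return counts
    rep_selfs = {c.cluster_id: self_score(c.representative_seq) for c in cluster_db.clusters}
    for pid in sorted(proteins):
        seq = proteins[pid]
        if not seq:
            continue
        sp = self_score(seq)
        best: tuple[float, int] | None = None
        for c in cluster_db.clusters:
            raw = sw_score(seq, c.representative_seq, gap_open, gap_extend)
            ns = norm_score(raw, sp, rep_selfs[c.cluster_id])
            if ns >= assign_threshold and (best is None or (ns, -c.cluster_id) > (best[0], -best[1])):
                best = (ns, c.cluster_id)
        if best is None and member_seqs is not None:
            for c in cluster_db.clusters:
                for mid in sorted(c.member_ids):
                    mseq = member_seqs.get(mid)
                    if not mseq:
                        continue
                    raw = sw_score(seq, mseq, gap_open, gap_extend)
                    ns = norm_score(raw, sp, self_score(mseq))
                    if ns >= assign_threshold and (best is None or (ns, -c.cluster_id) > (best[0], -best[1])):
                        best = (ns, c.cluster_id)
        if best is not None and best[1] in counts.index:
            counts[best[1]] += 1
    return counts


def vectorize_genomes(
    per_genome_proteins: Mapping[str, Mapping[str, str]],
    cluster_db: ClusterDB,
    kept_columns: list[int],
    **kwargs,
) -> pd.DataFrame:
    """Stack vectorize_novel over several genomes into a matrix."""
    rows = {
        gid: vectorize_novel(prots, cluster_db, kept_columns, **kwargs)
        for gid, prots in per_genome_proteins.items()
    }
    mat = pd.DataFrame(rows).T.astype(int)
    mat = mat.reindex(sorted(rows.keys()))
    mat.index.name = "phage_id"
    return mat
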