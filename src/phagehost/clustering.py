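"""Protein gene-family clustering.

Pipeline: greedy identity deduplication (descending length), a shared
k-mer candidate-pair prefilter, exact Smith–Waterman local alignment with
affine gaps (BLOSUM62, gap open 11 / extend 1), a similarity graph
weighted by self-score-normalized alignment score, Markov clustering of
the graph, and finally a prevalence filter that drops families present
in fewer than 1% of training phages.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
import networkx as nx
import numpy as np
import scipy.sparse as sp
from Bio.Align import PairwiseAligner, substitution_matrices


def blosum62() -> "substitution_matrices.Array":
    """BLOSUM62 with the unknown residue X scored at the matrix worst (-4)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for ch in m.alphabet:
        m["X", ch] = -4.0
        m[ch, "X"] = -4.0
    return m


_MATRIX = blosum62()
_DIAG = {ch: _MATRIX[ch, ch] for ch in _MATRIX.alphabet}


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    # opening a gap costs gap_open + gap_extend for its first position
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=_MATRIX,
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )
    return aligner


_DEFAULT_ALIGNER = _make_aligner(11.0, 1.0)


def self_score(seq: str) -> float:
    """Local self-alignment score: the full BLOSUM62 diagonal sum."""
    return float(sum(_DIAG[ch] for ch in seq))


def smith_waterman(
    a: str,
    b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, tuple]:
    """Best local alignment score and aligned spans for two proteins.

    Affine gap model: a gap of length k costs gap_open + k * gap_extend.
    The score is never negative; sequences with no positive-scoring
    residue pair (or an empty sequence) score 0 with empty spans.
    """
    if not a or not b:
        return 0.0, ()
    if (gap_open, gap_extend) == (11.0, 1.0):
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(gap_open, gap_extend)
    score = float(aligner.score(a, b))
    if score <= 0:
        return 0.0, ()
    aln = aligner.align(a, b)[0]
    spans = tuple((tuple(map(tuple, block)) for block in np.asarray(aln.aligned).tolist()))
    return score, spans


def sw_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Score-only Smith–Waterman (fast path used in bulk graph building)."""
    if not a or not b:
        return 0.0
    if (gap_open, gap_extend) == (11.0, 1.0):
        return max(0.0, float(_DEFAULT_ALIGNER.score(a, b)))
    return max(0.0, float(_make_aligner(gap_open, gap_extend).score(a, b)))


def norm_score(raw: float, self_a: float, self_b: float) -> float:
    """Raw score normalized by the smaller self-score, clipped to [0, 1]."""
    denom = min(self_a, self_b)
    if denom <= 0:
        return 0.0
    return float(np.clip(raw / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# deduplication (greedy incremental, descending length)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    columns = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    matches = columns - res["editDistance"]
    return matches / columns


def dedup_proteins(
    proteins: Mapping[str, str],
    identity_threshold: float = 0.95,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy identity clustering in descending length order.

    A protein joins the first existing representative whose global
    identity is >= the threshold, else becomes a new representative.
    Returns (representatives, duplicate -> representative map).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))
    reps: dict[str, str] = {}
    dup_map: dict[str, str] = {}
    for pid in order:
        seq = proteins[pid]
        assigned = False
        for rid, rseq in reps.items():
            # identity <= min(len)/max(len): skip hopeless length ratios
            if len(seq) < identity_threshold * len(rseq):
                continue
            if global_identity(seq, rseq) >= identity_threshold:
                dup_map[pid] = rid
                assigned = True
                break
        if not assigned:
            reps[pid] = seq
    return reps, dup_map


# ---------------------------------------------------------------------------
# candidate pairs by shared k-mers

def candidate_pairs(
    proteins: Mapping[str, str],
    k: int = 4,
    min_shared: int = 2,
) -> set[tuple[str, str]]:
    """Unordered id pairs sharing at least min_shared distinct k-mers."""
    if k < 2:
        raise ValueError("k must be >= 2")
    index: dict[str, list[str]] = {}
    for pid in sorted(proteins):
        seq = proteins[pid]
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            index.setdefault(kmer, []).append(pid)
    shared: dict[tuple[str, str], int] = {}
    for ids in index.values():
        if len(ids) < 2:
            continue
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pair = (ids[i], ids[j])
                shared[pair] = shared.get(pair, 0) + 1
    return {pair for pair, n in shared.items() if n >= min_shared}


# ---------------------------------------------------------------------------
# similarity graph + Markov clustering

def build_graph(
    pairs: Iterable[tuple[str, str]],
    proteins: Mapping[str, str],
    norm_threshold: float = 0.4,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> nx.Graph:
    """Weighted similarity graph over all proteins.

    Every protein gets a node with a unit self-loop; candidate pairs are
    aligned and contribute an edge iff their normalized score is >= the
    threshold.
    """
    g = nx.Graph()
    selfs = {pid: self_score(seq) for pid, seq in proteins.items()}
    for pid in proteins:
        g.add_node(pid)
        g.add_edge(pid, pid, weight=1.0)
    for a, b in sorted(pairs):
        if a == b:
            continue
        raw = sw_score(proteins[a], proteins[b], gap_open, gap_extend)
        w = norm_score(raw, selfs[a], selfs[b])
        if w >= norm_threshold:
            g.add_edge(a, b, weight=w)
    return g


def _normalize_columns(m: sp.csc_array) -> sp.csc_array:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return m @ sp.diags_array(1.0 / sums, format="csc")


def _prune(m: sp.csc_array, prune_below: float) -> sp.csc_array:
    """Zero entries below the cutoff, but never empty a column entirely."""
    m = m.tocsc()
    data, indptr = m.data, m.indptr
    keep = data >= prune_below
    for col in range(m.shape[1]):
        lo, hi = indptr[col], indptr[col + 1]
        if lo == hi:
            continue
        if not keep[lo:hi].any():
            keep[lo + int(np.argmax(data[lo:hi]))] = True
    m.data = np.where(keep, data, 0.0)
    m.eliminate_zeros()
    return m


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
    return_flow: bool = False,
):
    """Markov clustering of a weighted undirected graph with self-loops.

    Column-normalize the adjacency matrix, then iterate expansion (matrix
    power), inflation (elementwise power + renormalization) and pruning
    until the flow matrix stabilizes.  Clusters are the connected
    components of the converged matrix's nonzero pattern, so nodes never
    move across components of the input graph.
    """
    nodes = sorted(graph.nodes())
    if not nodes:
        raise ValueError("empty graph")
    for n in nodes:
        if not graph.has_edge(n, n):
            raise ValueError(f"node {n!r} lacks a self-loop")
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csc")
    m = _normalize_columns(sp.csc_array(a, dtype=float))

    converged = False
    for _ in range(max_iter):
        prev = m
        new = m
        for _ in range(expansion - 1):
            new = new @ m
        new = sp.csc_array(new)
        new.data = np.power(new.data, inflation)
        new = _prune(new, prune_below)
        new = _normalize_columns(new)
        m = new
        delta = abs(m - prev)
        if delta.nnz == 0 or delta.max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "interpreting the current flow matrix",
            stacklevel=2,
        )

    pattern = (m + m.T).astype(bool)
    n_comp, labels = sp.csgraph.connected_components(pattern, directed=False)
    clusters: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), set()).add(node)
    partition = sorted(clusters.values(), key=lambda s: min(s))
    if return_flow:
        return partition, m, nodes
    return partition


def expand_clusters(
    partition: list[set[str]],
    dup_map: Mapping[str, str],
) -> list[set[str]]:
    """Fold deduplicated proteins back in: duplicates inherit their
    representative's cluster."""
    where: dict[str, int] = {}
    for i, members in enumerate(partition):
        for m in members:
            where[m] = i
    expanded = [set(members) for members in partition]
    for dup, rep in dup_map.items():
        if rep not in where:
            raise ValueError(f"duplicate {dup!r} maps to unclustered representative {rep!r}")
        expanded[where[rep]].add(dup)
    return expanded


# ---------------------------------------------------------------------------
# cluster DB and prevalence filter

@dataclass
class GeneCluster:
    """An MCL gene family: members, longest-member representative,
    training prevalence and optional annotation."""

    cluster_id: int
    member_ids: set[str]
    representative_id: str
    representative_seq: str
    prevalence: float
    annotation: str | None = None


@dataclass
class ClusterDB:
    clusters: list[GeneCluster]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_to_cluster: dict[str, int] = {}
        for c in self.clusters:
            for m in c.member_ids:
                if m in self.protein_to_cluster:
                    raise ValueError(f"protein {m!r} appears in two clusters")
                self.protein_to_cluster[m] = c.cluster_id

    @property
    def cluster_ids(self) -> list[int]:
        return [c.cluster_id for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


def _representative(members: set[str], sequences: Mapping[str, str]) -> str:
    return sorted(members, key=lambda m: (-len(sequences[m]), m))[0]


def filter_clusters(
    clusters: list[set[str]],
    protein_to_phage: Mapping[str, str],
    n_training_phages: int,
    sequences: Mapping[str, str],
    min_prevalence: float = 0.01,
    annotations: Mapping[str, str] | None = None,
    config: dict | None = None,
) -> ClusterDB:
    """Drop clusters present in fewer than min_prevalence of training
    phages (strict <) and re-index survivors by descending prevalence."""
    if n_training_phages < 1:
        raise ValueError("n_training_phages must be >= 1")
    scored: list[tuple[float, str, set[str]]] = []
    for members in clusters:
        phages = {protein_to_phage[m] for m in members}
        prevalence = len(phages) / n_training_phages
        if prevalence < min_prevalence:
            continue
        scored.append((prevalence, min(members), members))
    if not scored:
        raise ValueError(
            f"all {len(clusters)} clusters fall below prevalence {min_prevalence}; "
            "lower min_prevalence or supply more training phages"
        )
    scored.sort(key=lambda t: (-t[0], t[1]))
    out: list[GeneCluster] = []
    for cid, (prevalence, _, members) in enumerate(scored):
        annotation = None
        if annotations:
            found = [annotations[m] for m in members if m in annotations]
            if found:
                annotation = max(sorted(set(found)), key=found.count)
        rep = _representative(members, sequences)
        out.append(
            GeneCluster(
                cluster_id=cid,
                member_ids=set(members),
                representative_id=rep,
                representative_seq=sequences[rep],
                prevalence=prevalence,
                annotation=annotation,
            )
        )
    return ClusterDB(clusters=out, config=dict(config or {}))


def write_graph_abc(graph: nx.Graph, path) -> None:
    """Dump the similarity graph as an ABC edge list (node node weight)."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.6f}\n")
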