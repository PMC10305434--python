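"""Readers and writers for every on-disk representation used by the pipeline.

All formats are plain text: FASTA for genomes and proteins, TSV for host
labels and feature matrices, JSON for serialized models and cluster
databases, DOT for tree exports.  Round-trips are exact: reading back a
file written here reproduces the in-memory objects bit-stably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MODEL_SCHEMA_VERSION = 1

# bases kept verbatim; other IUPAC ambiguity codes collapse to N
_CANONICAL = set("ACGTN")
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


def normalize_genus(name: str) -> str:
    """Case-normalize a genus name: first letter upper, rest lower."""
    name = name.strip()
    if not name:
        raise ValueError("empty genus name")
    return name[0].upper() + name[1:].lower()


@dataclass
class GenomeRecord:
    """A phage genome with its known host genus labels (possibly none)."""

    id: str
    sequence: str
    host_genera: set[str] = field(default_factory=set)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"genome {self.id}: empty sequence")


class HostLabelTable:
    """Rows of (phage_id, genus); one row per admissible host of a phage."""

    def __init__(self, rows: Iterable[tuple[str, str]]):
        seen: set[tuple[str, str]] = set()
        self.rows: list[tuple[str, str]] = []
        for pid, genus in rows:
            genus = normalize_genus(genus)
            key = (pid, genus)
            if key in seen:
                continue
            seen.add(key)
            self.rows.append(key)
        self._by_phage: dict[str, set[str]] = {}
        for pid, genus in self.rows:
            self._by_phage.setdefault(pid, set()).add(genus)

    def genera_of(self, phage_id: str) -> set[str]:
        return set(self._by_phage.get(phage_id, set()))

    def phage_ids(self) -> list[str]:
        return sorted(self._by_phage)

    def genus_counts(self) -> dict[str, int]:
        """Number of phages per genus; a phage counts once per genus label."""
        counts: dict[str, int] = {}
        for _, genus in self.rows:
            counts[genus] = counts.get(genus, 0) + 1
        return counts

    def restricted_to(self, genera: set[str]) -> "HostLabelTable":
        """Drop rows outside `genera` and phages left with no label."""
        return HostLabelTable((p, g) for p, g in self.rows if g in genera)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HostLabelTable) and sorted(self.rows) == sorted(other.rows)


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    out = []
    for i, ch in enumerate(seq):
        if ch in _CANONICAL:
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS:
            out.append("N")
        else:
            raise ValueError(
                f"record {rec_id}: non-IUPAC character {ch!r} at position {i}"
            )
    return "".join(out)


def read_genomes(path: str | Path) -> list[GenomeRecord]:
    """Parse a genome FASTA file into GenomeRecords.

    The header token before the first whitespace becomes the record id; the
    remainder is kept as the description.  Sequences are upper-cased, RNA U
    is mapped to T and ambiguity codes other than N collapse to N.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            GenomeRecord(
                id=rec.id,
                sequence=_clean_sequence(str(rec.seq), rec.id),
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_genomes(records: Iterable[GenomeRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_proteins(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_proteins(proteins: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_host_table(path: str | Path) -> HostLabelTable:
    """Read a two-column TSV of (phage_id, genus) rows.

    A header line is detected by the literal token ``phage_id`` in the first
    column.  Multi-genus phages simply occupy several rows.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
            if lineno == 1 and parts[0].strip() == "phage_id":
                continue
            rows.append((parts[0].strip(), parts[1]))
    if not rows:
        raise ValueError(f"{path}: no label rows")
    return HostLabelTable(rows)


def write_host_table(labels: HostLabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phage_id\tgenus\n")
        for pid, genus in sorted(labels.rows):
            fh.write(f"{pid}\t{genus}\n")


# ---------------------------------------------------------------------------
# feature matrix TSV

def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an integer phage-by-cluster matrix; columns headed ``c<id>``."""
    out = matrix.copy()
    out.columns = [f"c{c}" for c in out.columns]
    out.index.name = "phage_id"
    out.to_csv(path, sep="\t")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="phage_id")
    df.columns = [int(c.lstrip("c")) for c in df.columns]
    return df.astype(int)


# ---------------------------------------------------------------------------
# model serialization (single self-describing JSON document)

def _tree_to_json(node) -> dict:
    if node.is_leaf:
        return {
            "kind": "leaf",
            "positive_fraction": node.positive_fraction,
            "n_samples": node.n_samples,
            "impurity": node.impurity,
        }
    return {
        "kind": "internal",
        "feature": node.feature,
        "threshold": node.threshold,
        "impurity": node.impurity,
        "n_samples": node.n_samples,
        "left": _tree_to_json(node.left),
        "right": _tree_to_json(node.right),
    }


def _tree_from_json(obj: dict):
    from .hosttrees import TreeNode

    if obj["kind"] == "leaf":
        return TreeNode(
            impurity=obj["impurity"],
            n_samples=obj["n_samples"],
            positive_fraction=obj["positive_fraction"],
        )
    return TreeNode(
        impurity=obj["impurity"],
        n_samples=obj["n_samples"],
        feature=obj["feature"],
        threshold=obj["threshold"],
        left=_tree_from_json(obj["left"]),
        right=_tree_from_json(obj["right"]),
    )


def _cluster_db_to_json(db) -> dict:
    return {
        "config": db.config,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "member_ids": sorted(c.member_ids),
                "representative_id": c.representative_id,
                "representative_seq": c.representative_seq,
                "prevalence": c.prevalence,
                "annotation": c.annotation,
            }
            for c in db.clusters
        ],
    }


def _cluster_db_from_json(obj: dict):
    from .clustering import ClusterDB, GeneCluster

    clusters = [
        GeneCluster(
            cluster_id=c["cluster_id"],
            member_ids=set(c["member_ids"]),
            representative_id=c["representative_id"],
            representative_seq=c["representative_seq"],
            prevalence=c["prevalence"],
            annotation=c.get("annotation"),
        )
        for c in obj["clusters"]
    ]
    return ClusterDB(clusters=clusters, config=obj["config"])


def write_cluster_db(db, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_cluster_db_to_json(db), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cluster_db(path: str | Path):
    with open(path) as fh:
        return _cluster_db_from_json(json.load(fh))


@dataclass
class ModelBundle:
    """Everything needed to classify a novel genome: trees + cluster DB."""

    suite: object  # HostTreeSuite
    cluster_db: object  # ClusterDB
    kept_columns: list[int]
    config: dict


def write_model(bundle: ModelBundle, path: str | Path) -> None:
    suite = bundle.suite
    if not suite.trees:
        raise ValueError("no trained trees")
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": bundle.config,
        "kept_columns": list(bundle.kept_columns),
        "columns": list(suite.columns),
        "suite_config": suite.config,
        "trees": {genus: _tree_to_json(root) for genus, root in suite.trees.items()},
        "cluster_db": _cluster_db_to_json(bundle.cluster_db),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path) -> ModelBundle:
    from .hosttrees import HostTreeSuite

    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: truncated or malformed model file: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: model schema version {version!r} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    suite = HostTreeSuite(
        trees={g: _tree_from_json(t) for g, t in doc["trees"].items()},
        columns=list(doc["columns"]),
        config=doc["suite_config"],
    )
    return ModelBundle(
        suite=suite,
        cluster_db=_cluster_db_from_json(doc["cluster_db"]),
        kept_columns=list(doc["kept_columns"]),
        config=doc["config"],
    )
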