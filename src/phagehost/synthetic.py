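"""Seeded synthetic phage corpora with planted, host-informative gene
families.

Each genus carries a private set of marker protein families that every
phage of that genus encodes; all genera additionally draw background
genes from one shared pool.  Genomes are concatenations of the encoded
genes in random order separated by random spacers, with per-nucleotide
substitution noise that never introduces premature stop codons, so each
planted gene stays one intact ORF.  This emulates the core assumption
behind gene-family host prediction — phages infecting the same host
share homologous genes — while giving every pipeline stage an exactly
known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .genecalling import CODON_TO_AA, STOP_CODONS, GeneCall
from .io_formats import GenomeRecord, HostLabelTable, write_genomes, write_host_table

_AA20 = sorted(set(CODON_TO_AA.values()))
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)

BACKGROUND_PREFIX = "shared."


@dataclass
class SyntheticSpec:
    """Generator settings; the seed fixes the full corpus byte-for-byte."""

    n_genera: int = 5
    phages_per_genus: int = 40
    markers_per_genus: int = 3
    marker_len_aa: tuple[int, int] = (50, 150)
    background_pool_size: int = 20
    background_genes_per_phage: int = 5
    mutation_rate: float = 0.02
    spacer_len: tuple[int, int] = (20, 80)
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_genera, self.phages_per_genus, self.markers_per_genus) < 1:
            raise ValueError("counts must be >= 1")
        if self.background_pool_size < 0 or self.background_genes_per_phage < 0:
            raise ValueError("background counts must be >= 0")
        if self.background_genes_per_phage > self.background_pool_size:
            raise ValueError("background_genes_per_phage exceeds the pool size")
        if not 0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5)")
        if self.marker_len_aa[0] < 2 or self.marker_len_aa[0] > self.marker_len_aa[1]:
            raise ValueError("invalid marker length range")
        if self.spacer_len[0] < 0 or self.spacer_len[0] > self.spacer_len[1]:
            raise ValueError("invalid spacer length range")


@dataclass(frozen=True)
class PlantedGene:
    """Ground-truth record: where a family's gene sits in a genome."""

    start: int
    end: int
    family: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(_AA20, size=length - 1)
    return "M" + "".join(body)


def _encode_gene(rng: np.random.Generator, protein: str) -> str:
    """ATG + synonymous codons for the tail of the protein + TAA."""
    codons = ["ATG"]
    for aa in protein[1:]:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append("TAA")
    return "".join(codons)


_BASES = ("A", "C", "G", "T")


def _mutate_gene(rng: np.random.Generator, nt: str, rate: float) -> str:
    """Per-nucleotide substitutions that keep the ORF intact.

    The start and stop codons are left untouched and a substitution is
    redrawn among the alternatives that do not turn its codon into a
    stop, so mutated genes still translate end to end.
    """
    if rate <= 0:
        return nt
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    for ci in range(1, len(codons) - 1):
        codon = codons[ci]
        for pos in range(3):
            if rng.random() >= rate:
                continue
            old = codon[pos]
            alts = [
                b
                for b in _BASES
                if b != old and (codon[:pos] + b + codon[pos + 1 :]) not in STOP_CODONS
            ]
            if alts:
                codon = codon[:pos] + alts[rng.integers(len(alts))] + codon[pos + 1 :]
        codons[ci] = codon
    return "".join(codons)


# stop codons in all three frames of both strands (the cassette is its
# own reverse complement); prefixing every spacer with it insulates
# neighbouring genes so no open reading frame can span a gene junction
_INSULATOR = "TTAATTAATTAA"


def _spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    tail = "".join(rng.choice(_BASES, size=length)) if length else ""
    return _INSULATOR + tail


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[GenomeRecord], HostLabelTable, dict[str, list[PlantedGene]]]:
    """Generate genomes, host labels, and a per-genome planted-gene map.

    Family ids are ``<Genus>.m<j>`` for genus markers and ``shared.b<j>``
    for the background pool.
    """
    rng = np.random.default_rng(spec.seed)
    genera = [f"Genus{i + 1:02d}" for i in range(spec.n_genera)]

    # each family has one ancestral gene sequence; copies diverge only
    # through the mutation model, as homologous genes do
    family_genes: dict[str, str] = {}
    for genus in genera:
        for j in range(spec.markers_per_genus):
            length = int(rng.integers(spec.marker_len_aa[0], spec.marker_len_aa[1] + 1))
            family_genes[f"{genus}.m{j}"] = _encode_gene(rng, _random_protein(rng, length))
    for j in range(spec.background_pool_size):
        length = int(rng.integers(spec.marker_len_aa[0], spec.marker_len_aa[1] + 1))
        family_genes[f"{BACKGROUND_PREFIX}b{j}"] = _encode_gene(
            rng, _random_protein(rng, length)
        )
    bg_ids = sorted(f for f in family_genes if f.startswith(BACKGROUND_PREFIX))

    genomes: list[GenomeRecord] = []
    label_rows: list[tuple[str, str]] = []
    truth: dict[str, list[PlantedGene]] = {}

    for genus in genera:
        families = [f"{genus}.m{j}" for j in range(spec.markers_per_genus)]
        for k in range(spec.phages_per_genus):
            pid = f"{genus}_p{k + 1:03d}"
            chosen_bg: list[str] = []
            if spec.background_genes_per_phage:
                picks = rng.choice(
                    len(bg_ids), size=spec.background_genes_per_phage, replace=False
                )
                chosen_bg = [bg_ids[i] for i in sorted(picks)]
            gene_plan = families + chosen_bg
            order = rng.permutation(len(gene_plan))
            parts: list[str] = []
            planted: list[PlantedGene] = []
            offset = 0
            chunk = _spacer(rng, *spec.spacer_len)
            parts.append(chunk)
            offset += len(chunk)
            for idx in order:
                fam = gene_plan[idx]
                gene = _mutate_gene(rng, family_genes[fam], spec.mutation_rate)
                planted.append(PlantedGene(start=offset, end=offset + len(gene), family=fam))
                parts.append(gene)
                offset += len(gene)
                chunk = _spacer(rng, *spec.spacer_len)
                parts.append(chunk)
                offset += len(chunk)
            genomes.append(
                GenomeRecord(id=pid, sequence="".join(parts), host_genera={genus})
            )
            label_rows.append((pid, genus))
            truth[pid] = planted

    return genomes, HostLabelTable(label_rows), truth


# ---------------------------------------------------------------------------
# ground-truth attribution and purity

def match_truth(
    calls: Mapping[str, GeneCall],
    truth: Mapping[str, list[PlantedGene]],
    locus_overlap: bool = False,
    min_overlap: float = 0.5,
) -> dict[str, str]:
    """Attribute gene calls to planted families.

    By default a call is attributed only when it is the planted gene's
    own reading: forward strand, the same stop position, and the same
    frame (the caller may open the ORF a little upstream of the planted
    start when the spacer happens to contain an in-frame start codon).
    With ``locus_overlap`` any call, either strand or frame, covering at
    least ``min_overlap`` of its span with a planted locus is attributed
    — useful for asking whether a cluster carries family-derived signal
    at all, e.g. antisense or frame-shifted readings of a marker locus.
    """
    out: dict[str, str] = {}
    for pid, call in calls.items():
        planted = truth.get(call.genome_id, [])
        if not locus_overlap:
            for gene in planted:
                if (
                    call.strand == "+"
                    and call.end == gene.end
                    and call.start <= gene.start
                    and (gene.start - call.start) % 3 == 0
                ):
                    out[pid] = gene.family
                    break
            continue
        best: tuple[float, str] | None = None
        span = call.end - call.start
        for gene in planted:
            overlap = min(call.end, gene.end) - max(call.start, gene.start)
            if overlap <= 0:
                continue
            frac = overlap / span
            if frac >= min_overlap and (best is None or frac > best[0]):
                best = (frac, gene.family)
        if best is not None:
            out[pid] = best[1]
    return out


def corpus_truth_purity(
    clusters: Iterable[set[str]],
    gene_families: Mapping[str, str],
) -> float:
    """Purity of a clustering against the planted marker families.

    purity = sum over clusters of the majority-family member count,
    divided by the total number of marker-derived genes.  Background
    (shared-pool) genes are excluded; splitting a family across clusters
    does not reduce purity, merging families does.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("empty clustering")
    markers = {
        pid: fam
        for pid, fam in gene_families.items()
        if not fam.startswith(BACKGROUND_PREFIX)
    }
    total = len(markers)
    if total == 0:
        raise ValueError("no marker-derived genes in the ground truth")
    agree = 0
    for members in clusters:
        fams = [markers[m] for m in members if m in markers]
        if fams:
            agree += max(fams.count(f) for f in set(fams))
    return agree / total


def write_corpus(
    genomes: list[GenomeRecord],
    labels: HostLabelTable,
    truth: dict[str, list[PlantedGene]],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit FASTA + labels TSV + truth JSON into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out_dir / "genomes.fasta",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "truth.json",
    }
    write_genomes(genomes, paths["genomes"])
    write_host_table(labels, paths["labels"])
    doc = {
        gid: [{"start": g.start, "end": g.end, "family": g.family} for g in genes]
        for gid, genes in truth.items()
    }
    with open(paths["truth"], "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_truth(path: str | Path) -> dict[str, list[PlantedGene]]:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        gid: [PlantedGene(start=g["start"], end=g["end"], family=g["family"]) for g in genes]
        for gid, genes in doc.items()
    }
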