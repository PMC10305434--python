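"""Deterministic six-frame ORF calling and translation (genetic code 11).

This is a deliberately simple maximal-ORF scanner: an ORF runs from the
first start codon (ATG/GTG/TTG) after the previous in-frame stop (or the
sequence start) to the next in-frame stop.  It has no coding-potential
model — downstream clustering only needs consistent gene products, and
user-supplied protein FASTA from a dedicated gene finder can be swapped
in at any pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .io_formats import GenomeRecord

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)  # TAA TAG TGA
START_CODONS: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneCall:
    """A predicted coding region in forward-strand coordinates.

    start/end are 0-based half-open; nt_seq is the coding-strand DNA
    (including the start codon and, when present, the terminal stop).
    """

    genome_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str


def translate(nt: str, as_start: bool = False) -> str:
    """Translate a CDS under genetic code 11.

    A terminal stop codon is dropped; an internal stop raises.  With
    ``as_start`` the leading codon is rendered M when it is a valid
    alternative start (GTG/TTG).
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    nt = nt.upper()
    aa: list[str] = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        try:
            aa.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"untranslatable codon {codon!r} at codon index {i}") from None
    if as_start and aa and nt[:3] in START_CODONS:
        aa[0] = "M"
    return "".join(aa)


def _scan_strand(seq: str, min_aa: int):
    """Yield (start, end, has_stop) spans of maximal ORFs on one strand."""
    n = len(seq)
    for frame in range(3):
        open_at: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if "N" in codon:
                # untranslatable codon truncates any open ORF here
                if open_at is not None and (pos - open_at) // 3 >= min_aa:
                    yield open_at, pos, False
                open_at = None
            elif codon in STOP_CODONS:
                if open_at is not None and (pos - open_at) // 3 >= min_aa:
                    yield open_at, pos + 3, True
                open_at = None
            elif open_at is None and codon in START_CODONS:
                open_at = pos
            pos += 3
        # trailing span without a stop codon is not an ORF


def find_orfs(genome: GenomeRecord, min_aa: int = 30) -> list[GeneCall]:
    """Scan all six frames of a genome for maximal ORFs of >= min_aa residues.

    Reverse-strand calls are reported in forward-strand coordinates with
    strand '-'.  Output is sorted by (start, end, strand).
    """
    seq = genome.sequence.upper()
    n = len(seq)
    calls: list[GeneCall] = []

    for s, e, has_stop in _scan_strand(seq, min_aa):
        nt = seq[s:e]
        aa = translate(nt, as_start=True)
        calls.append(GeneCall(genome.id, s, e, "+", nt, aa))

    rc = revcomp(seq)
    for s, e, has_stop in _scan_strand(rc, min_aa):
        nt = rc[s:e]
        aa = translate(nt, as_start=True)
        calls.append(GeneCall(genome.id, n - e, n - s, "-", nt, aa))

    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls


def call_genes(genome: GenomeRecord, min_aa: int = 30) -> dict[str, GeneCall]:
    """Call ORFs and key them as ``<genome_id>_<serial>`` in sorted order."""
    return {
        f"{genome.id}_{i + 1}": call
        for i, call in enumerate(find_orfs(genome, min_aa=min_aa))
    }


def proteins_of(calls: dict[str, GeneCall]) -> dict[str, str]:
    return {pid: c.aa_seq for pid, c in calls.items()}


def write_gff3(calls: dict[str, GeneCall], path) -> None:
    """Dump gene calls as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid, c in calls.items():
            fh.write(
                f"{c.genome_id}\tphagehost\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                f"{c.strand}\t0\tID={pid}\n"
            )
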