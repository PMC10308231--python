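"""Sequence and annotation I/O plus shared sequence utilities.

All genomic coordinates in this package are 1-based inclusive (GFF
convention).  The only place offsets change is in the slicing helpers
here, which convert to Python half-open slices internally.

Ambiguity policy: ``N`` is accepted in genomic sequence but never counts
as a match in any identity computation downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SeqIOError(ValueError):
    """Raised for malformed sequence or annotation input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(nt: str) -> str:
    """Translate a coding-strand CDS to protein.

    A terminal stop is trimmed; internal stops (possible in simulated
    sequence after substitution) are masked as ``X`` so downstream
    protein alignment never sees ``*``.
    """
    trimmed = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(trimmed).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa.replace("*", "X")


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


@dataclass
class GenomeRecord:
    """A strain's assembly: ordered contigs plus free-form metadata."""

    strain_id: str
    contigs: list[tuple[str, str]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if not seq:
                raise SeqIOError(f"empty contig {cid!r} in {self.strain_id}")
            if cid in seen:
                raise SeqIOError(f"duplicate contig id {cid!r} in {self.strain_id}")
            seen.add(cid)

    @property
    def total_size(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    @property
    def gc(self) -> float:
        joined = "".join(s for _, s in self.contigs)
        return gc_fraction(joined)

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def slice(self, contig_id: str, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end] (1-based inclusive) on the given strand."""
        seq = self.contig_seq(contig_id)
        if not (1 <= start <= end <= len(seq)):
            raise SeqIOError(
                f"coordinates {start}..{end} outside contig {contig_id!r} "
                f"(length {len(seq)})"
            )
        sub = seq[start - 1 : end]
        return sub if strand == "+" else reverse_complement(sub)


@dataclass
class GeneRecord:
    """One annotated CDS, sequence stored on the coding strand."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SeqIOError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not (1 <= self.start <= self.end):
            raise SeqIOError(f"bad coordinates for {self.gene_id}")
        if len(self.sequence) != self.end - self.start + 1:
            raise SeqIOError(
                f"sequence length mismatch for {self.gene_id}: "
                f"{len(self.sequence)} != {self.end - self.start + 1}"
            )


@dataclass
class MarkerProfile:
    """Per-strain marker genes used for OTU clustering and trees.

    ``concat`` is always the 16S-like sequence followed directly by the
    rpoD-like sequence (fixed order, no spacer).
    """

    strain_id: str
    seq_16s: str
    seq_rpod: str

    @property
    def concat(self) -> str:
        return self.seq_16s + self.seq_rpod


def _check_nucleotide(rec_id: str, seq: str, on_ambiguous: str) -> str:
    bad = set(seq) - NUCLEOTIDES
    if bad:
        if on_ambiguous == "reject":
            raise SeqIOError(
                f"record {rec_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        table = str.maketrans({c: "N" for c in bad})
        seq = seq.translate(table)
    return seq


def read_fasta(
    path: str | Path | io.TextIOBase,
    alphabet: str = "nucleotide",
    on_ambiguous: str = "reject",
) -> list[tuple[str, str]]:
    """Read a multi-FASTA file into ``[(id, SEQUENCE), ...]`` in file order.

    Sequences are upper-cased.  In nucleotide mode characters outside
    {A,C,G,T,N} are rejected (default) or mapped to N
    (``on_ambiguous="mask"``).  Duplicate ids and empty files are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise SeqIOError("FASTA record with empty header")
        if rec.id in seen:
            raise SeqIOError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            seq = _check_nucleotide(rec.id, seq, on_ambiguous)
        records.append((rec.id, seq))
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genome(path: str | Path, strain_id: str | None = None, **meta: str) -> GenomeRecord:
    """Load an assembly FASTA as a GenomeRecord (masking ambiguity to N)."""
    recs = read_fasta(path, on_ambiguous="mask")
    sid = strain_id or Path(path).stem
    return GenomeRecord(strain_id=sid, contigs=recs, metadata=dict(meta))


def read_annotation(path: str | Path, genome: GenomeRecord) -> list[GeneRecord]:
    """Read a GFF3-style table of CDS features against a genome.

    Only seqid, type==CDS, start, end, strand and the ID attribute are
    consumed.  Minus-strand features are reverse-complemented so the
    returned sequence is the coding strand.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise SeqIOError(f"malformed annotation line: {line[:80]!r}")
            seqid, _source, ftype, start, end, _score, strand, _frame, attrs = parts[:9]
            if ftype != "CDS":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise SeqIOError(f"CDS feature without ID attribute: {line[:80]!r}")
            s, e = int(start), int(end)
            try:
                seq = genome.slice(seqid, s, e, strand)
            except (KeyError, SeqIOError) as exc:
                raise SeqIOError(f"feature {gene_id!r}: {exc}") from exc
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome.strain_id,
                    contig_id=seqid,
                    start=s,
                    end=e,
                    strand=strand,
                    sequence=seq,
                )
            )
    return genes


def write_annotation(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as a GFF3-style CDS table (round-trips read_annotation)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tstrainsort\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.gene_id}\n"
            )


def read_marker_table(path: str | Path) -> list[MarkerProfile]:
    """Read a markers TSV with columns strain_id, seq_16s, seq_rpod."""
    profiles: list[MarkerProfile] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = [header.index(c) for c in ("strain_id", "seq_16s", "seq_rpod")]
        except ValueError as exc:
            raise SeqIOError(f"markers table needs strain_id/seq_16s/seq_rpod columns: {exc}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sid, s16, rpo = (parts[i] for i in idx)
            if sid in seen:
                raise SeqIOError(f"duplicate strain_id {sid!r} in markers table")
            seen.add(sid)
            profiles.append(MarkerProfile(sid, s16.upper(), rpo.upper()))
    if not profiles:
        raise SeqIOError(f"no marker profiles in {path}")
    return profiles


def write_marker_table(profiles: Sequence[MarkerProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\tseq_16s\tseq_rpod\n")
        for p in profiles:
            fh.write(f"{p.strain_id}\t{p.seq_16s}\t{p.seq_rpod}\n")


# Newick I/O lives with the tree structure; re-exported here because tree
# files are one of the package's external formats.
from .phylo import PhyloTree, read_newick, write_newick  # noqa: E402,F401
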