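"""Genomic coordinate model and flat-file I/O.

All coordinates are 1-based inclusive, matching GTF and the locus-string
convention used in published lncRNA tables (``start-end;start-end;...``).
The inclusive length of an interval is ``end - start + 1``; a transcript's
length is the sum of its exon lengths.  BED export converts to the 0-based
half-open convention at the boundary, nowhere else.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from intervaltree import IntervalTree

FORWARD = "+"
REVERSE = "-"
UNKNOWN = "."

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class LocusParseError(ValueError):
    """Raised when a locus string or GTF record cannot be interpreted."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval on a chromosome, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )
        if self.strand not in (FORWARD, REVERSE, UNKNOWN):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class TranscriptModel:
    """An oriented multi-exon transcript.

    Exons are stored sorted by start and must be pairwise non-overlapping;
    adjacent (gap-0) exons are tolerated with a warning since assembled
    catalogs occasionally contain them.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise LocusParseError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
            if b.start == a.end + 1:
                warnings.warn(
                    f"{self.transcript_id}: adjacent exons {a.end}/{b.start}",
                    stacklevel=2,
                )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def midpoint(self) -> int:
        s = self.span
        return (s.start + s.end) // 2

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end + 1:
                out.append(
                    GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
                )
        return out


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing chromosome and strand."""

    gene_id: str
    biotype: str = "other"  # protein_coding | noncoding | other
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs >= 1 transcript")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.gene_id}: transcripts disagree on chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def tss(self) -> int:
        """Strand-aware 5' end of the gene span."""
        s = self.span
        return s.start if self.strand != REVERSE else s.end

    def exons(self) -> Iterator[GenomicInterval]:
        for t in self.transcripts:
            yield from t.exons

    def introns(self) -> Iterator[GenomicInterval]:
        for t in self.transcripts:
            yield from t.introns()


class AnnotationSet:
    """Indexed collection of gene models with strand-aware overlap queries."""

    def __init__(self, genes: Iterable[GeneModel] = ()):
        self.genes: dict[str, GeneModel] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.add_gene(g)

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        spans = self._span_trees.setdefault(gene.chrom, IntervalTree())
        s = gene.span
        spans.addi(s.start, s.end + 1, gene.gene_id)  # tree is half-open
        exons = self._exon_trees.setdefault(gene.chrom, IntervalTree())
        for e in gene.exons():
            exons.addi(e.start, e.end + 1, gene.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self:
            yield from g.transcripts

    def get_transcript(self, transcript_id: str) -> TranscriptModel:
        for g in self:
            for t in g.transcripts:
                if t.transcript_id == transcript_id:
                    return t
        raise KeyError(transcript_id)

    def subset_biotype(self, biotype: str) -> "AnnotationSet":
        return AnnotationSet(g for g in self if g.biotype == biotype)

    def genes_overlapping_span(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._span_trees.get(iv.chrom)
        if tree is None:
            return []
        ids = {hit.data for hit in tree.overlap(iv.start, iv.end + 1)}
        return [self.genes[i] for i in sorted(ids)]

    def genes_overlapping_exons(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._exon_trees.get(iv.chrom)
        if tree is None:
            return []
        ids = {hit.data for hit in tree.overlap(iv.start, iv.end + 1)}
        return [self.genes[i] for i in sorted(ids)]


class SequenceStore:
    """Chromosome name -> nucleotide string, with bounds-checked extraction."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "SequenceStore":
        with open(path) as fh:
            return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.sequences:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def extract(self, iv: GenomicInterval) -> str:
        if iv.chrom not in self.sequences:
            raise KeyError(f"chromosome {iv.chrom!r} not in store")
        seq = self.sequences[iv.chrom]
        if iv.end > len(seq):
            raise IndexError(
                f"exon {iv.chrom}:{iv.start}-{iv.end} beyond chromosome "
                f"length {len(seq)}"
            )
        return seq[iv.start - 1 : iv.end]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_LOCUS_TOKEN = re.compile(r"^(\d+)-(\d+)$")


def parse_locus_string(
    locus: str, chrom: str, strand: str, transcript_id: str = "locus", gene_id: str = ""
) -> TranscriptModel:
    """Parse a semicolon-delimited ``start-end`` locus string into a transcript.

    Tolerates whitespace around tokens and thousands separators inside
    coordinates (both occur in typeset tables).
    """
    exons = []
    for raw in locus.split(";"):
        token = raw.strip().replace(",", "")
        if not token:
            continue
        m = _LOCUS_TOKEN.match(token)
        if not m:
            raise LocusParseError(f"malformed locus token {raw.strip()!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if end < start:
            raise LocusParseError(f"inverted coordinates in token {raw.strip()!r}")
        exons.append(GenomicInterval(chrom, start, end, strand))
    if not exons:
        raise LocusParseError(f"empty locus string {locus!r}")
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id or transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
    )


def transcript_length(t: TranscriptModel) -> int:
    """Sum of inclusive exon lengths in bp."""
    return t.length


def spliced_sequence(t: TranscriptModel, store: SequenceStore) -> str:
    """Exon sequences concatenated in genomic order; reverse-complemented as a
    whole for reverse-strand transcripts."""
    try:
        seq = "".join(store.extract(e) for e in t.exons)
    except (KeyError, IndexError) as err:
        raise type(err)(f"{t.transcript_id}: {err}") from err
    if t.strand == REVERSE:
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field8: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field8))


def read_gtf(path, default_biotype: str = "other") -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`.

    Only ``exon`` rows are used to build transcript models (Ensembl-dialect
    attributes, ``gene_id``/``transcript_id`` mandatory).  An optional
    ``gene_biotype`` attribute sets the gene biotype.
    """
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    gene_biotype: dict[str, str] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise LocusParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if feature != "exon":
                continue
            attr = _parse_gtf_attributes(attrs)
            for key in ("gene_id", "transcript_id"):
                if key not in attr:
                    raise LocusParseError(f"{path}:{lineno}: missing {key} attribute")
            tid, gid = attr["transcript_id"], attr["gene_id"]
            if gid not in gene_biotype:
                gene_order.append(gid)
            gene_biotype.setdefault(gid, attr.get("gene_biotype", default_biotype))
            if "gene_biotype" in attr:
                gene_biotype[gid] = attr["gene_biotype"]
            meta = (gid, chrom, strand)
            if tx_meta.setdefault(tid, meta) != meta:
                raise LocusParseError(
                    f"{path}:{lineno}: transcript {tid} changes gene/chrom/strand"
                )
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as err:
                raise LocusParseError(f"{path}:{lineno}: {err}") from err
            tx_exons.setdefault(tid, []).append(iv)

    genes: dict[str, list[TranscriptModel]] = {g: [] for g in gene_order}
    for tid, (gid, chrom, strand) in tx_meta.items():
        genes[gid].append(
            TranscriptModel(tid, gid, chrom, strand, exons=tx_exons[tid])
        )
    return AnnotationSet(
        GeneModel(gid, biotype=gene_biotype[gid], transcripts=sorted(
            txs, key=lambda t: t.transcript_id))
        for gid, txs in genes.items()
    )


def write_gtf(ann: AnnotationSet, path, source: str = "lncforge") -> None:
    with open(path, "w") as fh:
        for gene in ann:
            for t in gene.transcripts:
                for i, e in enumerate(t.exons, start=1):
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{t.transcript_id}"; '
                        f'exon_number "{i}"; '
                        f'gene_biotype "{gene.biotype}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                t.chrom,
                                source,
                                "exon",
                                str(e.start),
                                str(e.end),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def write_bed(transcripts: Iterable[TranscriptModel], path) -> None:
    """BED6 export of transcript spans (0-based half-open)."""
    with open(path, "w") as fh:
        for t in transcripts:
            s = t.span
            fh.write(
                "\t".join(
                    [t.chrom, str(s.start - 1), str(s.end), t.transcript_id, "0",
                     t.strand if t.strand != UNKNOWN else "."]
                )
                + "\n"
            )


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read BED3+ rows as 1-based inclusive intervals (strand from col 6)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise LocusParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = f[5] if len(f) >= 6 and f[5] in (FORWARD, REVERSE) else UNKNOWN
            out.append(GenomicInterval(f[0], int(f[1]) + 1, int(f[2]), strand))
    return out
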