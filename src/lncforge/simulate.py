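"""Deterministic synthetic-data generator with known ground truth.

Emulates the inputs of the lncRNA discovery analysis: a small
multi-chromosome genome, multi-exon protein-coding genes carrying a
codon-biased CDS, planted lncRNAs of the four positional classes
(intergenic, intronic, sense-exonic, antisense), catalog noise
(sub-200-nt fragments, single-exon assemblies, coding-like decoys, known
structural ncRNAs), negative-binomial read counts for two conditions with
a planted differentially expressed fraction, and qPCR/bioassay tables.

Placement is collision-free by construction: every gene or intergenic
transcript occupies its own slot separated by a minimum gap, so the
planted positional class of each lncRNA is unambiguous.  An optional
ambiguous mode deliberately plants precedence conflicts (same-strand
exon overlap plus opposite-strand overlap) to exercise tie-breaking.
One seed fixes every output byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coding_potential import longest_orf
from .genome import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
    reverse_complement,
    write_gtf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Codon pool with a crude but strongly biased usage (no stop codons):
# favors G/C-ending codons the way highly expressed insect CDS does, which
# is what gives coding sequence its hexamer signature.
_PREFERRED_CODONS = [
    "GCC", "CGC", "AAC", "GAC", "TGC", "CAG", "GAG", "GGC", "CAC", "ATC",
    "CTG", "AAG", "TTC", "CCC", "TCC", "ACC", "TAC", "GTG", "ATG", "TGG",
]
_RARE_CODONS = [
    "GCA", "CGT", "AAT", "GAT", "TGT", "CAA", "GAA", "GGT", "CAT", "ATA",
    "TTA", "AAA", "TTT", "CCT", "AGT", "ACT", "TAT", "GTT", "ATT", "GGA",
]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults follow the study design it emulates
    (3,470 lncRNAs split 1879/853/493/245 across the four classes, 632 DE
    transcripts split 297/335, 116 all-zero rows, 3 replicates per strain,
    40-55M mapped fragments per library)."""

    seed: int = 0
    chrom_names: tuple[str, ...] = (
        "Chr1", "Chr2", "Chr3", "Chr4", "Chr5", "Chr6",
        "Scaffold_83", "Scaffold_789",
    )
    chrom_lengths: dict[str, int] | None = None  # None -> auto-sized

    n_coding_genes: int = 2000
    second_isoform_prob: float = 0.5

    n_linc: int = 1879
    n_sense: int = 853
    n_antisense: int = 493
    n_intronic: int = 245

    n_short: int = 22
    n_single_exon: int = 1500
    n_long_orf_decoys: int = 150
    n_hexamer_decoys: int = 150
    n_known_ncrna: int = 200

    n_all_zero: int = 116
    n_de_up_S: int = 297
    n_de_up_R: int = 335
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    library_size_range: tuple[int, int] = (40_000_000, 55_000_000)
    fpkm_log_mean: float = math.log(10.0)
    fpkm_log_sd: float = 1.5

    max_orf_planted: int = 300  # lncRNA sequences are rejected above this
    min_gap: int = 1000

    qpcr_fold: float = 35.86
    qpcr_replicates: int = 4
    qpcr_ct_noise_sd: float = 0.15
    bioassay_mortality: dict = field(
        default_factory=lambda: {
            ("siRNA", 4): 0.7009, ("control", 4): 0.3862,
            ("siRNA", 8): 0.3936, ("control", 8): 0.2675,
        }
    )
    bioassay_n_per_replicate: int = 25
    bioassay_replicates: int = 3

    ambiguous_mode: bool = False
    n_ambiguous: int = 25

    def validate(self) -> None:
        counts = [
            self.n_coding_genes, self.n_linc, self.n_sense, self.n_antisense,
            self.n_intronic, self.n_short, self.n_single_exon,
            self.n_long_orf_decoys, self.n_hexamer_decoys, self.n_known_ncrna,
            self.n_all_zero, self.n_de_up_S, self.n_de_up_R, self.n_replicates,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("negative count in simulation config")
        if self.n_sense + self.n_antisense + self.n_intronic > self.n_coding_genes:
            raise ValueError("not enough coding genes to host attached lncRNAs")
        n_lnc = self.n_linc + self.n_sense + self.n_antisense + self.n_intronic
        if self.n_all_zero + self.n_de_up_S + self.n_de_up_R > n_lnc:
            raise ValueError("all-zero + DE transcripts exceed lncRNA count")

    @property
    def n_lncRNA(self) -> int:
        return self.n_linc + self.n_sense + self.n_antisense + self.n_intronic


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything :func:`generate` produces."""

    config: SimulationConfig
    genome: SequenceStore
    catalog: list[TranscriptModel]
    reference: AnnotationSet  # protein-coding annotation
    counts: pd.DataFrame
    conditions: dict[str, str]
    lengths: pd.Series
    library_sizes: pd.Series
    truth: pd.DataFrame
    known_ncrna_ids: set[str]
    ct_table: pd.DataFrame
    bioassay_table: pd.DataFrame

    def catalog_annotation(self) -> AnnotationSet:
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in self.catalog:
            by_gene.setdefault(t.gene_id, []).append(t)
        return AnnotationSet(
            GeneModel(g, biotype="other", transcripts=txs)
            for g, txs in by_gene.items()
        )

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "catalog": outdir / "catalog.gtf",
            "reference": outdir / "reference.gtf",
            "counts": outdir / "counts.tsv",
            "design": outdir / "design.tsv",
            "truth": outdir / "truth.tsv",
            "known_ncrna_ids": outdir / "known_ncrna_ids.txt",
            "qpcr": outdir / "qpcr_ct.tsv",
            "bioassay": outdir / "bioassay.tsv",
        }
        self.genome.to_fasta(paths["genome"])
        write_gtf(self.catalog_annotation(), paths["catalog"])
        write_gtf(self.reference, paths["reference"])
        self.counts.to_csv(paths["counts"], sep="\t", index_label="transcript_id")
        design = pd.DataFrame(
            {
                "sample": list(self.counts.columns),
                "condition": [self.conditions[s] for s in self.counts.columns],
                "library_size": [
                    int(self.library_sizes[s]) for s in self.counts.columns
                ],
            }
        )
        design.to_csv(paths["design"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["known_ncrna_ids"], "w") as fh:
            for tid in sorted(self.known_ncrna_ids):
                fh.write(tid + "\n")
        self.ct_table.to_csv(paths["qpcr"], sep="\t", index=False)
        self.bioassay_table.to_csv(paths["bioassay"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# sequence helpers

def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _biased_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + codon-biased body + stop; no in-frame internal stops."""
    body_n = max(0, n_codons - 2)
    pick_pref = rng.random(body_n) < 0.8
    pref = rng.integers(0, len(_PREFERRED_CODONS), size=body_n)
    rare = rng.integers(0, len(_RARE_CODONS), size=body_n)
    body = "".join(
        _PREFERRED_CODONS[p] if use else _RARE_CODONS[r]
        for use, p, r in zip(pick_pref, pref, rare)
    )
    stop = _STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _coding_mrna(rng: np.random.Generator, n_codons: int) -> tuple[str, int]:
    """UTR5 + CDS + UTR3; returns (sequence, CDS offset)."""
    utr5 = "".join(chr(b) for b in _random_bases(rng, int(rng.integers(30, 150))))
    utr3 = "".join(chr(b) for b in _random_bases(rng, int(rng.integers(50, 300))))
    cds = _biased_cds(rng, n_codons)
    return utr5 + cds + utr3, len(utr5)


def _hexamer_decoy_seq(rng: np.random.Generator, n_codons: int) -> str:
    """Codon-biased content but with stops seeded every ~70 codons so no
    reading frame carries an ORF longer than the planted cap."""
    out = []
    remaining = n_codons
    while remaining > 0:
        block = int(min(remaining, rng.integers(40, 70)))
        out.append(_biased_cds(rng, block))
        remaining -= block
    return "".join(out)


def _shuffle_seq(rng: np.random.Generator, seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def generate_coding_training_sets(
    n_coding: int = 200,
    n_noncoding: int = 200,
    seed: int = 0,
    codon_range: tuple[int, int] = (120, 400),
) -> tuple[list[str], list[str]]:
    """Training sequences for the coding-potential model: CDS-bearing
    mRNAs vs base-composition-matched shuffles of the same molecules."""
    rng = np.random.default_rng(seed)
    coding = [
        _coding_mrna(rng, int(rng.integers(*codon_range)))[0]
        for _ in range(n_coding)
    ]
    noncoding = []
    for i in range(n_noncoding):
        template = coding[i % len(coding)] if coding else "".join(
            chr(b) for b in _random_bases(rng, 800)
        )
        noncoding.append(_shuffle_seq(rng, template))
    return coding, noncoding


# ---------------------------------------------------------------------------
# layout machinery

@dataclass
class _Chrom:
    name: str
    cursor: int = 0  # next free 0-based offset
    segments: list = field(default_factory=list)  # (offset, np.uint8 array)

    def reserve(self, width: int, gap: int) -> int:
        """Reserve `width` bp; returns the 0-based offset of the slot."""
        offset = self.cursor
        self.cursor += width + gap
        return offset


class _GenomeBuilder:
    def __init__(self, rng: np.random.Generator, names: tuple[str, ...]):
        self.rng = rng
        self.chroms = {n: _Chrom(n) for n in names}
        self._arrays: dict[str, np.ndarray] | None = None

    def place(self, width: int, gap: int) -> tuple[str, int]:
        # round-robin weighted by randomness; deterministic under the rng
        name = list(self.chroms)[int(self.rng.integers(0, len(self.chroms)))]
        return name, self.chroms[name].reserve(width, gap)

    def paste(self, chrom: str, offset: int, seq: str) -> None:
        self.chroms[chrom].segments.append(
            (offset, np.frombuffer(seq.encode(), dtype=np.uint8))
        )

    def finalize(self, tail: int = 2000,
                 fixed_lengths: dict[str, int] | None = None) -> SequenceStore:
        arrays = {}
        for name, ch in self.chroms.items():
            length = ch.cursor + tail
            if fixed_lengths and name in fixed_lengths:
                if fixed_lengths[name] < ch.cursor:
                    raise ValueError(
                        f"chromosome {name} too short ({fixed_lengths[name]} bp) "
                        f"for the requested genes ({ch.cursor} bp needed)"
                    )
                length = fixed_lengths[name]
            arr = _random_bases(self.rng, length).copy()
            for offset, seg in ch.segments:
                arr[offset : offset + seg.size] = seg
            arrays[name] = arr
        self._arrays = arrays
        return SequenceStore(
            {n: a.tobytes().decode() for n, a in arrays.items()}
        )


def _layout_exons(
    exon_lengths: list[int], intron_lengths: list[int]
) -> tuple[int, list[tuple[int, int]]]:
    """Transcription-order exon offsets within a contiguous segment.

    Returns (segment length, [(offset, length), ...]).
    """
    assert len(intron_lengths) == len(exon_lengths) - 1
    offsets = []
    pos = 0
    for i, ex in enumerate(exon_lengths):
        offsets.append((pos, ex))
        pos += ex
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return pos, offsets


def _genome_exons(
    chrom: str,
    slot_offset: int,
    strand: str,
    segment_len: int,
    tx_offsets: list[tuple[int, int]],
) -> list[GenomicInterval]:
    """Map transcription-order offsets to 1-based genome intervals."""
    exons = []
    for off, ln in tx_offsets:
        if strand == "-":
            g_off = segment_len - off - ln
        else:
            g_off = off
        start = slot_offset + g_off + 1  # 1-based
        exons.append(GenomicInterval(chrom, start, start + ln - 1, strand))
    return sorted(exons, key=lambda e: e.start)


def _segment_sequence(strand: str, tx_seq_with_introns: str) -> str:
    return tx_seq_with_introns if strand == "+" else reverse_complement(
        tx_seq_with_introns
    )


# ---------------------------------------------------------------------------
# generation

_LNC_EXON_P = {2: 0.70, 3: 0.14, 4: 0.07, 5: 0.04, 6: 0.03, 7: 0.02}
_CODING_EXON_P = {2: 0.13, 3: 0.17, 4: 0.17, 5: 0.16, 6: 0.14, 7: 0.12, 8: 0.11}


def _draw_from(rng: np.random.Generator, table: dict[int, float]) -> int:
    ks = list(table)
    return int(rng.choice(ks, p=np.array([table[k] for k in ks])))


def _partition(rng: np.random.Generator, total: int, parts: int,
               minimum: int) -> list[int]:
    """Split `total` into `parts` pieces, each >= minimum."""
    if total < parts * minimum:
        raise ValueError("segment too short to partition")
    spare = total - parts * minimum
    w = rng.random(parts) + 0.25
    alloc = np.floor(w / w.sum() * spare).astype(int)
    alloc[-1] += spare - alloc.sum()
    return [minimum + int(a) for a in alloc]


def _rand_str(rng: np.random.Generator, n: int) -> str:
    return _random_bases(rng, n).tobytes().decode()


class _LncPlanner:
    """Assembles a planted transcript from genome-orientation pieces,
    re-randomizing the free pieces until the spliced sequence satisfies
    its ORF constraint, then pastes them into the genome builder."""

    def __init__(self, rng: np.random.Generator, builder: _GenomeBuilder):
        self.rng = rng
        self.builder = builder

    def realize(
        self,
        chrom: str,
        pieces: list[tuple[int, int, str | None]],  # (abs0 start, len, fixed)
        strand: str,
        max_orf: int | None,
        content: str | None = None,
        min_orf: int | None = None,
    ) -> str:
        pieces = sorted(pieces, key=lambda p: p[0])
        for _ in range(60):
            chunks = []
            free_chunks = []
            if content is not None:
                # distribute provided content across the free pieces in
                # transcription order
                free_total = sum(ln for _, ln, fx in pieces if fx is None)
                body = content[:free_total].ljust(free_total, "A")
                pos = 0
            for start, ln, fixed in pieces:
                if fixed is not None:
                    chunks.append(fixed)
                    free_chunks.append(None)
                elif content is not None:
                    chunk = body[pos : pos + ln]
                    pos += ln
                    chunks.append(chunk)
                    free_chunks.append(chunk)
                else:
                    chunk = _rand_str(self.rng, ln)
                    chunks.append(chunk)
                    free_chunks.append(chunk)
            genome_seq = "".join(chunks)
            spliced = genome_seq if strand == "+" else reverse_complement(
                genome_seq
            )
            orf = longest_orf(spliced)
            if (max_orf is None or orf <= max_orf) and (
                min_orf is None or orf > min_orf
            ):
                for (start, ln, fixed), chunk in zip(pieces, free_chunks):
                    if fixed is None:
                        self.builder.paste(chrom, start, chunk)
                return spliced
            if content is not None and max_orf is not None:
                content = None  # give up on exact content, fall back random
        raise RuntimeError("could not satisfy ORF constraint after 60 draws")


def generate(config: SimulationConfig | None = None,
             outdir=None) -> SyntheticDataset:
    """Generate the full synthetic study; optionally write it to ``outdir``."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    builder = _GenomeBuilder(rng, config.chrom_names)
    planner = _LncPlanner(rng, builder)

    catalog: list[TranscriptModel] = []
    ref_genes: list[GeneModel] = []
    truth_rows: list[dict] = []

    def record(tid, category, is_lnc, lnc_class="", host=""):
        truth_rows.append(
            {
                "transcript_id": tid,
                "category": category,
                "is_lncRNA": bool(is_lnc),
                "lnc_class": lnc_class,
                "host_gene": host,
            }
        )

    # ---- host assignment for attached lncRNA classes
    attach: list[str | None] = (
        ["sense"] * config.n_sense
        + ["antisense"] * config.n_antisense
        + ["intronic"] * config.n_intronic
        + [None] * (config.n_coding_genes - config.n_sense
                    - config.n_antisense - config.n_intronic)
    )
    rng.shuffle(attach)

    lnc_counter = 0

    def lnc_exon_geometry(max_exon=2500, max_gap=900) -> tuple[
        list[int], list[int]
    ]:
        # one exon-count/size law for all four classes (the catalog-wide
        # two-exon share is ~70%)
        n_ex = _draw_from(rng, _LNC_EXON_P)
        lens = [
            int(np.clip(rng.lognormal(math.log(350.0), 0.5), 80, max_exon))
            for _ in range(n_ex)
        ]
        gaps = [int(rng.integers(100, max_gap)) for _ in range(n_ex - 1)]
        return lens, gaps

    # ---- coding genes (with attached lncRNAs where assigned)
    for gi in range(config.n_coding_genes):
        kind = attach[gi]
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(150, 450))
        mrna, cds_off = _coding_mrna(rng, n_codons)
        n_exons = _draw_from(rng, _CODING_EXON_P)
        while len(mrna) < n_exons * 60:
            n_exons -= 1
        exon_lens = _partition(rng, len(mrna), n_exons, 60)

        # attached-lncRNA geometry decided before intron sizing
        lnc_lens: list[int] = []
        lnc_gaps: list[int] = []
        if kind in ("intronic", "antisense"):
            lnc_lens, lnc_gaps = lnc_exon_geometry(max_exon=1200, max_gap=400)
        lnc_span_inside = sum(lnc_lens) + sum(lnc_gaps)

        intron_lens = [int(rng.integers(200, 1200)) for _ in range(n_exons - 1)]
        if kind in ("intronic", "antisense"):
            intron_lens[0] = lnc_span_inside + 160

        segment_len, tx_offsets = _layout_exons(exon_lens, intron_lens)

        # sense lncRNA extends into a margin left of the gene slot
        margin = 0
        sense_extra: list[tuple[int, int]] = []  # (gap, length) leftward
        sense_ext = 0
        if kind == "sense":
            sense_ext = int(rng.integers(80, 400))
            extra_lens, extra_gaps = lnc_exon_geometry(max_exon=1200,
                                                       max_gap=400)
            # first drawn exon becomes the gene-overlapping one; the rest
            # extend leftward into the margin
            sense_extra = list(zip(extra_gaps, extra_lens[1:]))
            margin = sense_ext + sum(g + L for g, L in sense_extra) + 60

        chrom, slot = builder.place(margin + segment_len, config.min_gap)
        gene_start0 = slot + margin

        # build and paste the gene's genomic segment
        tx_seq = []
        pos = 0
        for i, ex in enumerate(exon_lens):
            tx_seq.append(mrna[pos : pos + ex])
            pos += ex
            if i < len(intron_lens):
                tx_seq.append(_rand_str(rng, intron_lens[i]))
        seg = _segment_sequence(strand, "".join(tx_seq))
        builder.paste(chrom, gene_start0, seg)

        exons = _genome_exons(chrom, gene_start0, strand, segment_len, tx_offsets)
        gid = f"GENE{gi + 1:05d}"
        primary = TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons=exons)
        ref_genes.append(
            GeneModel(gid, biotype="protein_coding", transcripts=[primary])
        )

        # catalog entries for the gene (assembled isoforms)
        cat_gid = f"MSTRG.C{gi + 1}"
        catalog.append(
            TranscriptModel(f"{cat_gid}.1", cat_gid, chrom, strand, exons=exons)
        )
        record(f"{cat_gid}.1", "coding", False)
        if n_exons >= 3 and rng.random() < config.second_isoform_prob:
            # truncated isoform keeps the complete CDS: drop the last
            # transcription-order exon only if the stop codon survives
            kept = exon_lens[:-1]
            if cds_off + 3 * n_codons <= sum(kept):
                if strand == "+":
                    iso_exons = exons[:-1]
                else:
                    iso_exons = exons[1:]
                catalog.append(
                    TranscriptModel(
                        f"{cat_gid}.2", cat_gid, chrom, strand, exons=iso_exons
                    )
                )
                record(f"{cat_gid}.2", "coding", False)

        # attached lncRNA
        if kind is not None:
            lnc_counter += 1
            tid = f"LNC.{lnc_counter:05d}"
            if kind == "sense":
                host_exon = exons[0]  # genome-leftmost exon
                ov = int(rng.integers(40, min(180, len(host_exon)) + 1))
                pieces = []
                a_start0 = host_exon.start - 1 - sense_ext
                pieces.append((a_start0, sense_ext, None))
                seg_idx = host_exon.start - 1 - gene_start0
                pieces.append(
                    (host_exon.start - 1, ov, seg[seg_idx : seg_idx + ov])
                )
                left = a_start0
                for gap, L in sense_extra:
                    left = left - gap - L
                    pieces.append((left, L, None))
                lnc_strand = strand
                planner.realize(chrom, pieces, lnc_strand,
                                config.max_orf_planted)
                merged = sorted(
                    (s, ln) for s, ln, _ in pieces
                )
                # exon A is split into its free and fixed halves above;
                # merge contiguous pieces back into exons
                exon_ivs = []
                cur_s, cur_l = merged[0]
                for s, ln in merged[1:]:
                    if s == cur_s + cur_l:
                        cur_l += ln
                    else:
                        exon_ivs.append((cur_s, cur_l))
                        cur_s, cur_l = s, ln
                exon_ivs.append((cur_s, cur_l))
                lnc_exons = [
                    GenomicInterval(chrom, s + 1, s + ln, lnc_strand)
                    for s, ln in exon_ivs
                ]
            else:
                # inside the inflated first intron (transcription order)
                i_off = exon_lens[0]
                i_len = intron_lens[0]
                if strand == "-":
                    i_g_off = segment_len - (i_off + i_len)
                else:
                    i_g_off = i_off
                base0 = gene_start0 + i_g_off + 80
                pieces = []
                pos0 = base0
                for k, L in enumerate(lnc_lens):
                    pieces.append((pos0, L, None))
                    pos0 += L
                    if k < len(lnc_gaps):
                        pos0 += lnc_gaps[k]
                lnc_strand = strand if kind == "intronic" else (
                    "-" if strand == "+" else "+"
                )
                planner.realize(chrom, pieces, lnc_strand,
                                config.max_orf_planted)
                lnc_exons = [
                    GenomicInterval(chrom, s + 1, s + ln, lnc_strand)
                    for s, ln, _ in pieces
                ]
            lnc_cls = {"sense": "sense", "antisense": "antisense",
                       "intronic": "intronic"}[kind]
            catalog.append(
                TranscriptModel(tid, tid, chrom, lnc_strand, exons=lnc_exons)
            )
            record(tid, "lncRNA", True, lnc_cls, gid)

    # ---- intergenic units ------------------------------------------------
    def place_intergenic(lens: list[int], gaps: list[int], strand: str):
        span = sum(lens) + sum(gaps)
        chrom, slot = builder.place(span, config.min_gap)
        pieces = []
        pos0 = slot
        for k, L in enumerate(lens):
            pieces.append((pos0, L, None))
            pos0 += L
            if k < len(gaps):
                pos0 += gaps[k]
        return chrom, pieces

    # lincRNAs
    for _ in range(config.n_linc):
        lnc_counter += 1
        tid = f"LNC.{lnc_counter:05d}"
        lens, gaps = lnc_exon_geometry()
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, pieces = place_intergenic(lens, gaps, strand)
        planner.realize(chrom, pieces, strand, config.max_orf_planted)
        catalog.append(
            TranscriptModel(
                tid, tid, chrom, strand,
                exons=[GenomicInterval(chrom, s + 1, s + ln, strand)
                       for s, ln, _ in pieces],
            )
        )
        record(tid, "lncRNA", True, "lincRNA")

    # coding-like decoys: long-ORF and hexamer-biased
    for d in range(config.n_long_orf_decoys):
        tid = f"DECOY.ORF.{d + 1}"
        lens, gaps = lnc_exon_geometry()
        n_codons = int(rng.integers(config.max_orf_planted // 3 + 40, 320))
        while sum(lens) < 3 * n_codons + 60:
            lens[int(rng.integers(0, len(lens)))] += 3 * n_codons
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, pieces = place_intergenic(lens, gaps, strand)
        total = sum(lens)
        cds = _biased_cds(rng, n_codons)
        at = int(rng.integers(0, total - len(cds) + 1))
        content = _rand_str(rng, at) + cds + _rand_str(rng, total - at - len(cds))
        planner.realize(chrom, pieces, strand, None, content=content,
                        min_orf=config.max_orf_planted)
        catalog.append(
            TranscriptModel(
                tid, tid, chrom, strand,
                exons=[GenomicInterval(chrom, s + 1, s + ln, strand)
                       for s, ln, _ in pieces],
            )
        )
        record(tid, "long_orf_decoy", False)

    for d in range(config.n_hexamer_decoys):
        tid = f"DECOY.HEX.{d + 1}"
        lens, gaps = lnc_exon_geometry()
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, pieces = place_intergenic(lens, gaps, strand)
        content = _hexamer_decoy_seq(rng, sum(lens) // 3 + 2)
        planner.realize(chrom, pieces, strand, config.max_orf_planted,
                        content=content)
        catalog.append(
            TranscriptModel(
                tid, tid, chrom, strand,
                exons=[GenomicInterval(chrom, s + 1, s + ln, strand)
                       for s, ln, _ in pieces],
            )
        )
        record(tid, "hexamer_decoy", False)

    # known structural ncRNAs (removed via the exclusion list)
    known_ncrna_ids = set()
    for d in range(config.n_known_ncrna):
        tid = f"NCRNA.{d + 1}"
        known_ncrna_ids.add(tid)
        lens = [int(rng.integers(120, 320)) for _ in range(2)]
        gaps = [int(rng.integers(80, 400))]
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, pieces = place_intergenic(lens, gaps, strand)
        planner.realize(chrom, pieces, strand, config.max_orf_planted)
        catalog.append(
            TranscriptModel(
                tid, tid, chrom, strand,
                exons=[GenomicInterval(chrom, s + 1, s + ln, strand)
                       for s, ln, _ in pieces],
            )
        )
        record(tid, "known_ncrna", False)

    # ambiguous-precedence plants (optional)
    if config.ambiguous_mode:
        for d in range(config.n_ambiguous):
            tid = f"LNC.AMB.{d + 1}"
            # gene A (same strand as lnc) and gene B (opposite), adjacent
            strand = "+" if rng.random() < 0.5 else "-"
            a_len = int(rng.integers(400, 900))
            b_len = int(rng.integers(400, 900))
            spacer = 150
            chrom, slot = builder.place(a_len + spacer + b_len,
                                        config.min_gap)
            a_seq = _rand_str(rng, a_len)
            b_seq = _rand_str(rng, b_len)
            builder.paste(chrom, slot, a_seq)
            builder.paste(chrom, slot + a_len + spacer, b_seq)
            gid_a = f"GENEAMB{d + 1:03d}A"
            gid_b = f"GENEAMB{d + 1:03d}B"
            opp = "-" if strand == "+" else "+"
            ga = GenomicInterval(chrom, slot + 1, slot + a_len, strand)
            gb = GenomicInterval(chrom, slot + a_len + spacer + 1,
                                 slot + a_len + spacer + b_len, opp)
            ref_genes.append(GeneModel(gid_a, biotype="protein_coding",
                                       transcripts=[TranscriptModel(
                                           f"{gid_a}.t1", gid_a, chrom,
                                           strand, exons=[ga])]))
            ref_genes.append(GeneModel(gid_b, biotype="protein_coding",
                                       transcripts=[TranscriptModel(
                                           f"{gid_b}.t1", gid_b, chrom,
                                           opp, exons=[gb])]))
            # lnc exon 1 overlaps A's 3' end, exon 2 sits inside B's span
            ov = 60
            pieces = [
                (slot + a_len - ov, ov, a_seq[a_len - ov :]),
                (slot + a_len, 80, None),
                (slot + a_len + spacer + 30, 120, b_seq[30:150]),
            ]
            planner.realize(chrom, pieces, strand, config.max_orf_planted)
            exon_ivs = [
                GenomicInterval(chrom, slot + a_len - ov + 1,
                                slot + a_len + 80, strand),
                GenomicInterval(chrom, slot + a_len + spacer + 31,
                                slot + a_len + spacer + 150, strand),
            ]
            catalog.append(TranscriptModel(tid, tid, chrom, strand,
                                           exons=exon_ivs))
            record(tid, "lncRNA_ambiguous", True, "sense", gid_a)

    genome = builder.finalize(fixed_lengths=config.chrom_lengths)

    # short fragments and single-exon assemblies: positions are immaterial
    # (removed by the structural filters), so they sample existing sequence
    for d in range(config.n_short):
        tid = f"JUNK.S{d + 1}"
        L = int(rng.integers(60, 200))
        chrom = config.chrom_names[int(rng.integers(0, len(config.chrom_names)))]
        start = int(rng.integers(1, genome.chrom_length(chrom) - L))
        strand = "+" if rng.random() < 0.5 else "-"
        if L >= 120 and rng.random() < 0.5:
            half = L // 2
            exons = [
                GenomicInterval(chrom, start, start + half - 1, strand),
                GenomicInterval(chrom, start + half + 100,
                                start + half + 100 + (L - half) - 1, strand),
            ]
        else:
            exons = [GenomicInterval(chrom, start, start + L - 1, strand)]
        catalog.append(TranscriptModel(tid, tid, chrom, strand, exons=exons))
        record(tid, "short", False)

    for d in range(config.n_single_exon):
        tid = f"JUNK.E{d + 1}"
        L = int(rng.integers(250, 1500))
        chrom = config.chrom_names[int(rng.integers(0, len(config.chrom_names)))]
        start = int(rng.integers(1, genome.chrom_length(chrom) - L))
        strand = "+" if rng.random() < 0.5 else "-"
        catalog.append(
            TranscriptModel(
                tid, tid, chrom, strand,
                exons=[GenomicInterval(chrom, start, start + L - 1, strand)],
            )
        )
        record(tid, "single_exon", False)

    truth = pd.DataFrame(truth_rows)

    # ---- expression ------------------------------------------------------
    lnc_ids = truth.loc[truth["category"] == "lncRNA", "transcript_id"].tolist()
    picked = rng.permutation(np.array(lnc_ids))
    all_zero = set(picked[: config.n_all_zero])
    up_s = set(picked[config.n_all_zero : config.n_all_zero + config.n_de_up_S])
    up_r = set(
        picked[
            config.n_all_zero + config.n_de_up_S :
            config.n_all_zero + config.n_de_up_S + config.n_de_up_R
        ]
    )

    samples = [f"S{i + 1}" for i in range(config.n_replicates)] + [
        f"R{i + 1}" for i in range(config.n_replicates)
    ]
    conditions = {s: s[0] for s in samples}
    lib_lo, lib_hi = config.library_size_range
    library_sizes = pd.Series(
        rng.integers(lib_lo, lib_hi, size=len(samples)).astype(float),
        index=samples,
    )

    ids = [t.transcript_id for t in catalog]
    lengths = pd.Series([t.length for t in catalog], index=ids, dtype=float)
    base_fpkm = pd.Series(
        rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd, size=len(ids)),
        index=ids,
    )

    de_status, true_lfc = [], []
    for tid in ids:
        if tid in all_zero:
            de_status.append("all_zero")
            true_lfc.append(np.nan)
        elif tid in up_s:
            de_status.append("up_in_S")
            true_lfc.append(-config.de_log2fc)
        elif tid in up_r:
            de_status.append("up_in_R")
            true_lfc.append(config.de_log2fc)
        else:
            de_status.append("none")
            true_lfc.append(0.0)
    status = pd.Series(de_status, index=ids)
    lfc = pd.Series(true_lfc, index=ids)

    mean_s = base_fpkm * np.power(2.0, -lfc.fillna(0.0) / 2.0)
    mean_r = base_fpkm * np.power(2.0, lfc.fillna(0.0) / 2.0)
    mean_s[status == "all_zero"] = 0.0
    mean_r[status == "all_zero"] = 0.0

    counts = {}
    r_shape = 1.0 / config.nb_dispersion
    for s in samples:
        mu = (mean_s if conditions[s] == "S" else mean_r) * (
            lengths / 1e3
        ) * (library_sizes[s] / 1e6)
        mu_arr = mu.values
        c = np.zeros(len(ids), dtype=np.int64)
        pos = mu_arr > 0
        p = r_shape / (r_shape + mu_arr[pos])
        c[pos] = rng.negative_binomial(r_shape, p)
        counts[s] = c
    counts = pd.DataFrame(counts, index=ids)

    truth = truth.set_index("transcript_id")
    truth["de_status"] = status
    truth["true_log2fc_R_vs_S"] = lfc
    truth["base_fpkm"] = base_fpkm
    truth = truth.reset_index()

    # ---- qPCR and bioassay ----------------------------------------------
    ct_rows = []
    for grp, n_rep in (("control", config.qpcr_replicates),
                       ("treatment", config.qpcr_replicates)):
        for r in range(n_rep):
            ref_ct = float(rng.normal(18.0, 0.2))
            dct = 5.0 + float(rng.normal(0.0, config.qpcr_ct_noise_sd))
            if grp == "treatment":
                dct -= math.log2(config.qpcr_fold)
            ct_rows.append(
                {
                    "sample": f"{grp}_{r + 1}",
                    "group": grp,
                    "target_ct": round(ref_ct + dct, 4),
                    "reference_ct": round(ref_ct, 4),
                }
            )
    ct_table = pd.DataFrame(ct_rows)

    bio_rows = []
    for (grp, day), p_mort in sorted(config.bioassay_mortality.items()):
        for r in range(config.bioassay_replicates):
            n = config.bioassay_n_per_replicate
            dead = int(rng.binomial(n, p_mort))
            bio_rows.append(
                {"group": grp, "replicate": r + 1, "day": day,
                 "n_treated": n, "n_dead": dead}
            )
    bioassay_table = pd.DataFrame(bio_rows)

    dataset = SyntheticDataset(
        config=config,
        genome=genome,
        catalog=catalog,
        reference=AnnotationSet(ref_genes),
        counts=counts,
        conditions=conditions,
        lengths=lengths,
        library_sizes=library_sizes,
        truth=truth,
        known_ncrna_ids=known_ncrna_ids,
        ct_table=ct_table,
        bioassay_table=bioassay_table,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
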