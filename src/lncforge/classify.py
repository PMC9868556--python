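"""Positional classification of lncRNAs against a protein-coding annotation.

Each lncRNA receives exactly one of four classes:

* ``sense`` — an lncRNA exon overlaps a same-strand coding-gene exon;
* ``intronic`` — the lncRNA span lies inside a same-strand coding gene and
  touches only intronic sequence;
* ``antisense`` — an lncRNA exon overlaps an opposite-strand coding gene
  (exonic or intronic sequence);
* ``lincRNA`` — no overlap with any coding gene (intergenic).

Precedence when several rules fire is sense > intronic > antisense >
lincRNA: same-strand evidence outranks opposite-strand.  Structural
summaries (exon-number, exon-size and length distributions) live here too.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import AnnotationSet, GeneModel, TranscriptModel

LNC_CLASSES = ("lincRNA", "intronic", "sense", "antisense")


@dataclass
class ClassEvidence:
    lnc_class: str
    gene_id: str | None
    overlap_bp: int


def _exon_overlap_bp(t: TranscriptModel, gene: GeneModel) -> int:
    """Total lncRNA-exon vs gene-exon overlap (bp), merged per lnc exon."""
    total = 0
    for e in t.exons:
        covered: list[tuple[int, int]] = []
        for g in gene.exons():
            ov_s, ov_e = max(e.start, g.start), min(e.end, g.end)
            if ov_s <= ov_e:
                covered.append((ov_s, ov_e))
        # merge to avoid double-counting overlapping isoform exons
        covered.sort()
        cur_s = cur_e = None
        for s, en in covered:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    total += cur_e - cur_s + 1
                cur_s, cur_e = s, en
            else:
                cur_e = max(cur_e, en)
        if cur_e is not None:
            total += cur_e - cur_s + 1
    return total


def _span_overlap_bp(t: TranscriptModel, gene: GeneModel) -> int:
    span = gene.span
    return sum(
        max(0, min(e.end, span.end) - max(e.start, span.start) + 1) for e in t.exons
    )


def _best(gene_hits: dict[str, int]) -> tuple[str, int]:
    # max overlap bp, ties broken by lexicographically smaller gene_id
    gid = min(gene_hits, key=lambda g: (-gene_hits[g], g))
    return gid, gene_hits[gid]


def classify(
    t: TranscriptModel,
    ann: AnnotationSet,
    antisense_exon_only: bool = False,
) -> ClassEvidence:
    """Classify one lncRNA against a (protein-coding) annotation.

    ``antisense_exon_only`` restricts rule 3 to opposite-strand *exon*
    overlap; by default any opposite-strand overlap within the gene span
    triggers ``antisense``.
    """
    span = t.span
    candidates = ann.genes_overlapping_span(span)
    if span.chrom not in ann._span_trees:
        warnings.warn(
            f"{t.transcript_id}: chromosome {span.chrom!r} absent from "
            "annotation; classified lincRNA",
            stacklevel=2,
        )
        return ClassEvidence("lincRNA", None, 0)

    same = [g for g in candidates if g.strand == t.strand]
    opposite = [g for g in candidates if g.strand != t.strand]

    # rule 1: same-strand exonic overlap -> sense
    sense_hits = {
        g.gene_id: bp for g in same if (bp := _exon_overlap_bp(t, g)) >= 1
    }
    if sense_hits:
        gid, bp = _best(sense_hits)
        return ClassEvidence("sense", gid, bp)

    # rule 2: contained in a same-strand gene, intronic sequence only
    intronic_hits = {}
    for g in same:
        gspan = g.span
        if gspan.start <= span.start and span.end <= gspan.end:
            intronic_hits[g.gene_id] = _span_overlap_bp(t, g)
    if intronic_hits:
        gid, bp = _best(intronic_hits)
        return ClassEvidence("intronic", gid, bp)

    # rule 3: opposite-strand overlap -> antisense
    antisense_hits = {}
    for g in opposite:
        bp = _exon_overlap_bp(t, g) if antisense_exon_only else _span_overlap_bp(t, g)
        if bp >= 1:
            antisense_hits[g.gene_id] = bp
    if antisense_hits:
        gid, bp = _best(antisense_hits)
        return ClassEvidence("antisense", gid, bp)

    return ClassEvidence("lincRNA", None, 0)


def classify_all(
    catalog: list[TranscriptModel],
    ann: AnnotationSet,
    antisense_exon_only: bool = False,
) -> tuple[pd.DataFrame, Counter]:
    """Classify a catalog; returns a per-transcript table and class counts.

    The counts always partition the catalog: every transcript gets exactly
    one class.
    """
    rows = []
    for t in catalog:
        ev = classify(t, ann, antisense_exon_only=antisense_exon_only)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "lnc_class": ev.lnc_class,
                "evidence_gene": ev.gene_id or "",
                "overlap_bp": ev.overlap_bp,
            }
        )
    table = pd.DataFrame(
        rows, columns=["transcript_id", "lnc_class", "evidence_gene", "overlap_bp"]
    )
    counts = Counter({c: 0 for c in LNC_CLASSES})
    counts.update(table["lnc_class"].tolist() if rows else [])
    return table, counts


# ---------------------------------------------------------------------------
# Structural summaries

def exon_number_distribution(catalog: list[TranscriptModel]) -> Counter:
    """Histogram of exon counts; masses sum to catalog size."""
    return Counter(t.exon_count for t in catalog)


def exon_size_distribution(
    catalog: list[TranscriptModel], bin_edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of exon lengths.  Default bins are 200-bp wide starting at 0
    (the first bin isolates the sub-200-bp exon share)."""
    sizes = np.array([len(e) for t in catalog for e in t.exons], dtype=float)
    if bin_edges is None:
        top = sizes.max() if sizes.size else 200.0
        bin_edges = np.arange(0, top + 200.0, 200.0)
    hist, edges = np.histogram(sizes, bins=bin_edges)
    return hist, edges


def length_summary(catalog: list[TranscriptModel]) -> dict[str, float]:
    """Mean and median spliced transcript length (bp)."""
    if not catalog:
        raise ValueError("length summary of an empty catalog")
    lengths = np.array([t.length for t in catalog], dtype=float)
    return {
        "n": int(lengths.size),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "min": float(lengths.min()),
        "max": float(lengths.max()),
    }
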