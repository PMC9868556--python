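"""Cis-neighbor mapping: lncRNAs to candidate target protein-coding genes.

Following the GREAT regulatory-zone convention, a coding gene is a
candidate cis target of an lncRNA when the distance between the lncRNA
gene-span midpoint and the coding gene's TSS is at most the window
(default 1000 kb), on the same chromosome.  The boundary is inclusive;
strand affects only where the TSS sits, never inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AnnotationSet, TranscriptModel

DEFAULT_WINDOW = 1_000_000


@dataclass
class NeighborPair:
    lnc_id: str
    gene_id: str
    distance_bp: int  # |midpoint - TSS|
    signed_offset: int  # TSS - midpoint (chromosome orientation)
    side: str  # upstream | downstream | overlapping
    families: list[str] = field(default_factory=list)


def _side(signed_offset: int, lnc: TranscriptModel) -> str:
    span = lnc.span
    # TSS inside the lncRNA span counts as overlapping; otherwise the side
    # is reported in chromosome orientation relative to the lncRNA.
    tss = lnc.midpoint + signed_offset
    if span.start <= tss <= span.end:
        return "overlapping"
    return "downstream" if signed_offset > 0 else "upstream"


def _tss_index(ann: AnnotationSet) -> dict[str, tuple[np.ndarray, list[str]]]:
    """Per-chromosome (sorted TSS positions, gene ids), cached on the
    annotation object."""
    cached = getattr(ann, "_tss_index_cache", None)
    if cached is not None and cached[0] == len(ann.genes):
        return cached[1]
    index: dict[str, tuple[np.ndarray, list[str]]] = {}
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene in ann:
        per_chrom.setdefault(gene.chrom, []).append((gene.tss, gene.gene_id))
    for chrom, items in per_chrom.items():
        items.sort()
        index[chrom] = (
            np.array([t for t, _ in items], dtype=np.int64),
            [g for _, g in items],
        )
    ann._tss_index_cache = (len(ann.genes), index)
    return index


def neighbors_within(
    lnc: TranscriptModel,
    ann: AnnotationSet,
    window: int = DEFAULT_WINDOW,
) -> list[NeighborPair]:
    """All coding genes with |TSS - lnc midpoint| <= window on the lncRNA's
    chromosome, sorted by distance ascending (ties by gene_id)."""
    mid = lnc.midpoint
    index = _tss_index(ann)
    pairs = []
    if lnc.chrom in index:
        tss_arr, gene_ids = index[lnc.chrom]
        lo = int(np.searchsorted(tss_arr, mid - window, side="left"))
        hi = int(np.searchsorted(tss_arr, mid + window, side="right"))
        for i in range(lo, hi):
            offset = int(tss_arr[i]) - mid
            dist = abs(offset)
            pairs.append(
                NeighborPair(
                    lnc_id=lnc.transcript_id,
                    gene_id=gene_ids[i],
                    distance_bp=dist,
                    signed_offset=offset,
                    side=_side(offset, lnc),
                )
            )
    pairs.sort(key=lambda p: (p.distance_bp, p.gene_id))
    return pairs


def annotate_families(
    pairs: list[NeighborPair], families: dict[str, set[str]]
) -> list[NeighborPair]:
    """Tag pairs whose gene belongs to named gene families (e.g. P450,
    esterase, ABC).  A gene may carry several tags."""
    for p in pairs:
        p.families = sorted(
            name for name, ids in families.items() if p.gene_id in ids
        )
    return pairs


def load_family_file(path) -> set[str]:
    """One gene_id per line; blank lines and ``#`` comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    return out


def neighbor_table(
    catalog: list[TranscriptModel],
    ann: AnnotationSet,
    window: int = DEFAULT_WINDOW,
    families: dict[str, set[str]] | None = None,
    classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All in-window (lncRNA, coding gene) pairs as a flat table."""
    rows = []
    for lnc in catalog:
        pairs = neighbors_within(lnc, ann, window)
        if families:
            annotate_families(pairs, families)
        for p in pairs:
            rows.append(
                {
                    "lnc_id": p.lnc_id,
                    "lnc_class": (classes or {}).get(p.lnc_id, ""),
                    "gene_id": p.gene_id,
                    "family": ",".join(p.families),
                    "distance_bp": p.distance_bp,
                    "signed_offset": p.signed_offset,
                    "side": p.side,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_id",
            "lnc_class",
            "gene_id",
            "family",
            "distance_bp",
            "signed_offset",
            "side",
        ],
    )


def nearest_neighbor_report(
    catalog: list[TranscriptModel],
    ann: AnnotationSet,
    window: int = DEFAULT_WINDOW,
    classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per lncRNA: the nearest coding gene by midpoint-to-TSS distance and
    the number of in-window candidates; ideogram-ready coordinates."""
    rows = []
    for lnc in catalog:
        pairs = neighbors_within(lnc, ann, window)
        span = lnc.span
        rows.append(
            {
                "lnc_id": lnc.transcript_id,
                "lnc_class": (classes or {}).get(lnc.transcript_id, ""),
                "chrom": lnc.chrom,
                "start": span.start,
                "end": span.end,
                "strand": lnc.strand,
                "nearest_gene": pairs[0].gene_id if pairs else "",
                "nearest_distance_bp": pairs[0].distance_bp if pairs else -1,
                "n_in_window": len(pairs),
            }
        )
    return pd.DataFrame(rows)
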