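"""The lncRNA identification filter cascade.

An assembled transcript catalog is reduced to a lncRNA set by successive
filters — minimum length, minimum exon count, coding-gene exclusion,
maximum-ORF, coding-potential, and known-ncRNA exclusion lists — with a
:class:`FilterReport` recording per-stage counts and removed ids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .coding_potential import CodingPotentialClassifier, longest_orf
from .genome import (
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
    spliced_sequence,
)
from intervaltree import IntervalTree


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int
    n_retained: int
    removed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_in == self.n_removed + self.n_retained


@dataclass
class FilterReport:
    """Ordered per-stage bookkeeping of the cascade."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_retained:
            raise ValueError(
                f"stage {stage.name!r} input {stage.n_in} != previous retained "
                f"{self.stages[-1].n_retained}"
            )
        self.stages.append(stage)

    def conserves_counts(self) -> bool:
        ok = all(s.n_in == s.n_removed + s.n_retained for s in self.stages)
        chain = all(
            b.n_in == a.n_retained for a, b in zip(self.stages, self.stages[1:])
        )
        return ok and chain

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_removed\tn_retained\tremoved_ids\n")
            for s in self.stages:
                fh.write(
                    f"{s.name}\t{s.n_in}\t{s.n_removed}\t{s.n_retained}\t"
                    + ",".join(s.removed_ids)
                    + "\n"
                )


@dataclass
class IdentificationConfig:
    """Thresholds of the cascade, in the order the stages run."""

    min_nt: int = 200
    min_exons: int = 2
    max_orf_nt: int = 300
    cp_cutoff: float = 0.5

    def validate(self) -> None:
        if self.min_nt < 0 or self.min_exons < 1 or self.max_orf_nt <= 0:
            raise ValueError("nonpositive threshold in identification config")
        if not (0.0 < self.cp_cutoff <= 1.0):
            raise ValueError("cp_cutoff must be in (0, 1]")


Catalog = list[TranscriptModel]


def _split(
    catalog: Catalog, keep, name: str
) -> tuple[Catalog, FilterStage]:
    retained, removed = [], []
    for t in catalog:
        (retained if keep(t) else removed).append(t)
    stage = FilterStage(
        name=name,
        n_in=len(catalog),
        n_removed=len(removed),
        n_retained=len(retained),
        removed_ids=[t.transcript_id for t in removed],
    )
    return retained, stage


def filter_min_length(catalog: Catalog, min_nt: int = 200):
    """Retain transcripts with spliced length >= ``min_nt``."""
    return _split(catalog, lambda t: t.length >= min_nt, "min_length")


def filter_min_exons(catalog: Catalog, min_exons: int = 2):
    """Retain transcripts with at least ``min_exons`` exons (drops the
    single-exon assembly noise class)."""
    return _split(catalog, lambda t: t.exon_count >= min_exons, "min_exons")


def filter_max_orf(
    catalog: Catalog, seqs: dict[str, str], max_orf_nt: int = 300
):
    """Retain transcripts whose longest six-frame ORF is <= ``max_orf_nt``
    (transcripts with an ORF strictly longer are removed as putative coding)."""
    for t in catalog:
        if t.transcript_id not in seqs:
            raise KeyError(f"no sequence for {t.transcript_id}")
    return _split(
        catalog,
        lambda t: longest_orf(seqs[t.transcript_id]) <= max_orf_nt,
        "max_orf",
    )


def filter_coding_potential(
    catalog: Catalog,
    seqs: dict[str, str],
    model: CodingPotentialClassifier,
    cutoff: float | None = None,
):
    """Retain transcripts the coding-potential model labels noncoding."""
    if cutoff is not None:
        model = clone_with_cutoff(model, cutoff)
    ids = [t.transcript_id for t in catalog]
    if ids:
        probs = model.predict_proba([seqs[i] for i in ids])[:, 1]
        noncoding = {i for i, p in zip(ids, probs) if p < model.cutoff}
    else:
        noncoding = set()
    return _split(
        catalog, lambda t: t.transcript_id in noncoding, "coding_potential"
    )


def clone_with_cutoff(
    model: CodingPotentialClassifier, cutoff: float
) -> CodingPotentialClassifier:
    out = CodingPotentialClassifier(cutoff=cutoff, random_state=model.random_state)
    for attr in (
        "hexamer_table_",
        "feature_means_",
        "feature_scales_",
        "coef_",
        "intercept_",
        "classes_",
    ):
        setattr(out, attr, getattr(model, attr))
    return out


def filter_exclusion_lists(
    catalog: Catalog,
    id_lists: list[set[str]] | None = None,
    interval_lists: list[list[GenomicInterval]] | None = None,
):
    """Remove transcripts whose id is on any list or whose exons overlap any
    listed interval (stand-in for Rfam/NONCODE known-ncRNA hits)."""
    excluded_ids: set[str] = set().union(*id_lists) if id_lists else set()
    trees: dict[str, IntervalTree] = {}
    for ivs in interval_lists or []:
        for iv in ivs:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1)

    def keep(t: TranscriptModel) -> bool:
        if t.transcript_id in excluded_ids:
            return False
        tree = trees.get(t.chrom)
        if tree is not None:
            for e in t.exons:
                if tree.overlap(e.start, e.end + 1):
                    return False
        return True

    return _split(catalog, keep, "known_ncrna_exclusion")


def filter_coding_gene_ids(catalog: Catalog, coding_ids: set[str]):
    """Remove transcripts on a caller-supplied putative-coding id list (the
    injection point standing in for NR/Swiss-Prot protein homology hits)."""
    return _split(
        catalog, lambda t: t.transcript_id not in coding_ids, "coding_gene_exclusion"
    )


def run_identification(
    catalog: Catalog,
    seq_store: SequenceStore,
    model: CodingPotentialClassifier,
    config: IdentificationConfig | None = None,
    coding_ids: set[str] | None = None,
    exclude_ids: list[set[str]] | None = None,
    exclude_intervals: list[list[GenomicInterval]] | None = None,
) -> tuple[Catalog, FilterReport]:
    """Run the full cascade in order: length -> exon count -> coding-id
    exclusion -> ORF -> coding potential -> known-ncRNA exclusion.

    Sequences are extracted lazily after the structural filters, so catalogs
    dominated by short/single-exon noise never touch the genome sequence.
    """
    config = config or IdentificationConfig()
    config.validate()
    report = FilterReport()

    cat, stage = filter_min_length(catalog, config.min_nt)
    report.add(stage)
    cat, stage = filter_min_exons(cat, config.min_exons)
    report.add(stage)
    if coding_ids:
        cat, stage = filter_coding_gene_ids(cat, coding_ids)
        report.add(stage)
    seqs = {t.transcript_id: spliced_sequence(t, seq_store) for t in cat}
    if math.isfinite(config.max_orf_nt):
        cat, stage = filter_max_orf(cat, seqs, config.max_orf_nt)
        report.add(stage)
    cat, stage = filter_coding_potential(cat, seqs, model, config.cp_cutoff)
    report.add(stage)
    cat, stage = filter_exclusion_lists(cat, exclude_ids, exclude_intervals)
    report.add(stage)
    return cat, report
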