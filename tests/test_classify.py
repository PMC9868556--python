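"""Positional classification rules, precedence, and structural summaries."""

import warnings
from collections import Counter

import numpy as np
import pytest

from lncforge.classify import (
    classify,
    classify_all,
    exon_number_distribution,
    exon_size_distribution,
    length_summary,
)
from lncforge.genome import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


def _gene(gid, chrom, strand, exon_pairs, biotype="protein_coding"):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs]
    return GeneModel(
        gid, biotype=biotype,
        transcripts=[TranscriptModel(f"{gid}.t", gid, chrom, strand,
                                     exons=exons)],
    )


def _lnc(tid, chrom, strand, exon_pairs):
    return TranscriptModel(
        tid, tid, chrom, strand,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs],
    )


@pytest.fixture
def two_gene_ann():
    # gene A: + strand, exons 1000-1400 and 2000-2400 (intron 1401-1999)
    # gene B: - strand, exons 10000-10500 and 11000-11500
    return AnnotationSet([
        _gene("geneA", "c", "+", [(1000, 1400), (2000, 2400)]),
        _gene("geneB", "c", "-", [(10000, 10500), (11000, 11500)]),
    ])


class TestRules:
    def test_no_overlap_is_lincRNA(self, two_gene_ann):
        ev = classify(_lnc("x", "c", "+", [(5000, 5600)]), two_gene_ann)
        assert ev.lnc_class == "lincRNA" and ev.gene_id is None

    def test_same_strand_exon_overlap_is_sense(self, two_gene_ann):
        ev = classify(_lnc("x", "c", "+", [(1300, 1600)]), two_gene_ann)
        assert ev.lnc_class == "sense"
        assert ev.gene_id == "geneA"
        assert ev.overlap_bp == 101  # 1300..1400 inclusive

    def test_contained_in_same_strand_intron_is_intronic(self, two_gene_ann):
        ev = classify(_lnc("x", "c", "+", [(1500, 1700), (1800, 1900)]),
                      two_gene_ann)
        assert ev.lnc_class == "intronic" and ev.gene_id == "geneA"

    def test_opposite_strand_exon_overlap_is_antisense(self, two_gene_ann):
        ev = classify(_lnc("x", "c", "+", [(10400, 10800)]), two_gene_ann)
        assert ev.lnc_class == "antisense" and ev.gene_id == "geneB"

    def test_opposite_strand_intron_overlap_is_antisense_by_default(
        self, two_gene_ann
    ):
        ev = classify(_lnc("x", "c", "+", [(10600, 10900)]), two_gene_ann)
        assert ev.lnc_class == "antisense"
        strict = classify(_lnc("x", "c", "+", [(10600, 10900)]),
                          two_gene_ann, antisense_exon_only=True)
        assert strict.lnc_class == "lincRNA"

    def test_precedence_sense_beats_antisense(self):
        ann = AnnotationSet([
            _gene("geneA", "c", "+", [(1000, 1500)]),
            _gene("geneB", "c", "-", [(1400, 1900)]),
        ])
        ev = classify(_lnc("x", "c", "+", [(1450, 1600)]), ann)
        assert ev.lnc_class == "sense"

    def test_absent_chromosome_warns_and_returns_lincRNA(self, two_gene_ann):
        with pytest.warns(UserWarning, match="absent"):
            ev = classify(_lnc("x", "elsewhere", "+", [(1, 500)]),
                          two_gene_ann)
        assert ev.lnc_class == "lincRNA"


def oracle_classify(t, genes, antisense_exon_only=False):
    """Brute-force all-pairs classifier applying the same precedence."""
    def exon_bp(gene):
        bp = 0
        for e in t.exons:
            covered = set()
            for g in gene.exons():
                for p in range(max(e.start, g.start), min(e.end, g.end) + 1):
                    covered.add(p)
            bp += len(covered)
        return bp

    def span_bp(gene):
        gs = gene.span
        return sum(max(0, min(e.end, gs.end) - max(e.start, gs.start) + 1)
                   for e in t.exons)

    same = [g for g in genes if g.chrom == t.chrom and g.strand == t.strand]
    opp = [g for g in genes if g.chrom == t.chrom and g.strand != t.strand]
    span = t.span
    hits = {g.gene_id: exon_bp(g) for g in same if exon_bp(g) >= 1}
    if hits:
        return "sense", min(hits, key=lambda g: (-hits[g], g))
    hits = {
        g.gene_id: span_bp(g) for g in same
        if g.span.start <= span.start and span.end <= g.span.end
    }
    if hits:
        return "intronic", min(hits, key=lambda g: (-hits[g], g))
    hits = {}
    for g in opp:
        bp = exon_bp(g) if antisense_exon_only else span_bp(g)
        if bp >= 1:
            hits[g.gene_id] = bp
    if hits:
        return "antisense", min(hits, key=lambda g: (-hits[g], g))
    return "lincRNA", None


def random_instance(rng, n_genes=20, n_lnc=30, size=100_000):
    genes = []
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, size))
        exons, pos = [], start
        for _ in range(int(rng.integers(1, 4))):
            end = pos + int(rng.integers(50, 800))
            exons.append((pos, end))
            pos = end + int(rng.integers(2, 1200))
        genes.append(_gene(f"g{i:03d}", "c", strand, exons))
    lncs = []
    for i in range(n_lnc):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, size))
        exons, pos = [], start
        for _ in range(int(rng.integers(1, 4))):
            end = pos + int(rng.integers(50, 1500))
            exons.append((pos, end))
            pos = end + int(rng.integers(2, 900))
        lncs.append(_lnc(f"l{i:03d}", "c", strand, exons))
    return genes, lncs


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(31)
        for _ in range(8):
            genes, lncs = random_instance(rng)
            ann = AnnotationSet(genes)
            for t in lncs:
                ev = classify(t, ann)
                cls, gid = oracle_classify(t, genes)
                assert (ev.lnc_class, ev.gene_id) == (cls, gid), t.transcript_id


class TestInvariances:
    def test_partition_and_planted_truth(self, small_sim):
        truth = small_sim.truth.set_index("transcript_id")
        lncs = [t for t in small_sim.catalog
                if truth.loc[t.transcript_id, "is_lncRNA"]]
        ref = small_sim.reference.subset_biotype("protein_coding")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, counts = classify_all(lncs, ref)
        assert sum(counts.values()) == len(lncs)
        merged = table.set_index("transcript_id").join(
            truth[["lnc_class"]], rsuffix="_true"
        )
        assert (merged["lnc_class"] == merged["lnc_class_true"]).all()

    def test_empty_catalog_counts_zero(self, small_sim):
        _, counts = classify_all([], small_sim.reference)
        assert all(v == 0 for v in counts.values())

    def test_strand_flip_exchanges_sense_and_antisense(self):
        rng = np.random.default_rng(41)
        genes, lncs = random_instance(rng)
        ann = AnnotationSet(genes)
        flipped = AnnotationSet([
            _gene(g.gene_id, g.chrom,
                  "-" if g.strand == "+" else "+",
                  [(e.start, e.end) for e in g.transcripts[0].exons])
            for g in genes
        ])
        # the strict exon-only mode makes sense/antisense exact mirrors;
        # truly intergenic transcripts (no span overlap at all) stay lincRNA
        for t in lncs:
            before = classify(t, ann, antisense_exon_only=True)
            after = classify(t, flipped, antisense_exon_only=True)
            if before.lnc_class == "sense":
                assert after.lnc_class == "antisense"
            elif before.lnc_class == "antisense":
                assert after.lnc_class == "sense"
            span = t.span
            touches_any = any(
                g.chrom == t.chrom and g.span.start <= span.end
                and span.start <= g.span.end for g in genes
            )
            if not touches_any:
                assert before.lnc_class == after.lnc_class == "lincRNA"

    def test_translation_invariance(self):
        rng = np.random.default_rng(51)
        genes, lncs = random_instance(rng)
        shift = 7777
        ann = AnnotationSet(genes)
        shifted_ann = AnnotationSet([
            _gene(g.gene_id, g.chrom, g.strand,
                  [(e.start + shift, e.end + shift)
                   for e in g.transcripts[0].exons])
            for g in genes
        ])
        for t in lncs:
            shifted_t = _lnc(t.transcript_id, t.chrom, t.strand,
                             [(e.start + shift, e.end + shift)
                              for e in t.exons])
            assert classify(t, ann).lnc_class == classify(
                shifted_t, shifted_ann
            ).lnc_class

    def test_ambiguous_plants_resolve_to_sense(self):
        from lncforge.simulate import SimulationConfig, generate

        cfg = SimulationConfig(
            seed=3, n_coding_genes=20, n_linc=5, n_sense=3, n_antisense=3,
            n_intronic=2, n_short=0, n_single_exon=0, n_long_orf_decoys=0,
            n_hexamer_decoys=0, n_known_ncrna=0, n_all_zero=0,
            n_de_up_S=2, n_de_up_R=2, ambiguous_mode=True, n_ambiguous=6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = generate(cfg)
            amb = [t for t in ds.catalog
                   if t.transcript_id.startswith("LNC.AMB")]
            assert len(amb) == 6
            ref = ds.reference.subset_biotype("protein_coding")
            for t in amb:
                assert classify(t, ref).lnc_class == "sense"


class TestStructuralSummaries:
    def test_mean_of_two_lengths(self):
        cat = [_lnc("a", "c", "+", [(1, 100)]),
               _lnc("b", "c", "+", [(200, 499)])]
        s = length_summary(cat)
        assert s["mean"] == 200 and s["n"] == 2

    def test_exon_number_histogram(self):
        cat = [
            _lnc("a", "c", "+", [(1, 50), (100, 150)]),
            _lnc("b", "c", "+", [(i * 1000, i * 1000 + 10)
                                 for i in range(1, 8)]),
        ]
        assert exon_number_distribution(cat) == Counter({2: 1, 7: 1})

    def test_histograms_equal_direct_recount(self, small_sim):
        truth = small_sim.truth.set_index("transcript_id")
        lncs = [t for t in small_sim.catalog
                if truth.loc[t.transcript_id, "is_lncRNA"]]
        hist = exon_number_distribution(lncs)
        assert sum(hist.values()) == len(lncs)
        recount = Counter(len(t.exons) for t in lncs)
        assert hist == recount
        sizes, edges = exon_size_distribution(lncs)
        assert sizes.sum() == sum(t.exon_count for t in lncs)

    def test_empty_catalog_summary_errors(self):
        with pytest.raises(ValueError):
            length_summary([])
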