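"""End-to-end orchestration: identify -> classify -> structure stats ->
differential expression -> cis neighbors, with structured logging and a
run manifest recording inputs, per-stage counts and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_all, exon_number_distribution, length_summary
from .coding_potential import train_coding_model
from .expression import DEThresholds, ExpressionMatrix, call_de, volcano_table
from .genome import SequenceStore, read_gtf, read_bed_intervals
from .identify import IdentificationConfig, run_identification
from .neighbors import DEFAULT_WINDOW, load_family_file, neighbor_table, \
    nearest_neighbor_report
from .simulate import generate_coding_training_sets

log = logging.getLogger("lncforge")


@dataclass
class PipelineConfig:
    """Input paths and thresholds driving a full run."""

    catalog_gtf: str
    reference_gtf: str
    genome_fasta: str
    counts_tsv: str
    design_tsv: str
    outdir: str
    exclude_id_files: list[str] = field(default_factory=list)
    exclude_bed_files: list[str] = field(default_factory=list)
    family_files: dict[str, str] = field(default_factory=dict)
    identification: IdentificationConfig = field(
        default_factory=IdentificationConfig
    )
    de_thresholds: DEThresholds = field(default_factory=DEThresholds)
    window: int = DEFAULT_WINDOW
    condition_a: str = "S"
    condition_b: str = "R"
    seed: int = 0
    n_training: int = 200

    def input_paths(self) -> dict[str, str]:
        paths = {
            "catalog_gtf": self.catalog_gtf,
            "reference_gtf": self.reference_gtf,
            "genome_fasta": self.genome_fasta,
            "counts_tsv": self.counts_tsv,
            "design_tsv": self.design_tsv,
        }
        for i, p in enumerate(self.exclude_id_files):
            paths[f"exclude_ids_{i}"] = p
        for i, p in enumerate(self.exclude_bed_files):
            paths[f"exclude_bed_{i}"] = p
        for name, p in self.family_files.items():
            paths[f"family_{name}"] = p
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    input_checksums: dict[str, str]
    stage_counts: list[dict]
    outputs: dict[str, str]
    output_checksums: dict[str, str]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _log_stage(stage: str, n_in: int, n_out: int) -> None:
    log.info("stage=%s n_in=%d n_out=%d", stage, n_in, n_out)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline; the manifest is written last so a crash
    never leaves a manifest pointing at partial outputs."""
    t0 = time.time()
    # fail fast on inputs before any computation
    missing = [p for p in config.input_paths().values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
    input_checksums = {k: _sha256(p) for k, p in config.input_paths().items()}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage_counts: list[dict] = []

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, err) from err

    # --- load
    catalog_ann = run_stage("load_catalog", lambda: read_gtf(config.catalog_gtf))
    catalog = list(catalog_ann.transcripts())
    reference = run_stage(
        "load_reference",
        lambda: read_gtf(config.reference_gtf, default_biotype="protein_coding"),
    ).subset_biotype("protein_coding")
    store = run_stage(
        "load_genome", lambda: SequenceStore.from_fasta(config.genome_fasta)
    )
    _log_stage("load", len(catalog), len(catalog))

    # --- identification
    coding_train, noncoding_train = generate_coding_training_sets(
        n_coding=config.n_training, n_noncoding=config.n_training,
        seed=config.seed,
    )
    model = run_stage(
        "train_coding_model",
        lambda: train_coding_model(
            coding_train, noncoding_train, seed=config.seed,
            cutoff=config.identification.cp_cutoff,
        ),
    )
    exclude_ids = [
        set(Path(p).read_text().split()) for p in config.exclude_id_files
    ]
    exclude_ivs = [read_bed_intervals(p) for p in config.exclude_bed_files]
    lnc_catalog, report = run_stage(
        "identification",
        lambda: run_identification(
            catalog, store, model, config.identification,
            exclude_ids=exclude_ids, exclude_intervals=exclude_ivs,
        ),
    )
    for s in report.stages:
        _log_stage(s.name, s.n_in, s.n_retained)
    outputs["filter_report"] = str(outdir / "filter_report.tsv")
    report.to_tsv(outputs["filter_report"])

    # --- classification & structure
    class_table, class_counts = run_stage(
        "classification", lambda: classify_all(lnc_catalog, reference)
    )
    _log_stage("classification", len(lnc_catalog), len(class_table))
    outputs["classes"] = str(outdir / "classes.tsv")
    class_table.to_csv(outputs["classes"], sep="\t", index=False)

    structure = {
        "exon_number_lncRNA": dict(
            sorted(exon_number_distribution(lnc_catalog).items())
        ),
        "length_lncRNA": length_summary(lnc_catalog) if lnc_catalog else {},
    }
    coding_tx = [g.transcripts[0] for g in reference]
    structure["exon_number_coding"] = dict(
        sorted(exon_number_distribution(coding_tx).items())
    )
    structure["length_coding"] = length_summary(coding_tx) if coding_tx else {}
    outputs["structure"] = str(outdir / "structure.json")
    with open(outputs["structure"], "w") as fh:
        json.dump(structure, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # --- differential expression (on the identified lncRNA set)
    lengths = pd.Series({t.transcript_id: float(t.length) for t in catalog})
    matrix = run_stage(
        "load_expression",
        lambda: ExpressionMatrix.from_tsv(
            config.counts_tsv, config.design_tsv, lengths
        ),
    )
    lnc_ids = [t.transcript_id for t in lnc_catalog
               if t.transcript_id in matrix.counts.index]
    matrix.counts = matrix.counts.loc[lnc_ids]
    de_table = run_stage(
        "differential_expression",
        lambda: call_de(
            matrix, config.de_thresholds,
            condition_a=config.condition_a, condition_b=config.condition_b,
        ),
    )
    n_de = int((~de_table["call"].isin(["not_DE", "pruned_all_zero"])).sum())
    _log_stage("differential_expression", len(lnc_ids), n_de)
    outputs["de_results"] = str(outdir / "de_results.tsv")
    de_table.to_csv(outputs["de_results"], sep="\t", index=False)
    outputs["volcano"] = str(outdir / "volcano.tsv")
    volcano_table(de_table, outputs["volcano"])

    # --- cis neighbors of DE lncRNAs
    de_ids = set(
        de_table.loc[
            ~de_table["call"].isin(["not_DE", "pruned_all_zero"]),
            "transcript_id",
        ]
    )
    de_lncs = [t for t in lnc_catalog if t.transcript_id in de_ids]
    families = {
        name: load_family_file(path)
        for name, path in config.family_files.items()
    }
    classes = dict(zip(class_table["transcript_id"], class_table["lnc_class"]))
    pairs = run_stage(
        "cis_neighbors",
        lambda: neighbor_table(
            de_lncs, reference, window=config.window,
            families=families or None, classes=classes,
        ),
    )
    _log_stage("cis_neighbors", len(de_lncs), len(pairs))
    outputs["neighbors"] = str(outdir / "neighbors.tsv")
    pairs.to_csv(outputs["neighbors"], sep="\t", index=False)
    outputs["nearest"] = str(outdir / "nearest_neighbors.tsv")
    nearest_neighbor_report(
        de_lncs, reference, window=config.window, classes=classes
    ).to_csv(outputs["nearest"], sep="\t", index=False)

    stage_counts = [
        {"stage": s.name, "n_in": s.n_in, "n_removed": s.n_removed,
         "n_retained": s.n_retained}
        for s in report.stages
    ] + [
        {"stage": "classification", "n_in": len(lnc_catalog),
         "n_removed": 0, "n_retained": len(lnc_catalog),
         "class_counts": {k: int(v) for k, v in sorted(class_counts.items())}},
        {"stage": "differential_expression", "n_in": len(lnc_ids),
         "n_removed": len(lnc_ids) - n_de, "n_retained": n_de},
    ]

    ident = config.identification
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config={
            "min_nt": ident.min_nt,
            "min_exons": ident.min_exons,
            "max_orf_nt": ident.max_orf_nt,
            "cp_cutoff": ident.cp_cutoff,
            "lfc": config.de_thresholds.lfc,
            "p": config.de_thresholds.p,
            "q": config.de_thresholds.q,
            "window": config.window,
            "orientation": f"{config.condition_b}_vs_{config.condition_a}",
        },
        input_checksums=input_checksums,
        stage_counts=stage_counts,
        outputs=outputs,
        output_checksums={k: _sha256(p) for k, p in outputs.items()},
    )
    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    outputs["manifest"] = str(manifest_path)
    log.info("stage=done n_in=%d n_out=%d elapsed=%.1fs",
             len(catalog), len(lnc_catalog), time.time() - t0)
    return manifest
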