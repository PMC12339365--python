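"""End-to-end pipeline: simulate -> demultiplex -> score -> benchmark.

Stages run in dependency order; every output file is recorded in a manifest
with its SHA-256 digest alongside a snapshot of the configuration, so a run
is fully reproducible from the manifest and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import evaluate_per_allele
from .config import RunConfig
from .escore import EScoreWeights, replicate_qc, score_screen
from .readproc import AnchorSpec, count_reads
from .simdata import SorterModel, make_fixture, random_library, simulate_screen
from .libdesign import design_barcodes

log = logging.getLogger("escapeseq")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-screen pipeline described by ``config``.

    Returns a manifest dict (also written to ``out_dir/manifest.json``) and
    leaves the stage outputs (counts, scores, calls, metrics) as TSV/JSON
    files under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in zip(
        ("library", "barcodes", "screen"),
        rng.integers(0, 2**31 - 1, size=3))}

    anchors = AnchorSpec(**config.anchors) if config.anchors else AnchorSpec()

    log.info("stage design: %d peptides x %d alleles",
             config.n_peptides, config.n_alleles)
    library = random_library(config.n_peptides, k=config.peptide_length,
                             seed=seeds["library"], anchors=anchors)
    barcodes = design_barcodes(config.n_alleles, min_hamming=2,
                               seed=seeds["barcodes"])

    log.info("stage simulate")
    model = SorterModel(
        sigma_log10=config.sigma_log10,
        cells_per_construct=config.cells_per_construct,
        reads_per_bin=config.reads_per_bin,
        recombination_rate=config.recombination_rate,
        binder_fraction=config.binder_fraction,
        seed=seeds["screen"],
    )
    sim = simulate_screen(library, barcodes, model,
                          replicates=config.replicates,
                          out_dir=out / "fastq", anchors=anchors)

    log.info("stage count")
    table = count_reads(sim.fastq_files, library, barcodes, anchors=anchors)
    table.to_tsv(out / "counts.tsv")
    (out / "qc_demux.json").write_text(json.dumps(table.qc, indent=2))

    log.info("stage score")
    w = config.weights
    result = score_screen(
        table, mode=config.mode, align=config.align,
        threshold=config.threshold,
        weights=EScoreWeights(*w), min_trimers=config.min_trimers)
    result["scores"].to_csv(out / "escores_by_replicate.tsv", sep="\t",
                            index=False)
    result["mean"].to_csv(out / "escores.tsv", sep="\t", index=False)
    if result["shifts"] is not None:
        result["shifts"].to_csv(out / "allele_shifts.tsv", sep="\t",
                                index=False)
    qc = replicate_qc(result["scores"]) if config.replicates >= 2 else None
    if qc is not None:
        qc.to_csv(out / "qc_replicates.tsv", sep="\t", index=False)

    log.info("stage benchmark (vs simulation ground truth)")
    reference = sim.truth.constructs[["peptide", "allele", "label"]].rename(
        columns={"label": "eluted"})
    metrics = evaluate_per_allele(result["mean"], reference,
                                  B=config.bootstrap_B, seed=config.seed)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    sim.truth.constructs.to_csv(out / "ground_truth.tsv", sep="\t",
                                index=False)
    model.to_json(out / "model.json")
    config.to_yaml(out / "config.yaml")

    manifest = {
        "escapeseq_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "threshold": result["threshold"],
        "outputs": {},
    }
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
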