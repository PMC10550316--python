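"""End-to-end orchestration: simulate -> call -> features -> model.

Each stage reads and writes declared files only, so intermediates can be
regenerated from the manifest; re-running with an identical configuration
reproduces identical outputs for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from somarna import __version__, io
from somarna.annotation import GenomeAnnotation
from somarna.config import RunConfig
from somarna.features import COVARIATE_COLS, MUTATION_TYPES, build_feature_table
from somarna.filters import apply_filters
from somarna.modeling import (
    build_catalog,
    build_locus_table,
    extract_signatures,
    fit_poisson_lasso,
    fit_recurrence_model,
    locus_entropy_table,
    partial_correlation_tvalues,
)
from somarna.simulate import (
    CHROMATIN_TRACKS,
    DepthParams,
    ErrorParams,
    LengthParams,
    Tracks,
    TruthSpec,
    simulate_genome,
    simulate_pileup,
    simulate_tracks,
)

logger = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def simulate_stage(config: RunConfig, outdir: str) -> dict[str, str]:
    """Generate all pipeline inputs into ``outdir``; return emitted paths."""
    os.makedirs(outdir, exist_ok=True)
    sp = config.simulate_params
    ann = simulate_genome(
        n_chrom=config.n_chrom,
        n_genes=config.n_genes,
        length_params=LengthParams(**sp.get("length_params", {})),
        gc_target=sp.get("gc_target", 0.42),
        polyrun_rate=sp.get("polyrun_rate", 0.0008),
        seed=config.seed,
    )
    tracks = simulate_tracks(ann, seed=config.seed)
    masks = pd.concat([tracks.blacklist, tracks.rna_edit], ignore_index=True)
    result = simulate_pileup(
        ann,
        truth_spec=TruthSpec(**sp.get("truth_spec", {})),
        n_accessions=config.n_accessions,
        depth_params=DepthParams(**sp.get("depth_params", {})),
        error_params=ErrorParams(**sp.get("error_params", {})),
        seed=config.seed,
        avoid_intervals=masks,
    )

    paths = {
        "reference": os.path.join(outdir, "reference.fasta"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "germline_vcf": os.path.join(outdir, "germline.vcf"),
        "blacklist": os.path.join(outdir, "blacklist.bed"),
        "rna_edit": os.path.join(outdir, "rna_edit.bed"),
        "rt_early": os.path.join(outdir, "replication_early.bedgraph"),
        "rt_late": os.path.join(outdir, "replication_late.bedgraph"),
        "pileup": os.path.join(outdir, "pileup.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    io.write_fasta(ann.chromosomes, paths["reference"])
    io.write_gff3(ann, paths["annotation"])
    io.write_vcf(
        result.germline, paths["germline_vcf"],
        contigs={c: len(s) for c, s in ann.chromosomes.items()},
    )
    io.write_bed(tracks.blacklist, paths["blacklist"])
    io.write_bed(tracks.rna_edit, paths["rna_edit"])
    io.write_bedgraph(tracks.rt_early, paths["rt_early"])
    io.write_bedgraph(tracks.rt_late, paths["rt_late"])
    for mark, reps in tracks.chromatin.items():
        for fi, rep in enumerate(reps):
            p = os.path.join(outdir, f"{mark}.rep{fi + 1}.bedgraph")
            io.write_bedgraph(rep, p)
            paths[f"track:{mark}:{fi + 1}"] = p
    io.write_table(result.pileup, paths["pileup"], "pileup")
    io.write_table(result.truth.records, paths["truth"], "truth")
    return paths


def load_tracks(outdir: str) -> Tracks:
    chromatin: dict[str, list[pd.DataFrame]] = {}
    for mark in CHROMATIN_TRACKS:
        reps = []
        fi = 1
        while True:
            p = os.path.join(outdir, f"{mark}.rep{fi}.bedgraph")
            if not os.path.exists(p):
                break
            reps.append(io.read_bedgraph(p))
            fi += 1
        if not reps:
            raise FileNotFoundError(f"no replicate bedGraph found for {mark}")
        chromatin[mark] = reps
    return Tracks(
        rt_early=io.read_bedgraph(_require(os.path.join(outdir, "replication_early.bedgraph"))),
        rt_late=io.read_bedgraph(_require(os.path.join(outdir, "replication_late.bedgraph"))),
        chromatin=chromatin,
        blacklist=io.read_bed(_require(os.path.join(outdir, "blacklist.bed"))),
        rna_edit=io.read_bed(_require(os.path.join(outdir, "rna_edit.bed"))),
    )


def call_stage(config: RunConfig, indir: str, outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    chroms = io.read_fasta(_require(os.path.join(indir, "reference.fasta")))
    ann = io.read_gff3(_require(os.path.join(indir, "annotation.gff3")), chroms)
    pileup = io.read_table(_require(os.path.join(indir, "pileup.tsv")), "pileup")
    germline = io.read_vcf_positions(_require(os.path.join(indir, "germline.vcf")))
    blacklist = io.read_bed(_require(os.path.join(indir, "blacklist.bed")))
    rna_edit = io.read_bed(_require(os.path.join(indir, "rna_edit.bed")))
    cand, summary = apply_filters(
        pileup, germline, ann, blacklist=blacklist, rna_edit=rna_edit, config=config
    )
    paths = {
        "candidates": os.path.join(outdir, "candidates.tsv"),
        "filter_summary": os.path.join(outdir, "filter_summary.tsv"),
    }
    io.write_table(cand, paths["candidates"], "candidates")
    io.write_table(summary, paths["filter_summary"], "filter_summary")
    return paths


def features_stage(config: RunConfig, indir: str, calldir: str, outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    chroms = io.read_fasta(_require(os.path.join(indir, "reference.fasta")))
    ann = io.read_gff3(_require(os.path.join(indir, "annotation.gff3")), chroms)
    pileup = io.read_table(_require(os.path.join(indir, "pileup.tsv")), "pileup")
    cand = io.read_table(_require(os.path.join(calldir, "candidates.tsv")), "candidates")
    tracks = load_tracks(indir)
    mutations = cand.loc[cand["PASS"]] if "PASS" in cand.columns else cand
    tables = build_feature_table(
        mutations, ann, tracks, pileup, min_coverage=config.min_coverage
    )
    paths = {}
    for mut_type, table in tables.items():
        key = mut_type.replace(">", "to")
        p = os.path.join(outdir, f"features_{key}.tsv")
        io.write_table(table, p, "features")
        paths[f"features:{mut_type}"] = p
    return paths


def model_stage(config: RunConfig, indir: str, calldir: str, featdir: str,
                outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    chroms = io.read_fasta(_require(os.path.join(indir, "reference.fasta")))
    pileup = io.read_table(_require(os.path.join(indir, "pileup.tsv")), "pileup")
    cand = io.read_table(_require(os.path.join(calldir, "candidates.tsv")), "candidates")
    mutations = cand.loc[cand["PASS"]] if "PASS" in cand.columns else cand

    coeff_rows = []
    pc_frames = []
    for mut_type in MUTATION_TYPES:
        key = mut_type.replace(">", "to")
        p = os.path.join(featdir, f"features_{key}.tsv")
        if not os.path.exists(p):
            continue
        table = io.read_table(p, "features")
        if table.empty or table["m"].sum() == 0:
            logger.info("skipping %s: no mutations", mut_type)
            continue
        fit = fit_poisson_lasso(
            table, COVARIATE_COLS, mutation_type=mut_type,
            folds=min(config.cv_folds, len(table)), seed=config.seed,
        )
        co = fit.coefficients()
        co["mutation_type"] = mut_type
        co["lambda"] = fit.lambda_
        coeff_rows.append(co)
        if len(table) >= 4:
            pc = partial_correlation_tvalues(table, COVARIATE_COLS)
            pc["mutation_type"] = mut_type
            pc_frames.append(pc)
    paths = {}
    if coeff_rows:
        paths["model_fit"] = os.path.join(outdir, "model_fit.tsv")
        io.write_table(pd.DataFrame(coeff_rows), paths["model_fit"], "model_fit")
    if pc_frames:
        paths["partial_correlations"] = os.path.join(outdir, "partial_correlations.tsv")
        io.write_table(
            pd.concat(pc_frames, ignore_index=True),
            paths["partial_correlations"], "partial_correlations",
        )

    # locus recurrence model + entropy (on pre-recurrence survivors)
    loci = build_locus_table(mutations, pileup)
    if (loci["m"] > 0).any():
        alpha, beta, expected = fit_recurrence_model(loci)
        loci["expected"] = expected
        paths["recurrence"] = os.path.join(outdir, "recurrence_model.tsv")
        io.write_table(loci, paths["recurrence"], "recurrence")
        with open(os.path.join(outdir, "recurrence_params.json"), "w") as fh:
            json.dump({"alpha": alpha, "beta": beta}, fh, indent=1)
        paths["recurrence_params"] = os.path.join(outdir, "recurrence_params.json")
    entropy = locus_entropy_table(cand)
    paths["entropy"] = os.path.join(outdir, "entropy.tsv")
    io.write_table(entropy, paths["entropy"], "entropy")

    # trinucleotide catalog + signature stand-in
    catalog = build_catalog(mutations, chroms)
    paths["catalog"] = os.path.join(outdir, "catalog.tsv")
    io.write_table(
        catalog.rename("count").rename_axis("channel").reset_index(),
        paths["catalog"], "catalog",
    )
    if catalog.sum() > 0:
        decomp = extract_signatures(catalog, k=min(2, max(1, int((catalog > 0).sum()))),
                                    seed=config.seed)
        sig = decomp.signatures.copy()
        sig.insert(0, "signature", [f"S{i + 1}" for i in range(len(sig))])
        paths["signatures"] = os.path.join(outdir, "mutational_signatures.tsv")
        io.write_table(sig, paths["signatures"], "signatures")
    return paths


def run_pipeline(config: RunConfig, outdir: str) -> dict[str, str]:
    """Run all stages into ``outdir``; emit a provenance manifest."""
    os.makedirs(outdir, exist_ok=True)
    sim_dir = os.path.join(outdir, "sim")
    call_dir = os.path.join(outdir, "call")
    feat_dir = os.path.join(outdir, "features")
    model_dir = os.path.join(outdir, "model")
    paths = {}
    paths.update(simulate_stage(config, sim_dir))
    paths.update(call_stage(config, sim_dir, call_dir))
    paths.update(features_stage(config, sim_dir, call_dir, feat_dir))
    paths.update(model_stage(config, sim_dir, call_dir, feat_dir, model_dir))

    config_path = os.path.join(outdir, "config.yaml")
    config.to_yaml(config_path)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_path,
        "checksums": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
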