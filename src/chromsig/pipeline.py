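"""End-to-end orchestration: normalize -> differential -> cluster/label ->
score -> correlate -> (annotate / enrich / footprint where inputs are
given), with a run manifest for reproducibility.

The manifest records the config hash, seed, package version and per-stage
row counts; reruns with identical inputs, config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from . import annotation, clinical_stats, differential, enrichment, footprint
from . import io_formats, normalization, signature

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class ValidationError(ValueError):
    pass


_INPUT_KEYS = ("matrix", "metadata", "tss", "gene_sets", "fasta", "motifs",
               "states", "ranked")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_config(config: dict) -> None:
    """Check the config shape and that every named input exists, before any
    computation starts."""
    if "outdir" not in config:
        raise ValidationError("config key 'outdir' missing")
    inputs = config.get("inputs", {})
    if "matrix" not in inputs or "metadata" not in inputs:
        raise ValidationError("inputs.matrix and inputs.metadata are required")
    paths = [inputs[k] for k in _INPUT_KEYS if k in inputs]
    paths += list(inputs.get("tracks", {}).values())
    for path in paths:
        if not os.path.exists(path):
            raise ValidationError(f"input file not found: {path}")


def run_all(config: dict) -> dict:
    """Run the full analysis described by ``config``; returns the manifest
    (also written to <outdir>/manifest.json)."""
    validate_config(config)
    outdir = config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 17))
    inputs = config["inputs"]
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "stages": {},
    }

    def record(stage, **counts):
        manifest["stages"][stage] = counts
        logger.info("stage %s done: %s", stage, counts)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                logger.info("stage %s took %.2fs", name, time.perf_counter() - self.t0)
        return _Ctx()

    # ---- normalize ----
    with stage("normalize"):
        raw = io_formats.read_matrix(inputs["matrix"])
        metadata = io_formats.read_metadata(inputs["metadata"])
        ncfg = config.get("normalize", {})
        norm = normalization.normalize_pipeline(
            raw,
            drop_chroms=tuple(ncfg.get("drop_chroms", ["chrY"])),
            pseudocount=float(ncfg.get("pseudocount", 1.0)),
            min_mean=ncfg.get("min_mean", 3.0),
        )
        io_formats.write_matrix(os.path.join(outdir, "normalized.tsv"), norm)
        record("normalize", n_regions_in=raw.shape[0], n_regions_out=norm.shape[0],
               n_samples=norm.shape[1])

    # ---- differential ----
    with stage("differential"):
        dcfg = config.get("differential", {})
        groups = tuple(dcfg.get("groups", ("HD", "OA", "RA")))
        family = differential.ThresholdFamily(
            min_abs_log2fc=dcfg.get("min_abs_log2fc", 1.0),
            max_p=dcfg.get("max_p", 0.001),
            max_fdr=dcfg.get("max_fdr", 0.1),
        )
        all_records = {}
        diff_regions: set[str] = set()
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                recs, surv = differential.differential_table(
                    norm, metadata, groups[i], groups[j], family
                )
                all_records[f"{groups[i]}_vs_{groups[j]}"] = recs
                diff_regions |= surv
        for name, recs in all_records.items():
            differential.records_to_frame(recs).to_csv(
                os.path.join(outdir, f"differential_{name}.tsv"), sep="\t", index=False
            )
        record("differential", n_contrasts=len(all_records),
               n_differential_regions=len(diff_regions))

    # ---- cluster & label ----
    labelled = None
    with stage("cluster"):
        ccfg = config.get("cluster", {})
        k = int(ccfg.get("k", 3))
        if len(diff_regions) < k:
            logger.warning("only %d differential regions (< k=%d); "
                           "clustering skipped", len(diff_regions), k)
            record("cluster", n_labelled_clusters=0, skipped=True)
        else:
            subset = norm.subset_regions(sorted(diff_regions))
            clusters = signature.kmeans_regions(
                subset, k=k, seed=int(ccfg.get("seed", seed)),
                restarts=int(ccfg.get("restarts", 10)),
            )
            try:
                labelled = signature.label_clusters(clusters, metadata, groups=groups)
            except ValueError as err:
                logger.warning("cluster labelling failed (%s); score stage "
                               "will be skipped", err)
            if labelled is not None:
                rows = [{"region_id": rid, "cluster": c,
                         "label": labelled.semantics.get(c, "unlabelled")}
                        for rid, c in labelled.assignment.items()]
                pd.DataFrame(rows).to_csv(os.path.join(outdir, "clusters.tsv"),
                                          sep="\t", index=False)
            record("cluster",
                   n_labelled_clusters=len(labelled.semantics) if labelled else 0,
                   n_clustered_regions=len(diff_regions))

    # ---- score & correlate ----
    scores = None
    if labelled is not None:
        with stage("score"):
            scores = signature.raas_scores(norm, labelled, label=signature.C3)
            pd.DataFrame(
                [{"sample_id": s.sample_id, "label": s.cluster_label,
                  "score": s.score} for s in scores]
            ).to_csv(os.path.join(outdir, "raas.tsv"), sep="\t", index=False)
            record("score", n_samples=len(scores))

        with stage("correlate"):
            covariates = config.get("correlate", {}).get(
                "covariates", list(io_formats.CLINICAL_COVARIATES)
            )
            fits = clinical_stats.score_vs_clinical(scores, metadata, covariates)
            pd.DataFrame(
                [{"covariate": f.covariate, "slope": f.slope,
                  "intercept": f.intercept, "r_squared": f.r_squared,
                  "p": f.p_slope, "n": f.n_used, "significant": f.significant}
                 for f in fits]
            ).to_csv(os.path.join(outdir, "clinical_fits.tsv"), sep="\t", index=False)
            record("correlate", n_fits=len(fits),
                   n_significant=sum(f.significant for f in fits))
    else:
        logger.warning("no labelled clusters: score and correlate stages skipped")

    # ---- optional annotation ----
    if "tss" in inputs and labelled is not None:
        with stage("annotate"):
            tss = io_formats.read_tss(inputs["tss"])
            domains = annotation.build_domains(tss)
            c3_ids = labelled.regions_of(signature.C3)
            c3_regions = [r for r in norm.regions if r.region_id in c3_ids]
            mapping = annotation.associate(c3_regions, domains)
            pd.DataFrame(
                [{"region_id": rid, "genes": ",".join(sorted(genes))}
                 for rid, genes in mapping.items()]
            ).to_csv(os.path.join(outdir, "region2gene.tsv"), sep="\t", index=False)
            record("annotate", n_regions=len(mapping),
                   n_genes=len(annotation.associated_genes(mapping)))

    if "states" in inputs and labelled is not None:
        with stage("states"):
            states = io_formats.read_bed(inputs["states"])
            c3_ids = labelled.regions_of(signature.C3)
            c3_regions = [r for r in norm.regions if r.region_id in c3_ids]
            table = annotation.state_overlap(c3_regions, states)
            pd.DataFrame(
                [{"state": st, **vals} for st, vals in table.items()]
            ).to_csv(os.path.join(outdir, "state_overlap.tsv"), sep="\t", index=False)
            record("states", n_states=len(table))

    # ---- optional motif enrichment & footprinting ----
    hits_by_motif = None
    if "fasta" in inputs and "motifs" in inputs and labelled is not None:
        with stage("motifs"):
            sequences = io_formats.read_fasta(inputs["fasta"])
            motifs = io_formats.read_jaspar(inputs["motifs"])
            hits = []
            for m in motifs:
                hits.extend(enrichment.scan_sequences(sequences, m))
            c3_ids = labelled.regions_of(signature.C3) & set(sequences)
            background = set(sequences)
            table = enrichment.motif_enrichment(
                c3_ids, background, hits, background_includes_target=True
            )
            table.to_csv(os.path.join(outdir, "motif_enrichment.tsv"),
                         sep="\t", index=False)
            hits_by_motif = hits
            record("motifs", n_motifs=len(motifs), n_hits=len(hits))

    if "ranked" in inputs and "gene_sets" in inputs:
        with stage("gsea"):
            ranked = pd.read_csv(inputs["ranked"], sep="\t", index_col=0).iloc[:, 0]
            sets = io_formats.read_gmt(inputs["gene_sets"])
            gcfg = config.get("gsea", {})
            results = [
                enrichment.gsea_pvalue(ranked, s,
                                       n_perm=int(gcfg.get("n_perm", 1000)),
                                       seed=seed)
                for s in sets
            ]
            pd.DataFrame(
                [{"set": r.name, "es": r.es, "p": r.p, "n_perm": r.n_perm}
                 for r in results]
            ).to_csv(os.path.join(outdir, "gsea.tsv"), sep="\t", index=False)
            record("gsea", n_sets=len(results),
                   n_significant=sum(r.p < 0.05 for r in results))

    if inputs.get("tracks") and hits_by_motif:
        with stage("footprint"):
            fcfg = config.get("footprint", {})
            flank = int(fcfg.get("flank", 100))
            motif_widths = {m.motif_id: m.width
                            for m in io_formats.read_jaspar(inputs["motifs"])}
            region_ids = set(norm.region_ids)
            profiles = {}
            for arm, path in inputs["tracks"].items():
                track = io_formats.read_bedgraph(path)
                for motif_id, width in motif_widths.items():
                    mhits = [h for h in hits_by_motif
                             if h.motif_id == motif_id and h.region_id in region_ids]
                    if not mhits:
                        continue
                    sites = footprint.hits_to_sites(mhits, norm.regions, width)
                    prof = footprint.aggregate_footprint(track, sites, flank)
                    profiles[(arm, motif_id)] = prof
            rows = []
            for (arm, motif_id), prof in profiles.items():
                for off, val in zip(prof.offsets, prof.mean_cleavage):
                    rows.append({"arm": arm, "motif_id": motif_id,
                                 "offset": int(off), "mean_cleavage": val})
            pd.DataFrame(rows).to_csv(os.path.join(outdir, "footprints.tsv"),
                                      sep="\t", index=False)
            record("footprint", n_profiles=len(profiles))

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
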