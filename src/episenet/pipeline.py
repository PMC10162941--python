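"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full flow on a synthetic cohort —
simulate -> se-call -> landscape -> se-links -> tf-network ->
subtype-transfer -> signatures — writing each stage's outputs under one
directory and recording a manifest with SHA-256 content hashes, so that a
rerun with the same config and seed is verifiably identical.  With
``resume=True`` stages whose outputs already exist are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import (
    CohortConfig,
    LandscapeParams,
    LinkParams,
    NetworkParams,
    SECallingParams,
    TransferParams,
)
from .landscape import build_state_matrix, mds_mnn, select_features, state_score_difference
from .links import link_repertoire
from .regulons import aracne_lite, build_correlation_network, regulon_activity, select_network_tfs
from .se_calling import (
    build_consensus,
    call_superenhancers,
    differential_se,
    rank_enhancers,
    stitch_enhancers,
)
from .signatures import (
    GeneSet,
    adapt_plasticity_signature,
    sc_qc_and_markers,
    signature_space_projection,
)
from .synthetic import simulate_cohort, simulate_single_cell, write_cohort
from .transfer import ensemble_classify, harmonize

log = logging.getLogger("episenet")

STAGES = (
    "simulate",
    "se_call",
    "landscape",
    "se_links",
    "tf_network",
    "subtype_transfer",
    "signatures",
)


def _params(cls, block: Mapping[str, Any] | None):
    block = dict(block or {})
    fields = {f.name for f in dataclasses.fields(cls)}
    return cls(**{k: v for k, v in block.items() if k in fields})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def default_config(outdir: str | Path = "episenet_run", seed: int = 0) -> dict:
    """Default pipeline config; parameter blocks mirror the analysis
    defaults (12.5 kb stitch, TSS±2500, top 1000, min 2 samples, top 1%
    selections, k=6 / 2000 features, |activity| > 2, r >= 0.5)."""
    return {
        "outdir": str(outdir),
        "seed": seed,
        "cohort": {},
        "se_calling": {},
        "landscape": {},
        "links": {},
        "network": {"n_bootstraps": 20, "n_permutations": 200},
        "transfer": {"n_embeddings": 100},
        "single_cell": {"n_cells_per_pop": 150, "markers_per_pop": 40},
    }


def run_pipeline(config: Mapping[str, Any], resume: bool = False) -> dict:
    """Run all stages; returns the manifest (stage -> file -> sha256)."""
    cfg = dict(config)
    out = Path(cfg.get("outdir", "episenet_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest_path = out / "manifest.json"
    manifest: dict[str, dict[str, str]] = (
        json.loads(manifest_path.read_text()) if resume and manifest_path.exists()
        else {}
    )

    def record(stage: str, files: Mapping[str, Path]) -> None:
        manifest[stage] = {str(k): _sha256(Path(p)) for k, p in files.items()}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def done(stage: str, files: Mapping[str, Path]) -> bool:
        return (
            resume
            and stage in manifest
            and all(Path(p).exists() for p in files.values())
        )

    t0 = time.time()
    cohort_cfg = _params(CohortConfig, {**cfg.get("cohort", {}), "seed": seed})
    se_params = _params(SECallingParams, cfg.get("se_calling"))
    land_params = _params(LandscapeParams, cfg.get("landscape"))
    link_params = _params(LinkParams, cfg.get("links"))
    net_params = _params(NetworkParams, cfg.get("network"))
    tr_params = _params(TransferParams, {**cfg.get("transfer", {}),
                                         "base_seed": seed})

    # ---- simulate ---------------------------------------------------------
    stage_dir = out / "simulate"
    cohort = simulate_cohort(cohort_cfg)
    files = {"cohort_dir": stage_dir}
    if not done("simulate", {}):
        log.info("stage simulate: %d samples", len(cohort.sample_groups))
        paths = write_cohort(cohort, stage_dir)
        record("simulate", {k: Path(v) for k, v in paths.items()})

    groups = cohort.sample_groups
    tumours = cohort.sample_batches[cohort.sample_batches == "tumour"].index

    # ---- se_call ----------------------------------------------------------
    stage_dir = out / "se_call"
    stage_dir.mkdir(exist_ok=True)
    se_sets = {}
    for sample, peaks_df in cohort.peaks.items():
        from .intervals import intervals_from_bed

        stitched = stitch_enhancers(
            intervals_from_bed(peaks_df), cohort.genome, se_params
        )
        ranked = rank_enhancers(
            stitched, peaks_df[["chrom", "start", "end", "ip", "input"]]
        )
        called, _ = call_superenhancers(ranked, se_params)
        se_sets[sample] = called
    repertoire = build_consensus(se_sets, se_params)
    diff = differential_se(repertoire, groups, "Luminal", "Basal",
                           alpha=se_params.alpha)
    files = {
        "consensus": stage_dir / "consensus.bed",
        "occupancy": stage_dir / "occupancy.tsv",
        "activity": stage_dir / "activity.tsv",
        "differential": stage_dir / "differential_luminal_vs_basal.tsv",
    }
    if not done("se_call", files):
        log.info("stage se_call: %d consensus regions", len(repertoire.consensus_regions))
        pd.DataFrame(
            [(r.chrom, r.start, r.end) for r in repertoire.consensus_regions]
        ).to_csv(files["consensus"], sep="\t", header=False, index=False)
        repertoire.occupancy.to_csv(files["occupancy"], sep="\t")
        repertoire.activity.to_csv(files["activity"], sep="\t")
        diff.to_csv(files["differential"], sep="\t", index=False)
        record("se_call", files)

    # ---- landscape --------------------------------------------------------
    stage_dir = out / "landscape"
    stage_dir.mkdir(exist_ok=True)
    matrix = build_state_matrix(
        cohort.segmentations, exclude_sex_chroms=land_params.exclude_sex_chroms
    )
    selected = select_features(matrix, land_params)
    coords = mds_mnn(selected.numeric, cohort.sample_batches)
    delta = state_score_difference(selected.numeric, groups, group_a="Basal")
    files = {
        "selected": stage_dir / "selected_regions.bed",
        "coords": stage_dir / "sample_coords.tsv",
        "score_difference": stage_dir / "state_score_difference.tsv",
    }
    if not done("landscape", files):
        log.info("stage landscape: %d selected regions", len(selected.regions))
        pd.DataFrame(
            [(r.chrom, r.start, r.end) for r in selected.regions]
        ).to_csv(files["selected"], sep="\t", header=False, index=False)
        coords.to_csv(files["coords"], sep="\t")
        delta.to_csv(files["score_difference"], sep="\t")
        record("landscape", files)

    # ---- se_links ---------------------------------------------------------
    stage_dir = out / "se_links"
    stage_dir.mkdir(exist_ok=True)
    links = link_repertoire(
        repertoire, cohort.genome, cohort.bulk_expression, link_params,
        tumour_samples=list(tumours),
    )
    files = {"links": stage_dir / "se_gene_links.tsv"}
    if not done("se_links", files):
        log.info("stage se_links: %d links", len(links))
        links.to_csv(files["links"], sep="\t", index=False)
        record("se_links", files)

    # ---- tf_network -------------------------------------------------------
    stage_dir = out / "tf_network"
    stage_dir.mkdir(exist_ok=True)
    tf_list = cohort.tf_table["TF"].tolist()
    network = aracne_lite(cohort.bulk_expression, tf_list, net_params, seed=seed)
    activity = regulon_activity(cohort.bulk_expression, network)
    diff_regions = diff.loc[diff["significant"], "region"].tolist()
    from scipy import stats as _st

    lum = [s for s in cohort.bulk_expression.columns if groups[s] == "Luminal"]
    bas = [s for s in cohort.bulk_expression.columns if groups[s] == "Basal"]
    _, p = _st.ttest_ind(
        cohort.bulk_expression[lum], cohort.bulk_expression[bas],
        axis=1, equal_var=False,
    )
    de_genes = set(cohort.bulk_expression.index[np.nan_to_num(p, nan=1.0) < 0.05])
    selected_tfs = select_network_tfs(
        links, diff_regions, set(tf_list), de_genes, activity, groups,
        score_threshold=net_params.regulon_score_threshold,
    )
    files = {
        "edges": stage_dir / "regulon_edges.tsv",
        "activity": stage_dir / "regulon_activity.tsv",
        "selected_tfs": stage_dir / "selected_tfs.tsv",
        "graph": stage_dir / "tf_graph_edges.tsv",
    }
    if not done("tf_network", files):
        rows = [
            (tf, t, m, w) for tf, targets in network.items()
            for t, m, w in targets
        ]
        pd.DataFrame(rows, columns=["TF", "target", "mode", "weight"]).to_csv(
            files["edges"], sep="\t", index=False
        )
        activity.to_csv(files["activity"], sep="\t")
        selected_tfs.to_csv(files["selected_tfs"], sep="\t", index=False)
        if len(selected_tfs) >= 2:
            graph = build_correlation_network(
                cohort.bulk_expression, selected_tfs["TF"].tolist(),
                net_params.correlation_threshold,
            )
            pd.DataFrame(
                [(u, v, d["r"]) for u, v, d in graph.edges(data=True)],
                columns=["tf_a", "tf_b", "r"],
            ).to_csv(files["graph"], sep="\t", index=False)
        else:
            files["graph"].write_text("tf_a\ttf_b\tr\n")
        log.info("stage tf_network: %d selected TFs", len(selected_tfs))
        record("tf_network", files)

    # ---- subtype_transfer -------------------------------------------------
    stage_dir = out / "subtype_transfer"
    stage_dir.mkdir(exist_ok=True)
    cell_lines = [s for s in cohort.bulk_expression.columns if s not in set(tumours)]
    reference = cohort.bulk_expression[list(tumours)]
    query = cohort.bulk_expression[cell_lines]
    merged, _origin = harmonize(reference, query)
    from .transfer import select_features_ftest

    ref_labels = groups[list(tumours)]
    feat = select_features_ftest(
        merged, ref_labels, n_features=min(tr_params.n_features, merged.shape[0])
    )
    calls = ensemble_classify(feat, ref_labels, tr_params)
    files = {"calls": stage_dir / "subtype_calls.tsv"}
    if not done("subtype_transfer", files):
        log.info("stage subtype_transfer: %d queries", len(calls))
        calls.to_csv(files["calls"], sep="\t", index_label="sample")
        record("subtype_transfer", files)

    # ---- signatures -------------------------------------------------------
    stage_dir = out / "signatures"
    stage_dir.mkdir(exist_ok=True)
    sc_cfg = cfg.get("single_cell", {})
    sc_matrix, sc_labels, _truth = simulate_single_cell(
        n_cells_per_pop=int(sc_cfg.get("n_cells_per_pop", 150)),
        markers_per_pop=int(sc_cfg.get("markers_per_pop", 40)),
        seed=seed,
    )
    markers = sc_qc_and_markers(sc_matrix, sc_labels)
    lum_set = GeneSet(
        "luminal",
        frozenset(markers.loc[markers["cluster"] == "luminal-like", "gene"]),
    )
    bas_set = GeneSet(
        "basal",
        frozenset(markers.loc[markers["cluster"] == "basal-like", "gene"]),
    )
    # perturbation ranking: a synthetic luminal -> basal shift built from the
    # single-cell population means (up in basal-like = positive)
    pop_means = sc_matrix.groupby(sc_labels).mean()
    perturbation = (
        pop_means.loc["basal-like"] - pop_means.loc["luminal-like"]
    ).sort_values(ascending=False)
    adapted_lum, adapted_bas = adapt_plasticity_signature(
        perturbation, lum_set, bas_set, seed=seed
    )
    files = {
        "markers": stage_dir / "sc_markers.tsv",
        "adapted": stage_dir / "plasticity_signature.tsv",
        "projection": stage_dir / "signature_projection.tsv",
    }
    if not done("signatures", files):
        markers.to_csv(files["markers"], sep="\t", index=False)
        pd.DataFrame(
            [("luminal", g) for g in adapted_lum]
            + [("basal", g) for g in adapted_bas],
            columns=["signature", "gene"],
        ).to_csv(files["adapted"], sep="\t", index=False)
        # project cell lines into the tumour signature space built from the
        # bulk-cohort marker analogues (planted SE target genes)
        sig_genes = [
            se.target_gene
            for se in cohort.planted_ses
            if se.group in ("Luminal", "Basal")
        ]
        ref_coords, qry_coords, centroids = signature_space_projection(
            reference, groups[list(tumours)], sig_genes, query
        )
        both = pd.concat(
            [ref_coords.assign(kind="reference"), qry_coords.assign(kind="query")]
        )
        both.to_csv(files["projection"], sep="\t", index_label="sample")
        log.info("stage signatures: %d/%d adapted genes",
                 len(adapted_lum), len(adapted_bas))
        record("signatures", files)

    log.info("pipeline finished in %.1f s", time.time() - t0)
    return manifest
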