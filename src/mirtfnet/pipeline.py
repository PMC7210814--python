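"""End-to-end orchestration of the miRNA-TF-mRNA analysis.

A single RunConfig drives all stages in order: simulate (synthetic inputs
with planted truth), preprocess (probe collapsing), differential screening of
the mRNA and miRNA cohorts, weighted co-expression analysis of the DEGs,
promoter motif scanning of the trait module, miRNA-TF integration, triple
network assembly, shared-TF refinement, enrichment, and validation against
the second miRNA cohort. Every stage writes its output files plus an entry in
a manifest (parameters, row counts, SHA-256 checksums, wall time), and all
randomness flows from the single config seed through per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirtfnet import io as mio
from mirtfnet import synthetic
from mirtfnet.coexpression import run_coexpression, select_trait_module
from mirtfnet.diffexpr import differential_expression, flag_significant, select_features
from mirtfnet.enrichment import mirna_gene_set, ora
from mirtfnet.motifscan import score_all_pairs, select_top_pairs
from mirtfnet.preprocess import ExpressionProfile, collapse_probes, validate_profile
from mirtfnet.regnet import (
    bridge_tfs,
    build_triple_network,
    integrate_mirna_tf,
    network_stats,
    refine_pairs,
    to_edge_list,
)
from mirtfnet.validation import validate_key_mirnas

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]


@dataclass
class RunConfig:
    """All thresholds and sizes for one pipeline run.

    Threshold defaults are the published analysis values: DEG screening at
    FDR < 0.01 with |logFC| > 1, validation screening at FDR < 0.05, top 5%
    of motif scores, shared-TF significance at p < 0.05, minimum module size
    20, scale-free fit target 0.85.
    """

    outdir: str = "pipeline_out"
    seed: int = 42
    deg_fdr: float = 0.01
    deg_lfc: float = 1.0
    mirna_fdr: float = 0.01
    mirna_lfc: float = 1.0
    validation_fdr: float = 0.05
    top_frac: float = 0.05
    alpha: float = 0.05
    min_module_size: int = 20
    r2_target: float = 0.85
    betas: tuple = tuple(range(1, 21))
    shared_tf_mode: str = "upper_tail"
    # synthetic scenario sizes (two-group beadchip-style cohorts)
    n_genes: int = 2000
    n_tumor: int = 60
    n_normal: int = 60
    n_de_genes: int = 200
    gene_effect: float = 2.0
    n_modules: int = 3
    module_size: int = 40
    module_trait_r: float = 0.9  # first (trait) module
    secondary_module_trait_r: float = 0.5  # remaining modules
    noise_sd: float = 1.0
    de_noise_sd: float = 2.0  # biological spread of non-module DE genes
    n_mirnas: int = 300
    mirna_tumor: int = 68
    mirna_normal: int = 21
    n_de_mirnas: int = 60
    n_shared_de_mirnas: int = 30
    validation_tumor: int = 78
    validation_normal: int = 88
    n_tfs: int = 30
    motif_length: int = 10
    promoter_length: int = 2000
    plants_per_gene: int = 2
    n_primary_pairs: int = 150
    frac_val1: float = 0.6
    frac_val2: float = 0.5

    def to_file(self, path) -> None:
        with open(path, "w") as handle:
            for key, value in dataclasses.asdict(self).items():
                if isinstance(value, tuple):
                    value = ",".join(map(str, value))
                handle.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(raw)
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            elif isinstance(default, tuple):
                kwargs[key] = tuple(int(x) for x in raw.split(",") if x)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def _substream(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_inputs(config: RunConfig) -> dict:
    """Generate the full synthetic input set for one pipeline run.

    Returns a dict of in-memory objects (profiles, truth, PFMs, promoters,
    candidate tables, annotation) keyed by stage-input name.
    """
    seed = config.seed
    gene_profile, gene_truth = synthetic.generate_expression_cohort(
        n_features=config.n_genes,
        n_tumor=config.n_tumor,
        n_normal=config.n_normal,
        n_de=config.n_de_genes,
        effect=config.gene_effect,
        n_modules=config.n_modules,
        module_size=config.module_size,
        module_trait_r=[config.module_trait_r]
        + [config.secondary_module_trait_r] * (config.n_modules - 1),
        noise_sd=config.noise_sd,
        de_noise_sd=config.de_noise_sd,
        seed=_substream(seed, "mrna"),
        feature_prefix="G",
    )

    mirna_ids = [f"hsa-miR-{i:04d}" for i in range(config.n_mirnas)]
    shared = mirna_ids[: config.n_shared_de_mirnas]
    de1 = mirna_ids[: config.n_de_mirnas]
    n_extra = config.n_de_mirnas - config.n_shared_de_mirnas
    de2 = shared + mirna_ids[config.n_de_mirnas : config.n_de_mirnas + n_extra]
    mirna_profile, mirna_truth = synthetic.generate_expression_cohort(
        n_features=config.n_mirnas,
        n_tumor=config.mirna_tumor,
        n_normal=config.mirna_normal,
        n_de=config.n_de_mirnas,
        effect=config.gene_effect,
        noise_sd=config.noise_sd,
        seed=_substream(seed, "mirna"),
        feature_ids=mirna_ids,
        de_ids=de1,
    )
    validation_profile, validation_truth = synthetic.generate_expression_cohort(
        n_features=config.n_mirnas,
        n_tumor=config.validation_tumor,
        n_normal=config.validation_normal,
        n_de=config.n_de_mirnas,
        effect=config.gene_effect,
        noise_sd=config.noise_sd,
        seed=_substream(seed, "validation"),
        feature_ids=mirna_ids,
        de_ids=de2,
    )
    mirna_truth.shared_de_mirnas = set(shared)
    validation_truth.shared_de_mirnas = set(shared)

    rng = np.random.default_rng(_substream(seed, "probes"))
    probe_map = synthetic.generate_probe_table(
        gene_profile.feature_ids,
        frac_multi_probe=0.05,
        frac_multi_gene=0.02,
        seed=_substream(seed, "probes"),
    )
    probe_rows = []
    for _, row in probe_map.iterrows():
        genes = row["genes"].split(",")
        if len(genes) == 1:
            base = gene_profile.values.loc[genes[0]].to_numpy()
        else:  # ambiguous probe: arbitrary mixture, dropped by collapsing
            base = gene_profile.values.loc[genes].mean(axis=0).to_numpy()
        probe_rows.append(base + rng.normal(0.0, 0.05, size=base.shape))
    probe_matrix = pd.DataFrame(
        probe_rows, index=probe_map["probe"], columns=gene_profile.sample_ids
    )

    tf_ids = [f"TF{i:02d}" for i in range(config.n_tfs)]
    pfms = synthetic.generate_pfms(
        tf_ids, length=config.motif_length, seed=_substream(seed, "pfms")
    )
    module_genes = sorted(set().union(*gene_truth.module_members.values()))
    plant_rng = np.random.default_rng(_substream(seed, "plant"))
    planted = {}
    for gene in module_genes:
        for tf in plant_rng.choice(tf_ids, size=config.plants_per_gene, replace=False):
            planted[(gene, tf)] = True
    promoters, motif_truth = synthetic.generate_promoters(
        module_genes,
        pfms,
        planted,
        length=config.promoter_length,
        gc=0.41,
        seed=_substream(seed, "promoters"),
    )

    primary, val1, val2, validated = synthetic.generate_mirna_tf_candidates(
        de1,
        tf_ids,
        n_primary=config.n_primary_pairs,
        frac_val1=config.frac_val1,
        frac_val2=config.frac_val2,
        seed=_substream(seed, "candidates"),
    )
    annotation = synthetic.generate_annotation(
        module_genes + tf_ids, seed=_substream(seed, "annotation")
    )

    truth = gene_truth.merge(motif_truth).merge(mirna_truth)
    truth.true_mirna_tf = validated
    return {
        "gene_truth": gene_truth,
        "mirna_truth": mirna_truth,
        "validation_truth": validation_truth,
        "gene_profile": gene_profile,
        "probe_matrix": probe_matrix,
        "probe_map": probe_map,
        "mirna_profile": mirna_profile,
        "validation_profile": validation_profile,
        "pfms": pfms,
        "promoters": promoters,
        "primary": primary,
        "val1": val1,
        "val2": val2,
        "annotation": annotation,
        "truth": truth,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; return the manifest dict.

    The manifest records, per stage, the parameters used, output row counts,
    output file checksums and wall time. It is also written to
    ``<outdir>/manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    results: dict = {}

    def record(stage: str, t0: float, params: dict, counts: dict, files: list[Path]):
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "counts": counts,
                "outputs": {f.name: _sha256(f) for f in files},
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    inputs = simulate_inputs(config)
    truth = inputs["truth"]
    sim_files = []
    for name, values, group in (
        ("mirna_expression", inputs["mirna_profile"].values, inputs["mirna_profile"].group),
        (
            "validation_expression",
            inputs["validation_profile"].values,
            inputs["validation_profile"].group,
        ),
        ("probe_expression", inputs["probe_matrix"], inputs["gene_profile"].group),
    ):
        mio.write_expression(values, outdir / f"{name}.tsv")
        mio.write_annotation(group, outdir / f"{name}_samples.tsv")
        sim_files += [outdir / f"{name}.tsv", outdir / f"{name}_samples.tsv"]
    mio.write_pairs(inputs["probe_map"], outdir / "probe_map.tsv")
    mio.write_fasta(inputs["promoters"], outdir / "promoters.fasta")
    mio.write_jaspar(inputs["pfms"], outdir / "motifs.jaspar")
    for name in ("primary", "val1", "val2"):
        mio.write_pairs(inputs[name], outdir / f"mirna_tf_{name}.tsv")
        sim_files.append(outdir / f"mirna_tf_{name}.tsv")
    synthetic.write_truth(truth, outdir / "truth.json")
    sim_files += [
        outdir / "probe_map.tsv",
        outdir / "promoters.fasta",
        outdir / "motifs.jaspar",
        outdir / "truth.json",
    ]
    record("simulate", t0, {"seed": config.seed}, {"n_genes": config.n_genes}, sim_files)

    # --- preprocess ---------------------------------------------------
    t0 = time.perf_counter()
    gene_profile = collapse_probes(
        inputs["probe_matrix"], inputs["probe_map"], inputs["gene_profile"].group
    )
    violations = validate_profile(gene_profile)
    if violations:
        raise RuntimeError(f"stage preprocess: profile violations {violations[:3]}")
    mio.write_expression(gene_profile.values, outdir / "gene_expression.tsv")
    record(
        "preprocess",
        t0,
        {},
        {"n_probes": len(inputs["probe_matrix"]), "n_genes": gene_profile.n_features},
        [outdir / "gene_expression.tsv"],
    )

    # --- differential expression -------------------------------------
    t0 = time.perf_counter()
    deg_table = flag_significant(
        differential_expression(gene_profile), config.deg_fdr, config.deg_lfc
    )
    degs = select_features(deg_table, config.deg_fdr, config.deg_lfc)
    mirna_table = flag_significant(
        differential_expression(inputs["mirna_profile"]),
        config.mirna_fdr,
        config.mirna_lfc,
    )
    de_mirnas = select_features(mirna_table, config.mirna_fdr, config.mirna_lfc)
    deg_table.to_csv(outdir / "deg_mrna.tsv", sep="\t", index_label="feature_id")
    mirna_table.to_csv(outdir / "deg_mirna.tsv", sep="\t", index_label="feature_id")
    results.update(degs=degs, de_mirnas=de_mirnas)
    record(
        "diffexpr",
        t0,
        {"fdr": config.deg_fdr, "lfc": config.deg_lfc},
        {"n_degs": len(degs), "n_de_mirnas": len(de_mirnas)},
        [outdir / "deg_mrna.tsv", outdir / "deg_mirna.tsv"],
    )

    # --- co-expression ------------------------------------------------
    t0 = time.perf_counter()
    deg_profile = gene_profile.subset_features(degs)
    coexpr, scan = run_coexpression(
        deg_profile,
        betas=config.betas,
        r2_target=config.r2_target,
        min_module_size=config.min_module_size,
    )
    trait_module, module_genes = select_trait_module(coexpr)
    scan.to_csv(outdir / "soft_threshold_scan.tsv", sep="\t", index=False)
    coexpr.module_labels.rename("module").to_csv(
        outdir / "module_assignment.tsv", sep="\t", index_label="gene"
    )
    coexpr.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="module")
    results.update(coexpr=coexpr, trait_module=trait_module, module_genes=module_genes)
    record(
        "coexpression",
        t0,
        {"beta": coexpr.beta_used, "min_module_size": config.min_module_size},
        {
            "n_modules": int((coexpr.module_trait_r.index != "grey").sum()),
            "trait_module_size": len(module_genes),
        },
        [
            outdir / "soft_threshold_scan.tsv",
            outdir / "module_assignment.tsv",
            outdir / "eigengenes.tsv",
        ],
    )

    # --- motif scan ---------------------------------------------------
    t0 = time.perf_counter()
    module_promoters = {
        g: inputs["promoters"][g] for g in module_genes if g in inputs["promoters"]
    }
    if not module_promoters:
        raise RuntimeError("stage motif_scan: no promoters for trait-module genes")
    scored = score_all_pairs(inputs["pfms"], module_promoters)
    top_pairs = select_top_pairs(scored, config.top_frac)
    scored.to_csv(outdir / "motif_scores.tsv", sep="\t", index=False)
    top_pairs.to_csv(outdir / "mrna_tf_pairs.tsv", sep="\t", index=False)
    results.update(mrna_tf=top_pairs)
    record(
        "motif_scan",
        t0,
        {"top_frac": config.top_frac},
        {"n_scored": len(scored), "n_top_pairs": len(top_pairs)},
        [outdir / "motif_scores.tsv", outdir / "mrna_tf_pairs.tsv"],
    )

    # --- miRNA-TF integration ----------------------------------------
    t0 = time.perf_counter()
    mirna_tf = integrate_mirna_tf(
        inputs["primary"], inputs["val1"], inputs["val2"], de_mirnas
    )
    mirna_tf.to_csv(outdir / "mirna_tf_pairs.tsv", sep="\t", index=False)
    results.update(mirna_tf=mirna_tf)
    record(
        "integrate",
        t0,
        {},
        {"n_pairs": len(mirna_tf)},
        [outdir / "mirna_tf_pairs.tsv"],
    )

    # --- triple network ----------------------------------------------
    t0 = time.perf_counter()
    network = build_triple_network(top_pairs, mirna_tf)
    stats = network_stats(network)
    bridges = bridge_tfs(network)
    mio.write_graphml(network, outdir / "triple_network.graphml")
    to_edge_list(network).to_csv(outdir / "triple_network_edges.tsv", sep="\t", index=False)
    results.update(network=network, bridges=bridges, network_counts=stats)
    record(
        "network",
        t0,
        {},
        {
            "n_edges": stats["n_edges"],
            "n_mrna": stats["n_mrna"],
            "n_tf": stats["n_tf"],
            "n_mirna": stats["n_mirna"],
            "n_bridge_tfs": len(bridges),
        },
        [outdir / "triple_network.graphml", outdir / "triple_network_edges.tsv"],
    )

    # --- shared-TF refinement ----------------------------------------
    t0 = time.perf_counter()
    refined = refine_pairs(network, alpha=config.alpha, mode=config.shared_tf_mode)
    refined.to_csv(outdir / "refined_pairs.tsv", sep="\t", index=False)
    results.update(refined=refined)
    record(
        "refine",
        t0,
        {"alpha": config.alpha, "mode": config.shared_tf_mode},
        {
            "n_pairs": len(refined),
            "n_significant": int(refined["significant"].sum()),
            "n_mirnas": refined["mirna"].nunique(),
            "n_mrnas": refined["gene"].nunique(),
        },
        [outdir / "refined_pairs.tsv"],
    )

    # --- enrichment ---------------------------------------------------
    t0 = time.perf_counter()
    universe = set().union(
        *(genes for _, genes in inputs["annotation"].values())
    )
    enrich_files = []
    n_enriched = 0
    for mirna in sorted(refined["mirna"].unique()):
        query = mirna_gene_set(mirna, refined, network) & universe
        if not query:
            continue
        table = ora(query, universe, inputs["annotation"])
        fname = outdir / f"enrichment_{mirna.replace('/', '_')}.tsv"
        table.to_csv(fname, sep="\t", index=False)
        enrich_files.append(fname)
        n_enriched += 1
    record(
        "enrichment",
        t0,
        {},
        {"n_mirnas_enriched": n_enriched},
        enrich_files,
    )

    # --- validation ---------------------------------------------------
    t0 = time.perf_counter()
    network_mirnas = set(refined["mirna"].unique())
    report = validate_key_mirnas(
        inputs["validation_profile"], network_mirnas, fdr_max=config.validation_fdr
    )
    with open(outdir / "key_mirnas.json", "w") as handle:
        json.dump(report.as_dict(), handle, indent=1)
    results.update(report=report)
    record(
        "validation",
        t0,
        {"fdr": config.validation_fdr},
        {
            "n_cohort2_de": len(report.cohort2_de),
            "n_network_mirnas": len(report.network_mirnas),
            "n_key_mirnas": len(report.key_mirnas),
        },
        [outdir / "key_mirnas.json"],
    )

    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1)
    manifest["results"] = results
    manifest["truth"] = truth
    manifest["truths"] = {
        "gene": inputs["gene_truth"],
        "mirna": inputs["mirna_truth"],
        "validation": inputs["validation_truth"],
    }
    return manifest
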