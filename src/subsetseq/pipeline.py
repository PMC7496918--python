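"""End-to-end orchestration: simulate-or-load through report, deterministically.

Stage order: inputs -> 1-cpm filter -> TMM -> voom log2-cpm/weights ->
lineage fit (total ILC vs total Th) and subset fit -> mirror and all-pairs
contrasts -> GSEA per mirror comparison with a shared-set Venn partition ->
subset signatures and spider matrix -> top-variable-gene PCA -> lncRNA
sub-tables -> numeric report.  Every intermediate table is written as TSV;
a JSON manifest records the config, per-stage row counts and the SHA-256 of
every written file, so re-running with an identical config reproduces
byte-identical outputs.  One global seed fans out to per-stage child seeds
by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from subsetseq import io as sio
from subsetseq.gsea import GseaConfig, RankedList, gsea_run, results_frame, shared_enriched_sets
from subsetseq.linmod import build_design, de_pair_matrix, de_summary, fit_models, test_contrast
from subsetseq.normalize import filter_low_expression, log_cpm_and_weights, tmm_factors
from subsetseq.signatures import biotype_subset, pca_top_variable, subset_signatures
from subsetseq.simulate import SimulationConfig, simulate_counts, simulate_genesets

logger = logging.getLogger(__name__)

ILC_SUBSETS = ("ILC1", "ILC2", "ILCP")
TH_SUBSETS = ("Th1", "Th2", "Th17")
SUBSETS = ILC_SUBSETS + TH_SUBSETS
MIRROR_PAIRS = (("ILC1", "Th1"), ("ILC2", "Th2"), ("ILCP", "Th17"))

# fixed child-seed offsets (stage-level reproducibility)
SEED_SIMULATION = 1
SEED_GENESETS = 2
SEED_GSEA = 3


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs or simulation, thresholds, outputs."""

    outdir: str = "results/run"
    seed: int = 0
    alpha: float = 0.05
    min_cpm: float = 1.0
    min_samples: int = 1
    n_top_pca: int = 500
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    lncrna_biotype: str = "lncRNA"
    # load-from-files mode (all four set) or simulation mode (None)
    counts_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    genesets_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_null_sets: int = 450
    n_enriched_sets: int = 50
    geneset_size_range: tuple[int, int] = (20, 200)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geneset_size_range"] = list(self.geneset_size_range)
        d["simulation"]["baseline_mean_log_range"] = list(
            self.simulation.baseline_mean_log_range
        )
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.counts_path:
        needed = {
            "counts_path": config.counts_path,
            "metadata_path": config.metadata_path,
            "annotation_path": config.annotation_path,
            "genesets_path": config.genesets_path,
        }
        for key, path in needed.items():
            if path is None:
                raise ValueError(f"{key} not set while loading from files")
            if not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")
        counts = sio.read_counts(config.counts_path)
        samples = sio.read_metadata(config.metadata_path)
        samples.validate_against(counts)
        annotation = sio.read_annotation(config.annotation_path)
        genesets = sio.read_gmt(config.genesets_path)
        return counts, samples, annotation, genesets, None
    sim = dataclasses.replace(config.simulation, seed=config.seed + SEED_SIMULATION)
    counts, samples, annotation, truth = simulate_counts(sim)
    genesets = simulate_genesets(
        list(counts.gene_ids),
        truth,
        n_null_sets=config.n_null_sets,
        n_enriched_sets=config.n_enriched_sets,
        size_range=config.geneset_size_range,
        seed=config.seed + SEED_GENESETS,
        target_subsets=("ILC",) + ILC_SUBSETS,
    )
    return counts, samples, annotation, genesets, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write all tables under ``config.outdir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "files": {}}

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        manifest["files"][name] = _sha256(path)

    # ---- inputs -----------------------------------------------------------
    counts, samples, annotation, genesets, truth = _load_inputs(config)
    emit("counts.tsv", sio.write_counts, counts)
    emit("metadata.tsv", sio.write_metadata, samples)
    emit("annotation.tsv", sio.write_annotation, annotation)
    emit("genesets.gmt", sio.write_gmt, genesets)
    if truth is not None:
        emit("truth_genes.tsv", sio.write_table, truth.frame)
        emit(
            "truth_effects.tsv",
            sio.write_table,
            truth.effects.rename_axis("gene_id").reset_index(),
        )
    manifest["stages"]["input"] = {"n_genes": counts.n_genes, "n_samples": counts.n_samples}

    # ---- filter + normalize ----------------------------------------------
    filtered = filter_low_expression(counts, config.min_cpm, config.min_samples)
    logger.info("filter: retained %d of %d genes", filtered.n_genes, counts.n_genes)
    factors = tmm_factors(filtered)
    design6 = build_design(samples, "subset")
    # align design rows to matrix columns
    col_order = [design6.sample_ids.index(s) for s in filtered.sample_ids]
    design6_mat = design6.matrix[col_order]
    norm = log_cpm_and_weights(filtered, factors, design6_mat)
    emit(
        "normalization.tsv",
        sio.write_table,
        pd.DataFrame(
            {
                "sample_id": filtered.sample_ids,
                "lib_size": norm.lib_sizes,
                "tmm_factor": norm.tmm_factors,
            }
        ),
    )
    manifest["stages"]["normalize"] = {
        "n_genes_retained": filtered.n_genes,
        "tmm_geomean": float(np.exp(np.mean(np.log(factors)))),
    }

    # ---- linear models ----------------------------------------------------
    from subsetseq.linmod import DesignMatrix

    design_subset = DesignMatrix(design6_mat, design6.coef_names, list(filtered.sample_ids))
    fit_subset = fit_models(norm, design_subset)
    design_lineage = build_design(samples, "lineage")
    lin_mat = design_lineage.matrix[
        [design_lineage.sample_ids.index(s) for s in filtered.sample_ids]
    ]
    design_lin = DesignMatrix(lin_mat, design_lineage.coef_names, list(filtered.sample_ids))
    fit_lineage = fit_models(norm, design_lin)

    contrasts: dict[str, object] = {}
    table = test_contrast(fit_lineage, design_lin.contrast({"ILC": 1, "Th": -1}), "ILC_vs_Th")
    contrasts["ILC_vs_Th"] = table
    emit("de_ILC_vs_Th.tsv", sio.write_contrast_table, table)
    for a, b in MIRROR_PAIRS:
        name = f"{a}_vs_{b}"
        table = test_contrast(fit_subset, design_subset.contrast({a: 1, b: -1}), name)
        contrasts[name] = table
        emit(f"de_{name}.tsv", sio.write_contrast_table, table)
    pairwise = {}
    for i, a in enumerate(SUBSETS):
        for b in SUBSETS[i + 1 :]:
            name = f"{a}_vs_{b}"
            tab = test_contrast(fit_subset, design_subset.contrast({a: 1, b: -1}), name)
            pairwise[(a, b)] = tab
            emit(f"pairwise_{name}.tsv", sio.write_contrast_table, tab)
    summary = de_summary(
        {**{k: v for k, v in contrasts.items()}}, config.alpha
    )
    emit("de_summary.tsv", sio.write_table, summary)
    pair_mat = de_pair_matrix(pairwise, list(SUBSETS), config.alpha)
    emit(
        "de_pair_matrix.tsv",
        sio.write_table,
        pair_mat.rename_axis("subset").reset_index(),
    )
    manifest["stages"]["linear_model"] = {
        "d0_subset": float(fit_subset.d0),
        "d0_lineage": float(fit_lineage.d0),
        "de_counts": {
            r["comparison"]: [int(r["n_up"]), int(r["n_down"])]
            for _, r in summary.iterrows()
        },
    }

    # ---- GSEA -------------------------------------------------------------
    gsea_cfg = GseaConfig(
        weight_exponent=config.gsea_weight,
        n_permutations=config.gsea_permutations,
        seed=config.seed + SEED_GSEA,
        alpha=config.alpha,
    )
    gsea_results = {}
    for a, b in MIRROR_PAIRS:
        name = f"{a}_vs_{b}"
        ranked = RankedList.from_contrast(contrasts[name])
        res = gsea_run(ranked, genesets, gsea_cfg)
        gsea_results[name] = res
        emit(f"gsea_{name}.tsv", sio.write_gsea_table, res)
    venn = shared_enriched_sets(gsea_results, config.alpha)
    venn_frame = pd.DataFrame(
        [
            {"region": "&".join(region), "n_sets": len(names), "sets": ";".join(names)}
            for region, names in sorted(venn.items())
        ],
        columns=["region", "n_sets", "sets"],
    )
    emit("gsea_venn.tsv", sio.write_table, venn_frame)
    nes_rows = []
    for name, res in gsea_results.items():
        for r in res:
            if r.direction == "up":
                nes_rows.append(
                    {"comparison": name, "set": r.set_name, "nes": r.nes, "adj_p": r.adj_p}
                )
    emit("gsea_nes_matrix.tsv", sio.write_table, pd.DataFrame(nes_rows))
    manifest["stages"]["gsea"] = {
        name: {
            "n_tests": len(res),
            "n_significant_up": sum(
                1 for r in res if r.direction == "up" and r.adj_p < config.alpha
            ),
        }
        for name, res in gsea_results.items()
    }
    manifest["stages"]["gsea"]["venn_regions"] = {
        "&".join(region): len(names) for region, names in sorted(venn.items())
    }

    # ---- signatures, PCA, lncRNA -----------------------------------------
    signatures = subset_signatures(pairwise, list(SUBSETS), norm, samples, config.alpha)
    sig_rows = [
        {"subset": s, "n_genes": len(g), "genes": ";".join(g)}
        for s, g in signatures.members.items()
    ]
    emit("signatures.tsv", sio.write_table, pd.DataFrame(sig_rows))
    emit(
        "spider_matrix.tsv",
        sio.write_table,
        signatures.spider.rename_axis("signature").reset_index(),
    )
    pca = pca_top_variable(norm, config.n_top_pca)
    emit(
        "pca_variance.tsv",
        sio.write_table,
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(pca.variance_fraction.size)],
                "variance_fraction": pca.variance_fraction,
                "cumulative": pca.cumulative_variance,
            }
        ),
    )
    emit("pca_scores.tsv", sio.write_table, pca.scores.rename_axis("sample_id").reset_index())
    lnc_counts = {}
    for a, b in MIRROR_PAIRS:
        name = f"{a}_vs_{b}"
        lnc = biotype_subset(contrasts[name], annotation, config.lncrna_biotype)
        emit(f"lncrna_{name}.tsv", sio.write_contrast_table, lnc)
        lnc_counts[name] = int((lnc.frame["adj_p"] < config.alpha).sum())
    manifest["stages"]["signatures_pca"] = {
        "signature_sizes": signatures.sizes(),
        "pc1_variance_pct": float(100 * pca.variance_fraction[0]),
        "pc3_cumulative_pct": float(100 * pca.cumulative_variance[min(2, pca.cumulative_variance.size - 1)]),
        "lncrna_de_counts": lnc_counts,
    }

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", manifest_path)
    return manifest


def make_report(outdir: str | Path) -> str:
    """Assemble the numeric report document from a completed run directory."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {outdir}; run the pipeline first")
    with open(manifest_path, encoding="utf-8") as handle:
        manifest = json.load(handle)
    required = ["de_summary.tsv", "de_pair_matrix.tsv", "gsea_venn.tsv", "spider_matrix.tsv"]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing {missing}")

    lines = ["# Pipeline report", ""]
    lines += ["## Differential expression (up / down per comparison)", ""]
    lines.append(pd.read_csv(outdir / "de_summary.tsv", sep="\t").to_string(index=False))
    lines += ["", "## Pairwise DE counts (row subset up vs column subset)", ""]
    lines.append(pd.read_csv(outdir / "de_pair_matrix.tsv", sep="\t").to_string(index=False))
    lines += ["", "## Shared up-enriched gene sets (Venn regions)", ""]
    venn = pd.read_csv(outdir / "gsea_venn.tsv", sep="\t")
    lines.append(venn[["region", "n_sets"]].to_string(index=False) if not venn.empty else "(none)")
    lines += ["", "## Signature sizes", ""]
    for subset, n in manifest["stages"]["signatures_pca"]["signature_sizes"].items():
        lines.append(f"- {subset}: {n} genes")
    lines += ["", "## Spider matrix (mean log2 normalized cpm)", ""]
    lines.append(pd.read_csv(outdir / "spider_matrix.tsv", sep="\t").round(3).to_string(index=False))
    pca_block = manifest["stages"]["signatures_pca"]
    lines += [
        "",
        "## PCA",
        "",
        f"- PC1 variance explained: {pca_block['pc1_variance_pct']:.1f}%",
        f"- first 3 PCs cumulative: {pca_block['pc3_cumulative_pct']:.1f}%",
        "",
        "## lncRNA differential expression",
        "",
    ]
    for name, n in pca_block["lncrna_de_counts"].items():
        lines.append(f"- {name}: {n} lncRNAs at adj_p < {manifest['config']['alpha']}")
    report = "\n".join(lines) + "\n"
    with open(outdir / "report.md", "w", encoding="utf-8") as handle:
        handle.write(report)
    return report
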