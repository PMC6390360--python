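"""End-to-end orchestration of the analysis stage graph.

The stage order mirrors the study design: differential calling on both
platforms, directional set-crossing into HIF1A-dependent/independent
classes, probe annotation distributions, inverse expression-methylation
pairing, enhancer-probe filtering with target linking, and signature
clustering of the patient cohort.  Every filter logs before/after counts
into a ledger that is written with the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, differential, enhancers, integration, setops, signatures
from . import formats
from .containers import BetaMatrix, CohortExpression, ExpressionMatrix, MarkerTrack

log = logging.getLogger(__name__)

#: The analysis contrasts, as (name, reference group, test group).
CONTRASTS = {
    "hif1a_nx": ("shCTR_NX", "shHIF1A_NX"),
    "hif1a_hyp": ("shCTR_HYP", "shHIF1A_HYP"),
    "hypoxia": ("shCTR_NX", "shCTR_HYP"),
}


@dataclass
class PipelineConfig:
    """Thresholds, contrast definitions and optional input paths."""

    lfc_de: float = 0.5
    fdr: float = 0.05
    delta_beta: float = 0.2
    pair_p: float = 0.05
    pair_p_mode: str = "nominal"
    enhancer_min_markers: int = 4
    link_window_bp: int = 1_000_000
    link_lfc: float = 0.2
    min_geneset: int = 10
    linkage_method: str = "complete"
    n_perm: int = 10_000
    seed: int = 0
    expression_path: str | None = None
    expression_design_path: str | None = None
    beta_path: str | None = None
    beta_design_path: str | None = None
    manifest_path: str | None = None
    gene_coords_path: str | None = None
    bed_paths: list = field(default_factory=list)
    gmt_path: str | None = None
    cohort_path: str | None = None
    cohort_labels_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fdr <= 1 or not 0 < self.pair_p <= 1:
            raise ValueError("fdr and pair_p must lie in (0, 1]")
        if self.lfc_de < 0 or self.link_lfc < 0:
            raise ValueError("fold-change thresholds must be nonnegative")
        if not 0 < self.delta_beta < 1:
            raise ValueError("delta_beta threshold must lie in (0, 1)")
        if self.enhancer_min_markers < 1 or self.link_window_bp < 1:
            raise ValueError("enhancer parameters must be positive")
        if self.pair_p_mode not in ("nominal", "fdr"):
            raise ValueError("pair_p_mode must be 'nominal' or 'fdr'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_inputs(config: PipelineConfig) -> dict:
    """Read all configured inputs into typed containers."""
    inputs: dict = {}
    if config.expression_path:
        inputs["expression"] = formats.read_expression_tsv(
            config.expression_path, config.expression_design_path
        )
    if config.beta_path:
        inputs["beta"] = formats.read_beta_tsv(config.beta_path, config.beta_design_path)
    if config.manifest_path:
        inputs["manifest"] = formats.read_manifest_tsv(config.manifest_path)
    if config.gene_coords_path:
        inputs["gene_coords"] = formats.read_gene_coords_tsv(config.gene_coords_path)
    if config.bed_paths:
        inputs["tracks"] = [formats.read_bed(p) for p in config.bed_paths]
    if config.gmt_path:
        inputs["gene_sets"] = formats.read_gmt(config.gmt_path)
    if config.cohort_path:
        inputs["cohort"] = formats.read_cohort(config.cohort_path, config.cohort_labels_path)
    return inputs


def run_pipeline(
    config: PipelineConfig,
    *,
    expression: ExpressionMatrix,
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    gene_coords: pd.DataFrame | None = None,
    tracks: list[MarkerTrack] | None = None,
    gene_sets: annotation.GeneSetCollection | None = None,
    cohort: CohortExpression | None = None,
    outdir: str | None = None,
) -> dict:
    """Execute all stages in order and return the result bundle.

    Stages needing optional inputs (tracks, gene coordinates, gene sets,
    cohort) are skipped when those inputs are absent.  With ``outdir``
    set, per-stage tables plus a run manifest are written there.
    """
    ledger: dict[str, dict] = {}
    bundle: dict = {"ledger": ledger}

    def _stage(name):
        log.info("stage %s", name)

    try:
        _stage("differential")
        de, de_sets, dm, dm_sets = {}, {}, {}, {}
        for cname, (ref, test) in CONTRASTS.items():
            de[cname] = differential.contrast_expression(expression, ref, test)
            de_sets[cname] = differential.filter_de(
                de[cname], lfc_threshold=config.lfc_de, fdr=config.fdr,
                contrast_label=cname,
            )
            dm[cname] = differential.contrast_methylation(beta, ref, test)
            dm_sets[cname] = differential.filter_dm(
                dm[cname], delta_threshold=config.delta_beta, fdr=config.fdr
            )
            ledger[f"de_{cname}"] = {"before": len(de[cname]), "after": len(de_sets[cname])}
            ledger[f"dm_{cname}"] = {"before": len(dm[cname]), "after": len(dm_sets[cname])}
        bundle.update(de=de, de_sets=de_sets, dm=dm, dm_sets=dm_sets)

        _stage("setops")
        cross_hif1a = setops.cross_contrasts(de_sets["hif1a_nx"], de_sets["hif1a_hyp"])
        cross_hif1a = setops.classify_concordance(cross_hif1a)
        cross_hyp = setops.cross_contrasts(de_sets["hif1a_hyp"], de_sets["hypoxia"])
        cross_hyp = setops.classify_concordance(cross_hyp)
        bundle["hif1a_partition"] = setops.name_partitions(cross_hif1a, "hif1a_scheme")
        bundle["hypoxia_partition"] = setops.name_partitions(cross_hyp, "hypoxia_scheme")
        bundle["cross_hif1a"], bundle["cross_hypoxia"] = cross_hif1a, cross_hyp
        ledger["cross_hif1a"] = {
            "exclusive_a": len(cross_hif1a.exclusive_a),
            "exclusive_b": len(cross_hif1a.exclusive_b),
            "common": len(cross_hif1a.common_genes),
        }
        ledger["cross_hypoxia"] = {
            "common": len(cross_hyp.common_genes),
            "concordant": len(cross_hyp.concordant),
            "discordant": len(cross_hyp.discordant),
        }

        _stage("annotation")
        dists = {}
        for cname in ("hypoxia", "hif1a_hyp"):
            probes = list(dm_sets[cname].index)
            if probes:
                for system in ("cgi", "gene"):
                    dists[f"{cname}_{system}"] = annotation.feature_distribution(
                        probes, manifest, system=system, fdr=config.fdr
                    )
        bundle["feature_distributions"] = dists
        if gene_sets is not None:
            background = set(expression.gene_ids)
            enr = {}
            for label, genes in bundle["hif1a_partition"].items():
                if genes:
                    enr[label] = annotation.geneset_enrichment(
                        set(genes), background, gene_sets,
                        min_size=config.min_geneset, fdr=config.fdr,
                    )
            bundle["enrichment"] = enr

        _stage("integration")
        pairs = {}
        for cname in ("hif1a_hyp", "hypoxia"):
            pairs[cname] = integration.pair_inverse(
                dm[cname], de[cname], manifest,
                p_threshold=config.pair_p,
                delta_threshold=config.delta_beta,
                p_mode=config.pair_p_mode,
            )
            ledger[f"pairs_{cname}"] = {
                "after": len(pairs[cname]),
                "skipped_intergenic": pairs[cname].attrs["n_skipped_intergenic"],
            }
        bundle["pairs"] = pairs
        bundle["common_probes"] = integration.common_probe_inversion(
            dm_sets["hypoxia"], dm_sets["hif1a_hyp"]
        )
        ledger["common_probes"] = dict(bundle["common_probes"].attrs)

        if tracks and gene_coords is not None:
            _stage("enhancers")
            probe_pos = manifest.loc[dm_sets["hypoxia"].index, ["chrom", "pos"]]
            candidates, summary = enhancers.overlap_regulatory(
                probe_pos, tracks, min_markers=config.enhancer_min_markers
            )
            links = enhancers.link_targets(
                candidates, gene_coords, de["hypoxia"],
                window=config.link_window_bp, lfc_gate=config.link_lfc,
            )
            classified = enhancers.classify_dependency(
                links, dm["hypoxia"], dm["hif1a_hyp"], de["hif1a_hyp"],
                delta_gate=config.delta_beta, lfc_gate=config.link_lfc,
                fdr=config.fdr,
            )
            bundle["enhancer_candidates"] = candidates
            bundle["enhancer_summary"] = summary
            bundle["target_links"] = classified
            bundle["probe_dependency"] = enhancers.summarize_probe_dependency(classified)
            ledger["enhancers"] = dict(summary)

        if cohort is not None:
            _stage("signatures")
            reports = {}
            for cname, label in (("hif1a_hyp", "hif1a_signature"), ("hypoxia", "hypoxia_signature")):
                genes = [
                    g for g in pairs[cname]["gene_id"].unique()
                    if g in cohort.values.index
                ]
                if len(genes) >= 2:
                    reports[label] = signatures.signature_report(
                        cohort, genes, method=config.linkage_method,
                        n_perm=config.n_perm, seed=config.seed,
                    )
            bundle["signature_reports"] = reports
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    if outdir is not None:
        _write_bundle(config, bundle, Path(outdir))
    return bundle


def _write_bundle(config: PipelineConfig, bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for cname in bundle.get("de", {}):
        bundle["de"][cname].round(6).to_csv(outdir / f"de_{cname}.tsv", sep="\t")
        bundle["dm"][cname].round(6).to_csv(outdir / f"dm_{cname}.tsv", sep="\t")
    for key in ("hif1a_partition", "hypoxia_partition"):
        if key in bundle:
            formats.write_json(bundle[key], outdir / f"{key}.json")
    for cname, table in bundle.get("pairs", {}).items():
        table.round(6).to_csv(outdir / f"pairs_{cname}.tsv", sep="\t", index=False)
    if "common_probes" in bundle:
        bundle["common_probes"].round(6).to_csv(outdir / "common_probes.tsv", sep="\t")
    if "target_links" in bundle:
        bundle["target_links"].round(6).to_csv(
            outdir / "target_links.tsv", sep="\t", index=False
        )
    if "signature_reports" in bundle:
        formats.write_json(
            {
                label: {
                    "high_pct": r.high_pct,
                    "low_pct": r.low_pct,
                    "p_value": r.p_value,
                }
                for label, r in bundle["signature_reports"].items()
            },
            outdir / "signature_reports.json",
        )
    from . import __version__

    formats.write_json(
        {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "ledger": bundle["ledger"],
        },
        outdir / "run_manifest.json",
    )
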