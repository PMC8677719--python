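"""End-to-end orchestration: PBM -> motif -> stage filter -> upstream scan ->
intersection -> enrichment, from one YAML config, with plain-file handoff
between stages and a provenance manifest (input SHA-256 checksums, parameters,
seed, tool version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, enrichment, expression, io, motif, pbm, scan

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, stage parameters and toggles for one pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    # inputs
    probes: list[str] = field(default_factory=list)
    expression: str | None = None
    genome: str | None = None
    genes: str | None = None            # GFF3 (.gff/.gff3) or BED6
    categories: str | None = None
    annotations: str | None = None      # TSV: gene_id, annotation, human_homolog
    # parameters
    top_k: int = 25
    site_width: int | None = None       # center-crop width for motif building
    window: int = 500
    pthresh: float = 1e-4
    stage_order: list[str] = field(default_factory=lambda: list(expression.DEFAULT_STAGE_ORDER))
    exclusion_rule: str = "either"
    zero_rule: str = "any-stage"
    pseudocount: float = 0.1
    enrich_alpha: float = 0.05
    # toggles
    run_pbm: bool = True
    run_motif: bool = True
    run_filter: bool = True
    run_scan: bool = True
    run_enrich: bool = True

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.pthresh <= 1:
            raise ValueError("pthresh must lie in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineReport:
    parameters: dict[str, Any]
    counts: dict[str, Any] = field(default_factory=dict)
    version: str = __version__
    runtime_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        io.write_json(dataclasses.asdict(self), path)


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def intersect_annotations(kept: list[str] | set[str],
                          annotations: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Subset of kept genes carrying any annotation, and the further subset
    with a human-homolog entry."""
    kept = set(kept)
    if annotations.empty:
        return set(), set()
    annotated = kept & set(annotations.loc[annotations["annotation"].notna() &
                                           (annotations["annotation"] != ""), "gene_id"])
    if "human_homolog" in annotations.columns:
        hh = annotations.loc[annotations["human_homolog"].notna() &
                             (annotations["human_homolog"] != ""), "gene_id"]
        homolog = annotated & set(hh)
    else:
        homolog = set()
    return annotated, homolog


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute enabled stages in order, writing every intermediate artifact
    and a provenance manifest under ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}
    stage = "setup"
    profile = None
    pfm = None
    kept: list[str] | None = None
    try:
        if config.run_pbm:
            stage = "pbm"
            if not config.probes:
                raise ValueError("run_pbm enabled but no probe tables configured")
            profile = pbm.profile_from_probe_tables(config.probes)
            profile.to_tsv(outdir / "profile.tsv")
            counts["pbm_sequences"] = int(len(profile.z))
            counts["pbm_background"] = int(profile.n_background)
            log.info("pbm: %d sequences (%d background)",
                     len(profile.z), profile.n_background)

        if config.run_motif:
            stage = "motif"
            if profile is None:
                profile = pbm.BindingProfile.from_tsv(outdir / "profile.tsv")
            sites = motif.select_top_sites(profile, config.top_k)
            if config.site_width and config.site_width < len(sites[0]):
                start = (len(sites[0]) - config.site_width) // 2
                sites = [s[start:start + config.site_width] for s in sites]
            pfm = motif.build_pfm(sites, pseudocount=config.pseudocount)
            motif.write_meme(pfm, outdir / "motif.meme")
            counts["motif_width"] = pfm.width
            counts["motif_n_sites"] = pfm.n_sites
            log.info("motif: consensus %s from %d sites", pfm.consensus(), pfm.n_sites)

        if config.run_filter:
            stage = "filter"
            table = expression.ExpressionTable.from_tsv(config.expression,
                                                        tuple(config.stage_order))
            means = expression.stage_means(table)
            result = expression.concordance_filter(means, config.stage_order,
                                                   zero_rule=config.zero_rule)
            kept = result.kept_genes
            io.write_gene_list(kept, outdir / "kept.txt")
            io.write_gene_list(result.discarded_zero, outdir / "discarded_zero.txt")
            io.write_gene_list(result.discarded_order, outdir / "discarded_order.txt")
            means.to_csv(outdir / "stage_means.tsv", sep="\t")
            counts["genes_in"] = int(len(means))
            counts["discarded_zero"] = len(result.discarded_zero)
            counts["discarded_order"] = len(result.discarded_order)
            counts["kept"] = len(kept)
            log.info("filter: %d in, %d zero-discarded, %d order-discarded, %d kept",
                     len(means), len(result.discarded_zero),
                     len(result.discarded_order), len(kept))

        genes_with_hits: set[str] = set()
        if config.run_scan:
            stage = "scan"
            if pfm is None:
                pfm = motif.read_meme(outdir / "motif.meme")
            models = (scan.read_gff3_genes(config.genes)
                      if str(config.genes).endswith((".gff", ".gff3"))
                      else scan.read_bed6_genes(config.genes))
            if kept is not None:
                keep = set(kept)
                models = [m for m in models if m.gene_id in keep]
            windows = scan.extract_upstream(config.genome, models, window=config.window)
            result = scan.scan_windows(windows, pfm, threshold_p=config.pthresh)
            scan.hits_to_bed(result, windows, pfm.width, outdir / "hits.bed")
            scan.counts_to_tsv(result, outdir / "site_counts.tsv")
            genes_with_hits, histogram = scan.genes_with_sites(result)
            counts["genes_scanned"] = len(windows)
            counts["genes_with_sites"] = len(genes_with_hits)
            counts["site_count_histogram"] = {str(k): v for k, v in sorted(histogram.items())}
            log.info("scan: %d/%d genes with sites", len(genes_with_hits), len(windows))

        if kept is not None and genes_with_hits:
            stage = "intersect"
            targets = sorted(set(kept) & genes_with_hits)
            io.write_gene_list(targets, outdir / "targets.txt")
            counts["concordant_with_sites"] = len(targets)
        if config.annotations and kept is not None:
            stage = "annotate"
            ann = pd.read_csv(config.annotations, sep="\t", dtype=str)
            annotated, homolog = intersect_annotations(kept, ann)
            counts["kept_annotated"] = len(annotated)
            counts["kept_with_human_homolog"] = len(homolog)

        if config.run_enrich:
            stage = "enrich"
            cats = io.read_category_map(config.categories)
            universe = (sorted(pd.read_csv(config.expression, sep="\t")["gene_id"]
                               .astype(str).unique())
                        if config.expression else sorted(set(cats["gene_id"])))
            selected = kept if kept is not None else io.read_gene_list(outdir / "kept.txt")
            results = enrichment.hypergeometric_enrichment(selected, universe, cats)
            enrichment.write_results(results, outdir / "enrichment.tsv")
            n_sig = sum(r.bh_adjusted_p <= config.enrich_alpha for r in results)
            counts["categories_tested"] = len(results)
            counts["categories_enriched"] = n_sig
            log.info("enrich: %d/%d categories at BH p <= %g",
                     n_sig, len(results), config.enrich_alpha)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = PipelineReport(parameters=dataclasses.asdict(config), counts=counts,
                            runtime_s=round(time.time() - t0, 3))
    report.to_json(outdir / "report.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {key: {"path": str(p), "sha256": sha256(p)}
                   for key, p in {
                       **{f"probes_{i}": p for i, p in enumerate(config.probes)},
                       "expression": config.expression,
                       "genome": config.genome,
                       "genes": config.genes,
                       "categories": config.categories,
                       "annotations": config.annotations,
                   }.items() if p and Path(p).exists()},
    }
    io.write_json(manifest, outdir / "manifest.json")
    return report
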