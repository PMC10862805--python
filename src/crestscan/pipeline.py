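"""End-to-end pipeline driver: scan -> islands -> expression -> enrichment.

A single :class:`PipelineConfig` (loadable from YAML) names the input
files and all stage parameters; :func:`run_pipeline` executes the
stages, writes every output table and a machine-readable JSON manifest
recording the package version, seeds, parameter values and input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .enrichment import EnrichConfig, cluster_enrichment_test, score_genes
from .expression import (
    CountsMatrix,
    SampleMeta,
    call_degs,
    cluster_profiles,
    de_contrast,
    low_count_filter,
    make_contrasts,
    size_factors,
    stage_profiles,
)
from .islands import build_islands, link_closest_gene
from .scan import ScanConfig, xpehh_scan

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # input paths
    vcf: str = ""
    population_map: str = ""
    genes: str = ""
    counts: str = ""
    meta: str = ""
    out_dir: str = "crestscan_out"
    # population orientation: A is the xpEHH numerator
    pop_a: str = ""
    pop_b: str = ""
    # stage parameters
    scan: ScanConfig = field(default_factory=ScanConfig)
    logp_threshold: float = 3.0
    merge_distance: int = 50_000
    promoter_bp: int = 5_000
    k_clusters: int = 7
    lfc_threshold: float = 0.585
    alpha: float = 0.05
    min_count: int = 10
    contrast_mode: str = "between_species"
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("scan"), dict):
            d["scan"] = ScanConfig(**d["scan"])
        if isinstance(d.get("enrich"), dict):
            d["enrich"] = EnrichConfig(**d["enrich"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict.

    Stages with missing inputs are skipped and flagged in the manifest
    (e.g. a counts-only run performs no scan).  Any failure inside a
    stage aborts with a stage-tagged :class:`PipelineError`.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "crestscan_version": __version__,
        "parameters": cfg.to_dict(),
        "inputs": {},
        "outputs": {},
        "stages_run": [],
        "partial": False,
    }
    for name in ("vcf", "population_map", "genes", "counts", "meta"):
        p = getattr(cfg, name)
        if p:
            if not Path(p).exists():
                raise PipelineError("config", f"input path does not exist: {p}")
            manifest["inputs"][name] = {"path": str(p), "md5": _checksum(p)}

    records = []
    genes = []
    if cfg.vcf and cfg.population_map:
        try:
            pops = io.read_vcf_haplotypes(cfg.vcf, cfg.population_map)
            pop_a = cfg.pop_a or sorted(pops)[0]
            pop_b = cfg.pop_b or sorted(p for p in pops if p != pop_a)[0]
            for chrom in sorted(pops[pop_a]):
                records.extend(
                    xpehh_scan(pops[pop_a][chrom], pops[pop_b][chrom], cfg.scan)
                )
            scan_path = out / "scan.tsv"
            io.write_scan_tsv(
                scan_path,
                records,
                header={"pop_A": pop_a, "pop_B": pop_b, "seed": cfg.seed},
            )
            manifest["outputs"]["scan"] = str(scan_path)
            manifest["stages_run"].append("scan")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - re-tagged
            raise PipelineError("scan", str(e)) from e

        try:
            islands = build_islands(records, cfg.logp_threshold, cfg.merge_distance)
            io.write_islands_bed(out / "islands.bed", islands)
            manifest["outputs"]["islands"] = str(out / "islands.bed")
            if cfg.genes:
                genes = io.read_annotation(cfg.genes)
                links = [
                    link_closest_gene(isl, genes, cfg.promoter_bp) for isl in islands
                ]
                io.write_links_tsv(out / "links.tsv", links)
                manifest["outputs"]["links"] = str(out / "links.tsv")
            manifest["stages_run"].append("islands")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("islands", str(e)) from e

    clusters = []
    if cfg.counts and cfg.meta:
        try:
            M = io.read_counts_tsv(cfg.counts)
            meta = io.read_meta_tsv(cfg.meta)
            keep = low_count_filter(M, meta, cfg.min_count)
            Mf = CountsMatrix(
                [g for g, k in zip(M.gene_ids, keep) if k],
                M.sample_ids,
                M.counts[keep],
            )
            factors = size_factors(Mf)
            contrasts = make_contrasts(meta, cfg.contrast_mode)
            deg_records = []
            for c in contrasts:
                deg_records.extend(de_contrast(Mf, factors, meta, c))
            degs = call_degs(deg_records, cfg.lfc_threshold, cfg.alpha)
            io.write_deg_tsv(out / "degs.tsv", deg_records)
            Z, excluded = stage_profiles(Mf, factors, meta, sorted(degs))
            clusters = cluster_profiles(Z, cfg.k_clusters, excluded)
            io.write_clusters_tsv(out / "clusters.tsv", clusters)
            io.write_centroids_tsv(out / "centroids.tsv", clusters, Z.columns)
            manifest["outputs"]["degs"] = str(out / "degs.tsv")
            manifest["outputs"]["clusters"] = str(out / "clusters.tsv")
            manifest["outputs"]["centroids"] = str(out / "centroids.tsv")
            manifest["n_degs"] = len(degs)
            manifest["stages_run"].append("expression")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("expression", str(e)) from e

    if clusters and records and genes:
        try:
            enrich_cfg = dataclasses.replace(cfg.enrich, seed=cfg.enrich.seed or cfg.seed)
            scores = score_genes(genes, records, enrich_cfg)
            results = []
            for c in clusters:
                scored = [g for g in c.gene_ids if g in scores]
                if not scored:
                    logger.warning("cluster %s has no scored genes; skipped", c.cluster_id)
                    continue
                results.append(
                    cluster_enrichment_test(
                        c.gene_ids, genes, records, enrich_cfg,
                        cluster_id=c.cluster_id, scores=scores,
                    )
                )
            io.write_enrichment_tsv(out / "enrichment.tsv", results)
            manifest["outputs"]["enrichment"] = str(out / "enrichment.tsv")
            manifest["stages_run"].append("enrichment")
        except Exception as e:  # noqa: BLE001
            raise PipelineError("enrichment", str(e)) from e

    expected = {"scan", "islands"} if cfg.vcf else set()
    if cfg.counts:
        expected.add("expression")
    manifest["partial"] = not expected.issubset(set(manifest["stages_run"]))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
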