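"""Readers and writers for the pipeline's file formats.

Internally all coordinates are 1-based inclusive; BED output is 0-based
half-open per the BED standard, and BED input is converted on read.
TSV outputs carry ``#``-prefixed metadata header lines (parameters,
seeds, sign conventions) above the column header; pandas reads them
back with ``comment='#'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult
from .expression import CountsMatrix, DEGRecord, ExpressionCluster, SampleMeta
from .islands import GeneAnnotation, GeneIslandLink, SelectionIsland
from .scan import HaplotypeMatrix, InvalidInputError, XpEhhRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf_haplotypes",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "read_annotation",
    "write_bed_genes",
    "write_scan_tsv",
    "read_scan_tsv",
    "write_islands_bed",
    "write_links_tsv",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_meta_tsv",
    "read_meta_tsv",
    "write_deg_tsv",
    "write_clusters_tsv",
    "read_clusters_tsv",
    "write_enrichment_tsv",
]

MISSING = "."


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(path, panels: list[HaplotypeMatrix], seed: int | None = None) -> None:
    """Write aligned phased panels as one diploid VCF.

    Haplotype rows 2i and 2i+1 of each panel become sample i of that
    population (``<label>_<i>``); alleles are REF=A, ALT=T.  All panels
    must share chromosome and positions.
    """
    ref = panels[0]
    for p in panels[1:]:
        if p.chrom != ref.chrom or not np.array_equal(p.positions, ref.positions):
            raise InvalidInputError("panels must share chromosome and positions")
        if p.n_hap % 2:
            raise InvalidInputError("odd haplotype count cannot form diploids")
    sample_names = []
    for p in panels:
        label = p.population_label or "pop"
        sample_names += [f"{label}_{i}" for i in range(p.n_hap // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crestscan\n")
        if seed is not None:
            fh.write(f"##crestscan_seed={seed}\n")
        max_pos = int(ref.positions[-1]) if ref.positions.size else 1
        fh.write(f"##contig=<ID={ref.chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j in range(ref.n_sites):
            gts = []
            for p in panels:
                col = p.alleles[:, j]
                gts += [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(p.n_hap // 2)]
            fh.write(
                f"{ref.chrom}\t{int(ref.positions[j])}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf_haplotypes(
    path, population_map: dict[str, str] | str | Path
) -> dict[str, dict[str, HaplotypeMatrix]]:
    """Read phased haplotypes from a VCF, split by population.

    ``population_map`` maps sample id -> population label (or is a path
    to a two-column TSV).  Multi-allelic, unphased or incompletely
    genotyped records are skipped and counted.  Returns
    ``{population: {chrom: HaplotypeMatrix}}``.
    """
    from cyvcf2 import VCF

    if not isinstance(population_map, dict):
        population_map = read_population_map(population_map)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in population_map if s not in samples]
    if missing:
        raise InvalidInputError(f"samples in population map absent from VCF: {missing}")
    pops = sorted(set(population_map.values()))
    sample_idx = {pop: [i for i, s in enumerate(samples) if population_map.get(s) == pop]
                  for pop in pops}

    per_chrom_pos: dict[str, list[int]] = {}
    per_chrom_cols: dict[str, dict[str, list[np.ndarray]]] = {}
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        usable = True
        for pop in pops:
            for i in sample_idx[pop]:
                g = gts[i]
                if len(g) < 3 or not g[2] or g[0] < 0 or g[1] < 0:
                    usable = False
                    break
            if not usable:
                break
        if not usable:
            n_skipped += 1
            continue
        chrom = v.CHROM
        if chrom not in per_chrom_pos:
            per_chrom_pos[chrom] = []
            per_chrom_cols[chrom] = {pop: [] for pop in pops}
        per_chrom_pos[chrom].append(v.POS)
        for pop in pops:
            col = np.array(
                [a for i in sample_idx[pop] for a in (gts[i][0], gts[i][1])],
                dtype=np.uint8,
            )
            per_chrom_cols[chrom][pop].append(col)
    if n_skipped:
        logger.info("VCF %s: skipped %d unusable records", path, n_skipped)
    if not per_chrom_pos:
        raise InvalidInputError(f"no usable phased biallelic records in {path}")

    out: dict[str, dict[str, HaplotypeMatrix]] = {pop: {} for pop in pops}
    for chrom, positions in per_chrom_pos.items():
        pos = np.asarray(positions, dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise InvalidInputError(f"{path}: positions not strictly increasing on {chrom}")
        for pop in pops:
            alleles = np.column_stack(per_chrom_cols[chrom][pop])
            out[pop][chrom] = HaplotypeMatrix(chrom, pos, alleles, pop)
    return out


def write_population_map(path, mapping: dict[str, str]) -> None:
    pd.DataFrame(
        {"sample_id": list(mapping), "population": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_population_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"])
    return dict(zip(df["sample_id"].astype(str), df["population"].astype(str)))


# ---------------------------------------------------------------------------
# Gene annotation (BED6 / GFF3)
# ---------------------------------------------------------------------------


def write_bed_genes(path, genes: list[GeneAnnotation]) -> None:
    """BED6: 0-based half-open, strand in column 6."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def _read_bed_genes(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6 or fields[5] not in ("+", "-"):
                logger.warning("%s line %d: malformed/strandless BED record skipped", path, ln)
                continue
            try:
                start0, end1 = int(fields[1]), int(fields[2])
            except ValueError:
                logger.warning("%s line %d: malformed BED record skipped", path, ln)
                continue
            genes.append(
                GeneAnnotation(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=start0 + 1,
                    end=end1,
                    strand=fields[5],
                )
            )
    return genes


def _read_gff3_genes(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s line %d: malformed GFF3 record skipped", path, ln)
                continue
            if fields[2] != "gene":
                continue
            if fields[6] not in ("+", "-"):
                logger.warning("%s line %d: missing strand, record skipped", path, ln)
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id") or f"gene_line{ln}"
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    gene_name=attrs.get("Name"),
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


def read_annotation(path) -> list[GeneAnnotation]:
    """Gene annotations from BED6 (0-based, converted) or GFF3
    (1-based, ``gene`` features only), chosen by file extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gff3_genes(path)
    return _read_bed_genes(path)


# ---------------------------------------------------------------------------
# Scan / islands / expression / enrichment tables
# ---------------------------------------------------------------------------

_SCAN_COLS = [
    "chrom", "pos", "maf_A", "maf_B", "iES_A", "iES_B",
    "xpehh_raw", "z", "logp", "censored",
]


def write_scan_tsv(path, records: list[XpEhhRecord], header: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# xpEHH scan; xpehh_raw = ln(iES_A / iES_B): positive favours popA\n")
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(_SCAN_COLS) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.maf_A:.6g}\t{r.maf_B:.6g}\t"
                f"{r.iES_A:.6g}\t{r.iES_B:.6g}\t{r.xpehh_raw:.6g}\t"
                f"{r.z:.6g}\t{r.logp:.6g}\t{int(r.censored)}\n"
            )


def read_scan_tsv(path) -> list[XpEhhRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        XpEhhRecord(
            chrom=str(row.chrom), pos=int(row.pos),
            maf_A=float(row.maf_A), maf_B=float(row.maf_B),
            iES_A=float(row.iES_A), iES_B=float(row.iES_B),
            xpehh_raw=float(row.xpehh_raw), z=float(row.z),
            logp=float(row.logp), censored=bool(row.censored),
        )
        for row in df.itertuples()
    ]


def write_islands_bed(path, islands: list[SelectionIsland]) -> None:
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(
                f"{isl.chrom}\t{isl.start - 1}\t{isl.end}\t{isl.island_id}\t"
                f"{isl.n_sig_snps}\t{isl.max_logp:.6g}\n"
            )


def write_links_tsv(path, links: list[GeneIslandLink]) -> None:
    with open(path, "w") as fh:
        fh.write("island_id\tgene_id\tdistance\tcategory\n")
        for ln in links:
            if ln.gene is None:
                fh.write(f"{ln.island.island_id}\t{MISSING}\t{MISSING}\t{MISSING}\n")
            else:
                fh.write(
                    f"{ln.island.island_id}\t{ln.gene.gene_id}\t"
                    f"{ln.distance}\t{ln.category}\n"
                )


def write_counts_tsv(path, M: CountsMatrix) -> None:
    M.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_tsv(path) -> CountsMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return CountsMatrix.from_frame(df)


def write_meta_tsv(path, meta: SampleMeta) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_meta_tsv(path) -> SampleMeta:
    return SampleMeta(pd.read_csv(path, sep="\t", comment="#"))


def write_deg_tsv(path, records: list[DEGRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontrast\tlog2fc\tpvalue\tpadj\tis_deg\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.contrast}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t"
                f"{r.padj:.6g}\t{int(r.is_deg)}\n"
            )


def write_clusters_tsv(path, clusters: list[ExpressionCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcluster_id\n")
        for c in clusters:
            for g in c.gene_ids:
                fh.write(f"{g}\t{c.cluster_id}\n")


def read_clusters_tsv(path) -> dict[int, list[str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[int, list[str]] = {}
    for row in df.itertuples():
        out.setdefault(int(row.cluster_id), []).append(str(row.gene_id))
    return out


def write_centroids_tsv(path, clusters: list[ExpressionCluster], columns) -> None:
    df = pd.DataFrame(
        [c.centroid for c in clusters],
        index=[c.cluster_id for c in clusters],
        columns=columns,
    )
    df.rename_axis("cluster_id").to_csv(path, sep="\t")


def write_enrichment_tsv(path, results: list[EnrichmentResult]) -> None:
    from statsmodels.stats.multitest import multipletests

    ps = [r.empirical_p for r in results]
    padj = multipletests(ps, method="fdr_bh")[1] if results else []
    with open(path, "w") as fh:
        fh.write("cluster_id\tn_genes_scored\tobserved_stat\tempirical_p\tpadj_bh\n")
        for r, q in zip(results, padj):
            fh.write(
                f"{r.cluster_id}\t{r.n_genes_scored}\t{r.observed_stat:.6g}\t"
                f"{r.empirical_p:.6g}\t{q:.6g}\n"
            )
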