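"""Selection islands: threshold, merge, and link to the closest gene.

Significant scan SNPs (-log10 p >= 3 by default) are chained into
"islands": a SNP joins the current island when it lies within the merge
distance (default 50 kb) of the island's last member, matching
`bedtools merge -d` semantics.  Each island is then annotated with its
closest gene and classified as gene-body, promoter (within a
strand-aware upstream window of the TSS) or intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .scan import InvalidInputError, XpEhhRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionIsland",
    "GeneAnnotation",
    "GeneIslandLink",
    "significant_sites",
    "merge_islands",
    "link_closest_gene",
    "build_islands",
]

DEFAULT_LOGP_THRESHOLD = 3.0
DEFAULT_MERGE_DISTANCE = 50_000
DEFAULT_PROMOTER_BP = 5_000


@dataclass
class SelectionIsland:
    """A merged run of significant SNPs (1-based inclusive interval)."""

    chrom: str
    start: int
    end: int
    member_positions: np.ndarray
    max_logp: float
    mean_logp: float
    island_id: str = ""

    def __post_init__(self) -> None:
        self.member_positions = np.asarray(self.member_positions, dtype=np.int64)
        if self.start > self.end:
            raise InvalidInputError("island start > end")
        if self.member_positions.size and (
            self.member_positions.min() < self.start
            or self.member_positions.max() > self.end
        ):
            raise InvalidInputError("member positions outside island bounds")

    @property
    def n_sig_snps(self) -> int:
        return int(self.member_positions.size)


@dataclass
class GeneAnnotation:
    """A gene interval with a strand-derived transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidInputError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneIslandLink:
    island: SelectionIsland
    gene: GeneAnnotation | None
    distance: int | None
    category: str | None  # gene_body | promoter | intergenic


def significant_sites(
    records: list[XpEhhRecord], logp_threshold: float = DEFAULT_LOGP_THRESHOLD
) -> list[XpEhhRecord]:
    """Records with logp >= threshold (inclusive bound)."""
    return [r for r in records if r.logp >= logp_threshold]


def merge_islands(
    chrom: str,
    positions: np.ndarray,
    logps: np.ndarray | None = None,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
) -> list[SelectionIsland]:
    """Chain sorted significant positions into islands.

    Single left-to-right pass: a position joins the open island iff its
    distance to the island's *last member* is <= merge_distance
    (chained, not anchored at the island start).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        return []
    if np.any(np.diff(positions) <= 0):
        raise InvalidInputError("positions must be sorted and unique")
    if logps is None:
        logps = np.full(positions.size, np.nan)
    logps = np.asarray(logps, dtype=float)

    islands: list[SelectionIsland] = []
    run_start = 0
    for i in range(1, positions.size + 1):
        if i == positions.size or positions[i] - positions[i - 1] > merge_distance:
            members = positions[run_start:i]
            mem_logp = logps[run_start:i]
            has_logp = mem_logp.size and not np.isnan(mem_logp).all()
            islands.append(
                SelectionIsland(
                    chrom=chrom,
                    start=int(members[0]),
                    end=int(members[-1]),
                    member_positions=members,
                    max_logp=float(np.nanmax(mem_logp)) if has_logp else float("nan"),
                    mean_logp=float(np.nanmean(mem_logp)) if has_logp else float("nan"),
                )
            )
            run_start = i
    for k, isl in enumerate(islands):
        isl.island_id = f"{chrom}_isl{k + 1}"
    return islands


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two closed intervals; 0 when they overlap."""
    if a_end < b_start:
        return b_start - a_end
    if b_end < a_start:
        return a_start - b_end
    return 0


def promoter_window(gene: GeneAnnotation, promoter_bp: int = DEFAULT_PROMOTER_BP):
    """Strand-aware window immediately upstream of the TSS."""
    if gene.strand == "+":
        return max(1, gene.tss - promoter_bp), gene.tss - 1
    return gene.tss + 1, gene.tss + promoter_bp


def link_closest_gene(
    island: SelectionIsland,
    genes: list[GeneAnnotation],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
) -> GeneIslandLink:
    """Closest gene on the island's chromosome, with the island
    classified against that gene.

    Ties in distance are broken by (smaller gene start, then gene_id);
    the tie count is logged.  Category: gene_body when the island
    overlaps the gene interval; else promoter when it overlaps the
    upstream promoter window; else intergenic.
    """
    candidates = [g for g in genes if g.chrom == island.chrom]
    if not candidates:
        return GeneIslandLink(island, None, None, None)

    dists = [
        _interval_distance(island.start, island.end, g.start, g.end)
        for g in candidates
    ]
    best = min(dists)
    tied = [g for g, d in zip(candidates, dists) if d == best]
    if len(tied) > 1:
        logger.info(
            "island %s: %d genes tied at distance %d", island.island_id, len(tied), best
        )
    gene = min(tied, key=lambda g: (g.start, g.gene_id))

    if best == 0:
        category = "gene_body"
    else:
        pw_start, pw_end = promoter_window(gene, promoter_bp)
        if pw_start <= pw_end and _interval_distance(
            island.start, island.end, pw_start, pw_end
        ) == 0:
            category = "promoter"
        else:
            category = "intergenic"
    return GeneIslandLink(island, gene, best, category)


def build_islands(
    records: list[XpEhhRecord],
    logp_threshold: float = DEFAULT_LOGP_THRESHOLD,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
) -> list[SelectionIsland]:
    """Threshold a sorted scan and merge per chromosome."""
    sig = significant_sites(records, logp_threshold)
    by_chrom: dict[str, list[XpEhhRecord]] = {}
    for r in sig:
        by_chrom.setdefault(r.chrom, []).append(r)
    islands: list[SelectionIsland] = []
    for chrom in sorted(by_chrom):
        rs = by_chrom[chrom]
        pos = np.array([r.pos for r in rs], dtype=np.int64)
        lp = np.array([r.logp for r in rs])
        islands.extend(merge_islands(chrom, pos, lp, merge_distance))
    return islands
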