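"""Between-species expression divergence over developmental stages.

Pipeline: median-of-ratios size factors -> low-count filter -> per-stage
negative-binomial Wald contrasts between species -> DEG calls
(|log2FC| >= 0.585, i.e. 1.5-fold, and BH-adjusted p < 0.05 in at least
one contrast) -> per-gene Z-scored (species x stage) mean profiles ->
complete-linkage hierarchical clustering into k (default 7) clusters.

The differential test is a transparent NB Wald test with per-gene
method-of-moments dispersion; it is deliberately simpler than a full
shrinkage-based DE framework — downstream stages need DEG sets and
profiles, not exact parity with any particular tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .scan import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "CountsMatrix",
    "SampleMeta",
    "Contrast",
    "DEGRecord",
    "ExpressionCluster",
    "NormalizationError",
    "size_factors",
    "low_count_filter",
    "collapse_technical_replicates",
    "make_contrasts",
    "de_contrast",
    "call_degs",
    "stage_profiles",
    "cluster_profiles",
]

DEFAULT_LFC_THRESHOLD = 0.585  # log2(1.5), inclusive
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COUNT = 10
DEFAULT_K = 7
_PSEUDOCOUNT = 0.5
_DISPERSION_FLOOR = 1e-8


class NormalizationError(ValueError):
    """Raised when median-of-ratios normalisation is impossible."""


@dataclass
class CountsMatrix:
    """Raw integer counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InvalidInputError("counts shape does not match id lists")
        if self.counts.size and self.counts.min() < 0:
            raise InvalidInputError("counts must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountsMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleMeta:
    """Sample annotation: species in {A, B}, ordinal stage, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "species", "stage", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"metadata missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise InvalidInputError("duplicate sample_id in metadata")

    def check_covers(self, M: CountsMatrix) -> None:
        known = set(self.table["sample_id"])
        unknown = [s for s in M.sample_ids if s not in known]
        if unknown:
            raise InvalidInputError(f"samples missing from metadata: {unknown[:5]}")

    def samples_for(self, species: str | None = None, stage=None) -> list[str]:
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if stage is not None:
            t = t[t["stage"] == stage]
        return list(t["sample_id"])


@dataclass(frozen=True)
class Contrast:
    """Two named sample groups to compare (group2 over group1)."""

    name: str
    group1: tuple[str, ...]
    group2: tuple[str, ...]


@dataclass
class DEGRecord:
    gene_id: str
    contrast: str
    log2fc: float
    pvalue: float
    padj: float = float("nan")
    is_deg: bool = False


@dataclass
class ExpressionCluster:
    cluster_id: int
    gene_ids: list[str]
    centroid: np.ndarray


def size_factors(M: CountsMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    The per-gene reference is the geometric mean across samples; genes
    with a zero anywhere are excluded from the reference; each sample's
    factor is the median ratio of its counts to the reference.
    """
    counts = M.counts.astype(float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError("no gene has nonzero counts in every sample")
    sub = counts[all_nonzero]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return factors


def low_count_filter(
    M: CountsMatrix,
    meta: SampleMeta,
    min_count: int = DEFAULT_MIN_COUNT,
    mode: str = "both",
) -> np.ndarray:
    """Boolean mask of retained genes.

    ``mode='both'`` (default) removes a gene only when every sample of
    *both* species is below ``min_count`` (the least aggressive reading
    of a per-species low-count rule); ``mode='either'`` removes it when
    all samples of either single species are below the threshold.
    """
    meta.check_covers(M)
    if mode not in ("both", "either"):
        raise InvalidInputError("mode must be 'both' or 'either'")
    col = {s: j for j, s in enumerate(M.sample_ids)}
    low_by_species = []
    for sp in sorted(meta.table["species"].unique()):
        cols = [col[s] for s in meta.samples_for(species=sp) if s in col]
        low_by_species.append((M.counts[:, cols] < min_count).all(axis=1))
    low = np.vstack(low_by_species)
    removed = low.all(axis=0) if mode == "both" else low.any(axis=0)
    return ~removed


def collapse_technical_replicates(
    M: CountsMatrix, groups: dict[str, list[str]]
) -> CountsMatrix:
    """Sum counts of technical replicates; ``groups`` maps the collapsed
    sample id to the raw sample ids it absorbs."""
    col = {s: j for j, s in enumerate(M.sample_ids)}
    new_ids = list(groups)
    out = np.zeros((len(M.gene_ids), len(new_ids)), dtype=M.counts.dtype)
    for j, (new, members) in enumerate(groups.items()):
        out[:, j] = M.counts[:, [col[m] for m in members]].sum(axis=1)
    return CountsMatrix(M.gene_ids, new_ids, out)


def make_contrasts(meta: SampleMeta, mode: str = "between_species") -> list[Contrast]:
    """Build the contrast list.

    ``between_species`` (default): species A vs species B at each stage.
    ``all_cross_stage``: species A at stage s vs species B at stage t
    for every stage pair (the widest reading of "any pairwise stage
    comparison between species").
    """
    stages = sorted(meta.table["stage"].unique())
    contrasts = []
    if mode == "between_species":
        for st in stages:
            contrasts.append(
                Contrast(
                    name=f"B_vs_A_stage{st}",
                    group1=tuple(meta.samples_for("A", st)),
                    group2=tuple(meta.samples_for("B", st)),
                )
            )
    elif mode == "all_cross_stage":
        for s1 in stages:
            for s2 in stages:
                contrasts.append(
                    Contrast(
                        name=f"B{s2}_vs_A{s1}",
                        group1=tuple(meta.samples_for("A", s1)),
                        group2=tuple(meta.samples_for("B", s2)),
                    )
                )
    else:
        raise InvalidInputError("mode must be 'between_species' or 'all_cross_stage'")
    return [c for c in contrasts if c.group1 and c.group2]


def _mom_dispersion(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion alpha (var = mu + alpha mu^2) by pooled
    method of moments over the two groups.

    With 2-3 replicates the gene-wise moment estimate is very noisy and
    its underestimates make the Wald test anticonservative, so each
    gene's estimate is floored at the across-gene median (a crude but
    transparent form of dispersion moderation) and at a small positive
    constant.
    """
    alphas = []
    for x in (x1, x2):
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / np.square(mu)
        a[~np.isfinite(a)] = 0.0
        alphas.append(a)
    alpha = np.mean(alphas, axis=0)
    if alpha.size >= 10:
        alpha = np.maximum(alpha, np.median(alpha))
    return np.maximum(alpha, _DISPERSION_FLOOR)


def de_contrast(
    M: CountsMatrix,
    factors: np.ndarray,
    meta: SampleMeta,
    contrast: Contrast,
) -> list[DEGRecord]:
    """NB Wald test of one contrast, gene by gene.

    Counts are divided by their sample size factors; the effect is the
    difference of log group means (pseudocount 0.5), its variance the
    delta-method NB variance of a log mean, dispersion from pooled
    method of moments.  Two-sided normal p-values, BH-adjusted across
    genes within the contrast.
    """
    meta.check_covers(M)
    if len(contrast.group1) < 2 or len(contrast.group2) < 2:
        raise InvalidInputError("need >= 2 replicates per group")
    col = {s: j for j, s in enumerate(M.sample_ids)}
    j1 = [col[s] for s in contrast.group1]
    j2 = [col[s] for s in contrast.group2]
    norm_counts = M.counts.astype(float) / np.asarray(factors)[None, :]
    x1, x2 = norm_counts[:, j1], norm_counts[:, j2]
    if not x1.any() or not x2.any():
        raise InvalidInputError(
            f"contrast {contrast.name}: a group has all-zero counts for every gene"
        )
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    n1, n2 = len(j1), len(j2)

    log2fc = np.log2((m2 + _PSEUDOCOUNT) / (m1 + _PSEUDOCOUNT))
    alpha = _mom_dispersion(x1, x2)
    effect = np.log(m2 + _PSEUDOCOUNT) - np.log(m1 + _PSEUDOCOUNT)
    var = (
        1.0 / (n1 * (m1 + _PSEUDOCOUNT))
        + alpha / n1
        + 1.0 / (n2 * (m2 + _PSEUDOCOUNT))
        + alpha / n2
    )
    z = effect / np.sqrt(var)
    pvals = 2.0 * norm.sf(np.abs(z))
    padj = multipletests(pvals, method="fdr_bh")[1]

    return [
        DEGRecord(
            gene_id=g,
            contrast=contrast.name,
            log2fc=float(lfc),
            pvalue=float(p),
            padj=float(q),
        )
        for g, lfc, p, q in zip(M.gene_ids, log2fc, pvals, padj)
    ]


def call_degs(
    records: list[DEGRecord],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> set[str]:
    """Flag records and return the DEG union over all contrasts.

    A gene is a DEG when |log2FC| >= lfc_threshold (inclusive: 1.5-fold
    counts as differential) and BH-adjusted p < alpha in at least one
    contrast.
    """
    degs: set[str] = set()
    for r in records:
        r.is_deg = abs(r.log2fc) >= lfc_threshold and r.padj < alpha
        if r.is_deg:
            degs.add(r.gene_id)
    return degs


def stage_profiles(
    M: CountsMatrix,
    factors: np.ndarray,
    meta: SampleMeta,
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Z-scored per-gene profiles of mean normalised counts per
    (species, stage) cell.

    Returns the profile matrix (rows: genes; columns species-major,
    e.g. A_0..A_9, B_0..B_9) and a boolean mask of genes excluded for
    zero variance (their profiles are all-zero).
    """
    meta.check_covers(M)
    norm_counts = M.counts.astype(float) / np.asarray(factors)[None, :]
    col = {s: j for j, s in enumerate(M.sample_ids)}
    species = sorted(meta.table["species"].unique())
    stages = sorted(meta.table["stage"].unique())
    col_names, cell_cols = [], []
    for sp in species:
        for st in stages:
            cols = [col[s] for s in meta.samples_for(sp, st) if s in col]
            if not cols:
                raise InvalidInputError(f"no samples for species {sp} stage {st}")
            col_names.append(f"{sp}_{st}")
            cell_cols.append(cols)
    means = np.column_stack([norm_counts[:, c].mean(axis=1) for c in cell_cols])

    if gene_ids is not None:
        idx = {g: i for i, g in enumerate(M.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        means = means[rows]
        out_genes = list(gene_ids)
    else:
        out_genes = list(M.gene_ids)

    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=0, keepdims=True)
    excluded = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (means - mu) / safe_sd
    z[excluded] = 0.0
    return pd.DataFrame(z, index=out_genes, columns=col_names), excluded


def cluster_profiles(
    Z: pd.DataFrame,
    k: int = DEFAULT_K,
    excluded: np.ndarray | None = None,
    metric: str = "euclidean",
) -> list[ExpressionCluster]:
    """Complete-linkage hierarchical clustering of Z-profiles, tree cut
    at k clusters.

    Deterministic given input: scipy's agglomerative linkage breaks
    distance ties by merge order.  Cluster ids are 1..k in order of
    first member appearance is not guaranteed; treat labels as nominal.
    """
    if excluded is not None:
        Z = Z.loc[~np.asarray(excluded)]
    if len(Z) < k:
        raise InvalidInputError(f"need at least {k} non-excluded genes, got {len(Z)}")
    link = linkage(Z.to_numpy(), method="complete", metric=metric)
    labels = fcluster(link, t=k, criterion="maxclust")
    clusters = []
    for cid in range(1, labels.max() + 1):
        members = Z.index[labels == cid].tolist()
        centroid = Z.to_numpy()[labels == cid].mean(axis=0)
        clusters.append(ExpressionCluster(cid, members, centroid))
    return clusters
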