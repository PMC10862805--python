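"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* ``simulate_haplotypes`` — a forward-in-time haploid Wright–Fisher
  model producing two phased 0/1 panels that share a founding panel and
  then drift apart, optionally with a hard selective sweep in
  population A.  This is a deliberately simple stand-in for real
  two-population histories: no demography, migration or mutation-rate
  calibration is attempted.
* ``simulate_counts`` — negative-binomial RNA-seq-like counts for a
  two-species x somite-stage x replicate design, with genes planted on
  temporal archetype profiles (the ground-truth cluster labels are
  returned).
* ``simulate_annotation`` — a random gene map with strands, from which
  transcription start sites follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan import HaplotypeMatrix

__all__ = [
    "HapSimConfig",
    "CountsSimConfig",
    "AnnotationSimConfig",
    "InvalidConfigError",
    "simulate_haplotypes",
    "simulate_counts",
    "simulate_annotation",
    "default_archetypes",
]


class InvalidConfigError(ValueError):
    """Raised when a simulator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Haplotype panels
# ---------------------------------------------------------------------------


@dataclass
class HapSimConfig:
    """Two-population Wright–Fisher haplotype simulation.

    n_haplotypes_per_pop
        Haploid population size (= output panel size); must be even so
        haplotypes pair into diploid VCF samples.
    n_sites
        Segregating sites placed on the founding panel, with derived
        allele counts drawn from the neutral 1/i frequency spectrum.
    mutation_density
        Expected new (singleton) mutations per bp per generation per
        population; infinite-sites, so every site stays biallelic.
    recombination_rate
        Per-bp per-generation crossover probability; crossover points
        are uniform on the chromosome.
    sweep_position / selection_coefficient
        If both set (s > 0), a derived allele at ``sweep_position`` is
        introduced into population A at 5% frequency in the founders,
        all carriers on one founder background (single mutational
        origin), and carriers get multiplicative fitness 1 + s.  s = 0
        reduces exactly to the neutral model.
    population_size
        Haploid size of each evolving population; the output panel is a
        random sample of ``n_haplotypes_per_pop`` haplotypes from it.
        Sampling few haplotypes from a larger population keeps the
        identity-by-descent background low, as in real panels.  ``None``
        evolves the panel itself (population_size = panel size).
    """

    n_haplotypes_per_pop: int = 60
    n_sites: int = 6000
    chrom_length: int = 1_000_000
    mutation_density: float = 2e-6
    recombination_rate: float = 5e-6
    n_generations: int = 30
    sweep_position: int | None = None
    selection_coefficient: float = 0.0
    population_size: int | None = 400
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_haplotypes_per_pop < 4 or self.n_haplotypes_per_pop % 2:
            raise InvalidConfigError("n_haplotypes_per_pop must be even and >= 4")
        if self.n_sites < 1 or self.chrom_length < self.n_sites:
            raise InvalidConfigError("need 1 <= n_sites <= chrom_length")
        if self.sweep_position is not None and not (
            1 <= self.sweep_position <= self.chrom_length
        ):
            raise InvalidConfigError("sweep_position outside [1, chrom_length]")
        if self.selection_coefficient < 0:
            raise InvalidConfigError("selection_coefficient must be >= 0")
        if self.mutation_density < 0 or self.recombination_rate < 0:
            raise InvalidConfigError("rates must be non-negative")
        if self.n_generations < 0:
            raise InvalidConfigError("n_generations must be >= 0")
        if self.population_size is not None and (
            self.population_size < self.n_haplotypes_per_pop
        ):
            raise InvalidConfigError("population_size smaller than the output panel")

    @property
    def pop_size(self) -> int:
        return self.population_size or self.n_haplotypes_per_pop


def _founding_panel(
    rng: np.random.Generator, cfg: HapSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (sorted) and alleles of the founding panel.

    Derived-allele counts follow the neutral SFS p(i) proportional to
    1/i, assigned to uniformly random haplotypes, independently per
    site (founding linkage disequilibrium is therefore ~0).
    """
    n = cfg.pop_size
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_sites, replace=False)) + 1
    i = np.arange(1, n)
    w = (1.0 / i) / (1.0 / i).sum()
    counts = rng.choice(i, size=cfg.n_sites, p=w)
    # rank trick: per column, mark `count` random rows as derived
    u = rng.random((n, cfg.n_sites))
    ranks = u.argsort(axis=0).argsort(axis=0)
    alleles = (ranks < counts[None, :]).astype(np.uint8)
    return positions.astype(np.int64), alleles


def _evolve(
    H: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    cfg: HapSimConfig,
    sweep_col: int | None,
    used_positions: set[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve one population for cfg.n_generations; returns (alleles,
    positions), with new mutation columns appended unsorted."""
    n = H.shape[0]
    H = H.copy()
    positions = positions.copy()
    mean_crossovers = cfg.recombination_rate * cfg.chrom_length
    mean_new_mut = cfg.mutation_density * cfg.chrom_length

    for _ in range(cfg.n_generations):
        if sweep_col is not None:
            w = 1.0 + cfg.selection_coefficient * H[:, sweep_col]
            p = w / w.sum()
            parents = rng.choice(n, size=(n, 2), p=p)
        else:
            parents = rng.integers(0, n, size=(n, 2))
        n_cross = rng.poisson(mean_crossovers, size=n)
        child = H[parents[:, 0]].copy()
        for i in np.flatnonzero(n_cross):
            cuts = np.sort(rng.uniform(0, cfg.chrom_length, n_cross[i]))
            from_p2 = (np.searchsorted(cuts, positions) % 2) == 1
            child[i, from_p2] = H[parents[i, 1], from_p2]
        H = child

        m = rng.poisson(mean_new_mut)
        if m:
            new_cols = np.zeros((n, m), dtype=np.uint8)
            new_pos = np.empty(m, dtype=np.int64)
            for j in range(m):
                while True:
                    pos = int(rng.integers(1, cfg.chrom_length + 1))
                    if pos not in used_positions:
                        break
                used_positions.add(pos)
                new_pos[j] = pos
                new_cols[int(rng.integers(0, n)), j] = 1
            H = np.concatenate([H, new_cols], axis=1)
            positions = np.concatenate([positions, new_pos])
    return H, positions


def simulate_haplotypes(cfg: HapSimConfig) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Simulate two phased panels (population A, population B).

    Both populations start from one founding panel and evolve
    independently; at the end the two position vectors are unioned (a
    site private to one population is monomorphic ancestral in the
    other) so downstream code sees aligned panels.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_found, s_a, s_b, s_sample = ss.spawn(4)
    rng = np.random.default_rng(s_found)

    positions, alleles = _founding_panel(rng, cfg)
    used = set(int(p) for p in positions)

    sweep_active = cfg.sweep_position is not None and cfg.selection_coefficient > 0
    founders_a = alleles
    positions_a = positions
    sweep_col = None
    if sweep_active:
        n = cfg.pop_size
        carriers = rng.choice(n, size=max(1, round(0.05 * n)), replace=False)
        col = np.zeros(n, dtype=np.uint8)
        col[carriers] = 1
        hit = np.flatnonzero(positions == cfg.sweep_position)
        founders_a = alleles.copy()
        # single mutational origin: the derived allele arose once, so all
        # starting carriers share one founder background
        founders_a[carriers, :] = founders_a[carriers[0], :]
        if hit.size:
            sweep_col = int(hit[0])
            founders_a[:, sweep_col] = col
        else:
            sweep_col = founders_a.shape[1]
            founders_a = np.concatenate([founders_a, col[:, None]], axis=1)
            positions_a = np.concatenate(
                [positions, np.array([cfg.sweep_position], dtype=np.int64)]
            )
            used.add(int(cfg.sweep_position))

    hap_a, pos_a = _evolve(
        founders_a, positions_a, np.random.default_rng(s_a), cfg, sweep_col, used
    )
    hap_b, pos_b = _evolve(
        alleles, positions, np.random.default_rng(s_b), cfg, None, used
    )

    all_pos = np.union1d(pos_a, pos_b)

    def _align(hap: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros((hap.shape[0], all_pos.size), dtype=np.uint8)
        out[:, np.searchsorted(all_pos, pos)] = hap
        return out

    samp_rng = np.random.default_rng(s_sample)
    rows_a = np.sort(samp_rng.choice(cfg.pop_size, cfg.n_haplotypes_per_pop, replace=False))
    rows_b = np.sort(samp_rng.choice(cfg.pop_size, cfg.n_haplotypes_per_pop, replace=False))
    A = HaplotypeMatrix(cfg.chrom, all_pos, _align(hap_a, pos_a)[rows_a], "popA")
    B = HaplotypeMatrix(cfg.chrom, all_pos, _align(hap_b, pos_b)[rows_b], "popB")
    return A, B


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------


def default_archetypes(
    n_clusters: int = 7, n_stages: int = 10, effect_size_log2: float = 2.0
) -> np.ndarray:
    """Built-in temporal archetype profiles, log2 deviations from a
    gene's baseline, laid out species-major: columns are
    (species0, stage0..stageS-1, species1, stage0..stageS-1).

    The seven defaults cover rising/falling/transient dynamics shared
    by both species plus species-biased patterns, scaled by
    ``effect_size_log2``.
    """
    u = np.linspace(0.0, 1.0, n_stages)
    e = effect_size_log2
    ramp = e * (u - 0.5)                      # monotone, centred
    tri = e * (0.5 - np.abs(u - 0.5)) * 2 - e / 2  # transient mid peak, centred
    const = np.full(n_stages, e / 2)
    shapes = [
        np.concatenate([ramp, ramp]),          # rising in both species
        np.concatenate([-ramp, -ramp]),        # falling in both
        np.concatenate([tri, tri]),            # transient peak in both
        np.concatenate([const, -const]),       # constitutively higher in A
        np.concatenate([-const, const]),       # constitutively higher in B
        np.concatenate([ramp, -ramp]),         # opposite temporal trends
        np.concatenate([-ramp, ramp]),
    ]
    full = np.vstack(shapes)
    if n_clusters > full.shape[0]:
        raise InvalidConfigError(
            f"only {full.shape[0]} built-in archetypes; supply cluster_archetypes"
        )
    return full[:n_clusters]


@dataclass
class CountsSimConfig:
    """NB count matrix with planted expression clusters.

    nb_dispersion is the negative-binomial size (shape) parameter r,
    var = mu + mu^2 / r; larger r approaches Poisson.  Library-size
    factors are drawn log-uniform in [0.5, 2] so median-of-ratios
    normalisation is non-trivially testable.
    """

    n_genes: int = 2100
    n_clusters: int = 7
    n_stages: int = 10
    n_species: int = 2
    n_replicates: int = 3
    nb_dispersion: float = 20.0
    cluster_archetypes: np.ndarray | None = None
    effect_size_log2: float = 2.0
    base_log2_expression: float = 6.0
    gene_level_sd: float = 1.5
    replicate_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        if self.n_species != 2:
            raise InvalidConfigError("design is fixed at 2 species")
        if min(self.n_genes, self.n_clusters, self.n_stages, self.n_replicates) < 1:
            raise InvalidConfigError("counts design dimensions must be positive")
        if self.cluster_archetypes is not None:
            arch = np.asarray(self.cluster_archetypes, dtype=float)
            if arch.shape != (self.n_clusters, self.n_species * self.n_stages):
                raise InvalidConfigError(
                    "cluster_archetypes must be n_clusters x (n_species * n_stages)"
                )
            self.cluster_archetypes = arch


@dataclass
class CountsSimResult:
    counts: np.ndarray           # genes x samples, int64
    gene_ids: list[str]
    sample_ids: list[str]
    meta: "pd.DataFrame"         # sample_id, species, stage, replicate
    labels: np.ndarray           # true cluster per gene, 1-based
    size_factors: np.ndarray     # true per-sample library factors


def simulate_counts(cfg: CountsSimConfig) -> CountsSimResult:
    """Draw an NB count matrix over (species x stage x replicate).

    Gene g of cluster c has mean 2**(base + offset_g + archetype_c) in
    condition (species, stage), multiplied by lognormal replicate noise
    and a per-sample library-size factor; counts are NB with size
    ``nb_dispersion``.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    arch = (
        cfg.cluster_archetypes
        if cfg.cluster_archetypes is not None
        else default_archetypes(cfg.n_clusters, cfg.n_stages, cfg.effect_size_log2)
    )

    labels = rng.integers(0, cfg.n_clusters, size=cfg.n_genes)
    offsets = rng.normal(0.0, cfg.gene_level_sd, size=cfg.n_genes)

    sample_ids, species, stages, reps = [], [], [], []
    cond_cols = []
    for si, sp in enumerate(("A", "B")):
        for st in range(cfg.n_stages):
            for r in range(cfg.n_replicates):
                sample_ids.append(f"{sp}_s{st}_r{r}")
                species.append(sp)
                stages.append(st)
                reps.append(r)
                cond_cols.append(si * cfg.n_stages + st)
    n_samples = len(sample_ids)
    cond_cols = np.asarray(cond_cols)

    factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))

    log2_mean = (
        cfg.base_log2_expression + offsets[:, None] + arch[labels][:, cond_cols]
    )
    mu = np.exp2(log2_mean)
    mu = mu * np.exp(rng.normal(0.0, cfg.replicate_noise_sd, size=mu.shape))
    mu = mu * factors[None, :]

    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": species,
            "stage": stages,
            "replicate": reps,
        }
    )
    gene_ids = [f"g{str(i).zfill(5)}" for i in range(cfg.n_genes)]
    return CountsSimResult(
        counts=counts,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        meta=meta,
        labels=labels + 1,
        size_factors=factors,
    )


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSimConfig:
    n_genes: int = 100
    chrom_length: int = 1_000_000
    min_gene_length: int = 2_000
    max_gene_length: int = 20_000
    strand_probability: float = 0.5  # probability of '+'
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.min_gene_length > self.max_gene_length:
            raise InvalidConfigError("min_gene_length > max_gene_length")
        if self.max_gene_length > self.chrom_length:
            raise InvalidConfigError("max_gene_length exceeds chromosome")
        if not (0.0 <= self.strand_probability <= 1.0):
            raise InvalidConfigError("strand_probability must be in [0, 1]")
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be positive")


def simulate_annotation(cfg: AnnotationSimConfig) -> "list":
    """Random gene map; genes may overlap, every gene fits inside
    [1, chrom_length], strand is Bernoulli(strand_probability) '+'."""
    from .islands import GeneAnnotation

    rng = np.random.default_rng(cfg.seed)
    genes = []
    lengths = rng.integers(cfg.min_gene_length, cfg.max_gene_length + 1, cfg.n_genes)
    for i in range(cfg.n_genes):
        length = int(lengths[i])
        start = int(rng.integers(1, cfg.chrom_length - length + 2))
        strand = "+" if rng.random() < cfg.strand_probability else "-"
        genes.append(
            GeneAnnotation(
                # id scheme matches simulate_counts so a shared n_genes
                # yields a coherent dataset (expressed genes have loci)
                gene_id=f"g{str(i).zfill(5)}",
                chrom=cfg.chrom,
                start=start,
                end=start + length - 1,
                strand=strand,
            )
        )
    return genes
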