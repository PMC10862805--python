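"""Cross-population extended haplotype homozygosity (xpEHH) scan.

The scan compares the decay of haplotype homozygosity around each SNP
between two populations of phased haplotypes.  For a focal SNP the
site-specific extended haplotype homozygosity (EHHS) at a site x is the
probability that two haplotypes drawn at random are identical over the
closed interval [focal, x], normalised to 1 at the focal SNP itself.
Integrating EHHS against physical distance on both sides of the focal
SNP gives iES; the per-site statistic is

    xpEHH = ln(iES_A / iES_B)

which, after genome-wide standardisation, is approximately standard
normal under neutrality.  Large positive values indicate unusually long
haplotypes (a candidate sweep) in population A, large negative values in
population B.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

try:  # optional acceleration of the EHHS walk; numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeMatrix",
    "EhhsProfile",
    "XpEhhRecord",
    "ScanConfig",
    "InvalidInputError",
    "DegenerateDistributionError",
    "site_frequencies",
    "joint_maf_filter",
    "ehhs_profile",
    "integrate_ies",
    "standardize_and_logp",
    "xpehh_scan",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateDistributionError(ValueError):
    """Raised when standardisation is impossible (zero variance)."""


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 allele matrix for one population on one chromosome.

    Rows are haplotypes, columns are sites.  ``positions`` are 1-based
    base-pair coordinates, strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    population_label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 2:
            raise InvalidInputError("alleles must be a 2-D (haplotype x site) matrix")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise InvalidInputError(
                f"{self.alleles.shape[1]} allele columns but "
                f"{self.positions.shape[0]} positions"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise InvalidInputError("positions must be strictly increasing")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise InvalidInputError("alleles must be 0/1")
        if self.n_hap < 4:
            raise InvalidInputError("need at least 4 haplotypes (pairs must exist)")
        self.alleles = self.alleles.astype(np.uint8, copy=False)

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass
class EhhsProfile:
    """EHHS values outward from a focal site, one vector per side.

    Each side starts at the focal site itself (value exactly 1).  A side
    is censored when the scan reached the chromosome edge, or a gap
    larger than ``max_gap_bp``, before EHHS fell below the truncation
    threshold.
    """

    focal_index: int
    left_values: np.ndarray
    left_positions: np.ndarray
    right_values: np.ndarray
    right_positions: np.ndarray
    censored_left: bool
    censored_right: bool

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right


@dataclass
class XpEhhRecord:
    """Per-SNP xpEHH result (population A in the numerator)."""

    chrom: str
    pos: int
    maf_A: float
    maf_B: float
    iES_A: float
    iES_B: float
    xpehh_raw: float
    z: float = float("nan")
    logp: float = float("nan")
    censored: bool = False


@dataclass
class ScanConfig:
    """Tunable parameters of the scan.

    maf_threshold
        Sites with pooled minor allele frequency <= this value are
        excluded (strict ``>`` retention).
    ehhs_truncation
        EHHS integration stops at the first site where EHHS drops below
        this value; that site still contributes its trapezoid.
    max_gap_bp
        An inter-site gap larger than this censors the side.
    drop_censored
        Drop sites whose EHHS never crossed the truncation threshold
        before an edge or oversized gap; censored iES is biased downward.
    """

    maf_threshold: float = 0.05
    ehhs_truncation: float = 0.05
    max_gap_bp: int = 200_000
    drop_censored: bool = True
    seed: int | None = None  # reserved; the scan itself is deterministic

    def __post_init__(self) -> None:
        if not (0 < self.ehhs_truncation < 1):
            raise InvalidInputError("ehhs_truncation must lie in (0, 1)")
        if not (0 <= self.maf_threshold < 0.5):
            raise InvalidInputError("maf_threshold must lie in [0, 0.5)")
        if self.max_gap_bp <= 0:
            raise InvalidInputError("max_gap_bp must be positive")


def site_frequencies(H: HaplotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency and minor allele frequency."""
    if H.n_sites == 0:
        raise InvalidInputError("empty haplotype matrix")
    freq = H.alleles.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    return freq, maf


def joint_maf_filter(
    A: HaplotypeMatrix, B: HaplotypeMatrix, cfg: ScanConfig | None = None
) -> np.ndarray:
    """Indices of sites whose *pooled* MAF exceeds the threshold.

    Both panels must be aligned on identical position vectors; the MAF
    is computed on the union of the two samples so that a site fixed
    differently in the two populations is retained.
    """
    cfg = cfg or ScanConfig()
    if A.n_sites != B.n_sites or not np.array_equal(A.positions, B.positions):
        raise InvalidInputError("panels must share identical position vectors")
    pooled = np.vstack([A.alleles, B.alleles])
    freq = pooled.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    return np.flatnonzero(maf > cfg.maf_threshold)


def _walk_python(
    alleles: np.ndarray,
    positions: np.ndarray,
    focal_index: int,
    step: int,
    max_gap: int,
    trunc: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    n, n_sites = alleles.shape
    pairs_total = n * (n - 1) / 2.0

    labels = alleles[:, focal_index].astype(np.intp)
    counts = np.bincount(labels)
    h0 = float((counts * (counts - 1) // 2).sum()) / pairs_total
    # with binary alleles and n >= 4 some group always has >= 2 members
    n_groups = 2
    values = [1.0]
    poss = [int(positions[focal_index])]
    censored = False

    idx = focal_index
    while True:
        nxt = idx + step
        if nxt < 0 or nxt >= n_sites:
            censored = True
            break
        if abs(int(positions[nxt]) - int(positions[idx])) > max_gap:
            censored = True
            break
        # refine haplotype groups by the next site's allele; group labels
        # stay compact (bounded by n) so bincount-based relabelling is O(n)
        key = labels * 2 + alleles[:, nxt]
        counts = np.bincount(key, minlength=2 * n_groups)
        h = float((counts * (counts - 1) // 2).sum()) / pairs_total
        ehhs = h / h0
        values.append(ehhs)
        poss.append(int(positions[nxt]))
        idx = nxt
        if ehhs < trunc:
            break
        occupied = counts > 0
        remap = np.cumsum(occupied) - 1
        labels = remap[key]
        n_groups = int(occupied.sum())

    return (
        np.asarray(values, dtype=float),
        np.asarray(poss, dtype=np.int64),
        censored,
    )


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _walk_numba(alleles, positions, focal_index, step, max_gap, trunc):  # pragma: no cover
        n, n_sites = alleles.shape
        pairs_total = n * (n - 1) / 2.0
        labels = np.empty(n, np.int64)
        c0 = 0
        c1 = 0
        for i in range(n):
            labels[i] = alleles[i, focal_index]
            if labels[i] == 0:
                c0 += 1
            else:
                c1 += 1
        h0 = (c0 * (c0 - 1) // 2 + c1 * (c1 - 1) // 2) / pairs_total
        n_groups = 2

        values = np.empty(n_sites + 1, np.float64)
        poss = np.empty(n_sites + 1, np.int64)
        values[0] = 1.0
        poss[0] = positions[focal_index]
        m = 1
        censored = False
        cnt = np.zeros(2 * n + 2, np.int64)
        remap = np.empty(2 * n + 2, np.int64)

        idx = focal_index
        while True:
            nxt = idx + step
            if nxt < 0 or nxt >= n_sites:
                censored = True
                break
            gap = positions[nxt] - positions[idx]
            if gap < 0:
                gap = -gap
            if gap > max_gap:
                censored = True
                break
            width = 2 * n_groups
            for j in range(width):
                cnt[j] = 0
            for i in range(n):
                cnt[labels[i] * 2 + alleles[i, nxt]] += 1
            hsum = 0
            for j in range(width):
                c = cnt[j]
                hsum += c * (c - 1) // 2
            ehhs = (hsum / pairs_total) / h0
            values[m] = ehhs
            poss[m] = positions[nxt]
            m += 1
            idx = nxt
            if ehhs < trunc:
                break
            g = 0
            for j in range(width):
                if cnt[j] > 0:
                    remap[j] = g
                    g += 1
            for i in range(n):
                labels[i] = remap[labels[i] * 2 + alleles[i, nxt]]
            n_groups = g
        return values[:m], poss[:m], censored


def _ehhs_side(
    H: HaplotypeMatrix, focal_index: int, step: int, cfg: ScanConfig
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Walk outward from the focal site computing EHHS until the value
    drops below the truncation threshold (not censored) or the walk hits
    the chromosome edge / an oversized gap (censored)."""
    if _HAVE_NUMBA:
        values, poss, censored = _walk_numba(
            H.alleles,
            H.positions,
            focal_index,
            step,
            int(cfg.max_gap_bp),
            float(cfg.ehhs_truncation),
        )
        return values.copy(), poss.copy(), bool(censored)
    return _walk_python(
        H.alleles,
        H.positions,
        focal_index,
        step,
        int(cfg.max_gap_bp),
        float(cfg.ehhs_truncation),
    )


def ehhs_profile(
    H: HaplotypeMatrix, focal_index: int, cfg: ScanConfig | None = None
) -> EhhsProfile:
    """EHHS decay profile around one focal site.

    EHHS at site x groups the haplotypes by their full allele string
    over [focal, x]; the unnormalised homozygosity is the fraction of
    haplotype pairs falling in the same group, and EHHS is that fraction
    divided by its value at the focal site alone.  Values are therefore
    1 at the focal site and non-increasing outward on each side.
    """
    cfg = cfg or ScanConfig()
    if not (0 <= focal_index < H.n_sites):
        raise InvalidInputError(f"focal_index {focal_index} out of range")
    lv, lp, lc = _ehhs_side(H, focal_index, -1, cfg)
    rv, rp, rc = _ehhs_side(H, focal_index, +1, cfg)
    return EhhsProfile(
        focal_index=focal_index,
        left_values=lv,
        left_positions=lp,
        right_values=rv,
        right_positions=rp,
        censored_left=lc,
        censored_right=rc,
    )


def _side_area(values: np.ndarray, positions: np.ndarray, truncation: float) -> float:
    """Trapezoidal area of one side, stopping at the first sub-threshold
    value (which still contributes its trapezoid)."""
    area = 0.0
    for i in range(1, len(values)):
        width = abs(int(positions[i]) - int(positions[i - 1]))
        area += 0.5 * (values[i] + values[i - 1]) * width
        if values[i] < truncation:
            break
    return area


def integrate_ies(p: EhhsProfile, cfg: ScanConfig | None = None) -> tuple[float, bool]:
    """Integrate EHHS against bp position on both sides -> iES (bp).

    Returns ``(iES, censored)``; the censored flag is inherited from any
    profile side that never crossed the truncation threshold.
    """
    cfg = cfg or ScanConfig()
    left = _side_area(p.left_values, p.left_positions, cfg.ehhs_truncation)
    right = _side_area(p.right_values, p.right_positions, cfg.ehhs_truncation)
    return left + right, p.censored


def standardize_and_logp(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genome-wide standardisation of raw xpEHH and two-sided normal p.

    z uses the unconditional mean and sd (ddof=1) across all supplied
    sites; logp = -log10(2 * (1 - Phi(|z|))), computed through the
    normal log-survival function so that extreme z never underflows.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise InvalidInputError("raw xpEHH values must be finite")
    if np.unique(raw).size < 2:
        raise DegenerateDistributionError(
            "need at least 2 distinct raw values to standardise"
        )
    sd = raw.std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError("zero variance in raw xpEHH")
    z = (raw - raw.mean()) / sd
    logp = -(np.log(2.0) + norm.logsf(np.abs(z))) / np.log(10.0)
    # z == 0 gives p exactly 1; guard the sign of a -0.0 rounding
    logp = np.maximum(logp, 0.0)
    return z, logp


def xpehh_scan(
    A: HaplotypeMatrix, B: HaplotypeMatrix, cfg: ScanConfig | None = None
) -> list[XpEhhRecord]:
    """Full per-site xpEHH scan of two aligned phased panels.

    Sites are retained when the pooled MAF exceeds the threshold; sites
    with iES = 0 in either population are dropped, as are censored sites
    when ``drop_censored`` is set.  The remaining uncensored sites
    define the standardisation; records come back sorted by position.
    """
    cfg = cfg or ScanConfig()
    if A.chrom != B.chrom:
        raise InvalidInputError("panels are from different chromosomes")
    keep = joint_maf_filter(A, B, cfg)

    _, maf_a = site_frequencies(A) if A.n_sites else (None, None)
    _, maf_b = site_frequencies(B)

    records: list[XpEhhRecord] = []
    for i in keep:
        ies_a, cens_a = integrate_ies(ehhs_profile(A, int(i), cfg), cfg)
        ies_b, cens_b = integrate_ies(ehhs_profile(B, int(i), cfg), cfg)
        censored = cens_a or cens_b
        if ies_a == 0.0 or ies_b == 0.0:
            continue
        if censored and cfg.drop_censored:
            continue
        records.append(
            XpEhhRecord(
                chrom=A.chrom,
                pos=int(A.positions[i]),
                maf_A=float(maf_a[i]),
                maf_B=float(maf_b[i]),
                iES_A=ies_a,
                iES_B=ies_b,
                xpehh_raw=float(np.log(ies_a / ies_b)),
                censored=censored,
            )
        )

    if not records:
        warnings.warn("no sites survived filtering; empty scan result")
        return records

    uncensored = [r for r in records if not r.censored]
    basis = uncensored if uncensored else records
    raw_basis = np.array([r.xpehh_raw for r in basis])
    mean = raw_basis.mean()
    sd = raw_basis.std(ddof=1)
    if np.unique(raw_basis).size < 2 or sd == 0:
        raise DegenerateDistributionError("zero variance in raw xpEHH across sites")
    raw_all = np.array([r.xpehh_raw for r in records])
    z = (raw_all - mean) / sd
    logp = np.maximum(-(np.log(2.0) + norm.logsf(np.abs(z))) / np.log(10.0), 0.0)
    for r, zi, lp in zip(records, z, logp):
        r.z = float(zi)
        r.logp = float(lp)
    records.sort(key=lambda r: (r.chrom, r.pos))
    logger.info(
        "xpEHH scan: %d sites retained (%d censored kept)",
        len(records),
        sum(r.censored for r in records),
    )
    return records
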