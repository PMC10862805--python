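import numpy as np
import pytest

from crestscan import HaplotypeMatrix, ScanConfig
from crestscan.scan import ehhs_profile


def make_panel(alleles, positions=None, chrom="chr1", label="pop"):
    alleles = np.asarray(alleles, dtype=np.uint8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1) * 100
    return HaplotypeMatrix(chrom, np.asarray(positions, dtype=np.int64), alleles, label)


def random_panel(rng, n_hap=20, n_sites=50, max_span=100_000):
    """Random panel with strictly increasing positions and a mix of
    common and rare alleles."""
    positions = np.sort(rng.choice(max_span, size=n_sites, replace=False)) + 1
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    alleles = (rng.random((n_hap, n_sites)) < freqs[None, :]).astype(np.uint8)
    return make_panel(alleles, positions)


def ehhs_pairwise_oracle(H, focal):
    """Independent EHHS oracle: track the boolean haplotype-pair
    identity matrix outward and count surviving pairs directly.

    Returns (left_values, right_values), full span to both edges.
    """
    A = H.alleles
    n = H.n_hap
    n_pairs = n * (n - 1) / 2.0
    eq0 = A[:, focal][:, None] == A[:, focal][None, :]
    h0 = (eq0.sum() - n) / 2.0 / n_pairs

    def walk(indices):
        E = eq0.copy()
        values = [1.0]
        for j in indices:
            E &= A[:, j][:, None] == A[:, j][None, :]
            h = (E.sum() - n) / 2.0 / n_pairs
            values.append(h / h0)
        return np.array(values)

    left = walk(range(focal - 1, -1, -1))
    right = walk(range(focal + 1, A.shape[1]))
    return left, right


def full_profile(H, focal):
    """EHHS profile walked to both chromosome edges (no truncation or
    gap censoring in practice)."""
    cfg = ScanConfig(ehhs_truncation=1e-300, max_gap_bp=10**12)
    return ehhs_profile(H, focal, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
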