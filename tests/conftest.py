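import numpy as np
import pandas as pd
import pytest

from aohscan.observations import ObservationSet
from aohscan.panel import HaplotypePanel, PanelSNP


def make_panel(hap_rows, positions=None, chrom="chr1"):
    """Panel from a list of allele-code tuples (one per haplotype)."""
    haps = np.asarray(hap_rows, dtype=np.uint8)
    n_snps = haps.shape[1]
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_snps)]
    snps = [
        PanelSNP(chrom, int(p), "A", "G", index=i) for i, p in enumerate(positions)
    ]
    return HaplotypePanel(snps, haps)


def make_obs(rows, depth=1.0):
    """ObservationSet from (read_id, snp_index, allele[, baseq]) tuples."""
    table = pd.DataFrame(
        [(r[0], r[1], r[2], r[3] if len(r) > 3 else 30) for r in rows],
        columns=["read_id", "snp_index", "allele", "base_quality"],
    )
    table["snp_index"] = table["snp_index"].astype(np.int64)
    table["allele"] = table["allele"].astype(np.int8)
    table["base_quality"] = table["base_quality"].astype(np.int16)
    return ObservationSet(table, depth_estimate=depth)


@pytest.fixture
def small_panel():
    return make_panel([(0, 0), (0, 0), (1, 1), (1, 0)])


def oracle_likelihoods(haplotypes, weights, reads, epsilon):
    """Independent brute-force (L_hap, L_dip): nested sums over haplotypes.

    ``reads`` is a list of (snp_indices, alleles) pairs in panel index space.
    """
    haplotypes = np.asarray(haplotypes)
    weights = np.asarray(weights, dtype=float)

    def emis(read, hap_row):
        idx, alleles = read
        p = 1.0
        for i, a in zip(idx, alleles):
            p *= (1.0 - epsilon) if hap_row[i] == a else epsilon
        return p

    H = haplotypes.shape[0]
    l_hap = sum(
        weights[h] * np.prod([emis(r, haplotypes[h]) for r in reads])
        for h in range(H)
    )
    l_dip = 0.0
    for h1 in range(H):
        for h2 in range(H):
            prod = 1.0
            for r in reads:
                prod *= 0.5 * emis(r, haplotypes[h1]) + 0.5 * emis(r, haplotypes[h2])
            l_dip += weights[h1] * weights[h2] * prod
    return float(l_hap), float(l_dip)


@pytest.fixture(scope="session")
def full_benchmark():
    """The reference synthetic benchmark, shared by the acceptance tests.

    One 100 Mb chromosome, 60-haplotype panel, 8+8 individuals with one
    10-20 Mb implanted AOH each at 0.1x, plus the 0.05x/0.5x depth sweep and
    the HMM baseline.  Heavy (about ten minutes), hence session-scoped.
    """
    from aohscan.benchmark import run_full_benchmark

    return run_full_benchmark(seed=1)
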