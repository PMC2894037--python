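"""Synthetic paired tumor-normal allele-signal generator with full ground truth.

The generator reproduces, mechanistically, the structure that makes paired
BAF normalization both necessary and possible:

* genotypes drawn under Hardy-Weinberg equilibrium from per-SNP minor allele
  frequencies;
* a per-SNP, per-allele multiplicative affinity ``(phi_A, phi_B)`` (log-normal,
  sd ``affinity_sd`` on the log scale) *shared between the tumor and normal
  hybridizations* — this is the reproducible SNP effect, and produces the
  diagonal correlation of paired BAFs within each genotype;
* segmental parental copy-number states ``(c1, c2)`` in the tumor cells, with
  the B allele assigned to either parental copy with probability 1/2 at
  heterozygous SNPs;
* mixing of tumor and normal cells with purity ``kappa``, shrinking aberrant
  BAF bands toward 1/2;
* an additive intensity offset (incomplete offset correction, compressing
  ``|beta - 1/2|``) and additive Gaussian intensity noise, truncated at zero.

Intensities are ``theta = phi * (c / 2) * scale + offset + noise`` per allele,
so with no affinity spread, offset or noise the observed TCN equals the true
mixture TCN exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contamination import PcnState
from .evaluation import ChangePointSpec
from .signals import PairedSnpTable

__all__ = ["PcnSegment", "SimConfig", "SimTruth", "simulate_pair", "table1_scenario"]

MB = 1_000_000


@dataclass(frozen=True)
class PcnSegment:
    """A genomic interval with one true tumor parental copy-number state."""

    chromosome: str
    start: int  # bp, closed
    end: int    # bp, closed
    state: PcnState


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions used throughout.

    ``affinity_sd`` is the SD of log allele affinities (the SNP-effect
    magnitude); ``noise_sd`` the SD of additive intensity noise, in units of
    ``scale`` (one unit = the expected diploid total signal); ``offset`` an
    additive intensity offset left over from preprocessing.
    """

    n_snps: int = 10_000
    segments: tuple = ()
    kappa: float = 1.0
    maf_range: tuple = (0.2, 0.5)
    affinity_sd: float = 0.3
    offset: float = 0.0
    noise_sd: float = 0.03
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.segments:
            self.segments = (PcnSegment("1", 1, 100 * MB, PcnState(1, 1)),)
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if min(self.affinity_sd, self.noise_sd, self.scale) < 0 or self.offset < 0:
            raise ValueError("scale parameters must be nonnegative")
        by_chrom: dict = {}
        for seg in self.segments:
            if seg.start >= seg.end:
                raise ValueError(f"empty segment {seg}")
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs[:-1], segs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping segments on chromosome {chrom}")


@dataclass
class SimTruth:
    """Ground truth aligned with the emitted paired table."""

    genotype: np.ndarray      # true normal BAF mu in {0, 0.5, 1}
    b_on_major: np.ndarray    # het SNPs: True if allele B sits on the major copy
    segment_id: np.ndarray    # index into the config's segment tuple
    kappa: float
    phi_a: np.ndarray
    phi_b: np.ndarray


def _segment_snp_counts(config: SimConfig) -> np.ndarray:
    lengths = np.array([seg.end - seg.start + 1 for seg in config.segments], dtype=float)
    raw = config.n_snps * lengths / lengths.sum()
    counts = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts
    for i in np.argsort(raw - counts)[::-1][: config.n_snps - counts.sum()]:
        counts[i] += 1
    return counts


def simulate_pair(config: SimConfig, rng=None):
    """Draw one paired tumor-normal table plus its ground truth.

    Returns ``(PairedSnpTable, SimTruth)``.  Position collisions within a
    segment are dropped, so the realized SNP count can be marginally below
    ``config.n_snps``.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    counts = _segment_snp_counts(config)

    chroms, positions, seg_ids = [], [], []
    for i, (seg, n) in enumerate(zip(config.segments, counts)):
        pos = np.unique(rng.integers(seg.start, seg.end + 1, size=n))
        positions.append(pos)
        chroms.append(np.full(pos.size, seg.chromosome, dtype=object))
        seg_ids.append(np.full(pos.size, i))
    chromosome = np.concatenate(chroms)
    position = np.concatenate(positions)
    segment_id = np.concatenate(seg_ids)
    j = position.size

    maf = rng.uniform(*config.maf_range, size=j)
    mu = rng.binomial(2, maf) / 2.0
    het = mu == 0.5
    b_on_major = rng.random(j) < 0.5

    c1 = np.array([config.segments[s].state.c1 for s in segment_id], dtype=float)
    c2 = np.array([config.segments[s].state.c2 for s in segment_id], dtype=float)
    total = c1 + c2

    # tumor-cell allele copy numbers
    ct_b = np.where(het, np.where(b_on_major, c2, c1), np.where(mu == 1.0, total, 0.0))
    ct_a = total - ct_b
    # normal-cell allele copy numbers (germline genotype)
    cn_b = 2.0 * mu
    cn_a = 2.0 - cn_b
    # cell-mixture copy numbers seen in the "tumor sample"
    k = config.kappa
    cm_a = k * ct_a + (1.0 - k) * cn_a
    cm_b = k * ct_b + (1.0 - k) * cn_b

    phi_a = rng.lognormal(0.0, config.affinity_sd, size=j)
    phi_b = rng.lognormal(0.0, config.affinity_sd, size=j)

    def _intensity(phi, copies):
        raw = phi * (copies / 2.0) * config.scale + config.offset
        raw = raw + rng.normal(0.0, config.noise_sd, size=j) * config.scale
        return np.maximum(raw, 0.0)

    theta_na = _intensity(phi_a, cn_a)
    theta_nb = _intensity(phi_b, cn_b)
    theta_ta = _intensity(phi_a, cm_a)
    theta_tb = _intensity(phi_b, cm_b)

    table = PairedSnpTable.from_intensities(
        chromosome, position, theta_na, theta_nb, theta_ta, theta_tb
    )
    truth = SimTruth(mu, b_on_major, segment_id, k, phi_a, phi_b)
    return table, truth


# Scaled-down canonical layout: two synthetic chromosomes covering the five
# standard change points between diploid, gain, hemizygous-deletion and
# copy-neutral-LOH states, each flank one 10 Mb block.
_BLOCK = 10 * MB
_MARGIN = 1 * MB


def table1_scenario(
    kappa: float = 0.7,
    snps_per_region: int = 500,
    seed: int = 0,
    affinity_sd: float = 0.3,
    noise_sd: float = 0.03,
    offset: float = 0.0,
):
    """Simulate the canonical change-point layout with ``snps_per_region``
    heterozygous SNPs per flanking region (in expectation, after the safety
    margin).

    Chromosome "2" carries normal -> gain -> copy-neutral LOH; chromosome
    "10" carries normal -> deletion -> copy-neutral LOH; a no-change (N/N)
    control sits inside the diploid stretch of chromosome "2".  Returns
    ``(PairedSnpTable, SimTruth, [ChangePointSpec, ...])`` with specs for
    N/G, G/L, N/D, D/L and N/N.
    """
    # expected usable het fraction per block: ~0.44 het under HWE with
    # MAF ~ U(0.2, 0.5), times ~0.8 surviving the safety margin on both sides
    snps_per_block = int(np.ceil(snps_per_region / 0.35))
    segments = (
        PcnSegment("2", 1, 3 * _BLOCK, PcnState(1, 1)),
        PcnSegment("2", 3 * _BLOCK + 1, 4 * _BLOCK, PcnState(1, 2)),
        PcnSegment("2", 4 * _BLOCK + 1, 5 * _BLOCK, PcnState(0, 2)),
        PcnSegment("10", 1, 1 * _BLOCK, PcnState(1, 1)),
        PcnSegment("10", 1 * _BLOCK + 1, 2 * _BLOCK, PcnState(0, 1)),
        PcnSegment("10", 2 * _BLOCK + 1, 3 * _BLOCK, PcnState(0, 2)),
    )
    n_blocks = 8  # genomic blocks across both chromosomes
    config = SimConfig(
        n_snps=snps_per_block * n_blocks,
        segments=segments,
        kappa=kappa,
        affinity_sd=affinity_sd,
        noise_sd=noise_sd,
        offset=offset,
        seed=seed,
    )
    table, truth = simulate_pair(config)

    def spec(label, chrom, start, end, cp, s1, s2):
        return ChangePointSpec(label, chrom, start, end, cp, _MARGIN, PcnState(*s1), PcnState(*s2))

    specs = [
        spec("N/N", "2", 1, 2 * _BLOCK, 1 * _BLOCK, (1, 1), (1, 1)),
        spec("N/G", "2", 2 * _BLOCK, 4 * _BLOCK, 3 * _BLOCK, (1, 1), (1, 2)),
        spec("G/L", "2", 3 * _BLOCK, 5 * _BLOCK, 4 * _BLOCK, (1, 2), (0, 2)),
        spec("N/D", "10", 1, 2 * _BLOCK, 1 * _BLOCK, (1, 1), (0, 1)),
        spec("D/L", "10", 1 * _BLOCK, 3 * _BLOCK, 2 * _BLOCK, (0, 1), (0, 2)),
    ]
    return table, truth, specs
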