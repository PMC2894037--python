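"""Naive single-sample genotyping of the matched normal from its BAFs.

In a normal (germline) sample the allele B fractions fall into three bands —
near 0 (AA), near 1/2 (AB) and near 1 (BB) — so genotypes can be called with
no population reference by thresholding ``beta_N`` at the two local minima of
a Gaussian-kernel density estimate of its empirical distribution.  For
non-diploid sex chromosomes the number of classes drops to two and a single
threshold is used.

Every SNP is called with the same thresholds.  The per-SNP confidence score is
the distance from ``beta_N`` to the nearest threshold: calls sitting on a
density valley are exactly the doubtful ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

__all__ = [
    "DensityEstimate",
    "GenotypeCallSet",
    "estimate_beta_density",
    "find_genotype_thresholds",
    "call_genotypes",
    "genotype_normal",
    "filter_by_confidence",
]

GRID_SIZE = 512


class InsufficientDataError(ValueError):
    pass


class ModeDetectionError(ValueError):
    """Raised when the density does not show as many modes as genotype classes."""


@dataclass
class DensityEstimate:
    grid: np.ndarray        # ordered evaluation points covering [0, 1]
    density: np.ndarray     # nonnegative, integrates to ~1 over [0, 1]
    bandwidth: float


@dataclass
class GenotypeCallSet:
    """Per-SNP genotype calls ``mu_hat`` with confidence scores.

    ``mu_hat`` takes values in {0, 0.5, 1} (diploid) or {0, 1} (hemizygous),
    NaN for missing.  ``thresholds`` are the valley positions used, strictly
    increasing inside (0, 1).
    """

    mu_hat: np.ndarray
    confidence: np.ndarray
    thresholds: tuple
    source: str = "naive"

    def __len__(self) -> int:
        return len(self.mu_hat)

    @property
    def het_mask(self) -> np.ndarray:
        return self.mu_hat == 0.5


def estimate_beta_density(beta_n, bandwidth=None, min_snps: int = 100) -> DensityEstimate:
    """Gaussian KDE of normal BAFs on a 512-point uniform grid over [0, 1].

    The kernel mass that would leak outside [0, 1] is reflected back at both
    boundaries, so the homozygous bands at 0 and 1 appear as proper modes and
    the density integrates to ~1 on the unit interval.

    Parameters
    ----------
    bandwidth
        Kernel width; Silverman's rule by default.
    min_snps
        Minimum number of defined BAFs required.
    """
    b = np.asarray(beta_n, dtype=float)
    b = b[~np.isnan(b)]
    if b.size < min_snps:
        raise InsufficientDataError(f"need >= {min_snps} defined BAFs, got {b.size}")
    b = np.clip(b, 0.0, 1.0)
    if np.ptp(b) == 0:
        # degenerate constant input: represent as a narrow bump at the value
        grid = np.linspace(0.0, 1.0, GRID_SIZE)
        bw = bandwidth if bandwidth is not None else 0.01
        dens = _stats.norm.pdf(grid, loc=b[0], scale=bw)
        dens += _stats.norm.pdf(-grid, loc=b[0], scale=bw)
        dens += _stats.norm.pdf(2.0 - grid, loc=b[0], scale=bw)
        return DensityEstimate(grid, dens, float(bw))
    kde = _stats.gaussian_kde(b, bw_method="silverman" if bandwidth is None else bandwidth / b.std(ddof=1))
    bw = float(kde.factor * b.std(ddof=1))
    grid = np.linspace(0.0, 1.0, GRID_SIZE)
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)  # boundary reflection
    return DensityEstimate(grid, dens, bw)


def find_genotype_thresholds(dens: DensityEstimate, n_classes: int = 3) -> tuple:
    """Locate the ``n_classes - 1`` density valleys separating genotype modes.

    Modes are local maxima of the gridded density (boundary maxima included);
    when more than ``n_classes`` are present the ones with greatest prominence
    are kept.  Each threshold is the density minimum between two consecutive
    kept modes.
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 (hemizygous) or 3 (diploid)")
    d = dens.density
    padded = np.concatenate([[0.0], d, [0.0]])  # lets boundary modes register as peaks
    peaks, _ = _sig.find_peaks(padded)
    if peaks.size < n_classes:
        raise ModeDetectionError(
            f"found {peaks.size} density modes, need {n_classes}"
        )
    if peaks.size > n_classes:
        prom = _sig.peak_prominences(padded, peaks)[0]
        keep = np.sort(np.argsort(prom)[-n_classes:])
        peaks = peaks[keep]
    peaks = peaks - 1  # back to unpadded indexing
    thresholds = []
    for left, right in zip(peaks[:-1], peaks[1:]):
        if right - left < 2:
            raise ModeDetectionError("adjacent modes with no valley between them")
        valley = left + 1 + int(np.argmin(d[left + 1 : right]))
        thresholds.append(float(dens.grid[valley]))
    return tuple(thresholds)


def call_genotypes(beta_n, thresholds, source: str = "naive") -> GenotypeCallSet:
    """Call genotypes by interval membership of ``beta_N`` among thresholds.

    Diploid (two thresholds ``tau1 < tau2``): AA below ``tau1``, AB on
    ``[tau1, tau2]`` (boundaries count as heterozygous), BB above ``tau2``.
    Hemizygous (one threshold): A below-or-equal, B above.  Missing BAFs give
    missing calls.  Confidence is the distance to the nearest threshold.
    """
    b = np.asarray(beta_n, dtype=float)
    taus = tuple(float(t) for t in thresholds)
    if not all(0.0 < t < 1.0 for t in taus) or list(taus) != sorted(set(taus)):
        raise ValueError("thresholds must be strictly increasing inside (0, 1)")
    mu = np.full(b.shape, np.nan)
    ok = ~np.isnan(b)
    if len(taus) == 2:
        t1, t2 = taus
        mu[ok & (b < t1)] = 0.0
        mu[ok & (b >= t1) & (b <= t2)] = 0.5
        mu[ok & (b > t2)] = 1.0
    elif len(taus) == 1:
        (t1,) = taus
        mu[ok & (b <= t1)] = 0.0
        mu[ok & (b > t1)] = 1.0
    else:
        raise ValueError("expected one or two thresholds")
    conf = np.full(b.shape, np.nan)
    conf[ok] = np.min(np.abs(b[ok, None] - np.asarray(taus)[None, :]), axis=1)
    return GenotypeCallSet(mu, conf, taus, source=source)


def genotype_normal(beta_n, n_classes: int = 3, bandwidth=None) -> GenotypeCallSet:
    """Convenience pipeline: density -> thresholds -> calls on one BAF vector."""
    dens = estimate_beta_density(beta_n, bandwidth=bandwidth)
    taus = find_genotype_thresholds(dens, n_classes=n_classes)
    return call_genotypes(beta_n, taus)


def filter_by_confidence(calls: GenotypeCallSet, drop_fraction: float) -> np.ndarray:
    """Boolean mask keeping the ``ceil((1 - drop_fraction) * n)`` most confident calls.

    Ties in confidence are broken by genomic order (earlier SNPs kept first).
    Calls with missing confidence sort as least confident.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    n = len(calls)
    n_keep = int(np.ceil((1.0 - drop_fraction) * n))
    conf = np.where(np.isnan(calls.confidence), -np.inf, calls.confidence)
    # stable sort descending on confidence: ties keep genomic (input) order
    order = np.argsort(-conf, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_keep]] = True
    return mask
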