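"""Core allele-signal representations and conversions.

Genotyping arrays report, for each SNP ``j`` of each hybridization, a pair of
summarized allele intensities ``(theta_A, theta_B)``.  An equivalent and more
interpretable representation is the total SNP signal ``theta = theta_A + theta_B``
together with the allele B fraction (BAF) ``beta = theta_B / theta``.  From a
paired tumor-normal design, the tumor total copy number (TCN) relative to the
matched normal, allele-specific copy numbers (ASCN), the mirrored BAF
``|beta - 1/2|`` and the decrease in heterozygosity (DH) ``2|beta - 1/2|`` all
derive from these two quantities.

Missing values (a BAF at zero total signal, a TCN at zero normal signal) are
represented as NaN, produced deliberately rather than by 0/0 division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairedSnpTable",
    "theta_beta_from_alleles",
    "alleles_from_theta_beta",
    "tumor_tcn",
    "ascn",
    "mirrored_baf",
    "dh",
]


class InvalidSignalError(ValueError):
    """Raised when allele intensities violate their domain (negative/non-finite)."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def theta_beta_from_alleles(theta_a, theta_b):
    """Convert allele intensities ``(theta_A, theta_B)`` to ``(theta, beta)``.

    Parameters
    ----------
    theta_a, theta_b
        Nonnegative summarized allele intensities (scalars or arrays).

    Returns
    -------
    theta : ndarray
        Total SNP signal ``theta_A + theta_B``.
    beta : ndarray
        Allele B fraction ``theta_B / theta``; NaN where ``theta == 0`` (the
        one point where the transform is not invertible).
    """
    ta, tb = _as_float_array(theta_a), _as_float_array(theta_b)
    if np.any(ta < 0) or np.any(tb < 0):
        raise InvalidSignalError("allele intensities must be nonnegative")
    if not (np.all(np.isfinite(ta[~np.isnan(ta)])) and np.all(np.isfinite(tb[~np.isnan(tb)]))):
        raise InvalidSignalError("allele intensities must be finite")
    theta = ta + tb
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(theta > 0, tb / np.where(theta > 0, theta, 1.0), np.nan)
    return theta, beta


def alleles_from_theta_beta(theta, beta):
    """Invert :func:`theta_beta_from_alleles`.

    Requires a defined ``beta`` (non-NaN) in [0, 1]; returns
    ``(theta * (1 - beta), theta * beta)``.
    """
    th, b = _as_float_array(theta), _as_float_array(beta)
    if np.any(np.isnan(b)):
        raise InvalidSignalError("beta is undefined (NaN); cannot recover allele intensities")
    if np.any((b < 0) | (b > 1)):
        raise InvalidSignalError("beta must lie in [0, 1]")
    return th * (1.0 - b), th * b


def tumor_tcn(theta_t, theta_n):
    """Tumor total copy number relative to the matched normal.

    ``C_T = 2 * theta_T / theta_N``, scaling the diploid reference to two.
    SNPs with ``theta_N == 0`` are returned as NaN (missing).
    """
    tt, tn = _as_float_array(theta_t), _as_float_array(theta_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tn > 0, 2.0 * tt / np.where(tn > 0, tn, 1.0), np.nan)


def ascn(tcn, beta):
    """Decompose a total copy number into allele-specific copy numbers.

    Returns ``(C_A, C_B) = (C * (1 - beta), C * beta)``, which sum back to
    ``C`` exactly.
    """
    c, b = _as_float_array(tcn), _as_float_array(beta)
    if np.any(np.isnan(b) & ~np.isnan(c)):
        raise InvalidSignalError("beta is undefined (NaN); ASCN requires a defined BAF")
    return c * (1.0 - b), c * b


def mirrored_baf(beta):
    """Mirrored allele B fraction ``|beta - 1/2|``, folding the BAF about 1/2."""
    return np.abs(_as_float_array(beta) - 0.5)


def dh(beta_t):
    """Decrease in heterozygosity ``2 * |beta_T - 1/2|``.

    Defined so that DH is ~0 under allelic balance and ~1 in a pure-tumor LOH
    region.  Meaningful for SNPs heterozygous in the matched normal; callers
    are expected to restrict to those downstream.
    """
    return 2.0 * mirrored_baf(beta_t)


@dataclass
class PairedSnpTable:
    """Per-SNP paired allele signals for one tumor-normal pair.

    All vectors share length ``J``; positions are 1-based and strictly
    increasing within each chromosome.
    """

    chromosome: np.ndarray
    position: np.ndarray
    theta_n: np.ndarray
    beta_n: np.ndarray
    theta_t: np.ndarray
    beta_t: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome).astype(str)
        self.position = np.asarray(self.position, dtype=np.int64)
        for name in ("theta_n", "beta_n", "theta_t", "beta_t"):
            setattr(self, name, _as_float_array(getattr(self, name)))
        n = len(self.chromosome)
        for name in ("position", "theta_n", "beta_n", "theta_t", "beta_t"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length {len(getattr(self, name))}, expected {n}")
        for chrom in pd.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom!r}")

    def __len__(self) -> int:
        return len(self.position)

    @classmethod
    def from_intensities(cls, chromosome, position, theta_an, theta_bn, theta_at, theta_bt) -> "PairedSnpTable":
        """Build from raw per-allele intensities of the normal and tumor."""
        theta_n, beta_n = theta_beta_from_alleles(theta_an, theta_bn)
        theta_t, beta_t = theta_beta_from_alleles(theta_at, theta_bt)
        return cls(chromosome, position, theta_n, beta_n, theta_t, beta_t)

    def tcn(self) -> np.ndarray:
        """Tumor TCN relative to the normal, per SNP."""
        return tumor_tcn(self.theta_t, self.theta_n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "position": self.position,
                "theta_n": self.theta_n,
                "beta_n": self.beta_n,
                "theta_t": self.theta_t,
                "beta_t": self.beta_t,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedSnpTable":
        return cls(
            df["chromosome"].to_numpy(),
            df["position"].to_numpy(),
            df["theta_n"].to_numpy(),
            df["beta_n"].to_numpy(),
            df["theta_t"].to_numpy(),
            df["beta_t"].to_numpy(),
        )
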