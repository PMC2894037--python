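"""Genotype-stratified normalization of tumor allele B fractions.

Even after preprocessing, the observed BAF of a SNP deviates from its true
value by a reproducible, SNP-specific amount delta (the "SNP effect") that is
shared between the two hybridizations of a tumor-normal pair.  Since the true
normal BAF is just the genotype ``mu in {0, 1/2, 1}``, the effect can be
estimated from the normal alone as ``delta_N = beta_N - mu_hat`` and removed
from the tumor, SNP by SNP, without knowing anything about the tumor's copy
number state:

* homozygous SNPs (``mu_hat in {0, 1}``): ``beta_T_norm = beta_T - beta_N + mu_hat``;
* heterozygous SNPs (``mu_hat = 1/2``): ``beta_T_norm = beta_T - eta * (beta_N - 1/2)``
  with the scale factor ``eta = beta_T / beta_N`` when ``beta_T <= beta_N`` and
  ``(1 - beta_T) / (1 - beta_N)`` otherwise, which prevents overcorrection in
  regions of allelic imbalance where the het cloud is compressed toward 1/2.

Total signals and hence total copy numbers are untouched by design.  The same
correction has a dual form on the intensity scale: signal is moved between the
two alleles of the tumor while their sum ``theta_T`` is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotyping import GenotypeCallSet
from .signals import PairedSnpTable, mirrored_baf

__all__ = [
    "NormalizedTumorTrack",
    "snp_effect_normal",
    "eta",
    "normalize_beta",
    "normalize_pair",
    "dual_intensity_form",
    "dh_normalized",
]

DEFAULT_CHUNK_SIZE = 1_000_000


class AlignmentError(ValueError):
    """Inputs do not describe the same set of SNPs in the same order."""


@dataclass
class NormalizedTumorTrack:
    """Per-SNP normalized tumor BAF with provenance of the correction applied.

    ``eta`` holds the het-path scale factor (1.0 on the homozygous path);
    ``normalized_flag`` is False where the SNP was passed through uncorrected
    (missing genotype, missing BAF, or a degenerate het denominator).
    """

    beta_t_norm: np.ndarray
    eta: np.ndarray
    normalized_flag: np.ndarray


def snp_effect_normal(beta_n, mu_hat):
    """Estimated SNP effect in the normal: ``beta_N - mu_hat`` (NaN if uncalled)."""
    return np.asarray(beta_n, dtype=float) - np.asarray(mu_hat, dtype=float)


def eta(beta_t, beta_n):
    """Heterozygous-path scale factor in [0, 1].

    ``beta_T / beta_N`` if ``beta_T <= beta_N``, else
    ``(1 - beta_T) / (1 - beta_N)``; both branches agree (= 1) at
    ``beta_T = beta_N``.  Undefined (NaN) when ``beta_N`` is exactly 0 or 1 —
    a genotype/data inconsistency on the het path.
    """
    bt, bn = np.asarray(beta_t, dtype=float), np.asarray(beta_n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lo = bt / bn
        hi = (1.0 - bt) / (1.0 - bn)
        e = np.where(bt <= bn, lo, hi)
    e = np.where((bn <= 0.0) | (bn >= 1.0), np.nan, e)
    return np.clip(e, 0.0, 1.0)  # floating-error guard only; NaN passes through


def normalize_beta(beta_t, beta_n, mu_hat, clamp_hom: bool = False):
    """Normalize tumor BAFs given normal BAFs and normal genotype calls.

    Returns ``(beta_t_norm, eta_used, normalized_flag)`` arrays.  Homozygous
    outputs are not truncated to [0, 1] unless ``clamp_hom`` is set (keeping
    the correction linear for downstream segmentation); heterozygous outputs
    lie in [0, 1] by construction.  SNPs with missing genotype or missing BAFs
    pass through unchanged with ``normalized_flag`` False.
    """
    bt = np.atleast_1d(np.asarray(beta_t, dtype=float))
    bn = np.atleast_1d(np.asarray(beta_n, dtype=float))
    mu = np.atleast_1d(np.asarray(mu_hat, dtype=float))
    if not (bt.shape == bn.shape == mu.shape):
        raise AlignmentError("beta_t, beta_n and mu_hat must share a shape")

    out = bt.copy()
    eta_used = np.ones_like(bt)
    flag = np.zeros(bt.shape, dtype=bool)

    defined = ~np.isnan(bt) & ~np.isnan(bn) & ~np.isnan(mu)
    hom = defined & ((mu == 0.0) | (mu == 1.0))
    het = defined & (mu == 0.5)

    out[hom] = bt[hom] - bn[hom] + mu[hom]
    flag[hom] = True
    if clamp_hom:
        out[hom] = np.clip(out[hom], 0.0, 1.0)

    e = eta(bt[het], bn[het])
    good = ~np.isnan(e)
    het_idx = np.flatnonzero(het)
    out[het_idx[good]] = bt[het_idx[good]] - e[good] * (bn[het_idx[good]] - 0.5)
    eta_used[het_idx[good]] = e[good]
    flag[het_idx[good]] = True
    # degenerate het denominators (beta_N in {0,1}) stay unnormalized, flag False

    return out, eta_used, flag


def normalize_pair(
    table: PairedSnpTable,
    calls: GenotypeCallSet,
    clamp_hom: bool = False,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> NormalizedTumorTrack:
    """Apply the normalization to every SNP of a paired table.

    The correction is per-SNP local, so the table is processed in chunks of at
    most ``chunk_size`` SNPs (bounded memory, O(J) time) and output order is
    preserved.  Total signals are not touched: the returned track carries only
    the corrected BAFs.
    """
    if len(calls) != len(table):
        raise AlignmentError(
            f"genotype calls ({len(calls)}) and table ({len(table)}) differ in length"
        )
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    n = len(table)
    out = np.empty(n)
    eta_used = np.empty(n)
    flag = np.empty(n, dtype=bool)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        out[sl], eta_used[sl], flag[sl] = normalize_beta(
            table.beta_t[sl], table.beta_n[sl], calls.mu_hat[sl], clamp_hom=clamp_hom
        )
    return NormalizedTumorTrack(out, eta_used, flag)


def dual_intensity_form(theta_t, beta_t_norm):
    """Normalized tumor allele intensities implied by the corrected BAF.

    ``(theta_T * (1 - beta_norm), theta_T * beta_norm)`` — the correction on
    the intensity scale moves signal between the tumor's two alleles while
    conserving their total exactly (the identifiability constraint of the
    paired design).
    """
    th = np.asarray(theta_t, dtype=float)
    b = np.asarray(beta_t_norm, dtype=float)
    theta_b = th * b
    # conservation is exact to one ulp (bitwise for beta >= 1/2, by Sterbenz)
    return th - theta_b, theta_b


def dh_normalized(beta_t_norm):
    """Decrease in heterozygosity of the normalized tumor BAF: ``2|beta - 1/2|``."""
    return 2.0 * mirrored_baf(beta_t_norm)
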