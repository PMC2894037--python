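"""Change-point detectability evaluation on per-SNP tracks.

A change point of known location, padded by a safety margin absorbing
localization error, separates two flanking regions of constant parental copy
number.  How well a per-SNP statistic (raw DH, normalized DH, or TCN,
restricted to SNPs heterozygous in the normal) distinguishes the two regions
is quantified two ways:

* a two-sample Student t statistic on equal-size samples drawn from each
  flank (J' SNPs per flank), bootstrapped B times to report mean +/- sd of
  |t| — the statistic most segmentation methods threshold on;
* ROC analysis of the pooled per-SNP (or bin-averaged, H SNPs per bin)
  values, with the "positive" state the one whose total copy number differs
  from two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _metrics

from .contamination import PcnState
from .genotyping import GenotypeCallSet

__all__ = [
    "ChangePointSpec",
    "EvalConfig",
    "RegionSignal",
    "RocCurve",
    "extract_flanking_signals",
    "balanced_sample",
    "t_statistic",
    "bootstrap_t",
    "bin_signal",
    "roc_curve",
    "evaluate_changepoint",
]


class InsufficientDataError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class ChangePointSpec:
    """One change point to evaluate: region, location, margin and flank states."""

    label: str
    chromosome: str
    region_start: int
    region_end: int
    changepoint: int
    safety_margin: int
    state1: PcnState
    state2: PcnState

    def __post_init__(self):
        if not self.region_start < self.changepoint < self.region_end:
            raise ValueError(f"{self.label}: change point must lie inside the region")
        if (
            self.changepoint - self.safety_margin <= self.region_start
            or self.changepoint + self.safety_margin >= self.region_end
        ):
            raise ValueError(f"{self.label}: safety region leaves an empty flank")


@dataclass(frozen=True)
class EvalConfig:
    """Sampling sizes of the evaluation: J' SNPs per flank, B bootstrap repeats,
    bin sizes H, and whether to restrict to normal-heterozygous SNPs."""

    n_sampled: int = 250
    n_boot: int = 100
    bin_sizes: tuple = (1, 2, 4)
    het_only: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_sampled < 2 or self.n_boot < 1 or any(h < 1 for h in self.bin_sizes):
            raise ValueError("need n_sampled >= 2, n_boot >= 1, all H >= 1")


@dataclass
class RegionSignal:
    """Position-sorted per-SNP statistic for one flanking region."""

    values: np.ndarray
    positions: np.ndarray
    state_label: int  # 1 or 2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RocCurve:
    fp_rate: np.ndarray
    tp_rate: np.ndarray
    auc: float
    orientation: int  # +1: larger values called positive; -1: flipped


def extract_flanking_signals(
    values,
    positions,
    calls: GenotypeCallSet,
    spec: ChangePointSpec,
    chromosome=None,
    het_only: bool = True,
):
    """Split a per-SNP track into the two flanking regions of a change point.

    SNPs inside the closed safety interval
    ``[changepoint - margin, changepoint + margin]`` are excluded; with
    ``het_only`` only SNPs called heterozygous in the normal are kept.  SNPs
    with a missing statistic are dropped.  Returns
    ``(region1, region2, n_excluded_in_safety)``.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    keep = np.ones(len(values), dtype=bool)
    if chromosome is not None:
        keep &= np.asarray(chromosome) == spec.chromosome
    keep &= (positions >= spec.region_start) & (positions <= spec.region_end)
    if het_only:
        keep &= calls.het_mask
    keep &= ~np.isnan(values)
    in_safety = keep & (np.abs(positions - spec.changepoint) <= spec.safety_margin)
    n_excluded = int(in_safety.sum())
    left = keep & ~in_safety & (positions < spec.changepoint)
    right = keep & ~in_safety & (positions > spec.changepoint)
    if left.sum() == 0 or right.sum() == 0:
        raise InsufficientDataError(f"{spec.label}: empty flanking region")

    def _region(mask, label):
        order = np.argsort(positions[mask], kind="stable")
        return RegionSignal(values[mask][order], positions[mask][order], label)

    return _region(left, 1), _region(right, 2), n_excluded


def balanced_sample(r1: RegionSignal, r2: RegionSignal, n=None, rng=None):
    """Equal-size without-replacement samples of ``n`` values from each region."""
    rng = np.random.default_rng(rng)
    if n is None:
        n = min(len(r1), len(r2))
    if n > min(len(r1), len(r2)):
        raise InsufficientDataError(f"cannot sample {n} from regions of size {len(r1)}, {len(r2)}")
    x = rng.choice(r1.values, size=n, replace=False)
    y = rng.choice(r2.values, size=n, replace=False)
    return x, y


def t_statistic(x, y, welch: bool = False) -> float:
    """Two-sample t statistic for equal means (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise InsufficientDataError("each sample needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
    else:
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = pooled * (1.0 / nx + 1.0 / ny)
    if se2 == 0.0:
        raise UndefinedStatisticError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(se2))


def bootstrap_t(
    r1: RegionSignal,
    r2: RegionSignal,
    n_sampled: int = 250,
    n_boot: int = 100,
    rng=None,
    welch: bool = False,
    replace: bool = False,
):
    """Mean and sd of |t| over ``n_boot`` balanced resamples of ``n_sampled``.

    Draws are without replacement within each region by default (a
    with-replacement mode is available).  With ``n_boot = 1`` the sd is
    reported as 0 by convention.
    """
    rng = np.random.default_rng(rng)
    if n_sampled > min(len(r1), len(r2)) and not replace:
        raise InsufficientDataError(
            f"J'={n_sampled} exceeds a region size ({len(r1)}, {len(r2)})"
        )
    ts = np.empty(n_boot)
    for b in range(n_boot):
        if replace:
            x = rng.choice(r1.values, size=n_sampled, replace=True)
            y = rng.choice(r2.values, size=n_sampled, replace=True)
        else:
            x, y = balanced_sample(r1, r2, n_sampled, rng)
        ts[b] = abs(t_statistic(x, y, welch=welch))
    sd = float(ts.std(ddof=1)) if n_boot > 1 else 0.0
    return float(ts.mean()), sd


def bin_signal(r: RegionSignal, h: int) -> RegionSignal:
    """Average the region's values in non-overlapping, position-ordered bins of
    exactly ``h`` SNPs; a trailing incomplete bin is dropped.  ``h = 1`` is the
    identity."""
    if h < 1:
        raise ValueError("bin size must be >= 1")
    if h == 1:
        return r
    n_bins = len(r) // h
    v = r.values[: n_bins * h].reshape(n_bins, h).mean(axis=1)
    p = r.positions[: n_bins * h].reshape(n_bins, h)[:, 0]
    return RegionSignal(v, p, r.state_label)


def roc_curve(neg, pos) -> RocCurve:
    """ROC curve and AUC for separating positive from negative values.

    Orientation is chosen from the sign of the mean difference so that larger
    scores favor the positive class; a null comparison can still land just
    below 0.5.  The flip, if any, is recorded in ``orientation``.
    """
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if len(neg) == 0 or len(pos) == 0:
        raise InsufficientDataError("both classes must be nonempty")
    orientation = 1 if pos.mean() >= neg.mean() else -1
    scores = orientation * np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(len(neg)), np.ones(len(pos))])
    fpr, tpr, _ = _metrics.roc_curve(labels, scores)
    auc = float(_metrics.auc(fpr, tpr))
    return RocCurve(fpr, tpr, auc, orientation)


def _positive_state(spec: ChangePointSpec) -> int:
    """The "positive" flank is the one with total copy number != 2; if both
    (or neither) qualify, region 2 is used."""
    t1 = spec.state1.c1 + spec.state1.c2
    t2 = spec.state2.c1 + spec.state2.c2
    if t2 != 2:
        return 2
    if t1 != 2:
        return 1
    return 2


def evaluate_changepoint(
    tracks: dict,
    positions,
    calls: GenotypeCallSet,
    spec: ChangePointSpec,
    config: EvalConfig,
    chromosome=None,
    rng=None,
):
    """Bootstrap-t and ROC summaries for several signals at one change point.

    ``tracks`` maps a signal name (e.g. ``"dh_raw"``, ``"dh_norm"``,
    ``"tcn"``) to its per-SNP values; all tracks are evaluated on the same
    heterozygous SNPs with the same per-flank sample size, so numbers are
    comparable across signals.  Returns ``(report, curves)``: a tidy frame
    with one row per (signal, H) and a dict of the matching RocCurve objects.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    regions = {}
    common = None
    for name, values in tracks.items():
        r1, r2, n_exc = extract_flanking_signals(
            values, positions, calls, spec, chromosome=chromosome, het_only=config.het_only
        )
        regions[name] = (r1, r2, n_exc)
        size = min(len(r1), len(r2))
        common = size if common is None else min(common, size)
    n_sampled = min(config.n_sampled, common)
    pos_state = _positive_state(spec)

    rows = []
    curves = {}
    for name, (r1, r2, n_exc) in regions.items():
        for h in config.bin_sizes:
            b1, b2 = bin_signal(r1, h), bin_signal(r2, h)
            n_h = min(max(n_sampled // h, 2), len(b1), len(b2))
            mean_t, sd_t = bootstrap_t(
                b1, b2, n_sampled=n_h, n_boot=config.n_boot, rng=rng
            )
            n_roc = min(len(b1), len(b2))
            x, y = balanced_sample(b1, b2, n_roc, rng)
            neg, pos = (x, y) if pos_state == 2 else (y, x)
            roc = roc_curve(neg, pos)
            curves[(name, h)] = roc
            rows.append(
                {
                    "label": spec.label,
                    "signal": name,
                    "h": h,
                    "mean_t": mean_t,
                    "sd_t": sd_t,
                    "auc": roc.auc,
                    "n_used": n_h,
                    "n_excluded_safety": n_exc,
                    "orientation": roc.orientation,
                }
            )
    return pd.DataFrame(rows), curves
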