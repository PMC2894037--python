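"""Expected allelic signals of a contaminated tumor, and what they imply for
change-point detectability.

A "tumor sample" is modelled as a two-component mixture: a fraction
``kappa`` (tumor purity) of homogeneous tumor cells with parental copy number
``(c1, c2)``, ``c1 <= c2``, and a fraction ``1 - kappa`` of normal diploid
cells, with average tumor ploidy two.  For a SNP heterozygous in the normal,
the normal cells contribute one copy of each allele, so the true tumor BAF
and decrease in heterozygosity are

    beta* = (kappa * b + (1 - kappa)) / (kappa * (c1 + c2) + 2 * (1 - kappa))
    DH*   = kappa * (c2 - c1) / (kappa * (c1 + c2) + 2 * (1 - kappa))

where ``b`` is whichever of ``c1``/``c2`` carries the B allele.  Under the
assumption that the DH variance does not depend on its level, the power to
detect a change point between two flanking states is monotone in the absolute
difference of their true DH, ``Delta(kappa)`` — which is why some change
points (deletion vs copy-neutral LOH) are hardest at high purity and best
detected at an intermediate ``kappa``.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "PcnState",
    "true_het_beta",
    "true_dh",
    "dh_difference",
    "argmax_purity",
    "dh_difference_curves",
]


class PcnState(NamedTuple):
    """Parental copy number (minor, major) with ``c1 <= c2``, both >= 0."""

    c1: int
    c2: int

    def validate(self) -> "PcnState":
        if self.c1 < 0 or self.c2 < self.c1:
            raise ValueError(f"invalid parental copy number state {self!r}")
        return self


def _mixture_total(state: PcnState, kappa):
    return kappa * (state.c1 + state.c2) + 2.0 * (1.0 - np.asarray(kappa, dtype=float))


def true_het_beta(state: PcnState, kappa, b_copies):
    """True tumor BAF of a normal-heterozygous SNP under contamination.

    ``b_copies`` is the parental copy count carrying allele B and must be
    ``state.c1`` or ``state.c2``.  Returns NaN for the degenerate case of a
    pure homozygous deletion (zero total DNA).
    """
    state = PcnState(*state).validate()
    if b_copies not in (state.c1, state.c2):
        raise ValueError("b_copies must be one of the two parental copy numbers")
    k = np.asarray(kappa, dtype=float)
    if np.any((k < 0) | (k > 1)):
        raise ValueError("kappa must lie in [0, 1]")
    denom = _mixture_total(state, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (k * b_copies + (1.0 - k)) / denom
    return np.where(denom > 0, beta, np.nan)[()]


def true_dh(state: PcnState, kappa):
    """True decrease in heterozygosity ``kappa*(c2-c1) / (kappa*(c1+c2) + 2*(1-kappa))``.

    Equals ``2 * |true_het_beta - 1/2|`` for either allele assignment.
    NaN for a pure homozygous deletion.
    """
    state = PcnState(*state).validate()
    k = np.asarray(kappa, dtype=float)
    if np.any((k < 0) | (k > 1)):
        raise ValueError("kappa must lie in [0, 1]")
    denom = _mixture_total(state, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = k * (state.c2 - state.c1) / denom
    return np.where(denom > 0, d, np.nan)[()]


def dh_difference(state1: PcnState, state2: PcnState, kappa):
    """Detectability driver ``Delta(kappa) = |DH*(state2) - DH*(state1)|``."""
    return np.abs(true_dh(PcnState(*state2), kappa) - true_dh(PcnState(*state1), kappa))


def argmax_purity(state1: PcnState, state2: PcnState, grid_resolution: int = 1001) -> float:
    """Purity maximizing ``dh_difference`` over [0, 1].

    Scans a uniform grid, then refines the best grid cell with bounded
    golden-section search to 1e-6; exact ties resolve to the smallest kappa.
    """
    s1, s2 = PcnState(*state1).validate(), PcnState(*state2).validate()
    if s1 == s2:
        raise ValueError("identical states have no detectability maximum")
    grid = np.linspace(0.0, 1.0, grid_resolution)
    vals = dh_difference(s1, s2, grid)
    vals = np.where(np.isnan(vals), -np.inf, vals)
    i = int(np.argmax(vals))  # argmax returns first (smallest kappa) on ties
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_resolution - 1)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(
        lambda k: -dh_difference(s1, s2, k),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    k_star = float(res.x)
    # an interior refinement can never beat a boundary grid optimum by chance
    if dh_difference(s1, s2, k_star) < vals[i]:
        k_star = float(grid[i])
    return k_star


def dh_difference_curves(
    changepoints: Iterable[tuple], kappa_grid: Sequence[float] | None = None
) -> pd.DataFrame:
    """Tabulate ``Delta(kappa)`` for several change-point state pairs.

    ``changepoints`` yields ``(label, state1, state2)`` triples.  Returns a
    long-form frame with columns ``kappa``, ``label``, ``delta``.
    """
    if kappa_grid is None:
        kappa_grid = np.linspace(0.0, 1.0, 101)
    kappa_grid = np.asarray(kappa_grid, dtype=float)
    rows = []
    for label, s1, s2 in changepoints:
        delta = dh_difference(PcnState(*s1), PcnState(*s2), kappa_grid)
        rows.append(pd.DataFrame({"kappa": kappa_grid, "label": label, "delta": delta}))
    return pd.concat(rows, ignore_index=True)
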