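"""Tab-separated readers/writers for all table kinds, with chunked streaming.

All files are TSV with a header row and ``NA`` as the missing token.  Column
names are validated on read; unknown columns are preserved on passthrough.
Genotype calls are stored as AA/AB/BB (diploid), A/B (hemizygous) or NC
(no call), mapping to ``mu_hat`` 0 / 0.5 / 1 / 0 / 1 / missing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .contamination import PcnState
from .evaluation import ChangePointSpec
from .genotyping import GenotypeCallSet
from .normalize import NormalizedTumorTrack
from .signals import PairedSnpTable

__all__ = [
    "read_paired_signals",
    "iter_paired_signals",
    "write_paired_signals",
    "read_genotype_calls",
    "write_genotype_calls",
    "write_normalized_track",
    "read_region_specs",
    "write_region_specs",
]

NA_TOKEN = "NA"
MB = 1_000_000

PAIRED_COLUMNS = ["chromosome", "position", "theta_n", "beta_n", "theta_t", "beta_t"]
CALL_COLUMNS = ["chromosome", "position", "call", "confidence"]
REGION_COLUMNS = ["label", "chromosome", "start", "end", "changepoint", "safety", "pcn1", "pcn2"]

_CALL_TO_MU = {"AA": 0.0, "AB": 0.5, "BB": 1.0, "A": 0.0, "B": 1.0, "NC": np.nan}
_MU_TO_CALL = {0.0: "AA", 0.5: "AB", 1.0: "BB"}


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("dtype", {"chromosome": str})
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False, **kwargs)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_paired_signals(path) -> PairedSnpTable:
    """Read a whole paired-signal table into memory."""
    df = _read_tsv(path)
    _check_columns(df, PAIRED_COLUMNS, path)
    return PairedSnpTable.from_frame(df)


def iter_paired_signals(path, chunk_size: int) -> Iterator[PairedSnpTable]:
    """Stream a paired-signal table in chunks of at most ``chunk_size`` SNPs."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    with pd.read_csv(
        path,
        sep="\t",
        na_values=[NA_TOKEN],
        keep_default_na=False,
        dtype={"chromosome": str},
        chunksize=chunk_size,
    ) as reader:
        first = True
        for chunk in reader:
            if first:
                _check_columns(chunk, PAIRED_COLUMNS, path)
                first = False
            yield PairedSnpTable.from_frame(chunk)


def write_paired_signals(table: PairedSnpTable, path) -> None:
    _write_tsv(table.to_frame(), path)


def write_genotype_calls(table: PairedSnpTable, calls: GenotypeCallSet, path) -> None:
    call = np.array([_MU_TO_CALL.get(m, "NC") for m in calls.mu_hat], dtype=object)
    _write_tsv(
        pd.DataFrame(
            {
                "chromosome": table.chromosome,
                "position": table.position,
                "call": call,
                "confidence": calls.confidence,
            }
        ),
        path,
    )


def read_genotype_calls(path, source: str = "external") -> pd.DataFrame:
    """Read a genotype-call table; adds a ``mu_hat`` column decoded from ``call``.

    Returned as a DataFrame (not a :class:`GenotypeCallSet`) because external
    calls carry no thresholds; align against a paired table before use.
    """
    df = _read_tsv(path)
    _check_columns(df, ["chromosome", "position", "call"], path)
    bad = set(df["call"].dropna()) - set(_CALL_TO_MU)
    if bad:
        raise SchemaError(f"{path}: unknown genotype code(s) {sorted(bad)}")
    df = df.copy()
    df["mu_hat"] = df["call"].map(_CALL_TO_MU)
    if "confidence" not in df.columns:
        df["confidence"] = np.nan
    df.attrs["source"] = source
    return df


def calls_from_frame(df: pd.DataFrame, table: PairedSnpTable) -> GenotypeCallSet:
    """Align an external call frame to a paired table on (chromosome, position).

    SNPs of the table absent from the call set get missing calls; the count of
    unmatched call rows is recorded in ``GenotypeCallSet.source``-side logging
    by the caller.
    """
    key = pd.MultiIndex.from_arrays([np.asarray(table.chromosome, dtype=str), table.position])
    df = df.copy()
    df["chromosome"] = df["chromosome"].astype(str)
    df = df.set_index(["chromosome", "position"])
    df = df[~df.index.duplicated(keep="first")]
    aligned = df.reindex(key)
    return GenotypeCallSet(
        aligned["mu_hat"].to_numpy(dtype=float),
        aligned["confidence"].to_numpy(dtype=float),
        thresholds=(),
        source=df.attrs.get("source", "external"),
    )


def write_normalized_track(table: PairedSnpTable, track: NormalizedTumorTrack, path, intensities: bool = False) -> None:
    df = table.to_frame()
    df["beta_t_norm"] = track.beta_t_norm
    df["eta"] = track.eta
    df["normalized_flag"] = track.normalized_flag
    if intensities:
        df["theta_a_norm"] = df["theta_t"] * (1.0 - df["beta_t_norm"])
        df["theta_b_norm"] = df["theta_t"] * df["beta_t_norm"]
    _write_tsv(df, path)


def _parse_pcn(text) -> PcnState:
    parts = str(text).strip().strip("()").split(",")
    if len(parts) != 2:
        raise SchemaError(f"cannot parse parental copy number state {text!r}")
    return PcnState(int(parts[0]), int(parts[1]))


def read_region_specs(path, units: str = "bp") -> list:
    """Read change-point region specs; ``units`` is ``"bp"`` or ``"Mb"``."""
    if units not in ("bp", "Mb"):
        raise ValueError("units must be 'bp' or 'Mb'")
    factor = MB if units == "Mb" else 1
    df = _read_tsv(path, dtype={"chromosome": str})
    _check_columns(df, REGION_COLUMNS, path)
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            ChangePointSpec(
                label=row.label,
                chromosome=str(row.chromosome),
                region_start=int(round(row.start * factor)),
                region_end=int(round(row.end * factor)),
                changepoint=int(round(row.changepoint * factor)),
                safety_margin=int(round(row.safety * factor)),
                state1=_parse_pcn(row.pcn1),
                state2=_parse_pcn(row.pcn2),
            )
        )
    return specs


def write_region_specs(specs, path) -> None:
    _write_tsv(
        pd.DataFrame(
            {
                "label": [s.label for s in specs],
                "chromosome": [s.chromosome for s in specs],
                "start": [s.region_start for s in specs],
                "end": [s.region_end for s in specs],
                "changepoint": [s.changepoint for s in specs],
                "safety": [s.safety_margin for s in specs],
                "pcn1": [f"{s.state1.c1},{s.state1.c2}" for s in specs],
                "pcn2": [f"{s.state2.c1},{s.state2.c2}" for s in specs],
            }
        ),
        path,
    )
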