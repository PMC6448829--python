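"""MREBS read filtering and 1 kb window read counts around CpG dimers.

MRE digestion leaves a characteristic cut-site sequence at the fragment 5'
end, so a genuine MREBS read starts with one of a small set of trimers (CGG
for HpaII/MspI-type cuts, CGC for HinP1I/AciI-type cuts); reads with other
5' trimers are discarded. Read density then carries the methylation signal:
an unmethylated site is cut on more molecules, so counts around a CpG
anti-correlate with its methylation.

Reads are consumed as BED intervals; the 5' trimer travels in the BED name
field, optionally as ``PRE|POST`` carrying both the genomic (pre-bisulfite)
and the sequenced (post-bisulfite) trimer.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_digest import DimerIndex

#: Cut-site trimers of the HpaII/HinP1I/AciI cocktail, unconverted form.
DEFAULT_TRIMERS = frozenset({"CGG", "CGC"})

READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_reads_bed(path) -> pd.DataFrame:
    """Read an alignment BED (4–6 columns) into a reads DataFrame.

    Adds ``trimer`` (first ``|``-separated token of the name field) and,
    when present, ``trimer_post`` (second token).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=READ_COLUMNS + ["trimer"])
    ncol = df.shape[1]
    if ncol < 4:
        raise ValueError("reads BED needs at least 4 columns (name = 5' trimer)")
    df = df.iloc[:, :6]
    df.columns = READ_COLUMNS[:ncol]
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "+"
    parts = df["name"].astype(str).str.split("|", expand=True)
    df["trimer"] = parts[0]
    if parts.shape[1] > 1:
        df["trimer_post"] = parts[1]
    if (df["end"] <= df["start"]).any():
        raise ValueError("reads must have end > start")
    return df


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False, columns=READ_COLUMNS)


def filter_by_trimer(
    reads: pd.DataFrame, allowed: Iterable[str] = DEFAULT_TRIMERS
) -> pd.DataFrame:
    """Keep reads whose 5' trimer is in ``allowed`` (default CGG/CGC)."""
    allowed = frozenset(allowed)
    if not allowed:
        raise ValueError("allowed trimer set must be non-empty")
    return reads[reads["trimer"].isin(allowed)]


def five_prime_positions(reads: pd.DataFrame) -> np.ndarray:
    """Position of each read's 5' base: start for +, end-1 for -."""
    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    minus = (reads["strand"] == "-").to_numpy()
    return np.where(minus, end - 1, start)


def window_counts(
    reads: pd.DataFrame,
    dimers: DimerIndex,
    window_size: int = 1000,
    assign: str = "start",
) -> pd.Series:
    """Reads per window around every CpG dimer (one sample).

    The window around a dimer at ``p`` is ``[p - w/2, p + w/2)``, half-open.
    With ``assign='start'`` a read is counted iff its 5' position lies in
    the window (the default: the MRE signal is the cut at the fragment 5'
    end); ``assign='overlap'`` counts any read overlapping the window. A
    read may count toward several nearby dimers.

    Returns an int Series indexed by ``(chrom, pos)`` covering *all* dimers
    (zeros included).
    """
    if window_size % 2:
        raise ValueError("window_size must be even")
    if assign not in ("start", "overlap"):
        raise ValueError("assign must be 'start' or 'overlap'")
    half = window_size // 2
    pieces = []
    for chrom, pos in dimers.items():
        sub = reads[reads["chrom"] == chrom]
        lo = pos - half
        hi = pos + half
        if assign == "start":
            fp = np.sort(five_prime_positions(sub))
            count = np.searchsorted(fp, hi, side="left") - np.searchsorted(
                fp, lo, side="left"
            )
        else:
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
            count = np.searchsorted(starts, hi, side="left") - np.searchsorted(
                ends, lo, side="right"
            )
        pieces.append(
            pd.Series(
                count.astype(np.int64),
                index=pd.MultiIndex.from_arrays(
                    [np.repeat(chrom, len(pos)), pos], names=["chrom", "pos"]
                ),
            )
        )
    out = pd.concat(pieces) if pieces else pd.Series(dtype=np.int64)
    out.name = "count"
    return out


def pair_window_counts(counts_a: pd.Series, counts_b: pd.Series) -> pd.DataFrame:
    """Join two samples' window counts into columns ``count_a, count_b``."""
    return pd.DataFrame({"count_a": counts_a, "count_b": counts_b}).fillna(0).astype(
        np.int64
    )


def filter_window_counts(paired: pd.DataFrame, min_reads: int = 2) -> pd.DataFrame:
    """Keep dimers with >= ``min_reads`` in at least one of the two samples."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = (paired["count_a"] >= min_reads) | (paired["count_b"] >= min_reads)
    return paired[keep]


def differential_counts(
    paired: pd.DataFrame,
    scale: str = "raw",
    library_sizes: Optional[Tuple[int, int]] = None,
) -> pd.Series:
    """Per-dimer window-count difference, sample A minus sample B.

    ``scale='per-million'`` divides each sample's counts by its library size
    (total mapped reads, supplied explicitly) and multiplies by 1e6 before
    differencing; the default leaves counts raw.
    """
    if scale not in ("raw", "per-million"):
        raise ValueError("scale must be 'raw' or 'per-million'")
    a = paired["count_a"].astype(float)
    b = paired["count_b"].astype(float)
    if scale == "per-million":
        if library_sizes is None:
            raise ValueError("per-million scaling requires library_sizes")
        a = a / library_sizes[0] * 1e6
        b = b / library_sizes[1] * 1e6
    delta = a - b
    delta.name = "delta_count"
    return delta
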