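"""Per-cytosine bisulfite calls, strand merging, and differential methylation.

The on-disk dialect is CGmap-like: tab-separated columns
``chrom, position (1-based), strand (+/-), context (CG/CHG/CHH),
methylated_count, total_count``. Positions are converted to 0-based on
parsing. Methylation levels are expressed in percent (0–100) throughout, so
downstream error metrics are in percentage points.

Strand merging: a plus-strand CG call at position ``p`` and a minus-strand
call at ``p + 1`` (the G's paired C) are summed into the dimer keyed by
``p``. Dimers covered on one strand only are retained.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_digest import DimerIndex

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]
_CONTEXTS = {"CG", "CHG", "CHH"}


def parse_meth_calls(path) -> pd.DataFrame:
    """Read a CGmap-like call file into a DataFrame (positions 0-based).

    Raises ``ValueError`` on malformed rows: unknown strand/context,
    non-positive total counts, or methylated count exceeding the total.
    Non-CG contexts are retained (callers filter on the ``context`` column).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CALL_COLUMNS,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "context": str,
                "meth_count": np.int64,
                "total_count": np.int64,
            },
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CALL_COLUMNS)
    if not df["strand"].isin({"+", "-"}).all():
        raise ValueError("strand column must be '+' or '-'")
    if not df["context"].isin(_CONTEXTS).all():
        raise ValueError(f"context must be one of {sorted(_CONTEXTS)}")
    if (df["total_count"] <= 0).any():
        raise ValueError("total_count must be positive")
    if (df["meth_count"] < 0).any() or (df["meth_count"] > df["total_count"]).any():
        raise ValueError("meth_count must satisfy 0 <= meth_count <= total_count")
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based and positive")
    df["pos"] -= 1
    return df


def write_meth_calls(calls: pd.DataFrame, path) -> None:
    """Write calls back to the CGmap-like dialect (1-based positions)."""
    out = calls.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False, columns=CALL_COLUMNS)


def merge_strand_calls(calls: pd.DataFrame, dimers: DimerIndex) -> pd.DataFrame:
    """Sum plus/minus CG-context calls into CpG dimers.

    Returns a DataFrame indexed by ``(chrom, pos)`` — the forward-strand C
    position — with columns ``meth_count``, ``total_count`` and ``level``
    (percent). A CG call whose implied dimer position is absent from the
    dimer index is an error. Counts are conserved: the dimer totals sum to
    the CG call totals.
    """
    cg = calls[calls["context"] == "CG"]
    if cg.empty:
        return pd.DataFrame(
            columns=["meth_count", "total_count", "level"],
            index=pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"]),
        )
    dimer_pos = cg["pos"].to_numpy() - (cg["strand"] == "-").to_numpy().astype(np.int64)
    work = pd.DataFrame(
        {
            "chrom": cg["chrom"].to_numpy(),
            "pos": dimer_pos,
            "meth_count": cg["meth_count"].to_numpy(),
            "total_count": cg["total_count"].to_numpy(),
        }
    )
    for chrom, grp in work.groupby("chrom", sort=False):
        idx = dimers.get(chrom)
        if idx is None:
            raise ValueError(f"CG call on unknown chromosome {chrom!r}")
        where = np.searchsorted(idx, grp["pos"].to_numpy())
        ok = (where < len(idx)) & (
            idx[np.minimum(where, len(idx) - 1)] == grp["pos"].to_numpy()
        )
        if not ok.all():
            bad = grp["pos"].to_numpy()[~ok][0]
            raise ValueError(f"CG call at {chrom}:{bad} does not match a CpG dimer")
    merged = (
        work.groupby(["chrom", "pos"], sort=True)[["meth_count", "total_count"]]
        .sum()
        .query("total_count > 0")
    )
    merged["level"] = 100.0 * merged["meth_count"] / merged["total_count"]
    return merged


def filter_min_coverage(
    dimer_meth_a: pd.DataFrame, dimer_meth_b: pd.DataFrame, min_cov: int = 5
) -> pd.DataFrame:
    """Keep dimers covered by at least ``min_cov`` reads in *both* samples.

    Input frames are ``merge_strand_calls`` outputs. Returns a frame indexed
    by ``(chrom, pos)`` with columns ``level_a, total_a, level_b, total_b``.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    a = dimer_meth_a[["level", "total_count"]].rename(
        columns={"level": "level_a", "total_count": "total_a"}
    )
    b = dimer_meth_b[["level", "total_count"]].rename(
        columns={"level": "level_b", "total_count": "total_b"}
    )
    paired = a.join(b, how="inner")
    return paired[(paired["total_a"] >= min_cov) & (paired["total_b"] >= min_cov)]


def differential_methylation(paired: pd.DataFrame) -> pd.Series:
    """Per-dimer methylation difference, sample A minus sample B.

    In percentage points, range [-100, 100]; defined only on the dimers that
    passed the pairwise coverage filter.
    """
    delta = paired["level_a"] - paired["level_b"]
    delta.name = "delta"
    return delta


def coverage_summary(
    dimer_meth: pd.DataFrame, thresholds: Sequence[int] = (1, 5, 10, 20)
) -> pd.Series:
    """Number of dimers with total coverage >= t, for each threshold t."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    totals = dimer_meth["total_count"].to_numpy() if len(dimer_meth) else np.array([])
    counts = [int((totals >= t).sum()) for t in thresholds]
    return pd.Series(counts, index=thresholds, name="n_dimers")


def write_bedgraph(track: pd.Series, path, span: int = 2) -> None:
    """Write a per-dimer track as bedGraph (interval ``[pos, pos+span)``)."""
    rows = track.reset_index()
    rows.columns = ["chrom", "start", "value"]
    rows["end"] = rows["start"] + span
    rows[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.4f"
    )
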