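"""Chromatin-state-stratified methylation summaries.

Consumes a genome segmentation into 200 bp windows labelled with chromatin
states (e.g. an 18-state chromHMM model), computes mean methylation per
window from CpG-dimer calls, and summarises per-state distributions and the
observed/expected enrichment of covered windows in each state.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd


def read_state_bed(path, n_states: int = 18, window_size: int = 200) -> pd.DataFrame:
    """Read a state annotation BED (chrom, start, end, state).

    Windows must all be ``window_size`` long with integer labels in
    ``1..n_states``; overlap within a chromosome is rejected.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": np.int64},
    )
    if ((df["end"] - df["start"]) != window_size).any():
        raise ValueError(f"all state windows must be {window_size} bp")
    if not df["state"].between(1, n_states).all():
        raise ValueError(f"state labels must be in 1..{n_states}")
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    if (same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])).any():
        raise ValueError("state windows overlap")
    return df


def window_mean_methylation(
    dimer_meth: pd.DataFrame, windows: pd.DataFrame, min_cov: int = 5
) -> pd.DataFrame:
    """Mean methylation of qualifying dimers per window.

    A dimer qualifies when its total coverage is >= ``min_cov``; a window
    qualifies when it contains at least one qualifying dimer (by the C
    position, half-open interval membership). The mean is over qualifying
    dimers only. Returns columns ``chrom, start, end, mean_level, n_dimers``
    for qualifying windows.
    """
    covered = dimer_meth[dimer_meth["total_count"] >= min_cov]
    rows: List[dict] = []
    by_chrom = {
        chrom: grp.reset_index() for chrom, grp in covered.groupby(level="chrom")
    }
    for win in windows.itertuples(index=False):
        grp = by_chrom.get(win.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, win.start, side="left")
        hi = np.searchsorted(pos, win.end, side="left")
        if hi > lo:
            rows.append(
                {
                    "chrom": win.chrom,
                    "start": win.start,
                    "end": win.end,
                    "mean_level": float(grp["level"].to_numpy()[lo:hi].mean()),
                    "n_dimers": int(hi - lo),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_level", "n_dimers"])


def stratify_by_state(
    window_meth: pd.DataFrame, annotation: pd.DataFrame
) -> Dict[object, np.ndarray]:
    """Partition window mean-methylation values by chromatin state.

    Every covered window must appear in the annotation. Returns a map from
    state label to the array of its windows' mean levels, plus the key
    ``"genome"`` holding all values (so the per-state arrays partition it).
    """
    ann = annotation.set_index(["chrom", "start"])["state"]
    keyed = window_meth.set_index(["chrom", "start"])
    try:
        states = ann.loc[keyed.index]
    except KeyError as exc:
        raise ValueError(f"covered window missing from annotation: {exc}") from exc
    out: Dict[object, np.ndarray] = {
        state: keyed["mean_level"].to_numpy()[states.to_numpy() == state]
        for state in sorted(annotation["state"].unique())
    }
    out["genome"] = keyed["mean_level"].to_numpy()
    return out


def state_distribution_table(strata: Dict[object, np.ndarray]) -> pd.DataFrame:
    """Per-state count/mean/median summary of the stratified values."""
    rows = []
    for state, vals in strata.items():
        rows.append(
            {
                "state": state,
                "n_windows": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "median": float(np.median(vals)) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def state_enrichment(
    window_meth: pd.DataFrame, annotation: pd.DataFrame
) -> pd.Series:
    """log2 observed/expected share of covered windows per state.

    Observed: the fraction of methylation-covered windows in each state.
    Expected: that state's fraction of all annotation windows. A state with
    annotation windows but no covered windows yields ``-inf`` (documented
    sentinel); a state absent from the annotation is an error by
    construction (it has no expected share).
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    ann_counts = annotation["state"].value_counts()
    ann_total = int(ann_counts.sum())
    ann = annotation.set_index(["chrom", "start"])["state"]
    obs_states = ann.loc[window_meth.set_index(["chrom", "start"]).index]
    obs_counts = obs_states.value_counts()
    obs_total = int(obs_counts.sum())
    if obs_total == 0:
        raise ValueError("no covered windows")
    out = {}
    for state in sorted(ann_counts.index):
        expected = ann_counts[state] / ann_total
        observed = obs_counts.get(state, 0) / obs_total
        out[state] = float(np.log2(observed / expected)) if observed > 0 else -np.inf
    return pd.Series(out, name="log2_obs_over_expected")
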