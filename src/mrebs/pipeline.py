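"""End-to-end orchestration: from call/read files to model metrics.

Ties the modules together in the order a study would run them: index the
genome's CpG dimers; merge and filter WGBS, RRBS, and MREBS conversion
calls into differential tracks; filter MREBS reads and count them in 1 kb
windows; assemble the per-dimer record table; fit models 1–4; combine; and
evaluate everything against the WGBS response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import diff_models, meth_calls, read_counts
from .genome_digest import DimerIndex, index_cpg_dimers, n_dimers, read_fasta


@dataclass
class PipelineResult:
    """Everything the analysis produces, keyed per MREBS replicate."""

    n_genome_dimers: int
    y: pd.Series
    r: pd.Series
    x1: Dict[int, pd.Series]
    x2: Dict[int, pd.Series]
    records: Dict[int, pd.DataFrame]
    fits: Dict[Tuple[int, int], diff_models.ModelFit]  # (model_id, rep)
    predictions: Dict[Tuple[int, int], pd.Series]
    combined: Dict[int, pd.Series]
    metrics: Dict[str, diff_models.MetricsReport]
    coverage: Dict[str, int]

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.metrics.items():
            row = {"track": name}
            row.update(rep.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def run_pipeline(
    bundle_dir,
    replicates: Sequence[int] = (1, 2),
    min_cov: int = 5,
    min_reads: int = 2,
    window_size: int = 1000,
    allowed_trimers: Iterable[str] = read_counts.DEFAULT_TRIMERS,
) -> PipelineResult:
    """Run the full analysis on a fixture bundle directory.

    Expects the file layout written by
    :func:`mrebs.synthetic_data.end_to_end_fixture`: ``genome.fa``,
    ``{wgbs,rrbs}_sample{1,2}.cgmap``, and per-replicate
    ``mrebs_sample{s}_rep{r}.{bed,cgmap}``.
    """
    bundle = Path(bundle_dir)
    genome = read_fasta(bundle / "genome.fa")
    dimers = index_cpg_dimers(genome)

    def dimer_track(path) -> pd.DataFrame:
        return meth_calls.merge_strand_calls(meth_calls.parse_meth_calls(path), dimers)

    wgbs = {s: dimer_track(bundle / f"wgbs_sample{s}.cgmap") for s in (1, 2)}
    rrbs = {s: dimer_track(bundle / f"rrbs_sample{s}.cgmap") for s in (1, 2)}
    paired_w = meth_calls.filter_min_coverage(wgbs[1], wgbs[2], min_cov)
    y = meth_calls.differential_methylation(paired_w)
    paired_r = meth_calls.filter_min_coverage(rrbs[1], rrbs[2], min_cov)
    r = meth_calls.differential_methylation(paired_r)

    x1: Dict[int, pd.Series] = {}
    x2: Dict[int, pd.Series] = {}
    records: Dict[int, pd.DataFrame] = {}
    coverage: Dict[str, int] = {
        "genome_dimers": n_dimers(dimers),
        "wgbs_paired_5x": len(paired_w),
        "rrbs_paired_5x": len(paired_r),
    }
    for rep in replicates:
        conv = {
            s: dimer_track(bundle / f"mrebs_sample{s}_rep{rep}.cgmap") for s in (1, 2)
        }
        paired_m = meth_calls.filter_min_coverage(conv[1], conv[2], min_cov)
        x1[rep] = meth_calls.differential_methylation(paired_m)
        reads = {
            s: read_counts.filter_by_trimer(
                read_counts.read_reads_bed(bundle / f"mrebs_sample{s}_rep{rep}.bed"),
                allowed_trimers,
            )
            for s in (1, 2)
        }
        wc = read_counts.pair_window_counts(
            read_counts.window_counts(reads[1], dimers, window_size),
            read_counts.window_counts(reads[2], dimers, window_size),
        )
        wc_kept = read_counts.filter_window_counts(wc, min_reads)
        x2[rep] = read_counts.differential_counts(wc_kept)
        records[rep] = diff_models.assemble_records(y=y, r=r, x1=x1[rep], x2=x2[rep])
        coverage[f"mrebs_paired_5x_rep{rep}"] = len(paired_m)
        coverage[f"window_filter_rep{rep}"] = len(wc_kept)

    fits: Dict[Tuple[int, int], diff_models.ModelFit] = {}
    predictions: Dict[Tuple[int, int], pd.Series] = {}
    combined: Dict[int, pd.Series] = {}
    metrics: Dict[str, diff_models.MetricsReport] = {}

    first = records[replicates[0]]
    fits[(1, 0)] = diff_models.fit_model(first, 1)
    predictions[(1, 0)] = diff_models.predict(fits[(1, 0)], first)
    metrics["model1"] = diff_models.evaluate_fit(y, predictions[(1, 0)])
    for rep in replicates:
        for model_id in (2, 3, 4):
            fit = diff_models.fit_model(records[rep], model_id)
            fits[(model_id, rep)] = fit
            predictions[(model_id, rep)] = diff_models.predict(fit, records[rep])
            metrics[f"model{model_id}_rep{rep}"] = diff_models.evaluate_fit(
                y, predictions[(model_id, rep)]
            )
        combined[rep] = diff_models.combine_estimates(
            predictions[(4, rep)], predictions[(2, rep)]
        )
        metrics[f"combined_rep{rep}"] = diff_models.evaluate_fit(y, combined[rep])

    return PipelineResult(
        n_genome_dimers=n_dimers(dimers),
        y=y,
        r=r,
        x1=x1,
        x2=x2,
        records=records,
        fits=fits,
        predictions=predictions,
        combined=combined,
        metrics=metrics,
        coverage=coverage,
    )


def differential_correlations(result: PipelineResult) -> pd.DataFrame:
    """Pairwise Pearson correlations between the differential tracks
    (WGBS, RRBS, MREBS conversion and window-count deltas per replicate)."""
    tracks: Dict[str, pd.Series] = {"wgbs": result.y, "rrbs": result.r}
    for rep, s in result.x1.items():
        tracks[f"mrebs_conv_rep{rep}"] = s
    for rep, s in result.x2.items():
        tracks[f"mrebs_count_rep{rep}"] = s
    corr, _ = diff_models.correlation_matrix(tracks)
    return corr
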