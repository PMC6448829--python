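"""Synthetic two-sample methylomes and WGBS/RRBS/MREBS libraries.

The simulator produces, from a single seed, everything the analysis
pipeline consumes: a random genome with CpG-island segments, matched
methylomes for two samples that differ in localised differential blocks,
bisulfite call files (whole-genome and MspI-reduced modes), and MREBS read
libraries generated by molecule-level methylation-sensitive digestion.

The digestion model is the load-bearing piece: each sequenced molecule
draws an independent methylation state for every enzyme-site CpG from that
site's methylation level, and an enzyme cuts the molecule at a site only
when its CpG is unmethylated on that molecule. Partially methylated sites
are therefore cut on a proportional fraction of molecules, which is what
makes window read counts a *continuous*, anti-correlated readout of
methylation rather than a binary one. Fragments between consecutive cuts
are size-selected and sequenced as single-end reads from the fragment 5'
end on the forward strand; read sequences are bisulfite-converted
(unmethylated C -> T at the conversion rate, methylated C -> T at the
residual error rate).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genome_digest import (
    MRE_COCKTAIL,
    DimerIndex,
    Genome,
    build_reduced_reference,
    find_cut_sites,
    index_cpg_dimers,
    reduced_reference_intervals,
    write_fasta,
)
from .meth_calls import write_meth_calls
from .read_counts import DEFAULT_TRIMERS, write_reads_bed

# fixed per-purpose seed stream tags (combined with the user seed)
_TAG_GENOME = 1
_TAG_METHYLOME = 2
_TAG_MREBS = 10  # + 2*(sample-1) + (rep-1)
_TAG_WGBS = 20  # + (sample-1)
_TAG_RRBS = 30  # + (sample-1)
_TAG_STATES = 40


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Library defaults mirror the MREBS protocol: a HpaII/HinP1I/AciI
    digestion cocktail, 100 bp single-end reads, and a 99% bisulfite
    conversion rate. The size-selection default of 80–380 bp is the
    *genomic insert* equivalent of selecting 200–500 bp library molecules
    after ligating ~120 bp of sequencing adapters; selecting raw genomic
    fragments at 200–500 bp instead would discard the short fragments that
    fully digested hypomethylated regions produce and with them most of
    the count/methylation signal (both bounds are configurable). The
    background methylome is drawn from Beta(6, 2) (mean 75%, matching the
    70–80% of CpGs methylated in mammalian genomes) with near-zero
    methylation on CpG islands; two samples differ by ``effect_size``
    percentage points inside ``diff_block_count`` blocks of
    ``block_length`` bp.
    """

    seed: int
    genome_length: int = 200_000
    chrom_count: int = 2
    gc_content: float = 0.42
    island_fraction: float = 0.05
    island_length: int = 1_000
    island_gc: float = 0.60
    cpg_depletion: float = 0.2
    background_beta: Tuple[float, float] = (6.0, 2.0)
    island_beta: Tuple[float, float] = (0.6, 12.0)
    diff_block_count: int = 20
    block_length: int = 2_000
    effect_size: float = 50.0
    mrebs_molecules: int = 200
    wgbs_depth: float = 10.0
    rrbs_depth: float = 10.0
    read_length: int = 100
    frag_min: int = 80
    frag_max: int = 380
    conversion_rate: float = 0.99
    meth_error: float = 0.01

    def __post_init__(self) -> None:
        for name in ("gc_content", "island_fraction", "island_gc",
                     "cpg_depletion", "conversion_rate", "meth_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("genome_length", "chrom_count", "island_length",
                     "block_length", "read_length", "frag_min", "frag_max",
                     "mrebs_molecules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frag_min > self.frag_max:
            raise ValueError("frag_min must be <= frag_max")
        if not 0.0 <= self.effect_size <= 100.0:
            raise ValueError("effect_size in percentage points, [0, 100]")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(tag)])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _deplete_cpg(arr: np.ndarray, rng: np.random.Generator, oe: float) -> None:
    """Thin CG dinucleotides to an observed/expected ratio of ``oe``.

    Mammalian genomes are CpG-depleted outside islands (o/e around 0.2);
    without this the background is cut so densely that size selection
    discards unmethylated regions and the count/methylation relationship
    inverts. Each CG keeps its G with probability ``oe``, otherwise the G
    becomes A or T (which cannot create a new CG).
    """
    cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    kill = cg[rng.random(len(cg)) >= oe]
    arr[kill + 1] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=len(kill))


def _place_segments(
    rng: np.random.Generator,
    chrom_len: int,
    n_segments: int,
    seg_len: int,
    avoid: Optional[List[Tuple[int, int]]] = None,
    tries: int = 50,
) -> List[Tuple[int, int]]:
    """Place non-overlapping equal-length segments, one per genome stripe.

    With ``avoid``, each segment is re-drawn (up to ``tries`` times) until
    it overlaps none of the given intervals.
    """
    if n_segments == 0:
        return []
    stripe = chrom_len // n_segments
    if stripe <= seg_len:
        raise ValueError("chromosome too short for requested segments")
    out = []
    for i in range(n_segments):
        for _ in range(tries):
            off = int(rng.integers(0, stripe - seg_len))
            start, end = i * stripe + off, i * stripe + off + seg_len
            if not avoid or all(end <= a or start >= b for a, b in avoid):
                break
        out.append((start, end))
    return out


def simulate_genome(config: SimConfig) -> Tuple[Genome, pd.DataFrame]:
    """Random genome with embedded GC/CpG-rich island segments.

    Returns the genome and an island table (chrom, start, end). Enzyme
    recognition sites occur naturally in the random sequence; islands are
    generated at elevated GC so their CpG density exceeds background.
    """
    rng = config.rng(_TAG_GENOME)
    chrom_len = config.genome_length // config.chrom_count
    n_islands = int(round(chrom_len * config.island_fraction / config.island_length))
    genome: Genome = {}
    island_rows = []
    for c in range(config.chrom_count):
        chrom = f"chr{c + 1}"
        arr = _random_seq(rng, chrom_len, config.gc_content)
        _deplete_cpg(arr, rng, config.cpg_depletion)
        for start, end in _place_segments(rng, chrom_len, n_islands,
                                          config.island_length):
            arr[start:end] = _random_seq(rng, end - start, config.island_gc)
            island_rows.append({"chrom": chrom, "start": start, "end": end})
        genome[chrom] = arr.tobytes().decode("ascii")
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return genome, islands


def simulate_methylomes(
    genome: Genome, islands: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """True per-dimer methylation levels for two samples (percent).

    Background dimers draw a shared base level from ``background_beta``;
    island dimers from ``island_beta`` (hypomethylated). Inside each
    differential block sample B is shifted against sample A by
    ``effect_size`` percentage points (sign random per block), clipped to
    [0, 100], so |level_a - level_b| equals the effect size except where
    clipping intervenes. Blocks are placed outside CpG islands: core
    islands stay hypomethylated in both samples, mirroring how
    differential methylation concentrates in shores and enhancer-like
    sequence rather than in island cores.

    Returns a frame indexed by (chrom, pos) with columns
    ``level_a, level_b, in_island, block`` (block id, -1 outside blocks).
    """
    rng = config.rng(_TAG_METHYLOME)
    dimers = index_cpg_dimers(genome)
    blocks_per_chrom = config.diff_block_count // len(genome)
    frames = []
    block_id = 0
    for chrom, pos in dimers.items():
        base = 100.0 * rng.beta(*config.background_beta, size=len(pos))
        in_island = np.zeros(len(pos), dtype=bool)
        isl = islands[islands["chrom"] == chrom]
        for start, end in zip(isl["start"], isl["end"]):
            in_island |= (pos >= start) & (pos < end)
        n_isl = int(in_island.sum())
        base[in_island] = 100.0 * rng.beta(*config.island_beta, size=n_isl)
        level_a = base
        level_b = base.copy()
        block = np.full(len(pos), -1, dtype=np.int64)
        chrom_len = len(genome[chrom])
        avoid = list(zip(isl["start"], isl["end"]))
        for start, end in _place_segments(rng, chrom_len, blocks_per_chrom,
                                          config.block_length, avoid=avoid):
            sign = 1 if rng.random() < 0.5 else -1
            inside = (pos >= start) & (pos < end)
            level_b[inside] = np.clip(
                level_a[inside] - sign * config.effect_size, 0.0, 100.0
            )
            block[inside] = block_id
            block_id += 1
        frames.append(
            pd.DataFrame(
                {
                    "level_a": level_a,
                    "level_b": level_b,
                    "in_island": in_island,
                    "block": block,
                },
                index=pd.MultiIndex.from_arrays(
                    [np.repeat(chrom, len(pos)), pos], names=["chrom", "pos"]
                ),
            )
        )
    return pd.concat(frames)


def _levels_by_chrom(
    levels: pd.Series, dimers: DimerIndex
) -> Dict[str, np.ndarray]:
    """Per-chromosome level arrays aligned with the dimer index."""
    out = {}
    for chrom, pos in dimers.items():
        out[chrom] = levels.loc[chrom].reindex(pos).to_numpy(dtype=float)
    return out


def simulate_mrebs_library(
    genome: Genome,
    levels: pd.Series,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One MREBS library: molecule-level digestion, size selection, reads.

    ``levels`` is the true methylation (percent) per (chrom, pos) dimer for
    one sample. Each of ``config.mrebs_molecules`` genome copies is
    digested: every cocktail site whose CpG is drawn unmethylated
    (Bernoulli on the level) is cut, fragments between consecutive cuts
    (and the chromosome ends) within the size-selection range each yield
    one ``read_length`` read from their 5' end. Returns

    - reads: BED-style frame with ``name = "PRE|POST"`` carrying the
      genomic and bisulfite-converted 5' trimers, and
    - calls: per-dimer CG methylation calls in the parsed-CGmap schema
      (0-based, forward strand), obtained by comparing converted read bases
      to the reference — using only reads whose genomic 5' trimer passes
      the expected-trimer filter, as the protocol calls methylation on
      filtered reads.
    """
    dimers = index_cpg_dimers(genome)
    lev = _levels_by_chrom(levels, dimers)
    read_frames = []
    call_frames = []
    for chrom, seq in genome.items():
        L = len(seq)
        D = dimers[chrom]
        cuts, cpgs = find_cut_sites(seq, MRE_COCKTAIL)
        site_idx = np.searchsorted(D, cpgs)
        site_lev = lev[chrom][site_idx]
        p_cut = 1.0 - site_lev / 100.0
        starts_acc: List[np.ndarray] = []
        ends_acc: List[np.ndarray] = []
        batch = 1_000
        done = 0
        while done < config.mrebs_molecules:
            m = min(batch, config.mrebs_molecules - done)
            mask = rng.random((m, len(cuts))) < p_cut
            for row in mask:
                bounds = np.concatenate(([0], cuts[row], [L]))
                lens = np.diff(bounds)
                sel = (lens >= config.frag_min) & (lens <= config.frag_max)
                if sel.any():
                    fs = bounds[:-1][sel]
                    starts_acc.append(fs)
                    ends_acc.append(fs + np.minimum(config.read_length, lens[sel]))
            done += m
        if not starts_acc:
            continue
        starts = np.concatenate(starts_acc)
        ends = np.concatenate(ends_acc)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]

        # 5' trimers, genomic and bisulfite-converted
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        tri_pre = np.empty((len(starts), 3), dtype=np.uint8)
        tri_post = np.empty_like(tri_pre)
        for j in range(3):
            b = arr[starts + j]
            tri_pre[:, j] = b
            is_c = b == ord("C")
            at = starts + j
            w = np.searchsorted(D, at)
            is_dimer = (w < len(D)) & (D[np.minimum(w, len(D) - 1)] == at)
            lvl = np.where(is_dimer, lev[chrom][np.minimum(w, len(D) - 1)], 0.0)
            # the fragment-start CpG is unmethylated by construction
            if j == 0:
                lvl = np.where(is_dimer, 0.0, lvl)
            p_stay = (lvl / 100.0) * (1 - config.meth_error) + (
                1 - lvl / 100.0
            ) * (1 - config.conversion_rate)
            converted = rng.random(len(starts)) >= p_stay
            tri_post[:, j] = np.where(is_c & converted, ord("T"), b)
        names = [
            f"{bytes(p).decode()}|{bytes(q).decode()}"
            for p, q in zip(tri_pre, tri_post)
        ]
        read_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "name": names,
                    "score": 0,
                    "strand": "+",
                }
            )
        )

        # conversion calls come from the reads that pass the expected-trimer
        # filter, mirroring the protocol: filter first, then call. Reads from
        # reverse-strand AciI cuts or chromosome ends carry other trimers and
        # contribute counts only.
        keep = np.array(
            [bytes(t).decode() in DEFAULT_TRIMERS for t in tri_pre], dtype=bool
        )
        starts, ends = starts[keep], ends[keep]

        # per-read methylation states of the CpGs each kept read covers
        lo = np.searchsorted(D, starts)
        hi = np.searchsorted(D, ends)
        counts = hi - lo
        total = int(counts.sum())
        offs = np.concatenate(([0], np.cumsum(counts)))
        inner = np.arange(total) - np.repeat(offs[:-1], counts)
        flat = np.repeat(lo, counts) + inner
        meth = rng.random(total) < lev[chrom][flat] / 100.0
        # the cut-site CpG at the fragment start was necessarily
        # unmethylated on this molecule, or it would not have been cut
        meth[D[flat] == np.repeat(starts, counts)] = False
        u = rng.random(total)
        shows_c = np.where(meth, u >= config.meth_error,
                           u >= config.conversion_rate)
        total_count = np.bincount(flat, minlength=len(D))
        meth_count = np.bincount(flat[shows_c], minlength=len(D))
        covered = total_count > 0
        call_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": D[covered],
                    "strand": "+",
                    "context": "CG",
                    "meth_count": meth_count[covered],
                    "total_count": total_count[covered],
                }
            )
        )
    empty_reads = pd.DataFrame(
        columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    empty_calls = pd.DataFrame(
        columns=["chrom", "pos", "strand", "context", "meth_count", "total_count"]
    )
    reads = pd.concat(read_frames, ignore_index=True) if read_frames else empty_reads
    calls = pd.concat(call_frames, ignore_index=True) if call_frames else empty_calls
    return reads, calls


def simulate_bs_calls(
    genome: Genome,
    levels: pd.Series,
    config: SimConfig,
    mode: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Whole-genome or reduced-representation bisulfite calls for one sample.

    Coverage per dimer is Poisson (``wgbs_depth`` or ``rrbs_depth``), split
    binomially between strands; methylated-read counts are binomial with
    the success probability adjusted for bisulfite conversion (a read shows
    C when a methylated base escapes the error rate or an unmethylated base
    escapes conversion). ``mode='rrbs'`` restricts coverage to dimers on
    size-selected MspI fragments (20–500 bp), mimicking mapping to a
    reduced reference. Output rows follow the parsed-CGmap schema with the
    minus-strand call placed at the dimer's G position.
    """
    if mode not in ("wgbs", "rrbs"):
        raise ValueError("mode must be 'wgbs' or 'rrbs'")
    depth = config.wgbs_depth if mode == "wgbs" else config.rrbs_depth
    dimers = index_cpg_dimers(genome)
    lev = _levels_by_chrom(levels, dimers)
    if mode == "rrbs":
        frags = reduced_reference_intervals(build_reduced_reference(genome))
        frag_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom in genome:
            mine = sorted((f.start, f.end) for f in frags if f.chrom == chrom)
            s = np.array([a for a, _ in mine], dtype=np.int64)
            e = np.array([b for _, b in mine], dtype=np.int64)
            frag_by_chrom[chrom] = (s, e)
    rows = []
    for chrom, D in dimers.items():
        l = lev[chrom] / 100.0
        cov = rng.poisson(depth, size=len(D))
        if mode == "rrbs":
            s, e = frag_by_chrom[chrom]
            if len(s):
                which = np.searchsorted(s, D, side="right") - 1
                inside = (which >= 0) & (D < e[np.maximum(which, 0)])
            else:
                inside = np.zeros(len(D), dtype=bool)
            cov = np.where(inside, cov, 0)
        p_show = l * (1 - config.meth_error) + (1 - l) * (1 - config.conversion_rate)
        cov_plus = rng.binomial(cov, 0.5)
        cov_minus = cov - cov_plus
        meth_plus = rng.binomial(cov_plus, p_show)
        meth_minus = rng.binomial(cov_minus, p_show)
        for strand, pos_off, c, m in (
            ("+", 0, cov_plus, meth_plus),
            ("-", 1, cov_minus, meth_minus),
        ):
            keep = c > 0
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": D[keep] + pos_off,
                        "strand": strand,
                        "context": "CG",
                        "meth_count": m[keep],
                        "total_count": c[keep],
                    }
                )
            )
    calls = pd.concat(rows, ignore_index=True)
    return calls.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def simulate_state_annotation(
    genome: Genome,
    islands: pd.DataFrame,
    config: SimConfig,
    window_size: int = 200,
    n_states: int = 18,
) -> pd.DataFrame:
    """A toy chromatin-state segmentation at 200 bp resolution.

    Windows overlapping a CpG island get the promoter-like states 1–2;
    everything else draws uniformly from states 3–18. This is *synthetic*
    scaffolding for the state-stratification code, not a chromatin model.
    """
    rng = config.rng(_TAG_STATES)
    rows = []
    for chrom, seq in genome.items():
        isl = islands[islands["chrom"] == chrom]
        for start in range(0, len(seq) - window_size + 1, window_size):
            end = start + window_size
            on_island = bool(
                ((isl["start"] < end) & (isl["end"] > start)).any()
            )
            if on_island:
                state = int(rng.integers(1, 3))
            else:
                state = int(rng.integers(3, n_states + 1))
            rows.append({"chrom": chrom, "start": start, "end": end, "state": state})
    return pd.DataFrame(rows)


def end_to_end_fixture(config: SimConfig, outdir) -> Dict[str, Path]:
    """Simulate a full study and write every input the pipeline consumes.

    Writes, under ``outdir``: the genome FASTA, the true-methylome table,
    WGBS and RRBS call files for both samples, MREBS read BEDs and call
    files for two replicates per sample, and a toy chromatin-state BED.
    The bundle is byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, islands = simulate_genome(config)
    meth = simulate_methylomes(genome, islands, config)
    paths: Dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])

    truth = meth.reset_index()
    truth["delta"] = truth["level_a"] - truth["level_b"]
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.4f")

    levels = {"1": meth["level_a"], "2": meth["level_b"]}
    for sample in ("1", "2"):
        wgbs = simulate_bs_calls(
            genome, levels[sample], config, "wgbs",
            config.rng(_TAG_WGBS + int(sample) - 1),
        )
        paths[f"wgbs_{sample}"] = outdir / f"wgbs_sample{sample}.cgmap"
        write_meth_calls(wgbs, paths[f"wgbs_{sample}"])
        rrbs = simulate_bs_calls(
            genome, levels[sample], config, "rrbs",
            config.rng(_TAG_RRBS + int(sample) - 1),
        )
        paths[f"rrbs_{sample}"] = outdir / f"rrbs_sample{sample}.cgmap"
        write_meth_calls(rrbs, paths[f"rrbs_{sample}"])
        for rep in ("1", "2"):
            tag = _TAG_MREBS + 2 * (int(sample) - 1) + int(rep) - 1
            reads, calls = simulate_mrebs_library(
                genome, levels[sample], config, config.rng(tag)
            )
            key = f"mrebs_sample{sample}_rep{rep}"
            paths[f"{key}_bed"] = outdir / f"{key}.bed"
            write_reads_bed(reads, paths[f"{key}_bed"])
            paths[f"{key}_calls"] = outdir / f"{key}.cgmap"
            write_meth_calls(calls, paths[f"{key}_calls"])

    states = simulate_state_annotation(genome, islands, config)
    paths["states"] = outdir / "states.bed"
    states.to_csv(paths["states"], sep="\t", header=False, index=False)
    return paths


def bundle_checksums(paths: Dict[str, Path]) -> Dict[str, str]:
    """MD5 of every file in a fixture bundle (for determinism checks)."""
    return {
        key: hashlib.md5(Path(p).read_bytes()).hexdigest()
        for key, p in sorted(paths.items())
    }
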