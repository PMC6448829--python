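"""Genome I/O, CpG-dimer indexing, and in-silico restriction digestion.

All coordinates are 0-based, half-open (BED convention). A *CpG dimer* is a
forward-strand ``CG`` dinucleotide considered jointly with its reverse-strand
partner; it is identified throughout the package by the position of the
forward-strand C.

Digestion comes in two flavours: methylation-insensitive (e.g. the MspI
digest used to build a reduced reference for RRBS mapping) and
methylation-aware, where a predicate decides which recognition sites are
actually cut. Non-palindromic recognition sites (AciI) are by default also
searched on the reverse strand, with cut positions reported in forward
coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import yaml
from Bio import SeqIO

Genome = Dict[str, str]
DimerIndex = Dict[str, np.ndarray]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with a fixed-sequence recognition site.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"MspI"``.
    recognition : str
        Recognition sequence over {A,C,G,T}, written 5'->3' on the strand
        where the cut offset is defined (e.g. ``CCGG`` for MspI, cutting
        C^CGG).
    cut_offset : int
        0-based offset within the recognition site; the enzyme cuts
        immediately before this base.
    cpg_offset : int
        Offset of the CpG dinucleotide within the recognition site whose
        methylation blocks cutting.
    methylation_sensitive : bool
        Whether CpG methylation at ``cpg_offset`` blocks digestion.
    """

    name: str
    recognition: str
    cut_offset: int
    cpg_offset: int
    methylation_sensitive: bool = True

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition must be a non-empty ACGT string"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut_offset out of range")
        if self.recognition[self.cpg_offset : self.cpg_offset + 2] != "CG":
            raise ValueError(f"{self.name}: no CpG at cpg_offset")

    @property
    def palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


def load_enzymes() -> Dict[str, Enzyme]:
    """Load the shipped enzyme table (MspI, HpaII, HinP1I, AciI)."""
    text = resources.files("mrebs").joinpath("data/enzymes.yaml").read_text()
    return {
        e["name"]: Enzyme(
            name=e["name"],
            recognition=e["recognition"],
            cut_offset=int(e["cut_offset"]),
            cpg_offset=int(e["cpg_offset"]),
            methylation_sensitive=bool(e.get("methylation_sensitive", True)),
        )
        for e in yaml.safe_load(text)
    }


ENZYMES = load_enzymes()
#: The three methylation-sensitive enzymes of the MREBS digestion cocktail.
MRE_COCKTAIL = (ENZYMES["HpaII"], ENZYMES["HinP1I"], ENZYMES["AciI"])


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path) -> Genome:
    """Read a FASTA file into an ordered ``{name: sequence}`` map.

    Sequences are uppercased; characters outside {A,C,G,T,N} are rejected,
    as are duplicate record names and empty sequences.
    """
    genome: Genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if not name:
            raise ValueError("empty FASTA record name")
        if name in genome:
            raise ValueError(f"duplicate FASTA record name: {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {name!r}")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {name!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        genome[name] = seq
    return genome


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    """Write a genome as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def index_cpg_dimers(genome: Genome) -> DimerIndex:
    """Locate every forward-strand ``CG`` dinucleotide.

    Returns a map from chromosome to a sorted int64 array of C positions.
    Overlapping occurrences (``CGCG``) are each counted.
    """
    index: DimerIndex = {}
    for chrom, seq in genome.items():
        a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = np.flatnonzero((a[:-1] == ord("C")) & (a[1:] == ord("G")))
        index[chrom] = pos.astype(np.int64)
    return index


def n_dimers(index: DimerIndex) -> int:
    return int(sum(len(v) for v in index.values()))


def _occurrences(seq: str, pattern: str) -> np.ndarray:
    """Start positions of all (possibly overlapping) exact matches."""
    starts = [m.start() for m in re.finditer(f"(?={re.escape(pattern)})", seq)]
    return np.asarray(starts, dtype=np.int64)


def find_sites(seq: str, enzyme: Enzyme, search_reverse: bool = True) -> np.ndarray:
    """Cut positions of ``enzyme`` in ``seq``, sorted and deduplicated.

    A forward match at ``s`` cuts at ``s + cut_offset``. For non-palindromic
    recognition sites, the reverse strand is searched too (unless
    ``search_reverse`` is False) and the cut reported in forward coordinates
    at ``s + len(recognition) - cut_offset``.
    """
    cuts, _ = find_cut_sites(seq, [enzyme], search_reverse=search_reverse)
    return cuts


def find_cut_sites(
    seq: str, enzymes: Sequence[Enzyme], search_reverse: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Merged cut positions of several enzymes, with the blocking CpG of each.

    Returns ``(cuts, cpgs)``: sorted unique cut positions and, aligned with
    them, the forward-strand C position of the CpG whose methylation blocks
    that cut. When two enzymes cut at the same position the first enzyme's
    CpG is kept (for the shipped cocktail coincident cuts share their CpG).
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    all_cuts: List[np.ndarray] = []
    all_cpgs: List[np.ndarray] = []
    for enz in enzymes:
        L = len(enz.recognition)
        fwd = _occurrences(seq, enz.recognition)
        all_cuts.append(fwd + enz.cut_offset)
        all_cpgs.append(fwd + enz.cpg_offset)
        if search_reverse and not enz.palindromic:
            rev = _occurrences(seq, reverse_complement(enz.recognition))
            all_cuts.append(rev + L - enz.cut_offset)
            # the palindromic CG on the reverse strand maps to a forward CG
            all_cpgs.append(rev + L - enz.cpg_offset - 2)
    cuts = np.concatenate(all_cuts)
    cpgs = np.concatenate(all_cpgs)
    order = np.argsort(cuts, kind="stable")
    cuts, cpgs = cuts[order], cpgs[order]
    keep = np.ones(len(cuts), dtype=bool)
    keep[1:] = cuts[1:] != cuts[:-1]
    return cuts[keep], cpgs[keep]


SiteFilter = Callable[[str, int], bool]


def digest(
    genome: Genome,
    enzymes: Sequence[Enzyme],
    site_filter: Optional[SiteFilter] = None,
    search_reverse: bool = True,
) -> List[Fragment]:
    """Digest a genome with one or more enzymes.

    ``site_filter(chrom, cut_pos)`` decides which candidate cuts fire (None
    means all do — a methylation-insensitive digest). Fragments are the
    intervals between consecutive cuts plus the chromosome ends; they tile
    each chromosome exactly.
    """
    fragments: List[Fragment] = []
    for chrom, seq in genome.items():
        cuts, _ = find_cut_sites(seq, enzymes, search_reverse=search_reverse)
        if site_filter is not None:
            cuts = np.asarray(
                [c for c in cuts if site_filter(chrom, int(c))], dtype=np.int64
            )
        bounds = np.unique(np.concatenate(([0], cuts, [len(seq)])))
        bounds = bounds[(bounds >= 0) & (bounds <= len(seq))]
        for start, end in zip(bounds[:-1], bounds[1:]):
            fragments.append(Fragment(chrom, int(start), int(end)))
    return fragments


def build_reduced_reference(
    genome: Genome,
    enzyme: Optional[Enzyme] = None,
    min_len: int = 20,
    max_len: int = 500,
    search_reverse: bool = True,
) -> Genome:
    """In-silico digest and size-select, as used to map RRBS reads.

    Defaults to an MspI digest retaining 20–500 bp fragments. Records are
    named ``chrom:start-end`` (0-based half-open) so coordinates can be
    mapped back to the source genome.
    """
    if enzyme is None:
        enzyme = ENZYMES["MspI"]
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    reduced: Genome = {}
    for frag in digest(genome, [enzyme], search_reverse=search_reverse):
        length = len(frag)
        if min_len <= length <= max_len:
            name = f"{frag.chrom}:{frag.start}-{frag.end}"
            reduced[name] = genome[frag.chrom][frag.start : frag.end]
    return reduced


def reduced_reference_intervals(reduced: Genome) -> List[Fragment]:
    """Parse ``chrom:start-end`` record names back into genomic intervals."""
    out = []
    for name in reduced:
        chrom, _, span = name.rpartition(":")
        start, _, end = span.partition("-")
        out.append(Fragment(chrom, int(start), int(end)))
    return out
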