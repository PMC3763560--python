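"""CCGG site enumeration and genomic interval tracks.

HpaII and MspI are isoschizomers cutting the palindromic motif CCGG
(C^CGG, leaving a 5'-CG overhang).  Because CCGG is its own reverse
complement a forward-strand scan of the genome enumerates every cut
site once.  Each site carries the two genomic coordinates at which a
sequencing tag anchored at the cut is expected to start: ``pos+1`` for
the downstream plus-strand tag and ``pos+2`` for the upstream
minus-strand tag (5'-most base of the tag in genomic coordinates).

All coordinates are 0-based, half-open internally; BED dialect on disk.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

MOTIF = "CCGG"

#: contig name -> uppercase nucleotide string
GenomeSequence = Dict[str, str]


@dataclass(frozen=True)
class CCGGSite:
    """One genomic CCGG occurrence.

    ``pos`` is the 0-based coordinate of the leftmost C of the motif.
    """

    site_id: int
    chrom: str
    pos: int

    @property
    def tag_start_plus(self) -> int:
        return self.pos + 1

    @property
    def tag_start_minus(self) -> int:
        return self.pos + 2


@dataclass
class FeatureTrack:
    """A named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: List[Tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"track {self.name!r}: empty/inverted interval "
                    f"{chrom}:{start}-{end}"
                )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class Transcript:
    """Gene model with strand-aware TSS/TES.

    For a minus-strand gene the TSS is the rightmost transcribed base
    (``end - 1`` in genomic coordinates) so that windows centered on the
    TSS are symmetric in genomic space for both strands.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: Tuple[Tuple[int, int], ...]

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes) + 1


def load_genome(path: str | Path) -> GenomeSequence:
    """Read a FASTA into an in-memory contig -> uppercase string map."""
    fasta = Fasta(str(path), rebuild=True, as_raw=True, sequence_always_upper=True)
    genome = {name: str(fasta[name][:]) for name in fasta.keys()}
    if not genome:
        raise ValueError(f"no sequences in FASTA {path}")
    return genome


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def find_ccgg_sites(genome: GenomeSequence) -> List[CCGGSite]:
    """Enumerate every CCGG occurrence in the genome.

    The scan is case-insensitive (soft-masked sequence matches); windows
    containing N never match.  Overlapping occurrences each yield a site
    (a lookahead scan, although CCGG cannot in fact overlap itself).
    Sites are sorted by (chrom, pos) and get dense ids.
    """
    if not genome:
        logger.warning("empty genome: returning empty site catalog")
        return []
    pattern = re.compile(f"(?={MOTIF})")
    sites: List[CCGGSite] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for m in pattern.finditer(seq):
            sites.append(CCGGSite(len(sites), chrom, m.start()))
    return sites


def write_site_catalog(sites: Iterable[CCGGSite], path: str | Path) -> None:
    """Write the catalog as BED6: chrom, pos, pos+4, site_id, 0, '.'."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 4}\t{s.site_id}\t0\t.\n")


def read_site_catalog(path: str | Path) -> List[CCGGSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            sites.append(CCGGSite(int(fields[3]), fields[0], int(fields[1])))
    return sites


def load_track(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED3+ file into a FeatureTrack."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            intervals.append((fields[0], start, end))
    return FeatureTrack(name or Path(path).stem, intervals)


def _make_transcript(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    exons: List[Tuple[int, int]],
) -> Transcript:
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r} for {gene_id}")
    if start >= end:
        raise ValueError(f"{gene_id}: start >= end ({start} >= {end})")
    if strand == "+":
        tss, tes = start, end
    else:
        tss, tes = end - 1, start
    return Transcript(gene_id, chrom, strand, tss, tes, tuple(sorted(exons)))


def load_transcripts(path: str | Path) -> List[Transcript]:
    """Read gene models from BED12 or refFlat-style TSV.

    BED12 is detected by column count (>=12 with block columns); BED6
    rows become single-exon transcripts; refFlat rows (geneName, name,
    chrom, strand, txStart, txEnd, cdsStart, cdsEnd, exonCount,
    exonStarts, exonEnds) are detected by a strand symbol in column 4.
    """
    transcripts: List[Transcript] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) >= 5 and f[3] in ("+", "-"):  # refFlat
                chrom, strand = f[2], f[3]
                start, end = int(f[4]), int(f[5])
                starts = [int(x) for x in f[9].rstrip(",").split(",")]
                ends = [int(x) for x in f[10].rstrip(",").split(",")]
                exons = list(zip(starts, ends))
                transcripts.append(
                    _make_transcript(f[0], chrom, strand, start, end, exons)
                )
            elif len(f) >= 12:  # BED12
                chrom, start, end = f[0], int(f[1]), int(f[2])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
                transcripts.append(
                    _make_transcript(f[3], chrom, f[5], start, end, exons)
                )
            elif len(f) >= 6:  # BED6: single exon spanning the gene
                chrom, start, end = f[0], int(f[1]), int(f[2])
                transcripts.append(
                    _make_transcript(f[3], chrom, f[5], start, end, [(start, end)])
                )
            else:
                raise ValueError(f"{path}:{ln}: unrecognized gene-model row")
    return transcripts
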