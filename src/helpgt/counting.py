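"""Fractional tag counting per CCGG site.

Each aligned sequencing tag is matched to a CCGG site when its 5'-most
genomic coordinate equals the site's strand-appropriate expected tag
start (plus-strand tags start at ``pos+1``, minus-strand tags at
``pos+2``), optionally within a small slop.  A read reported at n
alignment locations contributes a partial count of 1/n at each matched
location, so a fully on-site read always contributes total weight 1.
Per-library normalization divides each site's fractional count by the
library total over all sites (partial counts included), making the
normalized table a probability vector over sites.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import CCGGSite

logger = logging.getLogger(__name__)

LIBRARIES = ("HpaII", "MspI", "GT_MspI")


@dataclass(frozen=True)
class TagAlignment:
    """One alignment location of a sequencing tag.

    ``start`` is the 0-based 5'-most genomic coordinate of the aligned
    tag (for a minus-strand alignment this is the rightmost base).
    ``n_locations`` is the total number of alignment locations reported
    for the read; ``mismatches`` its edit distance at this location.
    """

    read_id: str
    chrom: str
    start: int
    strand: str
    n_locations: int = 1
    mismatches: int = 0


@dataclass
class LibraryCounts:
    """Raw and normalized fractional tag counts for one digest library."""

    library: str
    raw: np.ndarray  # indexed by dense site_id
    total: float
    normalized: np.ndarray = field(init=False)
    n_assigned_reads: int = 0
    n_filtered_reads: int = 0

    def __post_init__(self) -> None:
        if self.library not in LIBRARIES:
            raise ValueError(f"unknown library {self.library!r}; expected one of {LIBRARIES}")
        if self.total <= 0:
            raise ValueError(f"empty library {self.library}: total count is zero")
        if abs(self.raw.sum() - self.total) > 1e-9 * max(1.0, self.total):
            raise ValueError("total does not match sum of raw counts")
        self.normalized = self.raw / self.total

    @property
    def n_sites(self) -> int:
        return len(self.raw)


def load_alignments(
    path: str | Path,
    missing_mismatch_policy: str = "zero",
) -> List[TagAlignment]:
    """Read tag alignments from SAM/BAM via pysam.

    Read multiplicity (n) is taken from the NH tag when present;
    otherwise it is the number of records sharing the read name in the
    file.  Mismatches come from the NM tag; a missing NM is treated per
    ``missing_mismatch_policy`` ("zero" or "error").
    """
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.is_reverse:
                start = rec.reference_end - 1  # 5'-most base of a minus-strand tag
                strand = "-"
            else:
                start = rec.reference_start
                strand = "+"
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            if rec.has_tag("NM"):
                nm = rec.get_tag("NM")
            elif missing_mismatch_policy == "zero":
                nm = 0
            else:
                raise ValueError(f"read {rec.query_name}: no NM tag")
            records.append((rec.query_name, rec.reference_name, start, strand, nh, nm))
    per_read = Counter(name for name, *_ in records)
    out = []
    n_missing_nh = 0
    for name, chrom, start, strand, nh, nm in records:
        if nh is None:
            nh = per_read[name]
            n_missing_nh += 1
        out.append(TagAlignment(name, chrom, start, strand, int(nh), int(nm)))
    if n_missing_nh:
        logger.info("NH tag absent on %d records; used per-read record counts", n_missing_nh)
    return out


def filter_alignments(
    alignments: Iterable[TagAlignment],
    max_mismatches: int = 2,
    max_locations: int = 10,
) -> tuple[List[TagAlignment], int]:
    """Apply the mismatch and multiplicity filters.

    Returns (kept alignments, number of removed records).
    """
    kept, dropped = [], 0
    for a in alignments:
        if a.mismatches > max_mismatches or a.n_locations > max_locations:
            dropped += 1
        else:
            kept.append(a)
    return kept, dropped


def assign_tags(
    alignments: Iterable[TagAlignment],
    sites: Sequence[CCGGSite],
    slop: int = 0,
    strand_aware: bool = True,
) -> tuple[np.ndarray, int]:
    """Accumulate 1/n partial counts per site.

    An alignment location matches a site when its start is within
    ``slop`` bases of the site's expected tag start for the alignment's
    strand (or of either tag start when ``strand_aware`` is False).
    Returns (raw count array indexed by site_id, number of alignment
    records that matched a site).
    """
    if slop < 0 or slop > 5:
        raise ValueError("slop must be in [0, 5]")
    plus: Dict[tuple, int] = {}
    minus: Dict[tuple, int] = {}
    for s in sites:
        plus[(s.chrom, s.tag_start_plus)] = s.site_id
        minus[(s.chrom, s.tag_start_minus)] = s.site_id
    contigs = {s.chrom for s in sites}

    raw = np.zeros(len(sites))
    n_assigned = 0
    n_foreign = 0
    for a in alignments:
        if a.chrom not in contigs:
            n_foreign += 1
            continue
        if strand_aware:
            lookup = plus if a.strand == "+" else minus
            tables = (lookup,)
        else:
            tables = (plus, minus)
        site_id = None
        for offset in range(-slop, slop + 1):
            key = (a.chrom, a.start + offset)
            for table in tables:
                if key in table:
                    site_id = table[key]
                    break
            if site_id is not None:
                break
        if site_id is not None:
            raw[site_id] += 1.0 / a.n_locations
            n_assigned += 1
    if n_foreign:
        logger.info("%d alignments on contigs absent from the site catalog", n_foreign)
    return raw, n_assigned


def normalize(
    raw: np.ndarray,
    library: str,
    n_assigned_reads: int = 0,
    n_filtered_reads: int = 0,
) -> LibraryCounts:
    """Divide per-site counts by the library total (partial counts included)."""
    total = float(raw.sum())
    if total <= 0:
        raise ValueError(f"empty library {library}: no tags assigned to any site")
    return LibraryCounts(
        library=library,
        raw=np.asarray(raw, dtype=float),
        total=total,
        n_assigned_reads=n_assigned_reads,
        n_filtered_reads=n_filtered_reads,
    )


def count_library(
    sam_path: str | Path,
    sites: Sequence[CCGGSite],
    library: str,
    max_mismatches: int = 2,
    max_locations: int = 10,
    slop: int = 0,
    strand_aware: bool = True,
) -> LibraryCounts:
    """SAM/BAM -> filtered -> assigned -> normalized counts, in one call."""
    alignments = load_alignments(sam_path)
    kept, dropped = filter_alignments(alignments, max_mismatches, max_locations)
    raw, n_assigned = assign_tags(kept, sites, slop=slop, strand_aware=strand_aware)
    return normalize(raw, library, n_assigned_reads=n_assigned, n_filtered_reads=dropped)


def write_counts(
    counts: LibraryCounts, sites: Sequence[CCGGSite], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "raw": counts.raw,
            "normalized": counts.normalized,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# library={counts.library}\ttotal={counts.total:.6f}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_counts(path: str | Path) -> LibraryCounts:
    with open(path) as fh:
        header = fh.readline()
        library = header.split("library=")[1].split("\t")[0].strip()
        df = pd.read_csv(fh, sep="\t")
    raw = np.zeros(int(df["site_id"].max()) + 1)
    raw[df["site_id"].to_numpy()] = df["raw"].to_numpy()
    return normalize(raw, library)
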