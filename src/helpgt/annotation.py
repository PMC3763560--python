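"""Genomic annotation of called loci and between-sample statistics.

The genome is partitioned into promoter / exon / intron / intergenic
with precedence promoter > exon > intron (promoters are the 2 kb
windows centered on transcription start sites).  CpG context is island
/ shore / open sea, shores being the 2000 bp flanks on either side of
an island.  Distributions of called loci over these categories are
compared between samples with the pooled two-proportion z-test, and
samples are grouped by average-linkage hierarchical clustering of their
site-level angle measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .sites import CCGGSite, FeatureTrack, Transcript

CATEGORIES = ("promoter", "exon", "intron", "intergenic")
CPG_CONTEXTS = ("island", "shore", "open_sea")


@dataclass(frozen=True)
class SiteAnnotation:
    site_id: int
    category: str
    cpg_context: str
    tfbs: bool


@dataclass(frozen=True)
class ProportionTestResult:
    category: str
    p1: float
    p2: float
    n1: int
    n2: int
    z: float
    p_value: float


@dataclass
class SampleLinkage:
    """Average-linkage merge history over samples.

    ``merges`` lists (cluster_a, cluster_b, height, size) rows in scipy
    convention: original samples are clusters 0..n-1 and the i-th merge
    creates cluster n+i.
    """

    sample_names: List[str]
    merges: np.ndarray
    leaf_order: List[int]

    def newick(self) -> str:
        n = len(self.sample_names)
        nodes: Dict[int, str] = {i: self.sample_names[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + i] = h
        return nodes[n + len(self.merges) - 1] + ";"


class GenomePartition:
    """Exhaustive, exclusive base-level partition of the genome.

    Every base gets exactly one of promoter / exon / intron / intergenic,
    resolved by precedence promoter > exon > intron > intergenic.
    """

    def __init__(
        self,
        transcripts: Sequence[Transcript],
        promoter_halfwidth: int = 1000,
        contig_lengths: Dict[str, int] | None = None,
    ):
        self.promoter_halfwidth = promoter_halfwidth
        self._promoters: Dict[str, IntervalTree] = {}
        self._exons: Dict[str, IntervalTree] = {}
        self._genes: Dict[str, IntervalTree] = {}
        for t in transcripts:
            lo = t.tss - promoter_halfwidth
            hi = t.tss + promoter_halfwidth
            if contig_lengths and t.chrom in contig_lengths:
                lo = max(lo, 0)
                hi = min(hi, contig_lengths[t.chrom])
            else:
                lo = max(lo, 0)
            if lo < hi:
                self._promoters.setdefault(t.chrom, IntervalTree()).addi(lo, hi)
            self._genes.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
            for es, ee in t.exons:
                if es < ee:
                    self._exons.setdefault(t.chrom, IntervalTree()).addi(es, ee)

    def category_at(self, chrom: str, pos: int) -> str:
        if chrom in self._promoters and self._promoters[chrom].at(pos):
            return "promoter"
        if chrom in self._exons and self._exons[chrom].at(pos):
            return "exon"
        if chrom in self._genes and self._genes[chrom].at(pos):
            return "intron"
        return "intergenic"


def build_partition(
    transcripts: Sequence[Transcript],
    promoter_halfwidth: int = 1000,
    contig_lengths: Dict[str, int] | None = None,
) -> GenomePartition:
    return GenomePartition(transcripts, promoter_halfwidth, contig_lengths)


def _track_trees(track: FeatureTrack | None) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    if track is not None:
        for chrom, start, end in track.intervals:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def classify_sites(
    sites: Sequence[CCGGSite],
    partition: GenomePartition,
    cpg_islands: FeatureTrack | None = None,
    tfbs: FeatureTrack | None = None,
    shore_width: int = 2000,
) -> List[SiteAnnotation]:
    """Assign genomic category, CpG context and TFBS overlap per site.

    A site overlapping an island is "island"; otherwise, within
    ``shore_width`` of an island edge it is "shore"; otherwise open sea.
    """
    islands = _track_trees(cpg_islands)
    shores: Dict[str, IntervalTree] = {}
    if cpg_islands is not None:
        for chrom, start, end in cpg_islands.intervals:
            tree = shores.setdefault(chrom, IntervalTree())
            tree.addi(max(start - shore_width, 0), start)
            tree.addi(end, end + shore_width)
    tfbs_trees = _track_trees(tfbs)

    out = []
    for s in sites:
        category = partition.category_at(s.chrom, s.pos)
        if s.chrom in islands and islands[s.chrom].at(s.pos):
            context = "island"
        elif s.chrom in shores and shores[s.chrom].at(s.pos):
            context = "shore"
        else:
            context = "open_sea"
        in_tfbs = bool(s.chrom in tfbs_trees and tfbs_trees[s.chrom].at(s.pos))
        out.append(SiteAnnotation(s.site_id, category, context, in_tfbs))
    return out


def distribution(
    called_site_ids: Sequence[int], annotations: Sequence[SiteAnnotation]
) -> Dict[str, Dict[str, float]]:
    """Relative distribution of called loci over annotation categories.

    Returns three tables keyed "category", "cpg_context" and "tfbs",
    each mapping label -> proportion of calls (summing to 1).
    """
    if len(called_site_ids) == 0:
        raise ValueError("empty call set")
    by_id = {a.site_id: a for a in annotations}
    called = [by_id[sid] for sid in called_site_ids]
    n = len(called)
    tables: Dict[str, Dict[str, float]] = {
        "category": {c: 0.0 for c in CATEGORIES},
        "cpg_context": {c: 0.0 for c in CPG_CONTEXTS},
        "tfbs": {"tfbs": 0.0, "non_tfbs": 0.0},
    }
    for a in called:
        tables["category"][a.category] += 1
        tables["cpg_context"][a.cpg_context] += 1
        tables["tfbs"]["tfbs" if a.tfbs else "non_tfbs"] += 1
    for table in tables.values():
        for key in table:
            table[key] /= n
    return tables


def proportion_test(
    k1: int, n1: int, k2: int, n2: int, category: str = ""
) -> ProportionTestResult:
    """Two-sided pooled two-sample z-test for equal proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # degenerate 0/0 tables
        z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    if np.isnan(z):  # both proportions 0 or both 1: no difference
        z, p = 0.0, 1.0
    return ProportionTestResult(category, k1 / n1, k2 / n2, n1, n2, float(z), float(p))


def proportion_tests_table(
    counts1: Dict[str, int],
    total1: int,
    counts2: Dict[str, int],
    total2: int,
    bh_correction: bool = True,
) -> pd.DataFrame:
    """Per-category proportion tests between two samples.

    Raw two-sided p-values, optionally with a Benjamini-Hochberg
    adjusted column.
    """
    rows = []
    for cat in sorted(set(counts1) | set(counts2)):
        r = proportion_test(counts1.get(cat, 0), total1, counts2.get(cat, 0), total2, cat)
        rows.append(
            {
                "category": cat,
                "p1": r.p1,
                "p2": r.p2,
                "n1": r.n1,
                "n2": r.n2,
                "z": r.z,
                "p_value": r.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if bh_correction and len(df):
        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def cluster_samples(
    matrix: np.ndarray,
    sample_names: Sequence[str],
    metric: str = "euclidean",
) -> SampleLinkage:
    """Average-linkage clustering of samples (columns of ``matrix``).

    ``matrix`` is sites x samples; rows containing NaN (sites not
    covered in every sample) are dropped first.  ``metric`` is
    "euclidean" or "correlation" (1 - Pearson).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != len(sample_names):
        raise ValueError("matrix must be sites x samples with one column per name")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    shared = matrix[~np.isnan(matrix).any(axis=1)]
    if shared.shape[0] == 0:
        raise ValueError("no sites covered in all samples")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    dists = pdist(shared.T, metric=metric)
    merges = linkage(dists, method="average")
    order = [int(i) for i in leaves_list(merges)]
    return SampleLinkage(list(sample_names), merges, order)


def write_linkage(link: SampleLinkage, prefix: str) -> dict:
    paths = {"newick": f"{prefix}.nwk", "merges": f"{prefix}.merges.tsv"}
    with open(paths["newick"], "w") as fh:
        fh.write(link.newick() + "\n")
    pd.DataFrame(
        link.merges, columns=["cluster_a", "cluster_b", "height", "size"]
    ).to_csv(paths["merges"], sep="\t", index=False)
    return paths
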