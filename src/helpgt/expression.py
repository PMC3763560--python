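"""Integration of site-level 5-hmC / 5-mC with gene expression.

Genes are binned by expression (low/high at the 10th/90th percentiles,
or quartiles), site scores are averaged in 10-bp bins around the TSS or
TES to form strand-oriented metagene profiles with 95% confidence
intervals, and per-gene mean modification levels are regressed on
expression (hmC/mC = beta0 + beta1 * X) over the proximal (TSS +/- 1 kb)
or intragenic (TSS to TES) region.  Affinity-pulldown qPCR validation
is summarized as fold enrichment 2^(Input - Pulldown) relative to a
control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import SiteScore
from .sites import CCGGSite, Transcript

logger = logging.getLogger(__name__)

REGIONS = ("proximal", "intragenic")


@dataclass
class MetaProfile:
    """Binned mean site values around an anchor, strand-oriented.

    ``offsets`` are bin left edges relative to the anchor (upstream
    negative); bins are half-open ``[offset, offset + bin_width)``.
    """

    anchor: str
    bin_width: int
    offsets: np.ndarray
    mean_value: np.ndarray
    ci95_halfwidth: np.ndarray
    n_sites: np.ndarray
    expression_bin: str


@dataclass(frozen=True)
class RegressionResult:
    beta0: float
    beta1: float
    p_value: float
    region: str
    n_genes: int


@dataclass(frozen=True)
class QpcrMeasurement:
    locus: str
    input_ct: float
    pulldown_ct: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.input_ct) and math.isfinite(self.pulldown_ct)):
            raise ValueError(f"{self.locus}: Ct values must be finite")


def load_expression(path: str | Path) -> Dict[str, float]:
    """TSV of gene_id, expression value (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_id", "value"])
    if df.iloc[0]["gene_id"] in ("gene_id", "gene"):  # header row
        df = df.iloc[1:]
    return {str(g): float(v) for g, v in zip(df["gene_id"], df["value"])}


def expression_bins(expression: Dict[str, float], mode: str = "decile") -> Dict[str, str]:
    """Bin genes by expression level.

    ``decile`` labels genes at or below the 10th percentile "low" and at
    or above the 90th percentile "high" (other genes unlabeled);
    ``quartile`` labels every gene Q1..Q4 by the quartile ranges
    0-25 / 26-50 / 51-75 / 76-100, boundary-inclusive.  Percentiles use
    the linear-interpolation definition.
    """
    values = np.array(list(expression.values()), dtype=float)
    if mode == "decile":
        if len(values) < 10:
            raise ValueError("decile binning needs at least 10 genes")
        p10, p90 = np.percentile(values, [10, 90])
        if p10 == p90:
            logger.warning("degenerate expression distribution: empty low/high bins")
            return {}
        return {
            g: ("low" if v <= p10 else "high")
            for g, v in expression.items()
            if v <= p10 or v >= p90
        }
    if mode == "quartile":
        if len(values) < 4:
            raise ValueError("quartile binning needs at least 4 genes")
        p25, p50, p75 = np.percentile(values, [25, 50, 75])
        out = {}
        for g, v in expression.items():
            if v <= p25:
                out[g] = "Q1"
            elif v <= p50:
                out[g] = "Q2"
            elif v <= p75:
                out[g] = "Q3"
            else:
                out[g] = "Q4"
        return out
    raise ValueError(f"unknown binning mode {mode!r}")


def _site_values(
    scores: Sequence[SiteScore], sites: Sequence[CCGGSite], value: str
) -> Dict[str, tuple]:
    """Per-chromosome sorted (positions, values) arrays for covered sites."""
    by_id = {s.site_id: s for s in sites}
    per_chrom: Dict[str, list] = {}
    for sc in scores:
        if not sc.covered:
            continue
        if value == "call_5hmc":
            v = float(sc.is_5hmc)
        elif value == "call_5mc":
            v = float(sc.is_5mc)
        else:
            v = getattr(sc, value)
        site = by_id[sc.site_id]
        per_chrom.setdefault(site.chrom, []).append((site.pos, v))
    out = {}
    for chrom, pairs in per_chrom.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs])
        vals = np.array([v for _, v in pairs])
        out[chrom] = (pos, vals)
    return out


def metaprofile(
    scores: Sequence[SiteScore],
    sites: Sequence[CCGGSite],
    transcripts: Sequence[Transcript],
    gene_bins: Dict[str, str],
    anchor: str = "TSS",
    window: int = 2000,
    bin_width: int = 10,
    value: str = "score_5hmc",
) -> Dict[str, MetaProfile]:
    """Strand-oriented binned profiles of site values around TSS or TES.

    Returns one MetaProfile per expression-bin label.  Bins span
    [-window, window) in ``bin_width`` steps; upstream is negative in
    the gene's reading direction.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    if window % bin_width != 0:
        raise ValueError("window must be divisible by bin_width")
    n_bins = 2 * window // bin_width
    offsets = np.arange(-window, window, bin_width)
    per_chrom = _site_values(scores, sites, value)

    sums: Dict[str, np.ndarray] = {}
    sumsq: Dict[str, np.ndarray] = {}
    counts: Dict[str, np.ndarray] = {}
    for t in transcripts:
        label = gene_bins.get(t.gene_id)
        if label is None or t.chrom not in per_chrom:
            continue
        if label not in sums:
            sums[label] = np.zeros(n_bins)
            sumsq[label] = np.zeros(n_bins)
            counts[label] = np.zeros(n_bins, dtype=int)
        pos, vals = per_chrom[t.chrom]
        a = t.tss if anchor == "TSS" else t.tes
        lo, hi = np.searchsorted(pos, [a - window, a + window])
        for p, v in zip(pos[lo:hi], vals[lo:hi]):
            d = p - a if t.strand == "+" else a - p
            if -window <= d < window:
                b = (d + window) // bin_width
                sums[label][b] += v
                sumsq[label][b] += v * v
                counts[label][b] += 1

    profiles = {}
    for label in sums:
        n = counts[label]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, sums[label] / np.maximum(n, 1), np.nan)
            var = np.where(
                n > 1,
                (sumsq[label] - sums[label] ** 2 / np.maximum(n, 1)) / np.maximum(n - 1, 1),
                0.0,
            )
            sem = np.where(n > 0, np.sqrt(np.maximum(var, 0) / np.maximum(n, 1)), np.nan)
        profiles[label] = MetaProfile(
            anchor, bin_width, offsets, mean, 1.96 * sem, n, label
        )
    return profiles


def write_profiles(profiles: Dict[str, MetaProfile], path: str | Path) -> None:
    rows = []
    for label, p in profiles.items():
        for o, m, ci, n in zip(p.offsets, p.mean_value, p.ci95_halfwidth, p.n_sites):
            rows.append(
                {"expression_bin": label, "anchor": p.anchor, "offset": int(o),
                 "mean": m, "ci95_halfwidth": ci, "n_sites": int(n)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def regress(
    scores: Sequence[SiteScore],
    sites: Sequence[CCGGSite],
    transcripts: Sequence[Transcript],
    expression: Dict[str, float],
    region: str = "proximal",
    value: str = "score_5hmc",
    proximal_halfwidth: int = 1000,
    log2_expression: bool = False,
) -> RegressionResult:
    """OLS of per-gene mean modification level on expression X.

    The per-gene response is the mean site value over covered sites in
    the region (proximal: TSS +/- 1 kb; intragenic: TSS to TES); genes
    with no covered site in the region are dropped.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    per_chrom = _site_values(scores, sites, value)
    ys, xs = [], []
    for t in transcripts:
        if t.gene_id not in expression or t.chrom not in per_chrom:
            continue
        if region == "proximal":
            lo, hi = t.tss - proximal_halfwidth, t.tss + proximal_halfwidth
        else:
            lo, hi = t.start, t.end
        pos, vals = per_chrom[t.chrom]
        i, j = np.searchsorted(pos, [lo, hi])
        if j > i:
            ys.append(vals[i:j].mean())
            x = expression[t.gene_id]
            xs.append(math.log2(x + 1) if log2_expression else x)
    if len(xs) < 3:
        raise ValueError("fewer than 3 genes with covered sites in the region")
    xs_arr = np.array(xs)
    if np.allclose(xs_arr, xs_arr[0]):
        raise ValueError("expression has no variance across genes")
    fit = stats.linregress(xs_arr, np.array(ys))
    return RegressionResult(
        float(fit.intercept), float(fit.slope), float(fit.pvalue), region, len(xs)
    )


def qpcr_fold_enrichment(sample: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Fold enrichment 2^(Input - Pulldown)_sample / 2^(Input - Pulldown)_control."""
    return 2.0 ** (sample.input_ct - sample.pulldown_ct) / 2.0 ** (
        control.input_ct - control.pulldown_ct
    )


def load_qpcr(path: str | Path) -> List[QpcrMeasurement]:
    """TSV of locus, input Ct, pulldown Ct."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return [
        QpcrMeasurement(str(r.iloc[0]), float(r.iloc[1]), float(r.iloc[2]))
        for _, r in df.iterrows()
    ]
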