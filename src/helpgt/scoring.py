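"""Arctangent methylation scoring and 5-mC / 5-hmC calling.

For each CCGG site the normalized MspI count goes on the x-axis and the
normalized count of the modification-sensitive library on the y-axis;
the angle of that point, atan2(y, x) in degrees, measures how much of
the MspI representation survives the sensitive digest.  A fully
protected (modified) site has y = 0 and angle 0; an unprotected site
with balanced representation sits at 45 degrees.

Calls:

* 5-mC: HpaII/MspI angle strictly below ``t_mc`` (default 20 degrees).
* 5-hmC: (beta-GT+MspI)/MspI angle strictly below ``t_hmc`` (default
  50 degrees) AND normalized GT count strictly greater than the HpaII
  count, AND (by default) the site is also called 5-mC.  Glucosylation
  of 5-hmC blocks MspI, so hydroxymethylated sites lose GT+MspI tags
  while retaining MspI tags.

For display, angles map affinely to a 0-100 scale, 100 * (1 - angle/90):
0 means no modification, 100 complete modification.

Sites with zero normalized MspI count are not covered and carry no
calls: an MspI dropout is a data absence, not a biological state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .counting import LibraryCounts
from .sites import CCGGSite


@dataclass(frozen=True)
class CallThresholds:
    """Angle cutoffs (degrees) and stringency flags for locus calling."""

    t_mc: float = 20.0
    t_hmc: float = 50.0
    require_methylated: bool = True
    require_gt_exceeds_hpaii: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.t_mc < 90) or not (0 < self.t_hmc < 90):
            raise ValueError("thresholds must lie strictly between 0 and 90 degrees")


DEFAULT_THRESHOLDS = CallThresholds()


@dataclass
class SiteScore:
    site_id: int
    covered: bool
    angle_hpaii: float = math.nan
    angle_gt: float = math.nan
    is_5mc: bool = False
    is_5hmc: bool = False

    @property
    def score_5mc(self) -> float:
        return 100.0 * (1.0 - self.angle_hpaii / 90.0)

    @property
    def score_5hmc(self) -> float:
        return 100.0 * (1.0 - self.angle_gt / 90.0)


def angle(y_norm: float, x_norm: float) -> float:
    """Angle in degrees of the point (x, y) in the first quadrant.

    Undefined (ValueError) when both inputs are zero.
    """
    if y_norm < 0 or x_norm < 0:
        raise ValueError("normalized counts must be non-negative")
    if y_norm == 0 and x_norm == 0:
        raise ValueError("angle undefined at (0, 0): site not covered")
    return math.degrees(math.atan2(y_norm, x_norm))


def call_5mc(angle_hpaii: float, thresholds: CallThresholds = DEFAULT_THRESHOLDS) -> bool:
    """A site is 5-mC when the HpaII/MspI angle is strictly below the cutoff."""
    return angle_hpaii < thresholds.t_mc


def call_5hmc(
    angle_gt: float,
    gt_norm: float,
    hpaii_norm: float,
    is_5mc: bool,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Dual-criteria 5-hmC call.

    Criterion 1: GT/MspI angle strictly below ``t_hmc``.
    Criterion 2 (stringency): normalized GT count strictly greater than
    the normalized HpaII count.
    Optionally the site must also carry a 5-mC call.
    """
    if angle_gt >= thresholds.t_hmc:
        return False
    if thresholds.require_gt_exceeds_hpaii and not (gt_norm > hpaii_norm):
        return False
    if thresholds.require_methylated and not is_5mc:
        return False
    return True


def score_sites(
    hpaii: LibraryCounts,
    mspi: LibraryCounts,
    gt: LibraryCounts,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> List[SiteScore]:
    """Score and call every site covered by the MspI library."""
    n = mspi.n_sites
    if hpaii.n_sites != n or gt.n_sites != n:
        raise ValueError("count tables cover different site catalogs")
    scores: List[SiteScore] = []
    for sid in range(n):
        x = mspi.normalized[sid]
        if x <= 0:
            scores.append(SiteScore(sid, covered=False))
            continue
        a_h = angle(hpaii.normalized[sid], x)
        a_g = angle(gt.normalized[sid], x)
        mc = call_5mc(a_h, thresholds)
        hmc = call_5hmc(a_g, gt.normalized[sid], hpaii.normalized[sid], mc, thresholds)
        scores.append(SiteScore(sid, True, a_h, a_g, mc, hmc))
    return scores


def summarize_calls(scores: Sequence[SiteScore]) -> dict:
    covered = [s for s in scores if s.covered]
    return {
        "n_sites": len(scores),
        "n_covered": len(covered),
        "n_5mc": sum(s.is_5mc for s in covered),
        "n_5hmc": sum(s.is_5hmc for s in covered),
    }


def write_scores(
    scores: Sequence[SiteScore], sites: Sequence[CCGGSite], prefix: str | Path
) -> dict:
    """Write bedGraph tracks (0-100 scores) and BED call files.

    Produces ``<prefix>.5mc.bedGraph``, ``<prefix>.5hmc.bedGraph``,
    ``<prefix>.5mc_calls.bed``, ``<prefix>.5hmc_calls.bed`` and
    ``<prefix>.scores.tsv``.  Returns the path map.
    """
    prefix = str(prefix)
    by_id = {s.site_id: s for s in sites}
    paths = {
        "bedgraph_5mc": f"{prefix}.5mc.bedGraph",
        "bedgraph_5hmc": f"{prefix}.5hmc.bedGraph",
        "calls_5mc": f"{prefix}.5mc_calls.bed",
        "calls_5hmc": f"{prefix}.5hmc_calls.bed",
        "table": f"{prefix}.scores.tsv",
    }
    with open(paths["bedgraph_5mc"], "w") as f_mc, open(
        paths["bedgraph_5hmc"], "w"
    ) as f_hmc:
        for sc in scores:
            if not sc.covered:
                continue
            site = by_id[sc.site_id]
            f_mc.write(f"{site.chrom}\t{site.pos}\t{site.pos + 4}\t{sc.score_5mc:.2f}\n")
            f_hmc.write(f"{site.chrom}\t{site.pos}\t{site.pos + 4}\t{sc.score_5hmc:.2f}\n")
    for key, flag in (("calls_5mc", "is_5mc"), ("calls_5hmc", "is_5hmc")):
        with open(paths[key], "w") as fh:
            fh.write(f"# helpgt {key.split('_')[1]} loci\n")
            for sc in scores:
                if sc.covered and getattr(sc, flag):
                    site = by_id[sc.site_id]
                    fh.write(f"{site.chrom}\t{site.pos}\t{site.pos + 4}\t{sc.site_id}\n")
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in scores],
            "covered": [int(s.covered) for s in scores],
            "angle_hpaii": [s.angle_hpaii for s in scores],
            "angle_gt": [s.angle_gt for s in scores],
            "score_5mc": [s.score_5mc if s.covered else np.nan for s in scores],
            "score_5hmc": [s.score_5hmc if s.covered else np.nan for s in scores],
            "is_5mc": [int(s.is_5mc) for s in scores],
            "is_5hmc": [int(s.is_5hmc) for s in scores],
        }
    )
    df.to_csv(paths["table"], sep="\t", index=False, float_format="%.6f")
    return paths


def read_scores(path: str | Path) -> List[SiteScore]:
    """Read back a ``.scores.tsv`` table written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        covered = bool(row.covered)
        out.append(
            SiteScore(
                int(row.site_id),
                covered,
                float(row.angle_hpaii) if covered else math.nan,
                float(row.angle_gt) if covered else math.nan,
                bool(row.is_5mc),
                bool(row.is_5hmc),
            )
        )
    return out
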