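"""Relate 5-hmC levels to gene expression: metaprofiles and regression.

Constructs genes over a simulated contig whose promoter-region
hydroxymethylation is made to track expression, bins genes at the
10th/90th expression percentiles, builds 10-bp TSS metaprofiles for the
two bins, and fits the linear model hmC = beta0 + beta1 * X over the
proximal (TSS +/- 1 kb) region.
"""

import numpy as np

from helpgt import expression, scoring
from helpgt.sites import _make_transcript, find_ccgg_sites

RNG = np.random.default_rng(9)


def main() -> None:
    # one CCGG every 100 bp; hmC score near each gene's TSS follows expression
    genome = {"chr1": ("A" * 96 + "CCGG") * 2000}
    sites = find_ccgg_sites(genome)
    genes, expr = [], {}
    for i in range(60):
        start = 2096 + i * 3200  # TSS on a site, genes well separated
        genes.append(_make_transcript(f"g{i}", "chr1", "+", start, start + 2500,
                                      [(start, start + 2500)]))
        expr[f"g{i}"] = float(RNG.uniform(0, 10))

    tss_level = {g.tss: 5.0 + 8.0 * expr[g.gene_id] for g in genes}
    scores = []
    for s in sites:
        near = [v for t, v in tss_level.items() if abs(s.pos - t) <= 1000]
        level = near[0] + RNG.normal(0, 2.0) if near else RNG.uniform(0, 5)
        level = float(np.clip(level, 0, 100))
        scores.append(scoring.SiteScore(s.site_id, True, 45.0, 90 * (1 - level / 100)))

    bins = expression.expression_bins(expr, mode="decile")
    profiles = expression.metaprofile(scores, sites, genes, bins, anchor="TSS")
    for label, p in sorted(profiles.items()):
        core = slice(190, 210)  # bins within ~100 bp of the TSS
        mean = np.nanmean(p.mean_value[core])
        print(f"{label}-expression genes: mean 5-hmC score near TSS = {mean:.1f} "
              f"({int(p.n_sites.sum())} sites in the 4 kb window)")

    r = expression.regress(scores, sites, genes, expr, region="proximal")
    print(f"proximal regression: hmC = {r.beta0:.2f} + {r.beta1:.2f} * X, "
          f"p = {r.p_value:.2g} over {r.n_genes} genes")
    print("(a positive slope means more promoter 5-hmC on highly expressed genes)")


if __name__ == "__main__":
    main()
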