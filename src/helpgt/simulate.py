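"""Digest simulator: synthetic genomes, methylation states and libraries.

The enzymatic model: HpaII cuts CCGG only when the site is unmodified
(both 5-mC and 5-hmC block it); MspI cuts regardless of cytosine
modification; beta-GT transfers a glucosyl group onto 5-hmC, and the
glucosylated site resists MspI.  A site whose alleles are a mixture of
fractions (u, m, h) of unmethylated / 5-mC / 5-hmC therefore yields
expected cut weights

    w_HpaII = u        w_MspI = 1        w_GT+MspI = u + m

(scaled by an optional glucosylation efficiency on the h term).  Each
library's tags are allocated across sites by a multinomial on these
weights, and tags are 27-base genomic sequences anchored at the cut:
starting at ``pos+1`` on the plus strand, ending at ``pos+2`` (reading
leftward) on the minus strand.  Sites can be planted in duplicated
sequence context to exercise fractional (1/n) multi-mapping counting.

All randomness flows through the single config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml

from . import scoring
from .counting import LIBRARIES, LibraryCounts
from .sites import CCGGSite, GenomeSequence, find_ccgg_sites

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SiteMethylationState:
    """Ground-truth allele fractions at one site: u + m + h = 1."""

    site_id: int
    u: float
    m: float
    h: float

    def __post_init__(self) -> None:
        if min(self.u, self.m, self.h) < 0 or abs(self.u + self.m + self.h - 1) > 1e-9:
            raise ValueError(
                f"site {self.site_id}: (u, m, h) must be non-negative and sum to 1"
            )


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults model a mostly unmethylated genome in which 10% of CCGG
    sites are fully methylated and 10% carry a 30/70 5-mC/5-hmC allele
    mixture, sequenced to a mean depth of 1000 tags per site -- deep
    enough that normalized counts are close to their expectations.
    """

    seed: int
    n_contigs: int = 1
    contig_length: int = 500_000
    gc_fraction: float = 0.45
    planted_site_spacing: int = 100
    state_mixture: List[Tuple[float, Tuple[float, float, float]]] = field(
        default_factory=lambda: [
            (0.8, (1.0, 0.0, 0.0)),
            (0.1, (0.0, 1.0, 0.0)),
            (0.1, (0.0, 0.3, 0.7)),
        ]
    )
    mean_depth: float = 1000.0
    read_length: int = 27
    multimap_fraction: float = 0.0
    gt_efficiency: float = 1.0
    sequencing_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.planted_site_spacing < 8:
            raise ValueError("planted_site_spacing must be >= 8")
        props = [p for p, _ in self.state_mixture]
        if any(not (0 <= p <= 1) for p in props) or abs(sum(props) - 1) > 1e-9:
            raise ValueError("state_mixture proportions must lie in [0,1] and sum to 1")
        if not 0 <= self.multimap_fraction <= 1:
            raise ValueError("multimap_fraction must lie in [0,1]")


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "state_mixture" in data:
        data["state_mixture"] = [(p, tuple(s)) for p, s in data["state_mixture"]]
    return SimulationConfig(**data)


def expected_weights(
    state: SiteMethylationState, gt_efficiency: float = 1.0
) -> Tuple[float, float, float]:
    """Expected cut weights (w_HpaII, w_MspI, w_GT+MspI) for one site.

    HpaII cuts only the unmodified fraction; MspI cuts everything;
    glucosylated 5-hmC resists MspI, so the GT library sees u + m plus
    any unglucosylated 5-hmC.
    """
    w_gt = state.u + state.m + (1.0 - gt_efficiency) * state.h
    return (state.u, 1.0, w_gt)


@dataclass
class SimulatedGenome:
    genome: GenomeSequence
    sites: List[CCGGSite]
    twin_of: Dict[int, int]  # site_id -> duplicated-context partner


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedGenome:
    """Random genome with CCGG sites planted at regular spacing.

    Spurious CCGG motifs arising in the random background are scrubbed
    (one C mutated to A, which can never create a new motif), so the
    site catalog equals the planted positions exactly.  A
    ``multimap_fraction`` of planted sites is paired into twins whose
    local sequence context is copied verbatim, making their tags
    ambiguous between the two locations.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    margin = config.read_length + 5
    genome: GenomeSequence = {}
    planted: List[Tuple[str, int]] = []
    bases = np.array(list("ACGT"))
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for c in range(config.n_contigs):
        chrom = f"chr{c + 1}"
        seq = rng.choice(bases, size=config.contig_length, p=probs)
        positions = list(
            range(
                config.planted_site_spacing,
                config.contig_length - margin - 4,
                config.planted_site_spacing,
            )
        )
        for p in positions:
            seq[p : p + 4] = list("CCGG")
            planted.append((chrom, p))
        text = "".join(seq)
        planted_here = {p for ch, p in planted if ch == chrom}
        # scrub spurious motifs; CCGG cannot overlap itself so planted
        # windows are never touched
        out = list(text)
        i = text.find("CCGG")
        while i != -1:
            if i not in planted_here:
                out[i] = "A"
            i = text.find("CCGG", i + 1)
        genome[chrom] = "".join(out)

    # duplicated-context twins
    twin_pairs: List[Tuple[Tuple[str, int], Tuple[str, int]]] = []
    n_dup = int(round(config.multimap_fraction * len(planted)))
    n_dup -= n_dup % 2
    if n_dup:
        chosen = rng.choice(len(planted), size=n_dup, replace=False)
        chosen = sorted(int(i) for i in chosen)
        for a_idx, b_idx in zip(chosen[::2], chosen[1::2]):
            (ca, pa), (cb, pb) = planted[a_idx], planted[b_idx]
            lo, hi = 30, config.read_length + 31
            src = genome[ca][pa - lo : pa + hi]
            s = genome[cb]
            genome[cb] = s[: pb - lo] + src + s[pb + hi :]
            twin_pairs.append(((ca, pa), (cb, pb)))
        # copying may have created motifs at window junctions; rescrub
        # outside planted positions (junction bases lie outside all tags)
        for chrom in genome:
            planted_here = {p for ch, p in planted if ch == chrom}
            text = genome[chrom]
            out = list(text)
            i = text.find("CCGG")
            while i != -1:
                if i not in planted_here:
                    out[i] = "A"
                i = text.find("CCGG", i + 1)
            genome[chrom] = "".join(out)

    sites = find_ccgg_sites(genome)
    site_ids = {(s.chrom, s.pos): s.site_id for s in sites}
    if set(site_ids) != set(planted):
        raise AssertionError("site catalog does not match planted positions")
    twin_of: Dict[int, int] = {}
    for a, b in twin_pairs:
        ia, ib = site_ids[a], site_ids[b]
        twin_of[ia] = ib
        twin_of[ib] = ia
    return SimulatedGenome(genome, sites, twin_of)


def assign_states(
    n_sites: int, config: SimulationConfig, rng: np.random.Generator | None = None
) -> List[SiteMethylationState]:
    """Draw each site's (u, m, h) class from the configured mixture."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    props = np.array([p for p, _ in config.state_mixture])
    classes = rng.choice(len(props), size=n_sites, p=props)
    return [
        SiteMethylationState(i, *config.state_mixture[k][1])
        for i, k in enumerate(classes)
    ]


def weight_matrix(
    states: Sequence[SiteMethylationState], gt_efficiency: float = 1.0
) -> Dict[str, np.ndarray]:
    ws = np.array([expected_weights(s, gt_efficiency) for s in states])
    return {"HpaII": ws[:, 0], "MspI": ws[:, 1], "GT_MspI": ws[:, 2]}


def simulate_counts(
    states: Sequence[SiteMethylationState],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Dict[str, np.ndarray]:
    """Multinomial tag counts per library: total = mean_depth * n_sites."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    weights = weight_matrix(states, config.gt_efficiency)
    total = int(round(config.mean_depth * len(states)))
    counts = {}
    for lib in LIBRARIES:
        w = weights[lib]
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError(f"library {lib}: all cut weights are zero")
        counts[lib] = rng.multinomial(total, w / wsum)
    return counts


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> Tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = list(seq)
    n_err = 0
    for i in range(len(arr)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
            n_err += 1
    return "".join(arr), n_err


def emit_tags(
    sim: SimulatedGenome,
    counts: Dict[str, np.ndarray],
    config: SimulationConfig,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
    write_fastq: bool = False,
) -> Dict[str, str]:
    """Write one SAM (optionally FASTQ) per library from sampled counts.

    Each tag is the ``read_length``-base genomic sequence anchored at
    the cut, on a uniformly random strand.  A tag at a duplicated-
    context site is reported at both twin locations (NH=2, one record
    secondary), so fractional counting assigns 1/2 to each.  Tags that
    would run off the contig end are skipped with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = config.read_length
    header_lines = ["@HD\tVN:1.6\tSO:unknown"] + [
        f"@SQ\tSN:{chrom}\tLN:{len(seq)}" for chrom, seq in sim.genome.items()
    ]
    paths = {}
    for lib in LIBRARIES:
        sam_path = out_dir / f"{lib}.sam"
        fq_path = out_dir / f"{lib}.fastq"
        paths[lib] = str(sam_path)
        fq = open(fq_path, "w") if write_fastq else None
        with open(sam_path, "w") as sam:
            sam.write("\n".join(header_lines) + "\n")
            tag_no = 0
            for site in sim.sites:
                c = int(counts[lib][site.site_id])
                if c == 0:
                    continue
                seq_len = len(sim.genome[site.chrom])
                if site.pos + 1 + L > seq_len or site.pos + 3 - L < 0:
                    logger.warning(
                        "site %d at %s:%d too close to contig end; skipped",
                        site.site_id, site.chrom, site.pos,
                    )
                    continue
                locations = [site]
                if site.site_id in sim.twin_of:
                    twin = sim.sites[sim.twin_of[site.site_id]]
                    locations.append(twin)
                nh = len(locations)
                for _ in range(c):
                    minus = bool(rng.random() < 0.5)
                    name = f"{lib}_t{tag_no}"
                    tag_no += 1
                    if minus:
                        ref_start = site.pos + 3 - L
                        ref_seq = sim.genome[site.chrom][ref_start : site.pos + 3]
                        read_seq = revcomp(ref_seq)
                    else:
                        ref_start = site.pos + 1
                        ref_seq = sim.genome[site.chrom][ref_start : ref_start + L]
                        read_seq = ref_seq
                    read_seq, n_err = _apply_errors(
                        read_seq, config.sequencing_error_rate, rng
                    )
                    stored = revcomp(read_seq) if minus else read_seq
                    for k, loc in enumerate(locations):
                        flag = (16 if minus else 0) | (256 if k > 0 else 0)
                        pos1 = (loc.pos + 3 - L if minus else loc.pos + 1) + 1
                        sam.write(
                            f"{name}\t{flag}\t{loc.chrom}\t{pos1}\t255\t{L}M\t*\t0\t0\t"
                            f"{stored}\t{'I' * L}\tNH:i:{nh}\tNM:i:{n_err}\n"
                        )
                    if fq:
                        fq.write(f"@{name}\n{read_seq}\n+\n{'I' * L}\n")
        if fq:
            fq.close()
            paths[f"{lib}_fastq"] = str(fq_path)
    return paths


def _normalized_or_zero(w: np.ndarray) -> np.ndarray:
    total = w.sum()
    return w / total if total > 0 else np.zeros_like(w)


def truth_calls(
    states: Sequence[SiteMethylationState],
    thresholds: scoring.CallThresholds = scoring.DEFAULT_THRESHOLDS,
    gt_efficiency: float = 1.0,
) -> List[scoring.SiteScore]:
    """Deterministic calls from noiseless expected weights.

    Applies the scoring rule to the per-library expected cut weights,
    each normalized over the whole site ensemble -- the limit the
    sampled pipeline must converge to at high depth.
    """
    weights = weight_matrix(states, gt_efficiency)
    norm = {lib: _normalized_or_zero(weights[lib]) for lib in LIBRARIES}
    out = []
    for i in range(len(states)):
        x = norm["MspI"][i]
        if x <= 0:
            out.append(scoring.SiteScore(i, covered=False))
            continue
        a_h = scoring.angle(norm["HpaII"][i], x)
        a_g = scoring.angle(norm["GT_MspI"][i], x)
        mc = scoring.call_5mc(a_h, thresholds)
        hmc = scoring.call_5hmc(
            a_g, norm["GT_MspI"][i], norm["HpaII"][i], mc, thresholds
        )
        out.append(scoring.SiteScore(i, True, a_h, a_g, mc, hmc))
    return out


def counts_to_libraries(counts: Dict[str, np.ndarray]) -> Dict[str, LibraryCounts]:
    """Wrap sampled count arrays as normalized LibraryCounts."""
    return {
        lib: LibraryCounts(lib, counts[lib].astype(float), float(counts[lib].sum()))
        for lib in LIBRARIES
    }


def write_truth(states: Sequence[SiteMethylationState], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tu\tm\th\n")
        for s in states:
            fh.write(f"{s.site_id}\t{s.u:.6g}\t{s.m:.6g}\t{s.h:.6g}\n")
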