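"""Group samples by similarity of their 5-hmC angle measurements.

Simulates two biological conditions (different hmC site fractions) with
two replicates of the first, scores each, and clusters the three
samples by average linkage on their GT/MspI angles over shared covered
sites.  Replicates of the same condition merge first.
"""

import numpy as np

from helpgt import annotation, scoring, simulate


def sample_angles(seed, hmc_fraction):
    mixture = [
        (0.9 - hmc_fraction, (1.0, 0.0, 0.0)),
        (0.1, (0.0, 1.0, 0.0)),
        (hmc_fraction, (0.0, 0.3, 0.7)),
    ]
    cfg = simulate.SimulationConfig(
        seed=seed, contig_length=100_000, mean_depth=200, state_mixture=mixture
    )
    rng = np.random.default_rng(cfg.seed)
    sim = simulate.simulate_genome(cfg, rng)
    states = simulate.assign_states(len(sim.sites), cfg, rng)
    libs = simulate.counts_to_libraries(simulate.simulate_counts(states, cfg, rng))
    scores = scoring.score_sites(libs["HpaII"], libs["MspI"], libs["GT_MspI"])
    return np.array([s.angle_gt if s.covered else np.nan for s in scores])


def main() -> None:
    # identical genomes (same seed for the genome-shaping rng) are not
    # needed: angles are per-site and the contigs share the site grid
    matrix = np.column_stack([
        sample_angles(5, 0.10),
        sample_angles(6, 0.10),
        sample_angles(7, 0.45),
    ])
    names = ["control_rep1", "control_rep2", "high_hmc"]
    link = annotation.cluster_samples(matrix, names, metric="euclidean")
    print("merge history (average linkage, Euclidean over shared sites):")
    n = len(names)
    for i, (a, b, h, size) in enumerate(link.merges):
        print(f"  step {i + 1}: clusters {int(a)} + {int(b)} at height {h:.1f} "
              f"({int(size)} samples)")
    print("newick:", link.newick())
    print("(the two control replicates merge before the high-hmC sample joins)")


if __name__ == "__main__":
    main()
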